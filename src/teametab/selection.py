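"""Stage-discriminatory feature selection and arm-differential testing.

The processing stages form an ordered response (picking first, roasting
last), encoded as equally spaced integers 0..k-1.  A random-forest
regression of stage on the feature matrix gives a model-level OOB R2 and a
per-feature %IncMSE importance; significance of both comes from refitting
the forest under permuted responses:

* model p-value: fraction of permuted-response refits whose R2 reaches
  the observed R2 (add-one formulation, so p >= 1/(n_perm+1));
* per-feature p-value: for each feature, the fraction of those same
  permuted refits in which its importance reaches its observed
  importance.

Permuted refits default to a reduced tree count so a 3000-permutation run
stays tractable; the selected set is all features with p below alpha.

Arm comparisons (4 h vs overnight oxidation branches) use per-feature
Welch's t-tests with Benjamini-Hochberg FDR control and a direction split
by the sign of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binning import FeatureMatrix
from .errors import DegenerateTestError, EmptyInputError, InvalidDesignError
from .forest import ForestFit, fit_forest


@dataclass
class RFConfig:
    """Random-forest selection parameters.

    ``n_trees_null`` is the (reduced) forest size used for every
    permuted-response refit; set it equal to ``n_trees`` when observed
    and null importances must be exchangeable (calibration studies).
    """

    seed: int
    n_trees: int = 1000
    max_features: object = "third"  # floor(p/3), the regression convention
    n_permutations: int = 3000
    n_trees_null: int | None = 200
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_trees_null is None:
            self.n_trees_null = self.n_trees


@dataclass
class RFSelection:
    """Model quality plus per-feature importance and permutation p-values."""

    model_r2: float
    model_p: float
    importance: pd.DataFrame  # columns inc_mse, p_value, selected
    null_r2: np.ndarray
    config: RFConfig
    fit: ForestFit = None

    @property
    def selected(self) -> list[str]:
        return list(self.importance.index[self.importance["selected"]])


def encode_stage_response(
    sample_table: pd.DataFrame,
    stage_order: list[str],
    arm: str | None = None,
) -> pd.Series:
    """Ordinal stage response per sample (0 for the first stage).

    QC samples are dropped.  With ``arm`` given, only samples whose arm
    is unset (shared early stages) or equals ``arm`` are kept.
    """
    table = sample_table[~sample_table["is_qc"].astype(bool)]
    stage_code = {stage: i for i, stage in enumerate(stage_order)}
    response = {}
    for _, row in table.iterrows():
        row_arm = row.get("arm")
        row_arm = None if pd.isna(row_arm) or row_arm in ("", None) else row_arm
        if arm is not None and row_arm is not None and row_arm != arm:
            continue
        if row["stage"] not in stage_code:
            raise InvalidDesignError(f"unknown stage label {row['stage']!r}")
        response[row["sample_id"]] = stage_code[row["stage"]]
    if not response:
        raise EmptyInputError("no samples left after arm filtering")
    return pd.Series(response, dtype=float)


def _design(matrix: FeatureMatrix, response: pd.Series):
    samples = [s for s in response.index if s in matrix.values.columns]
    if len(samples) < len(response):
        missing = sorted(set(response.index) - set(samples))
        raise EmptyInputError(f"samples absent from matrix: {missing[:5]}")
    X = np.ascontiguousarray(matrix.values[samples].to_numpy(dtype=float).T)
    y = response.loc[samples].to_numpy(dtype=float)
    return X, y


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def rf_fit(matrix: FeatureMatrix, response: pd.Series, config: RFConfig) -> ForestFit:
    """Fit the observed-response forest (seeded; OOB R2 and %IncMSE)."""
    X, y = _design(matrix, response)
    if len(np.unique(y)) < 2:
        raise InvalidDesignError("response has fewer than 2 distinct values")
    return fit_forest(
        X,
        y,
        n_trees=config.n_trees,
        max_features=config.max_features,
        seed=int(_child_seeds(config.seed, 1)[0]),
        compute_importance=True,
    )


def _null_runs(X, y, config: RFConfig, importance: bool) -> tuple[np.ndarray, np.ndarray]:
    """R2 (and importances) of n_permutations permuted-response refits."""
    seeds = _child_seeds(config.seed, config.n_permutations + 2)
    rng = np.random.default_rng(int(seeds[-1]))
    null_r2 = np.empty(config.n_permutations)
    null_imp = np.empty((config.n_permutations, X.shape[1])) if importance else None
    for i in range(config.n_permutations):
        y_perm = rng.permutation(y)
        f = fit_forest(
            X,
            y_perm,
            n_trees=config.n_trees_null,
            max_features=config.max_features,
            seed=int(seeds[i + 1]),
            compute_importance=importance,
        )
        null_r2[i] = f.oob_r2
        if importance:
            null_imp[i] = f.inc_mse
    return null_r2, null_imp


def permutation_model_test(
    matrix: FeatureMatrix, response: pd.Series, config: RFConfig
) -> tuple[float, np.ndarray]:
    """Model p-value (1 + #{null R2 >= observed R2}) / (n_perm + 1)."""
    X, y = _design(matrix, response)
    observed = rf_fit(matrix, response, config)
    null_r2, _ = _null_runs(X, y, config, importance=False)
    p = (1 + int(np.sum(null_r2 >= observed.oob_r2))) / (config.n_permutations + 1)
    return p, null_r2


def permutation_importance_test(
    matrix: FeatureMatrix, response: pd.Series, config: RFConfig
) -> pd.DataFrame:
    """%IncMSE per feature with permuted-response null p-values."""
    return select_features(matrix, response, config).importance


def select_features(
    matrix: FeatureMatrix, response: pd.Series, config: RFConfig
) -> RFSelection:
    """One permutation pass serving both the model test and selection.

    The same permuted-response refits provide the model R2 null and each
    feature's importance null, as a single forest per permutation.
    """
    X, y = _design(matrix, response)
    observed = rf_fit(matrix, response, config)
    null_r2, null_imp = _null_runs(X, y, config, importance=True)
    n_perm = config.n_permutations
    model_p = (1 + int(np.sum(null_r2 >= observed.oob_r2))) / (n_perm + 1)
    exceed = (null_imp >= observed.inc_mse[None, :]).sum(axis=0)
    p_values = (1 + exceed) / (n_perm + 1)
    importance = pd.DataFrame(
        {
            "inc_mse": observed.inc_mse,
            "p_value": p_values,
            "selected": p_values < config.alpha,
        },
        index=matrix.values.index,
    )
    return RFSelection(
        model_r2=observed.oob_r2,
        model_p=model_p,
        importance=importance,
        null_r2=null_r2,
        config=config,
        fit=observed,
    )


# ---------------------------------------------------------------------------
# Welch / BH differential testing
# ---------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_test(group_a, group_b) -> WelchResult:
    """Two-sided unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateTestError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        raise DegenerateTestError(
            "zero variance in both groups with unequal means"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_features(
    matrix: FeatureMatrix,
    sample_table: pd.DataFrame,
    stage: str,
    arm_a: str,
    arm_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch + BH comparison of two process arms at one stage.

    Direction is relative to ``arm_a``: a feature is ``increased`` when
    its mean in ``arm_b`` exceeds its mean in ``arm_a``.  Returns one row
    per feature (t, df, p, q, direction, significant).
    """
    table = sample_table[~sample_table["is_qc"].astype(bool)]
    cols = {}
    for arm in (arm_a, arm_b):
        ids = table[(table["stage"] == stage) & (table["arm"] == arm)]["sample_id"]
        ids = [s for s in ids if s in matrix.values.columns]
        if len(ids) < 2:
            raise InvalidDesignError(
                f"arm {arm!r} has fewer than 2 replicates at stage {stage!r}"
            )
        cols[arm] = ids
    rows = []
    for fid, row in matrix.values.iterrows():
        a = row[cols[arm_a]].to_numpy(dtype=float)
        b = row[cols[arm_b]].to_numpy(dtype=float)
        try:
            res = welch_test(a, b)
        except DegenerateTestError:
            rows.append((fid, np.nan, np.nan, np.nan, a.mean(), b.mean()))
            continue
        rows.append((fid, res.t, res.df, res.p, a.mean(), b.mean()))
    out = pd.DataFrame(
        rows, columns=["feature", "t", "df", "p", "mean_a", "mean_b"]
    ).set_index("feature")
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    out["direction"] = np.where(
        out["mean_b"] > out["mean_a"], "increased", "decreased"
    )
    out["significant"] = out["q"] < alpha
    return out
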