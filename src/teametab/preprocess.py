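"""Moisture/weight normalisation and stage-trend profiles.

Material collected along a manufacturing process varies in both mass and
moisture, so extract intensities are only comparable after scaling each
sample to a common dry-mass basis: the dry-mass equivalent of a sample is
its extraction weight times (1 - moisture fraction of its sample type),
and every sample is scaled down to the sample of lowest dry-mass
equivalent.  Moisture is measured destructively on one replicate per
sample type (stage, arm) and propagated to the others.

Trend displays and clustering work on per-stage mean intensities expressed
as percentage relative abundance (each feature's stage means scaled to sum
to 100), which makes features of very different absolute intensity
comparable by shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import FeatureMatrix
from .errors import EmptyInputError, InvalidDesignError

SAMPLE_COLUMNS = [
    "sample_id",
    "stage",
    "arm",
    "replicate",
    "fresh_weight",
    "dry_weight",
    "extract_weight",
    "is_qc",
]


def moisture_content(fresh_weight: float, dry_weight: float) -> float:
    """Moisture fraction (fresh - dry) / fresh of a weighed replicate."""
    if dry_weight <= 0 or fresh_weight <= 0:
        raise InvalidDesignError("weights must be positive")
    if dry_weight > fresh_weight:
        raise InvalidDesignError(
            f"dry weight {dry_weight} exceeds fresh weight {fresh_weight}"
        )
    return (fresh_weight - dry_weight) / fresh_weight


def _sample_type(row: pd.Series) -> tuple:
    arm = row.get("arm")
    return (row["stage"], None if pd.isna(arm) or arm in ("", None) else arm)


def type_moisture(sample_table: pd.DataFrame) -> dict[tuple, float]:
    """Per sample-type moisture from the replicate(s) with a dry weight."""
    table = sample_table[~sample_table["is_qc"].astype(bool)]
    measured: dict[tuple, list[float]] = {}
    for _, row in table.iterrows():
        if pd.notna(row.get("dry_weight")) and pd.notna(row.get("fresh_weight")):
            m = moisture_content(row["fresh_weight"], row["dry_weight"])
            measured.setdefault(_sample_type(row), []).append(m)
    return {k: float(np.mean(v)) for k, v in measured.items()}


def weight_normalise(
    matrix: FeatureMatrix,
    sample_table: pd.DataFrame,
    mode: str = "dry-mass",
) -> FeatureMatrix:
    """Scale every sample to the extract of lowest (dry-mass) weight.

    ``mode="dry-mass"`` (default) computes each sample's dry-mass
    equivalent d_i = extract_weight_i * (1 - moisture of its sample type)
    and multiplies its intensities by min(d)/d_i, so the lowest-weight
    sample is unchanged.  ``mode="raw-weight"`` uses the extract weight
    directly, ignoring moisture.  QC samples are left unscaled.
    """
    if mode not in ("dry-mass", "raw-weight"):
        raise ValueError(f"unknown mode {mode!r}")
    table = sample_table.set_index("sample_id")
    moisture = type_moisture(sample_table) if mode == "dry-mass" else {}
    d = {}
    for sample in matrix.samples:
        if sample not in table.index:
            raise InvalidDesignError(f"sample {sample!r} missing from sample table")
        row = table.loc[sample]
        if bool(row["is_qc"]):
            continue
        if pd.isna(row.get("extract_weight")):
            raise InvalidDesignError(f"sample {sample!r} has no extract weight")
        if mode == "dry-mass":
            key = _sample_type(row)
            if key not in moisture:
                raise InvalidDesignError(
                    f"no moisture measurement for sample type {key} (sample {sample!r})"
                )
            d[sample] = row["extract_weight"] * (1.0 - moisture[key])
        else:
            d[sample] = float(row["extract_weight"])
    if not d:
        raise EmptyInputError("no non-QC samples to normalise")
    d_series = pd.Series(d)
    factors = d_series.min() / d_series
    all_factors = pd.Series(1.0, index=matrix.samples)
    all_factors.update(factors)
    out = matrix.scale_samples(all_factors)
    out.provenance["weight_normalise"] = {
        "mode": mode,
        "reference_sample": d_series.idxmin(),
    }
    return out


def stage_mean_profiles(
    matrix: FeatureMatrix,
    sample_table: pd.DataFrame,
    stage_order: list[str],
    arm: str | None = None,
) -> pd.DataFrame:
    """Per-feature arithmetic mean over replicates at each stage, in order.

    QC samples are excluded.  With ``arm`` given, samples are restricted
    to shared (arm-less) stages plus that arm's branch.
    """
    table = sample_table[~sample_table["is_qc"].astype(bool)].set_index("sample_id")
    cols: dict[str, list[str]] = {stage: [] for stage in stage_order}
    for sample in matrix.samples:
        if sample not in table.index:
            continue
        row = table.loc[sample]
        row_arm = row.get("arm")
        row_arm = None if pd.isna(row_arm) or row_arm in ("", None) else row_arm
        if arm is not None and row_arm is not None and row_arm != arm:
            continue
        if row["stage"] in cols:
            cols[row["stage"]].append(sample)
    means = {}
    for stage in stage_order:
        if not cols[stage]:
            raise EmptyInputError(f"no samples for stage {stage!r}")
        means[stage] = matrix.values[cols[stage]].mean(axis=1)
    return pd.DataFrame(means, columns=stage_order)


def percent_relative_abundance(stage_means: pd.DataFrame) -> pd.DataFrame:
    """Scale each feature's stage means to percentages summing to 100."""
    if (stage_means < 0).any().any():
        raise ValueError("stage means must be non-negative")
    totals = stage_means.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise EmptyInputError(
            f"all-zero features cannot be profiled: {list(zero.index[:5])}"
        )
    return stage_means.mul(100.0 / totals, axis=0)
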