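"""Seeded synthetic datasets with the structure the analysis assumes.

The study's raw fingerprints are not publicly deposited, so every
downstream stage is exercised against generated data with known ground
truth.  A dataset emulates an ordered manufacturing design (6-7 stages x 3
replicates, optionally two late-process arms), thousands of polarity-tagged
m/z features with multiplicative log-normal intensity noise, a minority of
features following planted per-stage trend templates grouped into clusters,
ppm-scale mass jitter on the raw scans, pooled-QC samples, a compound
snapshot with hierarchical taxonomy paths, and a layered knowledge graph
with one pathway wired to the planted affected compounds.

All generators are pure functions of (config, seed): each operation draws
from its own child RNG stream of the config seed, so the pieces are
individually reproducible and mutually consistent.

What is deliberately not simulated: chromatography, isotope envelopes and
in-source fragmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .binning import FeatureMatrix, feature_id
from .errors import InvalidDesignError
from .formulas import format_formula, ion_mz, load_adduct_rules
from .mzml import CentroidScan

GREEN_STAGES = ("picking", "wither90", "fixation", "rolling", "oxidation", "roasting")
BLACK_STAGES = (
    "picking",
    "wither85",
    "wither70",
    "wither60",
    "rolling",
    "oxidation",
    "roasting",
)
BLACK_ARMS = ("4h", "overnight")
BLACK_ARM_STAGES = ("oxidation", "roasting")

#: typical moisture fraction by stage (withering stages encode their target)
STAGE_MOISTURE = {
    "picking": 0.78,
    "wither90": 0.90,
    "wither85": 0.85,
    "wither70": 0.70,
    "wither60": 0.60,
    "fixation": 0.62,
    "rolling": 0.58,
    "oxidation": 0.52,
    "roasting": 0.05,
}

_SUPERCLASSES = (
    "Phenylpropanoids and polyketides",
    "Organic oxygen compounds",
    "Organic acids and derivatives",
    "Lipids and lipid-like molecules",
    "Organoheterocyclic compounds",
    "Benzenoids",
)

_PATHWAY_THEMES = (
    "Flavonoid biosynthesis",
    "Biosynthesis of amino acids",
    "Starch and sucrose metabolism",
    "Citrate cycle (TCA cycle)",
    "Pentose phosphate pathway",
    "Phenylpropanoid biosynthesis",
    "Carotenoid biosynthesis",
    "Galactose metabolism",
    "Tyrosine metabolism",
    "Glyoxylate and dicarboxylate metabolism",
)

# RNG stream ids per generator
_STREAM_DESIGN = 1
_STREAM_MATRIX = 2
_STREAM_SPECTRA = 3
_STREAM_LIBRARY = 4
_STREAM_GRAPH = 5


@dataclass
class SimulationConfig:
    """The stated world of one synthetic experiment.

    Defaults mirror the emulated study: a green-tea design of 6 ordered
    stages x 3 replicates, 3 (+/-1) ppm mass accuracy, acquisition over
    m/z 55-1200, and a feature count (2000) chosen as a free parameter
    since post-binning dimensionality is not reported anywhere.
    """

    seed: int
    stages: tuple = GREEN_STAGES
    arms: tuple = ()
    arm_split_stages: tuple = ()
    replicates_per_stage: int = 3
    n_features: int = 2000
    n_informative: int = 200
    n_trend_clusters: int = 5
    noise_sigma: float = 0.2  # log-scale sd (~20% CV)
    ppm_jitter: float = 3.0
    mz_range: tuple = (55.0, 1200.0)
    n_compounds: int = 400
    n_pathways: int = 8
    planted_pathway_fraction: float = 0.3
    trend_amplitude: float = 1.0  # log-units span of a trend template
    mapped_fraction: float = 0.4  # non-planted features given a real formula
    arm_fold_change: float = 1.0
    n_arm_diff: int = 0
    n_qc: int = 3
    n_scans: int = 8  # scans per polarity per sample
    scan_weight_spread: float = 0.3
    qc_sigma: float = 0.1
    #: scale intensities by each sample's dry-mass equivalent (more extracted
    #: material -> more signal), which dry-mass weight normalisation undoes
    weight_effect: bool = True

    def __post_init__(self) -> None:
        if not self.stages:
            raise InvalidDesignError("stage list is empty")
        if self.replicates_per_stage < 2:
            raise InvalidDesignError("at least 2 replicates per stage are required")
        if self.n_informative > self.n_features:
            raise InvalidDesignError("n_informative exceeds n_features")
        if self.n_informative > 0 and self.n_trend_clusters > self.n_informative:
            raise InvalidDesignError("more trend clusters than informative features")
        if self.n_informative > 0 and self.n_trend_clusters < 1:
            raise InvalidDesignError("n_trend_clusters must be >= 1")
        if not self.mz_range[0] < self.mz_range[1]:
            raise InvalidDesignError("mz_range must be (low, high) with low < high")
        if self.arms and not self.arm_split_stages:
            raise InvalidDesignError("arms declared without arm_split_stages")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def green_config(seed: int, **overrides) -> SimulationConfig:
    """Green-tea template: 6 ordered stages, no arms."""
    return SimulationConfig(seed=seed, stages=GREEN_STAGES, **overrides)


def black_config(seed: int, **overrides) -> SimulationConfig:
    """Black-tea template: 7 stages with 4 h / overnight arms on the last two."""
    overrides.setdefault("arms", BLACK_ARMS)
    overrides.setdefault("arm_split_stages", BLACK_ARM_STAGES)
    return SimulationConfig(seed=seed, stages=BLACK_STAGES, **overrides)


@dataclass
class GroundTruth:
    informative_feature_ids: list = field(default_factory=list)
    cluster_membership: dict = field(default_factory=dict)
    trend_templates: dict = field(default_factory=dict)  # cluster -> stage means
    planted_pathway_ids: set = field(default_factory=set)
    feature_formula: dict = field(default_factory=dict)
    planted_feature_ids: list = field(default_factory=list)
    arm_diff_feature_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample table: one record per stage x (arm x) replicate, plus QCs.

    Fresh material is ~50 mg aliquots (U(45, 55)); extraction weights are
    U(40, 60) mg; one replicate per sample type carries the destructive
    moisture measurement (dry weight), drawn around the stage's typical
    moisture with +/-0.02 jitter.
    """
    rng = config.rng(_STREAM_DESIGN)
    rows = []
    for stage in config.stages:
        stage_arms = (
            list(config.arms)
            if (stage in config.arm_split_stages and config.arms)
            else [None]
        )
        for arm in stage_arms:
            moisture = STAGE_MOISTURE.get(stage, 0.5) + rng.uniform(-0.02, 0.02)
            moisture = float(np.clip(moisture, 0.01, 0.95))
            for rep in range(1, config.replicates_per_stage + 1):
                fresh = rng.uniform(45.0, 55.0)
                extract = rng.uniform(40.0, 60.0)
                name = stage if arm is None else f"{stage}-{arm}"
                rows.append(
                    {
                        "sample_id": f"{name}_r{rep}",
                        "stage": stage,
                        "arm": arm,
                        "replicate": rep,
                        "fresh_weight": fresh,
                        # moisture measured on replicate 1 of each type only
                        "dry_weight": fresh * (1 - moisture) if rep == 1 else np.nan,
                        "extract_weight": extract,
                        "is_qc": False,
                    }
                )
    for q in range(1, config.n_qc + 1):
        rows.append(
            {
                "sample_id": f"QC_r{q}",
                "stage": "QC",
                "arm": None,
                "replicate": q,
                "fresh_weight": np.nan,
                "dry_weight": np.nan,
                "extract_weight": np.nan,
                "is_qc": True,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compound library
# ---------------------------------------------------------------------------

def _random_formula(rng: np.random.Generator) -> dict:
    """A plausible even-electron CHNO(S) formula with integer RDBE."""
    while True:
        c = int(rng.integers(5, 31))
        n = int(rng.choice([0, 0, 0, 1, 2]))
        o = int(rng.integers(0, 13))
        r = int(rng.integers(0, min(c, 11)))
        h = 2 * c + 2 + n - 2 * r
        if h >= 1:
            counts = {"C": c, "H": h, "N": n, "O": o}
            return {el: v for el, v in counts.items() if v}


def simulate_compound_library(config: SimulationConfig) -> pd.DataFrame:
    """Compound snapshot: id, formula, database tier, taxonomy path.

    Planted compounds (the affected set wired to the planted pathway) come
    first, carry unique formulas, primary tier and a shared flavan-3-ol
    class so both enrichment analyses have a recoverable signal.  Among
    the remaining compounds some formulas are shared by several compounds
    to exercise consensus logic, including one formula held by three
    compounds whose paths agree to depth 2 only.
    """
    if config.n_compounds < 1:
        raise InvalidDesignError("n_compounds must be >= 1")
    rng = config.rng(_STREAM_LIBRARY)
    n_planted = min(
        config.n_compounds,
        max(5, round(config.planted_pathway_fraction * config.n_informative)),
    )
    formulas: set[str] = set()

    def fresh_formula() -> str:
        while True:
            f = format_formula(_random_formula(rng))
            if f not in formulas:
                formulas.add(f)
                return f

    rows = []
    planted_path = (
        "Organic compounds/Phenylpropanoids and polyketides/Flavonoids/Flavan-3-ols"
    )
    for i in range(n_planted):
        rows.append(
            {
                "compound_id": f"CPD{i + 1:05d}",
                "formula": fresh_formula(),
                "tier": "primary",
                "taxonomy_path": planted_path,
                "planted": True,
            }
        )
    # constructed fixture: one formula, three compounds, agreement to depth 2 only
    if config.n_compounds - n_planted >= 3:
        shared = fresh_formula()
        sc = _SUPERCLASSES[1]
        for j in range(3):
            rows.append(
                {
                    "compound_id": f"CPD{len(rows) + 1:05d}",
                    "formula": shared,
                    "tier": "primary",
                    "taxonomy_path": f"Organic compounds/{sc}/{sc} class {j + 1}/"
                    f"{sc} subclass {j + 1}.1",
                    "planted": False,
                }
            )
    remaining = config.n_compounds - len(rows)
    n_free_formulas = max(1, int(0.7 * remaining)) if remaining > 0 else 0
    pool = []
    for _ in range(n_free_formulas):
        f = fresh_formula()
        sc = str(rng.choice(_SUPERCLASSES))
        cls = int(rng.integers(1, 4))
        sub = int(rng.integers(1, 3))
        pool.append(
            (f, f"Organic compounds/{sc}/{sc} class {cls}/{sc} subclass {cls}.{sub}")
        )
    for _ in range(remaining):
        f, path = pool[int(rng.integers(0, len(pool)))]
        if rng.random() > 0.7:  # divergent classification for a shared formula
            sc = path.split("/")[1]
            cls = int(rng.integers(1, 4))
            path = f"Organic compounds/{sc}/{sc} class {cls}/{sc} subclass {cls}.1"
        rows.append(
            {
                "compound_id": f"CPD{len(rows) + 1:05d}",
                "formula": f,
                "tier": "primary" if rng.random() < 0.8 else "fallback",
                "taxonomy_path": path,
                "planted": False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def _template_shape(kind: int, n_stages: int, stages: tuple) -> np.ndarray:
    """Deterministic trend shapes on [0, 1] per stage."""
    x = np.linspace(0.0, 1.0, n_stages)
    peak_stage = stages.index("rolling") if "rolling" in stages else n_stages // 2
    xp = peak_stage / max(1, n_stages - 1)
    shapes = [
        x,  # monotone up
        1.0 - x,  # monotone down
        1.0 - np.abs(x - xp) / max(xp, 1.0 - xp, 1e-9),  # peak at rolling
        np.abs(x - xp) / max(xp, 1.0 - xp, 1e-9),  # valley at rolling
        np.clip((x - 0.6) / 0.4, 0.0, 1.0),  # late rise
        1.0 - np.clip(x / 0.4, 0.0, 1.0),  # early fall
    ]
    return shapes[kind % len(shapes)]


def trend_templates(config: SimulationConfig) -> dict[int, np.ndarray]:
    """Per-cluster per-stage intensity multipliers (centred on 1 in log)."""
    out = {}
    for c in range(1, config.n_trend_clusters + 1):
        shape = _template_shape(c - 1, len(config.stages), tuple(config.stages))
        log_t = config.trend_amplitude * (shape - shape.mean())
        out[c] = np.exp(log_t)
    return out


def simulate_feature_matrix(
    config: SimulationConfig, design: pd.DataFrame | None = None
) -> tuple[FeatureMatrix, GroundTruth]:
    """Intensity table over the design, with planted trends and formulas.

    Uninformative features are stage-independent log-normals around a
    feature-specific base intensity; informative features multiply the
    base by their cluster's per-stage template.  A planted fraction of
    informative features sits at the exact ion m/z of a planted-pathway
    compound (alternating [M-H]-/[M+H]+), so formula assignment and
    enrichment can recover them; a further slice of features maps to the
    remaining library formulas as classification background.  QC columns
    emulate pooled-QC injections around the all-sample geometric mean.
    """
    if design is None:
        design = simulate_design(config)
    rng = config.rng(_STREAM_MATRIX)
    library = simulate_compound_library(config)
    rules = {r.name: r for r in load_adduct_rules()}
    neg_rule, pos_rule = rules["[M-H]-"], rules["[M+H]+"]

    truth = GroundTruth(planted_pathway_ids={"PATH001"})
    truth.trend_templates = trend_templates(config) if config.n_informative else {}

    lo, hi = config.mz_range
    used_bins: set[tuple[str, int]] = set()

    def claim(polarity: str, mz: float) -> str | None:
        if not lo <= mz <= hi:
            return None
        b = int(np.floor(mz / 0.01 + 0.5))
        if (polarity, b) in used_bins:
            return None
        used_bins.add((polarity, b))
        return feature_id(polarity, b * 0.01)

    fids: list[str] = []
    info_rows: list[tuple[str, float]] = []  # polarity, true mz

    planted = library[library["planted"]]
    n_planted_features = min(
        round(config.planted_pathway_fraction * config.n_informative), len(planted)
    )
    # planted informative features at exact ion m/z of planted compounds
    for i in range(n_planted_features):
        compound = planted.iloc[i]
        polarity = "negative" if i % 2 == 0 else "positive"
        mz = ion_mz(compound["formula"], neg_rule if polarity == "negative" else pos_rule)
        fid = claim(polarity, mz)
        if fid is None:
            polarity = "positive" if polarity == "negative" else "negative"
            mz = ion_mz(
                compound["formula"], neg_rule if polarity == "negative" else pos_rule
            )
            fid = claim(polarity, mz)
        if fid is None:
            continue
        fids.append(fid)
        info_rows.append((polarity, mz))
        truth.planted_feature_ids.append(fid)
        truth.feature_formula[fid] = compound["formula"]

    # background features mapped to the remaining library formulas
    free_formulas = list(dict.fromkeys(library.loc[~library["planted"], "formula"]))
    rng.shuffle(free_formulas)
    n_mapped = min(
        int(config.mapped_fraction * (config.n_features - len(fids))),
        len(free_formulas),
    )
    for i in range(n_mapped):
        polarity = "negative" if rng.random() < 0.5 else "positive"
        mz = ion_mz(free_formulas[i], neg_rule if polarity == "negative" else pos_rule)
        fid = claim(polarity, mz)
        if fid is None:
            continue
        fids.append(fid)
        info_rows.append((polarity, mz))
        truth.feature_formula[fid] = free_formulas[i]

    # unassigned features at random m/z (50/50 polarity split)
    while len(fids) < config.n_features:
        polarity = "negative" if rng.random() < 0.5 else "positive"
        mz = float(rng.uniform(lo, hi))
        fid = claim(polarity, mz)
        if fid is None:
            continue
        fids.append(fid)
        info_rows.append((polarity, mz))

    # informative set: planted features first, then the earliest mapped ones
    informative = fids[: config.n_informative]
    truth.informative_feature_ids = list(informative)
    for j, fid in enumerate(informative):
        truth.cluster_membership[fid] = (j % config.n_trend_clusters) + 1
    if config.n_arm_diff:
        truth.arm_diff_feature_ids = list(informative[: config.n_arm_diff])

    samples = design[~design["is_qc"].astype(bool)]
    stage_index = {stage: i for i, stage in enumerate(config.stages)}
    base_log = rng.uniform(np.log(1e4), np.log(1e7), size=len(fids))
    arm_diff = set(truth.arm_diff_feature_ids)
    diff_arm = config.arms[-1] if config.arms else None

    # signal scales with the dry-mass equivalent of extracted material,
    # geometric-mean-centred so the overall intensity scale is unchanged
    log_weight = {sid: 0.0 for sid in samples["sample_id"]}
    if config.weight_effect:
        from .preprocess import _sample_type, type_moisture

        moisture = type_moisture(design)
        d = {
            row["sample_id"]: row["extract_weight"]
            * (1.0 - moisture[_sample_type(row)])
            for _, row in samples.iterrows()
        }
        centre = np.mean([np.log(v) for v in d.values()])
        log_weight = {sid: np.log(v) - centre for sid, v in d.items()}

    columns: dict[str, np.ndarray] = {}
    for _, srow in samples.iterrows():
        si = stage_index[srow["stage"]]
        noise = rng.normal(0.0, config.noise_sigma, size=len(fids))
        col = np.empty(len(fids))
        for j, fid in enumerate(fids):
            log_v = base_log[j] + noise[j] + log_weight[srow["sample_id"]]
            cluster = truth.cluster_membership.get(fid)
            if cluster is not None:
                log_v += np.log(truth.trend_templates[cluster][si])
            if (
                fid in arm_diff
                and srow["arm"] == diff_arm
                and srow["stage"] in config.arm_split_stages
            ):
                log_v += np.log(config.arm_fold_change)
            col[j] = np.exp(log_v)
        columns[srow["sample_id"]] = col

    values = pd.DataFrame(columns, index=fids)
    qc_ids = design.loc[design["is_qc"].astype(bool), "sample_id"]
    if len(qc_ids):
        pooled_log = np.log(values).mean(axis=1)
        for qid in qc_ids:
            values[qid] = np.exp(
                pooled_log + rng.normal(0.0, config.qc_sigma, size=len(fids))
            )
    order = sorted(range(len(fids)), key=lambda j: (info_rows[j][0], info_rows[j][1]))
    values = values.iloc[order]
    feature_info = pd.DataFrame(
        {
            "polarity": [info_rows[j][0] for j in order],
            "bin_mz": [float(fids[j][1:]) for j in order],
            "accurate_mz": [info_rows[j][1] for j in order],
        },
        index=[fids[j] for j in order],
    )
    matrix = FeatureMatrix(
        values=values,
        feature_info=feature_info,
        provenance={"synthetic": True, "seed": config.seed, "filters": []},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def simulate_spectra(
    matrix: FeatureMatrix, config: SimulationConfig
) -> dict[str, list[CentroidScan]]:
    """Per-sample centroided scan lists whose binning reproduces the matrix.

    Each polarity gets ``n_scans`` scans.  A feature's per-scan peak
    intensities are its matrix value times weights with mean exactly 1
    over the scans (a flat infusion plateau), so the mean-of-scan-sums
    binning recovers the matrix value; peak m/z is the true m/z perturbed
    per scan by a relative Normal(0, ppm_jitter x 1e-6) error.
    """
    rng = config.rng(_STREAM_SPECTRA)
    info = matrix.feature_info
    if config.ppm_jitter > 0:
        sigma_da = 4.0 * config.ppm_jitter * 1e-6 * info["accurate_mz"]
        lower = np.floor((info["accurate_mz"] - sigma_da) / 0.01 + 0.5)
        upper = np.floor((info["accurate_mz"] + sigma_da) / 0.01 + 0.5)
        at_risk = info.index[lower != upper]
        if len(at_risk):
            warnings.warn(
                f"ppm_jitter={config.ppm_jitter} may move {len(at_risk)} features "
                f"across bin boundaries (e.g. {list(at_risk[:5])})",
                stacklevel=2,
            )
    out: dict[str, list[CentroidScan]] = {}
    polarities = ("positive", "negative")
    for sample in matrix.samples:
        values = matrix.values[sample]
        scans: list[CentroidScan] = []
        scan_no = 0
        for polarity in polarities:
            mask = (info["polarity"] == polarity) & (values > 0)
            mzs = info.loc[mask, "accurate_mz"].to_numpy()
            vals = values[mask].to_numpy()
            u = rng.uniform(
                1 - config.scan_weight_spread,
                1 + config.scan_weight_spread,
                size=(len(mzs), config.n_scans),
            )
            w = u / u.mean(axis=1, keepdims=True)
            eps = rng.normal(0.0, config.ppm_jitter * 1e-6, size=(len(mzs), config.n_scans))
            for s in range(config.n_scans):
                scan_no += 1
                scans.append(
                    CentroidScan(
                        polarity=polarity,
                        scan_index=scan_no,
                        mz=mzs * (1.0 + eps[:, s]),
                        intensity=vals * w[:, s],
                    )
                )
        out[sample] = scans
    return out


# ---------------------------------------------------------------------------
# knowledge graph
# ---------------------------------------------------------------------------

def simulate_knowledge_graph(config: SimulationConfig):
    """Layered compound-reaction-enzyme-module-pathway graph.

    One pathway (PATH001) is wired to the planted affected-compound set;
    the rest partition the remaining compounds.  Every compound reaches
    its pathway through a reaction-enzyme-module chain, and occasional
    cross-links attach compounds to a second pathway's reactions.
    Returns (graph, planted_pathway_id).
    """
    import networkx as nx

    if config.n_pathways < 2:
        raise InvalidDesignError("n_pathways must be >= 2")
    rng = config.rng(_STREAM_GRAPH)
    library = simulate_compound_library(config)
    graph = nx.Graph()
    pathway_ids = [f"PATH{i + 1:03d}" for i in range(config.n_pathways)]
    for i, pid in enumerate(pathway_ids):
        theme = _PATHWAY_THEMES[i % len(_PATHWAY_THEMES)]
        graph.add_node(pid, type="pathway", label=theme)
    members: dict[str, list[str]] = {pid: [] for pid in pathway_ids}
    for j, row in library.iterrows():
        cid = row["compound_id"]
        graph.add_node(cid, type="compound", label=row["formula"])
        if row["planted"]:
            members[pathway_ids[0]].append(cid)
        else:
            members[pathway_ids[1 + j % (config.n_pathways - 1)]].append(cid)
    reaction_by_pathway: dict[str, list[str]] = {}
    for p, pid in enumerate(pathway_ids):
        mod = f"MOD{p + 1:03d}"
        graph.add_node(mod, type="module", label=f"Module {p + 1}")
        graph.add_edge(mod, pid)
        reaction_by_pathway[pid] = []
        compounds = members[pid]
        for k in range(0, max(len(compounds), 1), 3):
            chunk = compounds[k : k + 3]
            if not chunk:
                break
            rxn = f"RXN{p + 1:03d}_{k // 3 + 1}"
            enz = f"ENZ{p + 1:03d}_{k // 3 + 1}"
            graph.add_node(rxn, type="reaction", label=rxn)
            graph.add_node(enz, type="enzyme", label=enz)
            for cid in chunk:
                graph.add_edge(cid, rxn)
            graph.add_edge(rxn, enz)
            graph.add_edge(enz, mod)
            reaction_by_pathway[pid].append(rxn)
    # sparse cross-links between pathways
    all_compounds = list(library["compound_id"])
    for i in range(0, len(all_compounds), 9):
        pid = pathway_ids[int(rng.integers(1, config.n_pathways))]
        if reaction_by_pathway[pid]:
            rxn = reaction_by_pathway[pid][
                int(rng.integers(0, len(reaction_by_pathway[pid])))
            ]
            graph.add_edge(all_compounds[i], rxn)
    isolated = [n for n in graph.nodes if graph.degree(n) == 0]
    if isolated:
        warnings.warn(f"disconnected nodes in knowledge graph: {isolated[:5]}", stacklevel=2)
    return graph, pathway_ids[0]


# ---------------------------------------------------------------------------
# bundle + file output
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    design: pd.DataFrame
    matrix: FeatureMatrix
    truth: GroundTruth
    library: pd.DataFrame
    graph: object
    planted_pathway: str


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate every coupled piece of a synthetic experiment at once."""
    design = simulate_design(config)
    matrix, truth = simulate_feature_matrix(config, design)
    library = simulate_compound_library(config)
    graph, planted = simulate_knowledge_graph(config)
    return SyntheticDataset(
        config=config,
        design=design,
        matrix=matrix,
        truth=truth,
        library=library,
        graph=graph,
        planted_pathway=planted,
    )


def write_dataset(dataset: SyntheticDataset, outdir, write_spectra: bool = False) -> None:
    """Write design/matrix/truth/library/graph (and optionally mzML) to disk."""
    import os

    from .enrichment import save_graph_tsv
    from .mzml import write_mzml

    os.makedirs(outdir, exist_ok=True)
    dataset.design.to_csv(
        os.path.join(outdir, "samples.tsv"), sep="\t", index=False, float_format="%.10g"
    )
    dataset.matrix.write_tsv(os.path.join(outdir, "feature_matrix.tsv"))
    dataset.library.to_csv(os.path.join(outdir, "compounds.tsv"), sep="\t", index=False)
    save_graph_tsv(dataset.graph, os.path.join(outdir, "graph.tsv"))
    truth_rows = []
    for fid in dataset.matrix.values.index:
        truth_rows.append(
            {
                "feature": fid,
                "informative": fid in set(dataset.truth.informative_feature_ids),
                "cluster": dataset.truth.cluster_membership.get(fid, 0),
                "formula": dataset.truth.feature_formula.get(fid, ""),
                "planted": fid in set(dataset.truth.planted_feature_ids),
            }
        )
    pd.DataFrame(truth_rows).to_csv(
        os.path.join(outdir, "ground_truth.tsv"), sep="\t", index=False
    )
    import yaml

    cfg = asdict(dataset.config)
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.items()
    }
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    if write_spectra:
        mzml_dir = os.path.join(outdir, "mzml")
        os.makedirs(mzml_dir, exist_ok=True)
        spectra = simulate_spectra(dataset.matrix, dataset.config)
        for sample, scans in spectra.items():
            write_mzml(os.path.join(mzml_dir, f"{sample}.mzML"), scans)
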