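"""Molecular formula assignment, compound matching and consensus classification.

Binned FIE-MS features are annotated in three steps:

1. every ionisation rule of matching polarity is inverted to a neutral
   monoisotopic mass and all CHNOPS formulas within a ppm tolerance are
   enumerated (subject to ring-double-bond-equivalent feasibility);
2. each candidate formula is looked up in a local compound snapshot,
   preferring the primary database tier and falling back to the secondary
   tier only when the primary has no match;
3. the matched compounds' hierarchical taxonomy paths are reduced to the
   deepest prefix on which at least 66% of them agree — the feature's
   consensus structural class.

Ionisation rules are data (a TSV of mass transforms with applicability
conditions), so the rule inventory is extensible without code changes.
Each feature is assigned independently; no cross-feature adduct/isotope
grouping is attempted.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import (
    EmptyInputError,
    EnumerationLimitError,
    FormulaError,
    InapplicableRuleError,
)

#: most-abundant-isotope masses (CODATA/AME2020, rounded to 1e-6 Da)
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
}

PROTON_MASS = 1.007276

DEFAULT_ELEMENT_RANGES = {
    "C": (0, 30),
    "H": (0, 60),
    "N": (0, 5),
    "O": (0, 15),
    "P": (0, 2),
    "S": (0, 2),
}

DEFAULT_PPM_TOL = 3.0  # centre of the instrument's 3 (+/-1) ppm accuracy
PPM_PRESETS = {"strict": 2.0, "default": 3.0, "loose": 4.0}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict) -> dict[str, int]:
    """Parse ``"C15H14O6"`` into an element -> count map."""
    if isinstance(formula, dict):
        counts = {el: int(n) for el, n in formula.items() if n}
    else:
        if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
            raise FormulaError(f"cannot parse formula {formula!r}")
        counts = {}
        for el, num in _FORMULA_RE.findall(formula):
            if el:
                counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if not counts or all(n == 0 for n in counts.values()):
        raise FormulaError("empty formula")
    if any(n < 0 for n in counts.values()):
        raise FormulaError(f"negative element count in {formula!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Hill notation: C, H, then remaining elements alphabetically."""
    parts = []
    for el in ["C", "H"] + sorted(set(counts) - {"C", "H"}):
        n = counts.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | dict) -> float:
    """Sum of most-abundant-isotope masses for a neutral formula."""
    counts = parse_formula(formula)
    unknown = set(counts) - set(MONOISOTOPIC_MASS)
    if unknown:
        raise FormulaError(f"unknown element(s) {sorted(unknown)}")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


def rdbe(formula: str | dict) -> float:
    """Ring-plus-double-bond equivalents C + 1 + (N+P)/2 - H/2."""
    c = parse_formula(formula)
    return c.get("C", 0) + 1 + (c.get("N", 0) + c.get("P", 0)) / 2 - c.get("H", 0) / 2


# ---------------------------------------------------------------------------
# ionisation rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductRule:
    """A declarative ionisation product: mass transform + applicability.

    The observable ion m/z of a neutral of mass M is (n*M + mass_delta)/z.
    """

    name: str
    polarity: str
    n: int = 1
    z: int = 1
    mass_delta: float = 0.0
    requires_elements: frozenset = frozenset()
    requires_ion: str | None = None


@dataclass(frozen=True)
class IonisationContext:
    """Run context for applicability checks (declared mobile-phase ions)."""

    mobile_phase_ions: frozenset = frozenset()


DEFAULT_CONTEXT = IonisationContext()


def load_adduct_rules(path=None) -> list[AdductRule]:
    """Load ionisation rules from TSV (default: the packaged rule set)."""
    if path is None:
        source = resources.files("teametab.data").joinpath("adduct_rules.tsv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    rules = []
    for _, row in table.iterrows():
        req = row["requires_elements"]
        elements = frozenset() if req in ("-", "", None) or pd.isna(req) else frozenset(
            str(req).split(",")
        )
        ion = row["requires_ion"]
        ion = None if ion in ("-", "", None) or pd.isna(ion) else str(ion)
        rules.append(
            AdductRule(
                name=row["name"],
                polarity=row["polarity"],
                n=int(row["n"]),
                z=int(row["z"]),
                mass_delta=float(row["mass_delta"]),
                requires_elements=elements,
                requires_ion=ion,
            )
        )
    return rules


def rule_applicable(
    formula: str | dict | None,
    rule: AdductRule,
    context: IonisationContext = DEFAULT_CONTEXT,
) -> bool:
    """Can this rule act on this formula in this run context?

    False when a required element is absent from the formula (e.g. the
    ammonia-loss adduct needs N) or the rule needs a mobile-phase ion the
    run does not declare.  ``formula=None`` checks only the context.
    """
    if rule.requires_ion is not None and rule.requires_ion not in context.mobile_phase_ions:
        return False
    if formula is not None and rule.requires_elements:
        counts = parse_formula(formula)
        if any(counts.get(el, 0) < 1 for el in rule.requires_elements):
            return False
    return True


def ion_mz(formula: str | dict, rule: AdductRule) -> float:
    """Observable ion m/z (n*M + mass_delta)/z for a neutral formula."""
    if rule.requires_elements:
        counts = parse_formula(formula)
        missing = [el for el in rule.requires_elements if counts.get(el, 0) < 1]
        if missing:
            raise InapplicableRuleError(
                f"{rule.name} requires element(s) {missing} absent from formula"
            )
    m = monoisotopic_mass(formula)
    return (rule.n * m + rule.mass_delta) / rule.z


def neutral_mass_from_ion(mz: float, rule: AdductRule) -> float:
    """Invert a rule: the neutral mass whose ion under ``rule`` is ``mz``."""
    return (rule.z * mz - rule.mass_delta) / rule.n


# ---------------------------------------------------------------------------
# formula enumeration
# ---------------------------------------------------------------------------

_ENUM_BUDGET = 1_000_000


def enumerate_formulas(
    neutral_mass: float,
    ppm_tol: float = DEFAULT_PPM_TOL,
    element_ranges: dict[str, tuple[int, int]] | None = None,
) -> list[tuple[str, float, float]]:
    """All CHNOPS formulas within ppm_tol of a neutral mass.

    Candidates must have RDBE >= 0 and integer RDBE (even-electron
    neutral species).  Returns (formula, mass, ppm error) sorted by
    ascending |ppm|.  Raises if the search would visit more than 1e6
    combinations — narrow the element ranges.
    """
    if neutral_mass <= 0:
        raise FormulaError("neutral mass must be positive")
    ranges = dict(DEFAULT_ELEMENT_RANGES if element_ranges is None else element_ranges)
    unknown = set(ranges) - set(MONOISOTOPIC_MASS)
    if unknown:
        raise FormulaError(f"unknown element(s) {sorted(unknown)}")
    h_lo, h_hi = ranges.pop("H", (0, 0))
    # heavy elements first so mass pruning bites early
    order = sorted(ranges, key=lambda el: -MONOISOTOPIC_MASS[el])
    # 1e-9 Da floor so ppm_tol=0 still admits the exact mass despite
    # floating-point summation order
    tol = max(neutral_mass * ppm_tol * 1e-6, 1e-9)
    mh = MONOISOTOPIC_MASS["H"]
    # max mass attainable by elements order[i:] plus hydrogen
    suffix_max = [h_hi * mh] * (len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        el = order[i]
        suffix_max[i] = suffix_max[i + 1] + ranges[el][1] * MONOISOTOPIC_MASS[el]
    results: list[tuple[str, float, float]] = []
    counts: dict[str, int] = {}
    visited = 0

    def dfs(i: int, partial: float) -> None:
        nonlocal visited
        visited += 1
        if visited > _ENUM_BUDGET:
            raise EnumerationLimitError(
                "formula enumeration exceeded 1e6 candidates; narrow element ranges"
            )
        rem = neutral_mass - partial
        if rem + tol < 0 or rem - tol > suffix_max[i]:
            return
        if i == len(order):
            h_min = max(h_lo, math.ceil((rem - tol) / mh))
            h_max = min(h_hi, math.floor((rem + tol) / mh))
            if h_max >= h_min:
                visited += h_max - h_min + 1
                if visited > _ENUM_BUDGET:
                    raise EnumerationLimitError(
                        "formula enumeration exceeded 1e6 candidates; "
                        "narrow element ranges"
                    )
            for h in range(h_min, h_max + 1):
                cand = {el: n for el, n in counts.items() if n > 0}
                if h > 0:
                    cand["H"] = h
                if not cand:
                    continue
                r = rdbe(cand)
                if r < 0 or r != int(r):
                    continue
                mass = partial + h * mh
                if abs(mass - neutral_mass) <= tol:
                    ppm = 1e6 * (mass - neutral_mass) / neutral_mass
                    results.append((format_formula(cand), mass, ppm))
            return
        el = order[i]
        lo, hi = ranges[el]
        mass_el = MONOISOTOPIC_MASS[el]
        for n in range(lo, hi + 1):
            add = n * mass_el
            if partial + add - tol > neutral_mass:
                if n > lo:
                    break
            counts[el] = n
            dfs(i + 1, partial + add)
        counts.pop(el, None)

    dfs(0, 0.0)
    results.sort(key=lambda r: (abs(r[2]), r[0]))
    return results


# ---------------------------------------------------------------------------
# feature assignment
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    formula: str
    adduct: str
    neutral_mass: float
    ppm: float  # signed error of the observed ion vs the theoretical ion
    compounds: list[str] = field(default_factory=list)
    tier: str | None = None


@dataclass
class Assignment:
    """Candidate formulas/adducts for one feature, plus consensus class."""

    feature_id: str
    mz: float
    polarity: str
    candidates: list[Candidate] = field(default_factory=list)
    consensus_path: tuple = ()
    consensus_depth: int = 0

    @property
    def best(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


def assign_feature(
    feature_id: str,
    mz: float,
    polarity: str,
    rules: list[AdductRule],
    element_ranges: dict | None = None,
    ppm_tol: float = DEFAULT_PPM_TOL,
    context: IonisationContext = DEFAULT_CONTEXT,
) -> Assignment:
    """Enumerate candidate (formula, adduct) pairs explaining a feature.

    Every rule of the feature's polarity that is applicable in the run
    context is inverted to a neutral mass and formulas are enumerated;
    element-requirement checks then prune rule/formula pairs (e.g. the
    ammonia loss for N-free formulas).  Candidates are sorted by |ppm|
    of the observed ion against the theoretical ion m/z.
    """
    candidates: list[Candidate] = []
    for rule in rules:
        if rule.polarity != polarity:
            continue
        if not rule_applicable(None, rule, context):
            continue
        neutral = neutral_mass_from_ion(mz, rule)
        if neutral <= 0:
            continue
        # enumerate slightly wide, then filter on the exact ion-scale ppm
        for formula, mass, _ in enumerate_formulas(
            neutral, ppm_tol * 1.5, element_ranges
        ):
            if not rule_applicable(formula, rule, context):
                continue
            theo = (rule.n * mass + rule.mass_delta) / rule.z
            ppm = 1e6 * (mz - theo) / theo
            if abs(ppm) <= ppm_tol:
                candidates.append(
                    Candidate(formula=formula, adduct=rule.name, neutral_mass=mass, ppm=ppm)
                )
    candidates.sort(key=lambda c: (abs(c.ppm), c.formula, c.adduct))
    return Assignment(
        feature_id=feature_id, mz=mz, polarity=polarity, candidates=candidates
    )


def match_compounds(formula: str, snapshot: pd.DataFrame) -> pd.DataFrame:
    """Compounds of the snapshot with this formula, with tiered fallback.

    Primary-tier matches are returned when any exist; otherwise the
    fallback tier is searched.  The snapshot needs columns
    ``compound_id``, ``formula``, ``tier`` and ``taxonomy_path``.
    """
    hits = snapshot[snapshot["formula"] == formula]
    primary = hits[hits["tier"] == "primary"]
    return primary if len(primary) else hits[hits["tier"] == "fallback"]


def consensus_classification(
    paths: list, threshold: float = 0.66
) -> tuple[tuple, int]:
    """Deepest taxonomy prefix shared by >= ``threshold`` of the paths.

    Descends level by level: at each level the modal label among paths
    that survived the previous levels is kept iff its count over *all*
    input paths reaches the threshold; a tie for the modal label stops
    the descent.  Returns the consensus prefix and its depth.
    """
    if not paths:
        raise EmptyInputError("no taxonomy paths given")
    split = [tuple(p.split("/")) if isinstance(p, str) else tuple(p) for p in paths]
    total = len(split)
    consensus: list[str] = []
    survivors = split
    level = 0
    while True:
        labelled = [p for p in survivors if len(p) > level]
        if not labelled:
            break
        counts = Counter(p[level] for p in labelled)
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            break  # modal tie: no defensible class claim
        label, n = ranked[0]
        if n / total < threshold:
            break
        consensus.append(label)
        survivors = [p for p in labelled if p[level] == label]
        level += 1
    return tuple(consensus), len(consensus)


def classify_assignment(
    assignment: Assignment, snapshot: pd.DataFrame, threshold: float = 0.66
) -> Assignment:
    """Attach compounds and a consensus class to an assignment, in place.

    Compound matching is per candidate formula; the feature-level
    consensus comes from the best candidate (lowest |ppm|) that has at
    least one compound match.
    """
    consensus_set = False
    for cand in assignment.candidates:
        hits = match_compounds(cand.formula, snapshot)
        cand.compounds = list(hits["compound_id"])
        cand.tier = hits["tier"].iloc[0] if len(hits) else None
        if len(hits) and not consensus_set:
            path, depth = consensus_classification(
                list(hits["taxonomy_path"]), threshold
            )
            assignment.consensus_path = path
            assignment.consensus_depth = depth
            consensus_set = True
    return assignment


def class_frequency_table(assignments: list[Assignment]) -> pd.DataFrame:
    """Per-taxonomy-level counts of consensus labels across features.

    A feature contributes one count at every level its consensus reaches;
    features with an empty consensus contribute nothing.  Level-k totals
    are therefore monotone non-increasing in k.
    """
    rows = []
    counter: Counter = Counter()
    for a in assignments:
        for level in range(a.consensus_depth):
            counter[(level + 1, a.consensus_path[level])] += 1
    for (level, label), count in sorted(counter.items()):
        rows.append({"level": level, "label": label, "count": count})
    return pd.DataFrame(rows, columns=["level", "label", "count"])
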