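"""Spectral binning of flow-infusion scans and feature-matrix filtering.

Without chromatographic separation every retained scan observes the whole
sample, so a sample's fingerprint is formed by rounding peak m/z values to a
fixed-width bin (0.01 Da, half-up), summing intensities within a bin per
scan, and averaging the per-scan sums across the retained scans of the
infusion plateau.  Positive- and negative-mode scans from the same run are
binned side by side and distinguished by a ``p``/``n`` prefix on the feature
id.

Each bin also records an intensity-weighted mean of the contributing peak
m/z values ("accurate m/z").  The bin id is only 0.01 Da precise, far too
coarse for ppm-level formula assignment; the accurate m/z is what downstream
assignment works from.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FilterParameterError
from .mzml import CentroidScan

DEFAULT_BIN_WIDTH = 0.01
DEFAULT_MZ_RANGE = (55.0, 1200.0)
#: heuristic peak count above which a scan is suspected to be profile mode
CENTROID_PEAK_LIMIT = 10_000

_POLARITY_PREFIX = {"positive": "p", "negative": "n"}


def _bin_decimals(bin_width: float) -> int:
    return max(0, -int(round(math.log10(bin_width))))


def feature_id(polarity: str, bin_mz: float, bin_width: float = DEFAULT_BIN_WIDTH) -> str:
    """Feature id ``p289.07`` / ``n289.07`` for a (polarity, bin) pair."""
    return f"{_POLARITY_PREFIX[polarity]}{bin_mz:.{_bin_decimals(bin_width)}f}"


def parse_feature_id(fid: str) -> tuple[str, float]:
    polarity = "positive" if fid[0] == "p" else "negative"
    return polarity, float(fid[1:])


@dataclass
class FeatureMatrix:
    """Binned intensity table (features x samples) with provenance.

    ``feature_info`` is indexed like ``values`` and carries ``polarity``,
    ``bin_mz`` and ``accurate_mz`` columns.
    """

    values: pd.DataFrame
    feature_info: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return len(self.values)

    def subset(self, feature_ids, note: str | None = None) -> "FeatureMatrix":
        feature_ids = list(feature_ids)
        prov = dict(self.provenance)
        if note:
            prov.setdefault("filters", []).append({"step": note, "kept": len(feature_ids)})
            prov["filters"] = list(prov["filters"])
        return FeatureMatrix(
            values=self.values.loc[feature_ids].copy(),
            feature_info=self.feature_info.loc[feature_ids].copy(),
            provenance=prov,
        )

    def scale_samples(self, factors: pd.Series) -> "FeatureMatrix":
        vals = self.values.copy()
        for sample, f in factors.items():
            vals[sample] = vals[sample] * f
        return FeatureMatrix(vals, self.feature_info.copy(), dict(self.provenance))

    def write_tsv(self, path) -> None:
        out = pd.concat([self.feature_info, self.values], axis=1)
        out.index.name = "feature"
        out.to_csv(path, sep="\t", float_format="%.10g")
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        table = pd.read_csv(path, sep="\t", index_col="feature")
        info_cols = ["polarity", "bin_mz", "accurate_mz"]
        info = table[info_cols]
        values = table.drop(columns=info_cols)
        try:
            with open(str(path) + ".json") as fh:
                provenance = json.load(fh)
        except FileNotFoundError:
            provenance = {}
        return cls(values=values, feature_info=info, provenance=provenance)


# ---------------------------------------------------------------------------
# scan-window selection
# ---------------------------------------------------------------------------

def select_scan_window(
    scans: list[CentroidScan],
    tic_threshold: float = 0.5,
    override: tuple[int, int] | None = None,
) -> dict[str, list[int]]:
    """Retain the contiguous infusion-plateau scans per polarity.

    The default rule keeps the contiguous run of scans, containing the
    TIC maximum, whose total ion current is at least ``tic_threshold`` of
    that polarity's maximum TIC.  ``override=(lo, hi)`` instead keeps
    exactly the scans with ``lo <= scan_index <= hi`` (inclusive).
    """
    if not scans:
        raise EmptyInputError("no scans supplied")
    retained: dict[str, list[int]] = {}
    for polarity in sorted({s.polarity for s in scans}):
        pol_scans = sorted(
            (s for s in scans if s.polarity == polarity), key=lambda s: s.scan_index
        )
        if override is not None:
            lo, hi = override
            retained[polarity] = [
                s.scan_index for s in pol_scans if lo <= s.scan_index <= hi
            ]
            continue
        tics = np.array([s.tic for s in pol_scans])
        peak = int(np.argmax(tics))
        ok = tics >= tic_threshold * tics[peak]
        lo = peak
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        hi = peak
        while hi + 1 < len(ok) and ok[hi + 1]:
            hi += 1
        retained[polarity] = [s.scan_index for s in pol_scans[lo : hi + 1]]
    return retained


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_scans(
    scans: list[CentroidScan],
    bin_width: float = DEFAULT_BIN_WIDTH,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
    scan_window: dict[str, list[int]] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Bin one sample's scans into a feature intensity vector.

    Per scan, intensities of peaks rounding (half-up) to the same bin are
    summed; the per-bin value is the mean of those per-scan sums across
    the retained scans of that polarity (scans without the bin count as
    zero).  Returns the intensity series and a feature-info table with
    polarity, bin m/z and intensity-weighted accurate m/z.
    """
    if not scans:
        raise EmptyInputError("no scans supplied")
    import warnings

    for s in scans:
        if len(s.mz) >= CENTROID_PEAK_LIMIT:
            warnings.warn(
                f"scan {s.scan_index} has {len(s.mz)} peaks; input may not be centroided",
                stacklevel=2,
            )
    if scan_window is None:
        scan_window = select_scan_window(scans)
    lo, hi = mz_range
    totals: dict[tuple[str, int], float] = {}
    wsum_mz: dict[tuple[str, int], float] = {}
    wsum_int: dict[tuple[str, int], float] = {}
    n_scans: dict[str, int] = {}
    for polarity, indices in scan_window.items():
        index_set = set(indices)
        pol_scans = [
            s for s in scans if s.polarity == polarity and s.scan_index in index_set
        ]
        n_scans[polarity] = len(pol_scans)
        for scan in pol_scans:
            per_scan: dict[int, float] = {}
            for mz, inten in zip(scan.mz, scan.intensity):
                if mz < lo or mz > hi:
                    continue
                b = int(math.floor(mz / bin_width + 0.5))
                per_scan[b] = per_scan.get(b, 0.0) + inten
                key = (polarity, b)
                wsum_mz[key] = wsum_mz.get(key, 0.0) + mz * inten
                wsum_int[key] = wsum_int.get(key, 0.0) + inten
            for b, v in per_scan.items():
                key = (polarity, b)
                totals[key] = totals.get(key, 0.0) + v
    records = []
    for (polarity, b), total in totals.items():
        bin_mz = b * bin_width
        fid = feature_id(polarity, bin_mz, bin_width)
        wint = wsum_int[(polarity, b)]
        accurate = wsum_mz[(polarity, b)] / wint if wint > 0 else bin_mz
        records.append((fid, polarity, bin_mz, accurate, total / n_scans[polarity]))
    records.sort(key=lambda r: (r[1], r[2]))
    index = [r[0] for r in records]
    intensities = pd.Series([r[4] for r in records], index=index, dtype=float)
    info = pd.DataFrame(
        {
            "polarity": [r[1] for r in records],
            "bin_mz": [r[2] for r in records],
            "accurate_mz": [r[3] for r in records],
        },
        index=index,
    )
    return intensities, info


def build_feature_matrix(
    sample_scans: dict[str, list[CentroidScan]],
    bin_width: float = DEFAULT_BIN_WIDTH,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
    scan_window_override: tuple[int, int] | None = None,
) -> FeatureMatrix:
    """Bin every sample and align the bins into one features x samples table.

    Bins absent from a sample are zero-filled.  The accurate m/z of a
    feature is the intensity-weighted mean of the per-sample accurate
    m/z values.
    """
    if not sample_scans:
        raise EmptyInputError("no samples supplied")
    columns: dict[str, pd.Series] = {}
    acc_w: dict[str, float] = {}
    acc_wm: dict[str, float] = {}
    info_rows: dict[str, tuple[str, float]] = {}
    for sample, scans in sample_scans.items():
        window = None
        if scan_window_override is not None:
            window = select_scan_window(scans, override=scan_window_override)
        vec, info = bin_scans(scans, bin_width, mz_range, scan_window=window)
        columns[sample] = vec
        for fid in vec.index:
            w = vec[fid]
            acc_w[fid] = acc_w.get(fid, 0.0) + w
            acc_wm[fid] = acc_wm.get(fid, 0.0) + w * info.loc[fid, "accurate_mz"]
            info_rows[fid] = (info.loc[fid, "polarity"], info.loc[fid, "bin_mz"])
    values = pd.DataFrame(columns).fillna(0.0)
    values = values.sort_index(
        key=lambda ids: [(fid[0], float(fid[1:])) for fid in ids]
    )
    info = pd.DataFrame(
        {
            "polarity": [info_rows[f][0] for f in values.index],
            "bin_mz": [info_rows[f][1] for f in values.index],
            "accurate_mz": [
                acc_wm[f] / acc_w[f] if acc_w[f] > 0 else info_rows[f][1]
                for f in values.index
            ],
        },
        index=values.index,
    )
    provenance = {
        "bin_width": bin_width,
        "mz_range": list(mz_range),
        "scan_window": (
            "override" if scan_window_override is not None else "tic>=50% of max, contiguous"
        ),
        "filters": [],
    }
    return FeatureMatrix(values=values, feature_info=info, provenance=provenance)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def occupancy_filter(
    matrix: FeatureMatrix,
    class_labels: dict[str, str] | pd.Series,
    threshold: float = 2 / 3,
) -> FeatureMatrix:
    """Keep features detected in at least ``threshold`` of samples of some class.

    Occupancy of a feature within a class is the fraction of that class's
    samples with intensity > 0; a feature survives if any class reaches
    the threshold.
    """
    if not 0 < threshold <= 1:
        raise FilterParameterError(f"occupancy threshold {threshold} outside (0, 1]")
    labels = pd.Series(class_labels)
    missing = [s for s in matrix.samples if s not in labels.index]
    if missing:
        raise EmptyInputError(f"samples without class label: {missing}")
    present = matrix.values > 0
    keep = pd.Series(False, index=matrix.values.index)
    for cls in sorted(labels.unique()):
        cols = [s for s in matrix.samples if labels[s] == cls]
        if cols:
            keep |= present[cols].mean(axis=1) >= threshold
    return matrix.subset(matrix.values.index[keep], note=f"occupancy>={threshold:.3g}")


def qc_filter(
    matrix: FeatureMatrix,
    qc_sample_ids: list[str],
    max_rsd: float = 0.5,
    min_occupancy: float = 2 / 3,
) -> FeatureMatrix:
    """Drop features that are unstable across pooled-QC injections.

    A feature is removed when its QC occupancy is below ``min_occupancy``
    or its relative standard deviation (sd/mean, ddof=1) across QC
    injections exceeds ``max_rsd``.
    """
    qc_ids = [s for s in qc_sample_ids]
    if len(qc_ids) < 2:
        raise EmptyInputError("QC filtering needs at least 2 QC samples")
    qc = matrix.values[qc_ids]
    occupancy = (qc > 0).mean(axis=1)
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    keep = (occupancy >= min_occupancy) & (mean > 0) & (rsd <= max_rsd)
    return matrix.subset(
        matrix.values.index[keep], note=f"qc rsd<={max_rsd:.3g}, occ>={min_occupancy:.3g}"
    )
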