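"""Spectral binning: window selection, bin aggregation, filters."""

import numpy as np
import pytest

from teametab.binning import (
    bin_scans,
    build_feature_matrix,
    occupancy_filter,
    qc_filter,
    select_scan_window,
)
from teametab.errors import EmptyInputError, FilterParameterError
from teametab.mzml import read_mzml, write_mzml

from conftest import make_scan


def scans_with_tics(tics, polarity="negative"):
    return [
        make_scan(polarity, i + 1, [(100.0, t)]) for i, t in enumerate(tics)
    ]


class TestScanWindow:
    def test_plateau_rule(self):
        window = select_scan_window(scans_with_tics([1, 10, 10, 1]))
        assert window["negative"] == [2, 3]

    def test_uniform_tics_keep_all(self):
        window = select_scan_window(scans_with_tics([5, 5, 5, 5, 5]))
        assert window["negative"] == [1, 2, 3, 4, 5]

    def test_override_window(self):
        window = select_scan_window(scans_with_tics(range(1, 21)), override=(6, 14))
        assert window["negative"] == list(range(6, 15))

    def test_noncontiguous_high_scan_excluded(self):
        # scan 1 reaches the threshold but is separated from the plateau
        window = select_scan_window(scans_with_tics([9, 1, 10, 9, 1]))
        assert window["negative"] == [3, 4]

    def test_empty_error(self):
        with pytest.raises(EmptyInputError):
            select_scan_window([])


class TestBinScans:
    def test_same_bin_summed_within_scan(self):
        scans = [make_scan("negative", 1, [(89.0244, 100.0), (89.0249, 50.0)])]
        vec, info = bin_scans(scans)
        assert vec["n89.02"] == 150.0
        assert info.loc["n89.02", "polarity"] == "negative"

    def test_mean_across_scans(self):
        scans = [
            make_scan("negative", 1, [(89.0244, 150.0)]),
            make_scan("negative", 2, [(89.0244, 50.0)]),
        ]
        vec, _ = bin_scans(scans, scan_window={"negative": [1, 2]})
        assert vec["n89.02"] == 100.0

    def test_scan_missing_bin_counts_as_zero(self):
        scans = [
            make_scan("negative", 1, [(89.0244, 150.0), (200.0, 5.0)]),
            make_scan("negative", 2, [(200.0, 5.0)]),
        ]
        vec, _ = bin_scans(scans, scan_window={"negative": [1, 2]})
        assert vec["n89.02"] == 75.0

    def test_out_of_range_peak_dropped(self):
        scans = [make_scan("negative", 1, [(54.9, 10.0), (100.0, 1.0)])]
        vec, _ = bin_scans(scans)
        assert "n54.90" not in vec.index
        assert "n100.00" in vec.index

    def test_accurate_mz_weighted_mean(self):
        scans = [make_scan("negative", 1, [(89.0244, 100.0), (89.0249, 50.0)])]
        _, info = bin_scans(scans)
        expected = (89.0244 * 100 + 89.0249 * 50) / 150
        assert info.loc["n89.02", "accurate_mz"] == pytest.approx(expected, abs=1e-9)

    def test_peak_order_invariance(self):
        peaks = [(70.004, 3.0), (70.006, 5.0), (71.111, 2.0), (90.5, 7.0)]
        v1, _ = bin_scans([make_scan("negative", 1, peaks)])
        v2, _ = bin_scans([make_scan("negative", 1, peaks[::-1])])
        assert (v1.sort_index() == v2.sort_index()).all()

    def test_total_intensity_not_created(self):
        rng = np.random.default_rng(3)
        peaks = [(float(m), float(v)) for m, v in
                 zip(rng.uniform(55, 1200, 50), rng.uniform(0, 100, 50))]
        scans = [make_scan("positive", 1, peaks)]
        vec, _ = bin_scans(scans)
        assert vec.sum() <= sum(v for _, v in peaks) + 1e-9

    def test_profile_mode_warning(self):
        mz = np.linspace(100, 200, 10_000)
        scans = [make_scan("negative", 1, list(zip(mz, np.ones(10_000))))]
        with pytest.warns(UserWarning, match="centroided"):
            bin_scans(scans)


class TestOccupancyFilter:
    labels = {"s1": "a", "s2": "a", "s3": "a", "s4": "b"}

    def test_full_in_one_class_retained(self, tiny_matrix):
        out = occupancy_filter(tiny_matrix, self.labels, threshold=2 / 3)
        assert "n100.00" in out.values.index  # 3/3 in class a

    def test_sparse_everywhere_dropped(self):
        import pandas as pd

        from teametab.binning import FeatureMatrix

        # one feature present in 1 of 3 samples of every class
        values = pd.DataFrame(
            [[5.0, 0.0, 0.0, 7.0, 0.0, 0.0]],
            index=["n100.00"],
            columns=[f"s{i}" for i in range(6)],
        )
        info = pd.DataFrame(
            {"polarity": ["negative"], "bin_mz": [100.0], "accurate_mz": [100.0]},
            index=values.index,
        )
        fm = FeatureMatrix(values, info, {"filters": []})
        labels = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        out = occupancy_filter(fm, labels, threshold=2 / 3)
        assert len(out.values) == 0

    def test_all_zero_dropped(self, tiny_matrix):
        out = occupancy_filter(tiny_matrix, self.labels, threshold=2 / 3)
        assert "n200.00" not in out.values.index

    def test_threshold_boundary_full_class(self, tiny_matrix):
        # full occupancy in exactly one class suffices even at threshold 1.0
        out = occupancy_filter(tiny_matrix, self.labels, threshold=1.0)
        assert "n100.00" in out.values.index  # 3/3 in class a, 0/1 in b
        assert "p400.00" in out.values.index  # present everywhere

    def test_idempotent(self, tiny_matrix):
        once = occupancy_filter(tiny_matrix, self.labels, 2 / 3)
        twice = occupancy_filter(once, self.labels, 2 / 3)
        assert list(once.values.index) == list(twice.values.index)

    def test_bad_threshold(self, tiny_matrix):
        with pytest.raises(FilterParameterError):
            occupancy_filter(tiny_matrix, self.labels, threshold=0.0)

    def test_missing_label_error(self, tiny_matrix):
        with pytest.raises(EmptyInputError):
            occupancy_filter(tiny_matrix, {"s1": "a"}, 2 / 3)


class TestQCFilter:
    def test_zero_variance_retained_high_rsd_dropped(self, tiny_matrix):
        m = tiny_matrix
        m.values["q1"] = [100.0, 0.0, 10.0, 1.0]
        m.values["q2"] = [100.0, 0.0, 190.0, 1.0]
        m.values["q3"] = [100.0, 0.0, 100.0, 1.0]
        out = qc_filter(m, ["q1", "q2", "q3"], max_rsd=0.5)
        assert "n100.00" in out.values.index  # rsd 0
        assert "p300.00" not in out.values.index  # rsd ~0.9
        assert "n200.00" not in out.values.index  # absent in all QCs

    def test_two_point_rsd(self, tiny_matrix):
        m = tiny_matrix
        m.values["q1"] = [10.0, 1.0, 1.0, 1.0]
        m.values["q2"] = [190.0, 1.0, 1.0, 1.0]
        out = qc_filter(m, ["q1", "q2"], max_rsd=0.5)
        # sd/mean of (10, 190) = 127.28/100 > 0.5
        assert "n100.00" not in out.values.index

    def test_needs_two_qcs(self, tiny_matrix):
        with pytest.raises(EmptyInputError):
            qc_filter(tiny_matrix, ["s1"], 0.5)


class TestOracleEquivalence:
    """Binned vectors equal an independent per-peak brute-force assignment."""

    @staticmethod
    def brute_force(scans, bin_width=0.01, mz_range=(55.0, 1200.0)):
        import math

        by_polarity = {}
        for scan in scans:
            by_polarity.setdefault(scan.polarity, []).append(scan)
        totals = {}
        for polarity, pol_scans in by_polarity.items():
            n = len(pol_scans)
            for scan in pol_scans:
                per_scan = {}
                for mz, inten in zip(scan.mz, scan.intensity):
                    if mz_range[0] <= mz <= mz_range[1]:
                        b = int(math.floor(mz / bin_width + 0.5))
                        per_scan[b] = per_scan.get(b, 0.0) + inten
                for b, v in per_scan.items():
                    totals[(polarity, b)] = totals.get((polarity, b), 0.0) + v
        out = {}
        for (polarity, b), v in totals.items():
            out[(polarity, b)] = v / len(by_polarity[polarity])
        return out

    def test_random_scan_sets(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            scans = []
            for s in range(int(rng.integers(2, 6))):
                n = int(rng.integers(5, 40))
                mz = rng.uniform(50, 1250, n)
                inten = rng.uniform(0, 1e5, n)
                scans.append(make_scan("negative", s + 1, list(zip(mz, inten))))
            window = {"negative": [s.scan_index for s in scans]}
            vec, info = bin_scans(scans, scan_window=window)
            oracle = self.brute_force(scans)
            assert len(vec) == len(oracle)
            for fid, value in vec.items():
                b = int(round(info.loc[fid, "bin_mz"] / 0.01))
                assert value == oracle[("negative", b)]


def test_matrix_tsv_roundtrip(tmp_path, tiny_matrix):
    path = tmp_path / "matrix.tsv"
    tiny_matrix.provenance["bin_width"] = 0.01
    tiny_matrix.write_tsv(path)
    back = tiny_matrix.read_tsv(path)
    assert np.allclose(back.values.to_numpy(), tiny_matrix.values.to_numpy())
    assert back.provenance["bin_width"] == 0.01


def test_mzml_roundtrip(tmp_path):
    scans = [
        make_scan("positive", 1, [(100.123456, 55.5), (200.2, 1e6)]),
        make_scan("negative", 2, [(300.000001, 0.0)]),
    ]
    path = tmp_path / "sample.mzML"
    write_mzml(path, scans)
    back = read_mzml(path)
    assert len(back) == 2
    for a, b in zip(scans, back):
        assert a.polarity == b.polarity
        assert a.scan_index == b.scan_index
        assert np.array_equal(a.mz, b.mz)
        assert np.array_equal(a.intensity, b.intensity)


def test_build_feature_matrix_aligns_and_zero_fills():
    s1 = [make_scan("negative", 1, [(100.004, 10.0)])]
    s2 = [make_scan("negative", 1, [(100.004, 30.0), (150.0, 5.0)])]
    fm = build_feature_matrix({"a": s1, "b": s2})
    assert fm.values.loc["n150.00", "a"] == 0.0
    assert fm.values.loc["n100.00", "b"] == 30.0
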