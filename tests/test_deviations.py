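"""Motif-accessibility deviations, background sampling and Z-scores."""

import numpy as np
import pandas as pd
import pytest

from accessome.deviations import (
    deviation_zscores,
    differential_deviations,
    motif_observed_expected,
    resize_peaks,
    sample_background_sets,
)
from accessome.intervals import merge_to_accessome


def straight_line_zscores(counts, occupancy, backgrounds, library_sizes):
    """Independent plain-loop recomputation of the deviation Z-score formula."""
    peaks = list(counts.index)
    motifs = list(occupancy.columns)
    samples = list(counts.columns)

    def raw_dev(count_rows, lib):
        out = np.zeros((len(motifs), len(samples)))
        for mi, motif in enumerate(motifs):
            for si in range(len(samples)):
                obs = sum(
                    count_rows[pi][si]
                    for pi, pid in enumerate(peaks)
                    if occupancy.loc[pid, motif]
                )
                grand = sum(
                    sum(count_rows[pi])
                    for pi, pid in enumerate(peaks)
                    if occupancy.loc[pid, motif]
                )
                exp = grand / lib.sum() * lib[si]
                out[mi, si] = (obs - exp) / exp if exp > 0 else np.nan
        return out

    base_rows = [counts.iloc[i].to_numpy(dtype=float) for i in range(len(peaks))]
    lib = np.array([library_sizes[s] for s in samples], dtype=float)
    raw = raw_dev(base_rows, lib)
    bg = []
    for iteration in backgrounds:
        rows = [counts.iloc[idx].to_numpy(dtype=float) for idx in iteration]
        lib_bg = np.sum(rows, axis=0)  # background column totals
        bg.append(raw_dev(rows, lib_bg))
    bg = np.array(bg)
    mean, sd = bg.mean(axis=0), bg.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, (raw - mean) / sd, np.nan)


class TestResizePeaks:
    def make(self, intervals, size=10_000):
        return merge_to_accessome([intervals], {"chr1": size})

    def test_long_peak_centered_to_width(self):
        acc = self.make([("chr1", 0, 1_000)])
        out = resize_peaks(acc, 200)
        assert (int(out["start"].iloc[0]), int(out["end"].iloc[0])) == (400, 600)

    def test_exact_width_peak_unchanged(self):
        acc = self.make([("chr1", 300, 500)])
        out = resize_peaks(acc, 200)
        assert (int(out["start"].iloc[0]), int(out["end"].iloc[0])) == (300, 500)

    def test_clipped_at_origin(self):
        acc = self.make([("chr1", 10, 61)])
        out = resize_peaks(acc, 200)
        # center 35: window [-65, 135) clips to [0, 135)
        assert (int(out["start"].iloc[0]), int(out["end"].iloc[0])) == (0, 135)


class TestObservedExpected:
    def test_single_sample_deviation_is_exactly_zero(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["p1", "p2"])
        occ = pd.DataFrame({"m": [True, False]}, index=["p1", "p2"])
        _, _, dev = motif_observed_expected(counts, occ)
        assert dev.loc["m", "s1"] == 0.0

    def test_motif_on_every_peak_deviation_zero(self):
        counts = pd.DataFrame(
            {"s1": [10, 90], "s2": [30, 70]}, index=["p1", "p2"]
        )
        occ = pd.DataFrame({"m": [True, True]}, index=["p1", "p2"])
        _, _, dev = motif_observed_expected(counts, occ)
        np.testing.assert_allclose(dev.loc["m"].to_numpy(), [0.0, 0.0], atol=1e-15)

    def test_two_sample_hand_arithmetic(self):
        # counts [[10,30],[90,70]], motif on peak 1: grand fraction 40/200;
        # expected (20, 20); deviations (-0.5, +0.5)
        counts = pd.DataFrame(
            {"s1": [10, 90], "s2": [30, 70]}, index=["p1", "p2"]
        )
        occ = pd.DataFrame({"m": [True, False]}, index=["p1", "p2"])
        obs, exp, dev = motif_observed_expected(counts, occ)
        assert obs.loc["m"].tolist() == [10.0, 30.0]
        assert exp.loc["m"].tolist() == [20.0, 20.0]
        assert dev.loc["m"].tolist() == [-0.5, 0.5]

    def test_library_weighted_mean_deviation_is_zero(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 200, size=(30, 5)),
            index=[f"p{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(5)],
        )
        occ = pd.DataFrame(
            rng.random((30, 3)) < 0.4,
            index=counts.index, columns=["m1", "m2", "m3"],
        )
        lib = counts.sum(axis=0)
        _, _, dev = motif_observed_expected(counts, occ, lib)
        weighted = (dev * lib).sum(axis=1) / lib.sum()
        np.testing.assert_allclose(weighted.to_numpy(), 0.0, atol=1e-12)

    def test_library_scaling_invariance(self, rng):
        """Rescaling counts and library sizes jointly leaves deviations fixed.

        The sample's motif fraction obs/lib and the grand fraction both
        survive a common rescaling, so raw deviations are exactly invariant.
        """
        counts = pd.DataFrame(
            rng.integers(1, 200, size=(20, 4)).astype(float),
            index=[f"p{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(4)],
        )
        occ = pd.DataFrame(
            rng.random((20, 2)) < 0.5, index=counts.index, columns=["m1", "m2"]
        )
        lib = counts.sum(axis=0)
        _, _, d1 = motif_observed_expected(counts, occ, lib)
        _, _, d2 = motif_observed_expected(counts * 3.0, occ, lib * 3.0)
        np.testing.assert_allclose(
            d1.to_numpy(), d2.to_numpy(), atol=1e-9
        )


class TestBackgroundSampling:
    @pytest.fixture
    def inputs(self, rng):
        n = 40
        peaks = [f"p{i}" for i in range(n)]
        counts = pd.DataFrame(
            rng.integers(10, 500, size=(n, 4)),
            index=peaks, columns=[f"s{i}" for i in range(4)],
        )
        seqs = {
            pid: "".join(rng.choice(list("ACGT"), size=100)) for pid in peaks
        }
        return peaks, counts, seqs

    def test_seeded_runs_identical(self, inputs):
        peaks, counts, seqs = inputs
        a = sample_background_sets(peaks, counts, seqs, 5, 4, seed=3)
        b = sample_background_sets(peaks, counts, seqs, 5, 4, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_identical_peaks_sample_uniformly(self, inputs):
        peaks, counts, _ = inputs
        seqs = {pid: "ACGT" * 25 for pid in peaks}
        flat = pd.DataFrame(100, index=peaks, columns=counts.columns)
        idx = sample_background_sets(peaks, flat, seqs, 200, 10, seed=0)
        # single bin: every peak index should be drawn somewhere
        assert len(np.unique(idx)) > len(peaks) * 0.8

    def test_too_few_iterations_rejected(self, inputs):
        peaks, counts, seqs = inputs
        with pytest.raises(ValueError, match="at least 2"):
            sample_background_sets(peaks, counts, seqs, 0, 4, seed=0)

    def test_samples_come_from_matched_bins(self, inputs):
        peaks, counts, seqs = inputs
        n_bins = 4
        idx = sample_background_sets(peaks, counts, seqs, 10, n_bins, seed=0)
        from accessome.deviations import _gc_content
        from scipy.stats import rankdata

        gc = _gc_content(seqs, peaks)
        lib = counts.sum(axis=0).to_numpy(dtype=float)
        access = (counts.to_numpy() / lib[None, :]).mean(axis=1)

        def bins(x):
            r = rankdata(x, method="average") - 1
            return np.minimum((r / len(x) * n_bins).astype(int), n_bins - 1)

        cell = bins(gc) * n_bins + bins(access)
        for it in idx:
            assert (cell[it] == cell).all()


class TestDeviationZscores:
    @pytest.fixture
    def toy(self, rng):
        n = 30
        peaks = [f"p{i}" for i in range(n)]
        counts = pd.DataFrame(
            rng.integers(10, 400, size=(n, 6)),
            index=peaks, columns=[f"s{i}" for i in range(6)],
        )
        occ = pd.DataFrame(
            rng.random((n, 3)) < 0.4, index=peaks, columns=["m1", "m2", "m3"]
        )
        seqs = {pid: "".join(rng.choice(list("ACGT"), size=80)) for pid in peaks}
        backgrounds = sample_background_sets(peaks, counts, seqs, 8, 3, seed=0)
        return counts, occ, backgrounds

    def test_matches_straight_line_recomputation(self, toy):
        counts, occ, backgrounds = toy
        dev = deviation_zscores(counts, occ, backgrounds)
        lib = counts.sum(axis=0)
        want = straight_line_zscores(counts, occ, backgrounds, lib)
        np.testing.assert_allclose(dev.zscore.to_numpy(), want, atol=1e-9)

    def test_background_order_permutation_invariant(self, toy):
        counts, occ, backgrounds = toy
        a = deviation_zscores(counts, occ, backgrounds)
        b = deviation_zscores(counts, occ, backgrounds[::-1])
        pd.testing.assert_frame_equal(a.zscore, b.zscore)

    def test_motif_on_all_peaks_flagged_na(self, toy):
        counts, _, backgrounds = toy
        occ = pd.DataFrame(True, index=counts.index, columns=["everywhere"])
        dev = deviation_zscores(counts, occ, backgrounds)
        assert dev.zscore.isna().all().all()
        assert dev.flagged.all().all()

    def test_raw_deviation_at_background_mean_gives_zero_z(self):
        counts = pd.DataFrame(
            {"s1": [50, 50], "s2": [70, 30]}, index=["p1", "p2"]
        )
        occ = pd.DataFrame({"m": [True, False]}, index=["p1", "p2"])
        # backgrounds alternate identity and swap; the raw deviation of the
        # identity iteration equals the observed one
        backgrounds = np.array([[0, 1], [1, 0], [0, 1], [1, 0]])
        dev = deviation_zscores(counts, occ, backgrounds)
        mean_bg_is_zero = dev.zscore.loc["m"]
        # symmetric background: z is (raw - mean)/sd with mean centred between
        # the two permutations, so |z| must be equal for both samples
        assert np.isfinite(mean_bg_is_zero).all()
        assert abs(mean_bg_is_zero["s1"]) == pytest.approx(
            abs(mean_bg_is_zero["s2"])
        )


class TestDifferentialDeviations:
    def make_dev(self, z):
        return pd.DataFrame(
            z, index=["m1"], columns=[f"s{i}" for i in range(len(z[0]))]
        )

    def test_identical_groups_p_one(self):
        z = self.make_dev([[1.0, 1.0, 1.0, 1.0]])
        groups = pd.Series(["a", "a", "b", "b"], index=z.columns)
        out = differential_deviations(z, groups)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_shifted_groups_significant(self, rng):
        noise = rng.normal(0, 1, size=8)
        z = self.make_dev([list(noise[:4]) + list(noise[4:] + 5.0)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=z.columns)
        out = differential_deviations(z, groups)
        assert out["p_value"].iloc[0] < 0.01

    def test_three_groups_use_anova(self, rng):
        z = pd.DataFrame(
            rng.normal(size=(2, 9)), index=["m1", "m2"],
            columns=[f"s{i}" for i in range(9)],
        )
        z.iloc[0, 6:] += 8.0
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=z.columns)
        out = differential_deviations(z, groups)
        assert out["p_value"].loc["m1"] < 0.01
        assert out["significant"].loc["m1"]

    def test_single_sample_group_rejected(self):
        z = self.make_dev([[0.0, 1.0, 2.0]])
        groups = pd.Series(["a", "a", "b"], index=z.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            differential_deviations(z, groups)

    def test_default_threshold_is_stringent(self, rng):
        z = pd.DataFrame(
            rng.normal(size=(4, 8)),
            index=[f"m{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=z.columns)
        out = differential_deviations(z, groups)
        assert (out.loc[out["significant"], "fdr"] < 0.01).all()


def test_unmatched_uniform_background_mode(rng):
    peaks = [f"p{i}" for i in range(30)]
    counts = pd.DataFrame(
        rng.integers(10, 500, size=(30, 3)), index=peaks,
        columns=["s0", "s1", "s2"],
    )
    seqs = {p: "ACGT" * 20 for p in peaks}
    idx = sample_background_sets(peaks, counts, seqs, 20, 10, seed=0, matched=False)
    assert idx.shape == (20, 30)
    # uniform over all peaks, not restricted to any bin
    assert len(np.unique(idx)) == 30
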