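import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import entropy as scipy_entropy

import frameindep as fi
from frameindep.divergence import (
    all_intra_pairs,
    estimate_period,
    gray_histogram,
    inter_pairs,
    intra_pairs,
    js_divergence,
    kl_divergence,
    pool_shift_curves,
    shift_curve,
)
from frameindep.errors import (
    EmptyInputError,
    InsufficientCasesError,
    RangeError,
)

from conftest import constant_sequence, grid_rois


def random_histogram(rng, zeros=False):
    alpha = rng.uniform(0.1, 2.0, size=256)
    h = rng.dirichlet(alpha)
    if zeros:
        h[rng.random(256) < 0.3] = 0.0
        h /= h.sum()
    return h


class TestGrayHistogram:
    def test_constant_roi_concentrates_at_its_value(self):
        h = gray_histogram(np.full((8, 8), 100, np.uint8))
        assert h.sum() == pytest.approx(1.0, abs=1e-9)
        assert h[100] > 0.999
        assert (h > 0).all()

    def test_all_values_once_is_near_uniform(self):
        h = gray_histogram(np.arange(256, dtype=np.uint8).reshape(16, 16))
        assert np.allclose(h, 1.0 / 256, atol=1e-6)

    def test_sums_to_one_on_random_rois(self, rng):
        for _ in range(100):
            img = rng.integers(0, 256, size=(6, 6), dtype=np.uint8)
            assert gray_histogram(img).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyInputError):
            gray_histogram(np.empty((0, 4), dtype=np.uint8))


class TestKLDivergence:
    def test_identity_is_zero(self, rng):
        p = random_histogram(rng)
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_forced_one_bit(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_asymmetric(self):
        p, q = np.array([0.5, 0.5]), np.array([0.9, 0.1])
        assert kl_divergence(p, q) != pytest.approx(kl_divergence(q, p))

    def test_zero_bin_in_q_is_domain_error(self):
        with pytest.raises(ValueError, match="smoothed"):
            kl_divergence([0.5, 0.5], [1.0, 0.0])


class TestJSDivergence:
    def test_identity_and_disjoint_bounds(self, rng):
        p = random_histogram(rng)
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_half_point_analytic_value(self):
        # JS((0.5, 0.5), (1, 0)) = 1 - 0.5 h2(0.25)... evaluated by hand
        assert js_divergence([0.5, 0.5], [1.0, 0.0]) == pytest.approx(
            0.31127812, abs=1e-6
        )

    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_bounds_entropy_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = random_histogram(rng, zeros=rng.random() < 0.5)
        q = random_histogram(rng, zeros=rng.random() < 0.5)
        js = js_divergence(p, q)
        assert 0.0 <= js <= 1.0
        assert js == pytest.approx(js_divergence(q, p), abs=1e-12)
        m = 0.5 * (p + q)
        identity = scipy_entropy(m, base=2) - 0.5 * scipy_entropy(
            p, base=2
        ) - 0.5 * scipy_entropy(q, base=2)
        assert js == pytest.approx(identity, abs=1e-9)


class TestIntraPairs:
    def test_sample_count_contract(self, rng):
        frames = rng.integers(0, 256, size=(10, 32, 64), dtype=np.uint8)
        seq = fi.ImageSequence("c", "g", frames)
        rois = grid_rois(n=5, n_frames=10)
        assert len(intra_pairs(seq, rois, shift=1)) == 45
        assert len(intra_pairs(seq, rois, shift=9)) == 5  # boundary: F-1
        pooled = all_intra_pairs(seq, rois)
        assert len(pooled) == 5 * sum(range(1, 10))

    def test_identical_frames_have_zero_divergence(self):
        seq = constant_sequence(n_frames=5)
        samples = all_intra_pairs(seq, grid_rois(n=2, n_frames=5))
        assert (samples["js"] < 1e-9).all()
        assert (samples["shift"] == samples["frame_b"] - samples["frame_a"]).all()

    def test_shift_out_of_range_rejected(self):
        seq = constant_sequence(n_frames=3)
        with pytest.raises(RangeError):
            intra_pairs(seq, grid_rois(n_frames=3), shift=3)

    def test_cross_roi_pairing_covers_all_roi_combinations(self, rng):
        frames = rng.integers(0, 256, size=(6, 32, 64), dtype=np.uint8)
        seq = fi.ImageSequence("c", "g", frames)
        rois = grid_rois(n=3, n_frames=6)
        samples = intra_pairs(seq, rois, shift=2, cross_roi=True)
        assert len(samples) == (6 - 2) * 3 * 3
        # matched-roi samples are a subset of the cross-roi population
        matched = intra_pairs(seq, rois, shift=2)
        assert set(matched["js"]).issubset(set(samples["js"]))

    def test_shift_window_restricts_pooled_samples(self, rng):
        frames = rng.integers(0, 256, size=(8, 32, 64), dtype=np.uint8)
        seq = fi.ImageSequence("c", "g", frames)
        rois = grid_rois(n=2, n_frames=8)
        windowed = all_intra_pairs(seq, rois, min_shift=3, max_shift=5)
        assert sorted(windowed["shift"].unique()) == [3, 4, 5]
        assert len(windowed) == 2 * sum(8 - d for d in (3, 4, 5))
        with pytest.raises(RangeError):
            all_intra_pairs(seq, rois, min_shift=5, max_shift=3)


class TestInterPairs:
    def test_identical_constant_cases_have_zero_divergence(self):
        seqs = [constant_sequence(case_id=f"c{i}") for i in range(2)]
        rois = {s.case_id: grid_rois() for s in seqs}
        samples = inter_pairs(seqs, rois, max_pairs=50, seed=0)
        assert len(samples) == 50
        assert (samples["js"] < 1e-9).all()
        assert (samples["case_a"] != samples["case_b"]).all()

    def test_reproducible_from_seed(self, tiny_cohort):
        seqs = [s for s in tiny_cohort.sequences if s.group == "normal"]
        a = inter_pairs(seqs, tiny_cohort.rois, max_pairs=100, seed=3)
        b = inter_pairs(seqs, tiny_cohort.rois, max_pairs=100, seed=3)
        assert a.equals(b)
        c = inter_pairs(seqs, tiny_cohort.rois, max_pairs=100, seed=4)
        assert not a["js"].equals(c["js"])

    def test_single_case_rejected(self, tiny_cohort):
        seq = tiny_cohort.sequences[0]
        with pytest.raises(InsufficientCasesError):
            inter_pairs([seq], tiny_cohort.rois, max_pairs=10, seed=0)

    def test_different_intensity_distributions_diverge_more_than_intra(self):
        rng = np.random.default_rng(0)
        mk = lambda mu, cid: fi.ImageSequence(
            cid, "g",
            np.clip(rng.normal(mu, 10, size=(6, 32, 32)), 0, 255).astype(np.uint8),
        )
        seqs = [mk(60, "lo"), mk(140, "hi")]
        rois = {s.case_id: grid_rois(n=2, n_frames=6) for s in seqs}
        inter = inter_pairs(seqs, rois, max_pairs=200, seed=1)
        intra_lo = all_intra_pairs(seqs[0], rois["lo"])
        intra_hi = all_intra_pairs(seqs[1], rois["hi"])
        assert inter["js"].mean() > intra_lo["js"].mean()
        assert inter["js"].mean() > intra_hi["js"].mean()


class TestShiftCurve:
    def test_identical_frames_flat_zero(self):
        seq = constant_sequence(n_frames=6)
        curve = shift_curve(seq, grid_rois(n_frames=6))
        assert (curve["mean_js"] < 1e-9).all()
        assert curve["n"].tolist() == [(6 - d) * 2 for d in range(1, 6)]

    def test_two_state_alternation_gives_alternating_curve(self, rng):
        a = rng.integers(0, 100, size=(16, 16), dtype=np.uint8)
        b = rng.integers(156, 256, size=(16, 16), dtype=np.uint8)
        frames = np.stack([a if t % 2 == 0 else b for t in range(10)])
        seq = fi.ImageSequence("c", "g", frames)
        curve = shift_curve(seq, fi.ROISet.broadcast([fi.ROI(0, 0, 0, 16, 16)], 10))
        even = curve[curve["shift"] % 2 == 0]["mean_js"]
        odd = curve[curve["shift"] % 2 == 1]["mean_js"]
        assert (even < 1e-9).all()
        assert (odd > 0.5).all()

    def test_pool_shift_curves_weights_by_n(self):
        c1 = pd.DataFrame({"shift": [1, 2], "mean_js": [0.1, 0.2],
                           "sd_js": [0.0, 0.0], "n": [10, 5]})
        c2 = pd.DataFrame({"shift": [1, 2], "mean_js": [0.3, 0.4],
                           "sd_js": [0.0, 0.0], "n": [30, 5]})
        pooled = pool_shift_curves([c1, c2])
        assert pooled["mean_js"].tolist() == pytest.approx([0.25, 0.3])


class TestEstimatePeriod:
    def test_noiseless_sinusoid_recovers_its_period(self):
        shifts = np.arange(1, 120)
        curve = pd.DataFrame({
            "shift": shifts,
            "mean_js": 0.05 + 0.02 * np.sin(2 * np.pi * shifts / 35.0),
        })
        period = estimate_period(curve)
        assert period == pytest.approx(35.0, abs=1.0)

    def test_constant_curve_has_no_period(self):
        curve = pd.DataFrame({"shift": np.arange(1, 40),
                              "mean_js": np.full(39, 0.07)})
        assert estimate_period(curve) is None

    def test_too_short_curve_rejected(self):
        curve = pd.DataFrame({"shift": [1, 2, 3], "mean_js": [0.1, 0.2, 0.1]})
        with pytest.raises(RangeError):
            estimate_period(curve)


class TestRhoMonotonicity:
    def test_intra_inter_gap_grows_with_rho(self):
        gaps = []
        for rho in (0.0, 0.5, 0.9):
            cfg = fi.PhantomConfig(
                groups={"normal": fi.GroupParams(25.4, 13.2, sigma_structure=6.0)},
                cases_per_group=3, frames_per_case=10, rho=rho, seed=11,
            )
            cohort = fi.generate_cohort(cfg)
            intra = pd.concat(
                [all_intra_pairs(s, cohort.rois[s.case_id])
                 for s in cohort.sequences]
            )
            inter = inter_pairs(cohort.sequences, cohort.rois,
                                max_pairs=600, seed=5)
            gaps.append(inter["js"].mean() - intra["js"].mean())
        assert gaps[0] < gaps[1] < gaps[2]
        assert abs(gaps[0]) < 0.02  # rho = 0: intra ~ inter
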