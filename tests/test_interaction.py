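import numpy as np
import pandas as pd
import pytest

from epilink.core import GenomicInterval
from epilink.interaction import (
    FragmentMap,
    call_interactions,
    digest,
    fit_decay,
    percent_input,
    profile,
    relative_interaction_frequency,
)


def synthetic_map(n=60, length=2000, chrom="c"):
    bounds = np.arange(n + 1) * length
    frs = [GenomicInterval(chrom, int(a), int(b)) for a, b in zip(bounds, bounds[1:])]
    return FragmentMap(frs, n // 2)


class TestDigest:
    def test_cut_positions(self):
        frs = digest("AAGATCAAGATCAA", "GATC")
        assert [(f.start, f.end) for f in frs] == [(0, 2), (2, 8), (8, 14)]

    def test_absent_site_single_fragment(self):
        frs = digest("AAAA" * 5, "GATC")
        assert len(frs) == 1
        assert frs[0].length == 20

    def test_case_insensitive(self):
        assert [(f.start, f.end) for f in digest("aagatcaagatcaa", "gatc")] == [
            (0, 2), (2, 8), (8, 14),
        ]

    def test_bad_site_rejected(self):
        with pytest.raises(ValueError):
            digest("ACGT" * 10, "GAT")
        with pytest.raises(ValueError):
            digest("ACGT" * 10, "GATX")


class TestFragmentMap:
    def test_non_contiguous_rejected(self):
        frs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 12, 20)]
        with pytest.raises(ValueError):
            FragmentMap(frs, 0)

    def test_viewpoint_bounds(self):
        frs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20)]
        with pytest.raises(ValueError):
            FragmentMap(frs, 5)


class TestProfile:
    def test_uniform_counts_uniform_normalized(self):
        fmap = synthetic_map()
        prof = profile(np.full(60, 7.0), fmap)
        vals = prof.normalized[~prof.masked]
        assert np.allclose(vals, vals[0])

    def test_normalization_mass_conserved(self):
        rng = np.random.default_rng(0)
        prof = profile(rng.integers(0, 500, size=60), synthetic_map())
        assert np.nansum(prof.normalized) == pytest.approx(1e6, rel=1e-9)

    def test_masked_fragments_excluded(self):
        fmap = synthetic_map()
        counts = np.ones(60)
        counts[fmap.viewpoint_index] = 1e9  # must not leak into normalization
        prof = profile(counts, fmap, exclude_k=2)
        assert np.isnan(prof.normalized[fmap.viewpoint_index])
        assert prof.masked.sum() == 5
        vals = prof.normalized[~prof.masked]
        assert np.allclose(vals, vals[0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 100, size=60).astype(float)
        p1 = profile(counts, synthetic_map())
        p2 = profile(counts * 2, synthetic_map())
        assert np.allclose(p1.normalized, p2.normalized, equal_nan=True)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            profile(np.array([-1.0] + [1.0] * 59), synthetic_map())


class TestFitDecay:
    def test_noiseless_power_law_recovered(self):
        fmap = synthetic_map(n=200)
        prof = profile(np.zeros(200), fmap)
        d = prof.distance
        counts = np.where(d > 0, 1000.0 * (np.maximum(d, 1.0) / 1.0) ** -1.0 * 1e4, 0)
        # scale so counts are large where unmasked: use a = 1e7, b = 1
        counts = np.where(d > 0, 1e7 * np.maximum(d, 1.0) ** -1.0, 0)
        prof = fit_decay(profile(counts, fmap))
        assert prof.decay_b == pytest.approx(1.0, abs=0.05)

    def test_noisy_power_law_recovered(self):
        rng = np.random.default_rng(4)
        fmap = synthetic_map(n=300)
        prof0 = profile(np.zeros(300), fmap)
        lam = 1e7 * np.maximum(prof0.distance, 1.0) ** -1.2
        counts = rng.poisson(np.where(prof0.distance > 0, lam, 0))
        prof = fit_decay(profile(counts, fmap))
        assert prof.decay_b == pytest.approx(1.2, abs=0.2)

    def test_constant_counts_flagged(self):
        prof = fit_decay(profile(np.full(60, 50.0), synthetic_map()))
        assert prof.decay_flagged
        assert prof.decay_b <= 1e-5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(profile(np.zeros(60), synthetic_map()))


class TestCallInteractions:
    def fitted_profile(self, counts, n=300):
        return fit_decay(profile(counts, synthetic_map(n=n)))

    def test_pure_decay_no_calls(self):
        rng = np.random.default_rng(5)
        fmap = synthetic_map(n=300)
        d = profile(np.zeros(300), fmap).distance
        counts = rng.poisson(np.where(d > 0, 1e7 * np.maximum(d, 1.0) ** -1.0, 0))
        prof = self.fitted_profile(counts)
        assert call_interactions(prof) == []

    def test_planted_bump_called_once(self):
        rng = np.random.default_rng(6)
        fmap = synthetic_map(n=300)
        d = profile(np.zeros(300), fmap).distance
        lam = np.where(d > 0, 1e7 * np.maximum(d, 1.0) ** -1.0, 0.0)
        bump = slice(200, 206)
        lam[bump] *= 5
        prof = self.fitted_profile(rng.poisson(lam))
        calls = call_interactions(prof)
        assert len(calls) == 1
        planted = GenomicInterval("c", 200 * 2000, 206 * 2000)
        assert calls[0].overlaps(planted)

    def test_raising_threshold_never_adds_calls(self):
        rng = np.random.default_rng(7)
        fmap = synthetic_map(n=300)
        d = profile(np.zeros(300), fmap).distance
        lam = np.where(d > 0, 1e7 * np.maximum(d, 1.0) ** -1.0, 0.0)
        lam[150:160] *= 4
        prof = self.fitted_profile(rng.poisson(lam))
        loose = call_interactions(prof, z_min=1.5)
        strict = call_interactions(prof, z_min=3.0)
        loose_cover = {(c.start, c.end) for c in loose}
        for c in strict:
            assert any(c.start >= s and c.end <= e for s, e in loose_cover)

    def test_requires_fit(self):
        prof = profile(np.ones(60), synthetic_map())
        with pytest.raises(ValueError):
            call_interactions(prof)


class TestRelativeInteractionFrequency:
    def test_elementwise_ratios(self):
        values = {"ctrl": 3.0, "a": 6.0, "b": 1.5, "c": 3.0}
        rif = relative_interaction_frequency(values, "ctrl")
        assert rif["ctrl"] == 1.0
        assert rif["a"] == 2.0
        assert rif["b"] == 0.5
        assert rif["c"] == 1.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            relative_interaction_frequency({"ctrl": 0.0, "a": 1.0}, "ctrl")
        with pytest.raises(ValueError):
            relative_interaction_frequency({"a": 1.0}, "ctrl")


class TestPercentInput:
    def table(self, ct_ip, ct_input, frac):
        return pd.DataFrame(
            {"site": ["s"], "ct_ip": [ct_ip], "ct_input": [ct_input], "input_fraction": [frac]}
        )

    def test_full_input_equal_ct_gives_100(self):
        out = percent_input(self.table(20.0, 20.0, 1.0))
        assert out["percent_input"].iloc[0] == pytest.approx(100.0)

    def test_one_percent_input_equal_ct(self):
        out = percent_input(self.table(20.0, 20.0, 0.01))
        assert out["percent_input"].iloc[0] == pytest.approx(1.0)

    def test_worked_example(self):
        # 1% input, Ct_input 20 -> dilution-adjusted 20 - log2(100) = 13.356;
        # Ct_IP 19 -> 100 * 2^(13.356 - 19) = 2.0 %
        out = percent_input(self.table(19.0, 20.0, 0.01))
        assert out["percent_input"].iloc[0] == pytest.approx(2.0, rel=1e-3)

    def test_shift_invariance_and_monotonicity(self):
        base = percent_input(self.table(15.0, 18.0, 0.05))["percent_input"].iloc[0]
        shifted = percent_input(self.table(18.0, 21.0, 0.05))["percent_input"].iloc[0]
        assert shifted == pytest.approx(base)
        higher_ct = percent_input(self.table(16.0, 18.0, 0.05))["percent_input"].iloc[0]
        assert higher_ct < base

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            percent_input(self.table(15.0, 18.0, 0.0))
        with pytest.raises(ValueError):
            percent_input(self.table(np.inf, 18.0, 0.5))
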