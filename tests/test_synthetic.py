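import numpy as np
import pandas as pd
import pytest

from scncomplex.synthetic import (
    AbundanceConfig,
    DEFAULT_ABUNDANCE_MEANS,
    DecayParams,
    default_wt_abundance,
    sample_abundances,
    sample_binding,
    simulate_decay,
)


class TestAbundanceConfig:
    def test_default_pattern_matches_described_orderings(self):
        m = default_wt_abundance().means
        # BRAVO: anchor in SI, strictly decreasing towards the columella
        assert m["SI"]["BRAVO"] == 1.0
        assert m["SI"]["BRAVO"] > m["QC"]["BRAVO"] > m["CSC"]["BRAVO"] > m["CC"]["BRAVO"]
        # WOX5 peaks in the QC, nearly absent in CCs
        assert m["QC"]["WOX5"] == max(m[ct]["WOX5"] for ct in m)
        assert m["CC"]["WOX5"] < 0.05 and m["CC"]["BRAVO"] < 0.05
        # PLT3 similar across SI/QC/CSC, lower in CCs
        plt3 = [m[ct]["PLT3"] for ct in ("SI", "QC", "CSC")]
        assert max(plt3) - min(plt3) < 0.15
        assert m["CC"]["PLT3"] < min(plt3)

    def test_anchor_must_be_unique(self):
        means = {ct: dict(row) for ct, row in DEFAULT_ABUNDANCE_MEANS.items()}
        means["QC"]["WOX5"] = 1.0
        with pytest.raises(ValueError, match="exactly one"):
            AbundanceConfig(means=means)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AbundanceConfig(sd=-0.1)
        with pytest.raises(ValueError):
            AbundanceConfig(nuclei_per_root=4)
        with pytest.raises(ValueError):
            AbundanceConfig(n_roots=0)


class TestSampleAbundances:
    def test_zero_noise_reproduces_means_exactly(self):
        cfg = AbundanceConfig(sd=0.0, n_roots=2)
        df = sample_abundances(cfg)
        for _, row in df.iterrows():
            assert row["intensity"] == cfg.means[row["cell_type"]][row["protein"]]

    def test_seed_determinism(self):
        a = sample_abundances(AbundanceConfig(seed=42, n_roots=3))
        b = sample_abundances(AbundanceConfig(seed=42, n_roots=3))
        pd.testing.assert_frame_equal(a, b)

    def test_per_root_means_for_28_roots(self):
        df = sample_abundances(AbundanceConfig(n_roots=28))
        per_root = df.groupby(["cell_type", "protein"])["root_id"].nunique()
        assert (per_root == 28).all()
        # the root_cell_mean column aggregates that root's nuclei
        sub = df[(df.root_id == 1) & (df.cell_type == "QC") & (df.protein == "WOX5")]
        assert sub["root_cell_mean"].iloc[0] == pytest.approx(sub["intensity"].mean())

    def test_intensities_truncated_at_zero(self):
        cfg = AbundanceConfig(sd=0.5, n_roots=20)
        df = sample_abundances(cfg)
        assert (df["intensity"] >= 0).all()
        # the CC means are tiny, so truncation must actually have occurred
        assert (df[df.cell_type == "CC"]["intensity"] == 0).any()


class TestSampleBinding:
    def test_zero_sd_is_exact(self):
        s = sample_binding(12.5, 0.0, 5, seed=0)
        assert np.all(s.samples == 12.5)

    def test_untruncated_negative_values_allowed(self):
        s = sample_binding(2.3, 7.4, 500, seed=1)
        assert (s.samples < 0).any()

    def test_large_sample_mean_converges(self):
        s = sample_binding(28.0, 11.7, 10_000, seed=2)
        assert s.samples.mean() == pytest.approx(28.0, abs=0.5)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            sample_binding(10.0, 1.0, 0, seed=0)


class TestSimulateDecay:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DecayParams(tau_f=3.5, tau_d=3.0)
        with pytest.raises(ValueError):
            DecayParams(n_photons=0)

    def test_seed_determinism(self):
        p = DecayParams(alpha_f=0.3, seed=9)
        a = simulate_decay(p)
        b = simulate_decay(p)
        assert np.array_equal(a.counts, b.counts)

    def test_mean_arrival_time_matches_wrapped_exponential_moment(self):
        # E[t mod T] = tau - T*exp(-T/tau)/(1-exp(-T/tau)), numerically
        tau, window = 3.0, 31.25
        expected = tau - window * np.exp(-window / tau) / (1 - np.exp(-window / tau))
        p = DecayParams(alpha_f=0.0, tau_d=tau, sigma_irf=0.0, n_photons=2 * 10**5, seed=3)
        hist = simulate_decay(p)
        mean_t = np.sum(hist.bin_centers * hist.counts) / hist.counts.sum()
        assert mean_t == pytest.approx(expected, abs=0.03)

    def test_mixture_shifts_mean_arrival_by_photon_fraction(self):
        # photon-count amplitude convention: alpha_f of photons from Exp(tau_f)
        p = DecayParams(alpha_f=0.5, tau_f=1.0, tau_d=3.0, sigma_irf=0.0,
                        n_photons=2 * 10**5, seed=4)
        hist = simulate_decay(p)
        mean_t = np.sum(hist.bin_centers * hist.counts) / hist.counts.sum()
        assert mean_t == pytest.approx(0.5 * 1.0 + 0.5 * 3.0, abs=0.03)

    def test_background_adds_counts(self):
        base = simulate_decay(DecayParams(alpha_f=0.0, n_photons=10**4, seed=5))
        noisy = simulate_decay(
            DecayParams(alpha_f=0.0, n_photons=10**4, background=5.0, seed=5)
        )
        assert noisy.total_counts > base.total_counts
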