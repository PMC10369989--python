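import math

import numpy as np
import pandas as pd
import pytest

from tisdiv import synthetic
from tisdiv.profile_model import (
    ASRFit,
    DiversityProfile,
    aggregate_profile,
    asr_model,
    diversity_length_correlation,
    effect_estimates,
    effect_standard_errors,
    fit_asr,
    observed_effect_size,
)


def _noiseless_profile(dmin=0.01, dmax=0.05, c=0.01, n=120, w=3000.0):
    l = np.arange(n, dtype=float) * 4
    return DiversityProfile(l, asr_model(l, dmin, dmax, c), np.full(n, w))


def _gene_table(gene_id, offsets, pis):
    return pd.DataFrame({
        "gene_id": gene_id,
        "column_index": offsets,
        "offset_l": offsets,
        "codon_position": 2,
        "consensus": "A",
        "degeneracy": 4,
        "depth": 20,
        "pi": pis,
        "fourfold": True,
    })


class TestAggregateProfile:
    def test_single_gene_unit_weights(self):
        prof = aggregate_profile([_gene_table("g", [2, 5, 8], [0.0, 0.1, 0.2])], min_genes=1)
        assert (prof.weight == 1).all()
        assert list(prof.l) == [2, 5, 8]

    def test_two_gene_mean(self):
        tabs = [_gene_table("a", [2], [0.02]), _gene_table("b", [2], [0.04])]
        prof = aggregate_profile(tabs, min_genes=2)
        assert prof.mean_pi[0] == pytest.approx(0.03)
        assert prof.weight[0] == 2

    def test_min_genes_floor_drops_sparse_positions(self):
        tabs = [_gene_table("a", [2, 5], [0.1, 0.1]), _gene_table("b", [2], [0.3])]
        prof = aggregate_profile(tabs, min_genes=2)
        assert list(prof.l) == [2]

    def test_simulated_profile_tracks_generating_curve(self, ecoli_like_params, rng):
        """Profile mean at each l within 3 SE of dmax + (dmin-dmax) e^{-cl}."""
        p = ecoli_like_params
        n_genes, n_strains = 3000, 96
        prof = synthetic.simulate_profile(p, n_strains, n_genes, rng, max_l=400)
        truth = p.pi_at(prof.l)
        # per-site variance of a single draw, computed from the allele model
        H = synthetic.harmonic_number(n_strains - 1)
        k = np.arange(1, n_strains)
        pik = 2 * k * (n_strains - k) / (n_strains * (n_strains - 1))
        e2_poly = np.sum((1 / k) * pik**2) / H
        var = truth * H * e2_poly - truth**2
        se = np.sqrt(var / n_genes)
        assert (np.abs(prof.mean_pi - truth) < 3 * se).mean() > 0.99


class TestFitASR:
    def test_noiseless_recovery_exact(self):
        fit = fit_asr(_noiseless_profile())
        assert fit.converged
        assert fit.dmin == pytest.approx(0.01, rel=1e-6)
        assert fit.dmax == pytest.approx(0.05, rel=1e-6)
        assert fit.c == pytest.approx(0.01, rel=1e-6)

    def test_flat_profile_does_not_crash(self):
        l = np.arange(50, dtype=float)
        prof = DiversityProfile(l, np.full(50, 0.02), np.full(50, 100.0))
        fit = fit_asr(prof)  # c unidentifiable
        if fit.converged:
            est = effect_estimates(fit)
            assert abs(est.Se) < 0.05

    def test_midpoint_identity(self, ecoli_like_params, rng):
        """The fitted curve evaluated at Le equals (dmin+dmax)/2 to 1e-12."""
        prof = synthetic.simulate_profile(ecoli_like_params, 96, 2000, rng)
        fit = fit_asr(prof)
        assert fit.converged
        Le = math.log(2) / fit.c
        mid = asr_model(Le, fit.dmin, fit.dmax, fit.c)
        assert mid == pytest.approx((fit.dmin + fit.dmax) / 2, abs=1e-12)

    def test_weighted_fit_equals_row_duplication(self):
        base = _noiseless_profile(n=40, w=1.0)
        rng = np.random.default_rng(0)
        noisy = base.mean_pi + rng.normal(0, 0.003, len(base))
        k = 5
        weighted = DiversityProfile(base.l, noisy, np.full(len(base), float(k)))
        duplicated = DiversityProfile(np.repeat(base.l, k), np.repeat(noisy, k),
                                      np.ones(len(base) * k))
        fw, fd = fit_asr(weighted), fit_asr(duplicated)
        assert fw.dmin == pytest.approx(fd.dmin, abs=1e-10)
        assert fw.dmax == pytest.approx(fd.dmax, abs=1e-10)
        assert fw.c == pytest.approx(fd.c, abs=1e-10)

    def test_too_few_positions_rejected(self):
        l = np.arange(5, dtype=float)
        with pytest.raises(ValueError, match=">= 10"):
            fit_asr(DiversityProfile(l, np.full(5, 0.02), np.ones(5)))


class TestEffectEstimates:
    def _fit(self, dmin, dmax, c, cov=None):
        return ASRFit(dmin, dmax, c, cov, 0.0, True, 100)

    def test_flat_curve_zero_effect(self):
        est = effect_estimates(self._fit(0.03, 0.03, 0.01, np.zeros((3, 3))))
        assert est.Se == 0.0
        assert not est.positive_effect

    def test_unit_effect_length(self):
        est = effect_estimates(self._fit(0.01, 0.05, math.log(2), np.zeros((3, 3))))
        assert est.Le == pytest.approx(1.0)

    def test_saturation_point_is_four_le(self):
        est = effect_estimates(self._fit(0.01, 0.05, math.log(2) / 76, np.zeros((3, 3))))
        assert est.Le == pytest.approx(76.0)
        assert est.saturation_point == pytest.approx(304.0)
        assert est.saturation_point / est.Le == 4.0

    def test_zero_covariance_zero_ses(self):
        s_se, s_le = effect_standard_errors(self._fit(0.01, 0.05, 0.01, np.zeros((3, 3))))
        assert s_se == 0.0 and s_le == 0.0

    def test_se_formula_reduction(self):
        # only dmin uncertain: sigma_Se = sigma_dmin / (dmin ln 2)
        cov = np.zeros((3, 3))
        cov[0, 0] = 1e-6
        s_se, _ = effect_standard_errors(self._fit(0.01, 0.05, 0.01, cov))
        assert s_se == pytest.approx(math.sqrt(1e-6) / (0.01 * math.log(2)))

    def test_sigma_le_first_order(self):
        cov = np.zeros((3, 3))
        cov[2, 2] = 0.04
        fit = self._fit(0.01, 0.05, math.log(2) / 76, cov)
        _, s_le = effect_standard_errors(fit)
        assert s_le == pytest.approx(math.log(2) * 0.2 * math.exp(-fit.K))

    def test_delta_method_ses_match_parametric_bootstrap(self, ecoli_like_params):
        """Delta-method SEs within 25% of bootstrap SDs over 500 refits."""
        p = ecoli_like_params
        rng = np.random.default_rng(11)
        noise_sd = 0.002
        prof = synthetic.simulate_profile(p, 96, 3000, rng, noise_sd=noise_sd)
        fit = fit_asr(prof)
        est = effect_estimates(fit)
        fitted = synthetic.ProfileParams(fit.dmin, fit.dmax, fit.c)
        les, ses = [], []
        for _ in range(500):
            bp = synthetic.simulate_profile(fitted, 96, 3000, rng, noise_sd=noise_sd)
            bf = fit_asr(bp)
            if bf.converged and bf.dmin > 0:
                be = effect_estimates(bf)
                les.append(be.Le)
                ses.append(be.Se)
        assert est.sigma_Le == pytest.approx(np.std(les), rel=0.25)
        assert est.sigma_Se == pytest.approx(np.std(ses), rel=0.25)


class TestObservedEffectSize:
    def test_flat_profile_zero(self):
        prof = DiversityProfile([0, 100, 200], [0.03, 0.03, 0.03], [5, 5, 5])
        assert observed_effect_size(prof) == 0.0

    def test_fourfold_increase_is_two(self):
        prof = DiversityProfile([0, 100], [0.01, 0.04], [5, 5])
        assert observed_effect_size(prof) == pytest.approx(2.0)

    def test_max_at_start_gives_zero(self):
        prof = DiversityProfile([0, 100, 200], [0.05, 0.04, 0.03], [5, 5, 5])
        assert observed_effect_size(prof) == 0.0

    def test_zero_start_rejected(self):
        prof = DiversityProfile([0, 100], [0.0, 0.04], [5, 5])
        with pytest.raises(ValueError, match="first position"):
            observed_effect_size(prof)


class TestDiversityLengthCorrelation:
    def test_monotone_pair_perfect_rho(self):
        pairs = [(l, l / 1e4) for l in range(100, 400, 30)]
        rho, _ = diversity_length_correlation(pairs)
        assert rho == pytest.approx(1.0)

    def test_independent_simulation_near_zero(self, rng):
        n = 1000
        pairs = list(zip(rng.integers(150, 1200, n), rng.random(n)))
        rho, _ = diversity_length_correlation(pairs)
        assert abs(rho) < 0.09

    def test_tis_effect_induces_positive_correlation(self, ecoli_like_params, rng):
        cfg = synthetic.SimConfig(n_strains=50, n_genes=400,
                                  gene_length_distribution=(50, 400, 1.0), seed=1)
        pairs = synthetic.simulate_gene_summaries(ecoli_like_params, cfg, rng)
        rho, p = diversity_length_correlation(pairs)
        assert rho > 0 and p < 0.01
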