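"""Capture-spectrum construction and closed-population domain-size fits."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy.special import gammaln

from freelists import (
    CaptureSpectrum,
    ClosedPopulationModel,
    DomainSpec,
    best_domain_estimate,
    capture_spectrum,
    fit_closed_population,
    generate_dataset,
    two_sample_estimate,
)

from conftest import make_dataset, random_lists


class TestTwoSample:
    def test_worked_example(self):
        assert two_sample_estimate(15, 31, 5) == pytest.approx(93.0)

    def test_complete_recapture(self):
        assert two_sample_estimate(7, 7, 7) == pytest.approx(7.0)

    def test_direct_evaluation(self):
        assert two_sample_estimate(10, 10, 2) == pytest.approx(50.0)

    def test_no_overlap_is_undefined(self):
        with pytest.raises(ValueError, match="matching"):
            two_sample_estimate(10, 10, 0)


class TestSpectrum:
    def test_identical_lists(self):
        data = make_dataset([["a", "b", "c"]] * 4)
        spec = capture_spectrum(data)
        assert spec.t == 4
        assert list(spec.f) == [0, 0, 0, 3]

    def test_disjoint_lists(self):
        lists = [[f"i{j}_{k}" for k in range(2)] for j in range(3)]
        spec = capture_spectrum(make_dataset(lists))
        assert list(spec.f) == [6, 0, 0]

    @given(random_lists())
    def test_matches_occurrence_count_oracle_and_identities(self, lists):
        if len(lists) < 2:
            lists = lists + [[]]
        data = make_dataset(lists)
        spec = capture_spectrum(data)
        # brute force: occurrence count per item
        for j in range(1, spec.t + 1):
            expected = sum(
                1
                for item in data.item_universe
                if sum(item in set(l) for l in lists) == j
            )
            assert spec.f[j - 1] == expected
        assert spec.s == len(data.item_universe)
        assert spec.total_mentions == data.total_mentions


def glm_chao_oracle(spec):
    """Independent IRLS route to the Chao lower bound: Poisson loglinear fit
    on the singleton and doubleton classes only, with log C(t,j) offset."""
    j = np.array([1.0, 2.0])
    X = sm.add_constant(j)
    offset = gammaln(spec.t + 1) - gammaln(j + 1) - gammaln(spec.t - j + 1)
    res = sm.GLM(spec.f[:2].astype(float), X, family=sm.families.Poisson(),
                 offset=offset).fit()
    return float(np.exp(res.params[0]))


class TestChao:
    @pytest.mark.parametrize(
        "t,f_head", [(6, (10, 4)), (12, (30, 9)), (8, (5, 5)), (20, (50, 2))]
    )
    def test_glm_fit_equals_two_point_closed_form(self, t, f_head):
        f = np.zeros(t, dtype=int)
        f[0], f[1] = f_head
        f[2], f[4] = 3, 1
        spec = CaptureSpectrum(t, f)
        est = fit_closed_population(spec, "mh_chao_lb")
        f1, f2 = f_head
        closed = f1**2 * (t - 1) / (2 * t * f2)
        assert est.f0_hat == pytest.approx(closed, rel=1e-10)
        assert est.f0_hat == pytest.approx(glm_chao_oracle(spec), rel=1e-6)
        assert est.abundance == spec.s + est.f0_hat

    def test_no_singletons_means_nothing_unseen(self):
        spec = CaptureSpectrum(5, np.array([0, 4, 2, 1, 0]))
        est = fit_closed_population(spec, "mh_chao_lb")
        assert est.f0_hat == 0.0
        assert est.abundance == spec.s

    def test_no_doubletons_uses_flagged_fallback(self):
        spec = CaptureSpectrum(5, np.array([6, 0, 2, 0, 0]))
        est = fit_closed_population(spec, "mh_chao_lb")
        expected = 6 * 5 / 2 * (5 - 1) / 5
        assert est.f0_hat == pytest.approx(expected)
        assert any("fallback" in n for n in est.notes)


def homogeneous_spectrum(rng, domain=60, t=15, p=0.2):
    """Simulate equal-salience capture: each of `domain` items lands on each
    of t lists independently with probability p."""
    counts = rng.binomial(t, p, size=domain)
    f = np.zeros(t, dtype=int)
    for c in counts[counts > 0]:
        f[c - 1] += 1
    return CaptureSpectrum(t, f)


class TestClosedPopulationFits:
    def test_abundance_at_least_observed(self, heterogeneous_data):
        cpm = ClosedPopulationModel(capture_spectrum(heterogeneous_data))
        for est in cpm.fit_all():
            if est.converged:
                assert est.abundance >= est.s_observed - 1e-6

    def test_m0_recovers_homogeneous_domain_size(self, rng):
        """Coverage check: M0 point estimates center on the true domain size
        when capture probabilities really are homogeneous."""
        domain = 60
        estimates = []
        for _ in range(100):
            spec = homogeneous_spectrum(rng, domain=domain)
            est = fit_closed_population(spec, "m0")
            if est.converged:
                estimates.append(est.abundance)
        estimates = np.asarray(estimates)
        assert len(estimates) > 90
        assert abs(np.median(estimates) - domain) < 3
        # sampling error band, not a tuned tolerance: central 90% of runs
        lo, hi = np.percentile(estimates, [5, 95])
        assert lo < domain < hi

    def test_m0_competitive_on_homogeneous_data(self, rng):
        """With no heterogeneity the homogeneous model should not lose badly
        to the heterogeneity variants (median AIC gap within 2)."""
        gaps = []
        for _ in range(20):
            spec = homogeneous_spectrum(rng, domain=80, t=12, p=0.25)
            fits = {e.model: e for e in ClosedPopulationModel(spec).fit_all()}
            rivals = [
                e.aic for m, e in fits.items()
                if m != "m0" and e.converged and math.isfinite(e.aic)
            ]
            if fits["m0"].converged and rivals:
                gaps.append(fits["m0"].aic - min(rivals))
        assert np.median(gaps) < 2.0

    def test_heterogeneity_wins_on_long_tail_data(self):
        """Zipf-weighted items produce singleton-heavy spectra that the
        homogeneous model cannot fit; an Mh variant takes the AIC lead and
        estimates a larger domain."""
        wins, larger = 0, 0
        for seed in range(10):
            data = generate_dataset(
                DomainSpec(domain_size=150, n_respondents=30,
                           salience_law=("zipf", 1.0), seed=300 + seed)
            )
            best = best_domain_estimate(capture_spectrum(data))
            m0 = {e.model: e for e in best.candidates}["m0"]
            if best.model != "m0":
                wins += 1
            if not math.isfinite(m0.abundance) or best.abundance > m0.abundance:
                larger += 1
        assert wins >= 8
        assert larger >= 8

    def test_chao_below_gamma_on_singleton_excess(self):
        """Directional: with a heavy singleton excess the gamma model
        extrapolates a larger unseen mass than Chao's lower bound."""
        bigger = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(500 + seed)
            f = np.zeros(12, dtype=int)
            f[:6] = rng.poisson([40, 12, 6, 3, 2, 1])
            f[0] += 10  # force singleton excess
            spec = CaptureSpectrum(12, f)
            chao = fit_closed_population(spec, "mh_chao_lb")
            gamma = fit_closed_population(spec, "mh_gamma")
            if gamma.converged and chao.abundance <= gamma.abundance + 1e-6:
                bigger += 1
        assert bigger >= reps - 2

    def test_best_estimate_attaches_candidates(self, heterogeneous_data):
        best = best_domain_estimate(capture_spectrum(heterogeneous_data))
        assert best.candidates is not None
        assert {c.model for c in best.candidates} == {
            "m0", "mh_chao_lb", "mh_poisson2", "mh_darroch", "mh_gamma"
        }
        assert best.aic == min(
            c.aic for c in best.candidates
            if c.converged and math.isfinite(c.abundance)
        )

    def test_invalid_model_name(self, heterogeneous_data):
        with pytest.raises(ValueError):
            fit_closed_population(capture_spectrum(heterogeneous_data), "mth")
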