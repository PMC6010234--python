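"""Accumulation-model fitting, the saturation rule, and design calculators."""

import math

import numpy as np
import pytest

from freelists import (
    DomainSpec,
    SaturationFit,
    SaturationModel,
    batch_analyze,
    fit_accumulation_models,
    generate_dataset,
    n_for_confidence,
    new_item_series,
    p_at_least_once,
    select_best,
)
from freelists.accumulation import NewItemSeries


def series_from(y):
    y = np.asarray(y)
    return NewItemSeries(np.arange(1, len(y) + 1), y)


def log_fit(b0, b1, dispersion=None):
    """Hand-built log-link results object for closed-form checks."""
    return SaturationFit(
        "negative_binomial" if dispersion else "poisson", "log", b0, b1,
        dispersion, 0.0, 0.0, 0.0, True, 30,
    )


class TestFitting:
    def test_recovers_known_log_linear_coefficients(self):
        x = np.arange(1, 31)
        y = np.rint(np.exp(2.0 - 0.1 * x)).astype(int)
        fits = {(f.family, f.link): f for f in fit_accumulation_models(series_from(y))}
        for key in [("poisson", "log"), ("negative_binomial", "log")]:
            assert fits[key].converged
            assert fits[key].b1 == pytest.approx(-0.1, abs=0.01)
            assert fits[key].b0 == pytest.approx(2.0, abs=0.1)

    def test_constant_series_is_flat_no_saturation(self):
        fits = fit_accumulation_models(series_from([4] * 12))
        for f in fits:
            if f.converged:
                assert abs(f.b1) < 1e-6
                assert f.saturation_point() is None
                assert f.total_domain_size() is None

    def test_poisson_and_nb_coincide_when_dispersion_vanishes(self):
        # a clean Poisson-looking decline: NB alpha -> ~0, same predictions
        x = np.arange(1, 26)
        y = np.rint(np.exp(2.5 - 0.12 * x)).astype(int)
        model = SaturationModel(series_from(y))
        pois = model.fit("poisson", "log")
        nb = model.fit("negative_binomial", "log")
        assert nb.dispersion < 0.05
        np.testing.assert_allclose(nb.predict(x), pois.predict(x), rtol=0.02)

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError):
            SaturationModel(series_from([3, 1]))


class TestSelection:
    def test_single_candidate_and_lower_aic_win(self):
        a = log_fit(1.0, -0.1)
        a = SaturationFit(**{**a.__dict__, "aic": 100.0})
        b = SaturationFit(**{**log_fit(1.0, -0.2).__dict__, "aic": 101.0})
        assert select_best([a]) is a
        assert select_best([a, b]) is a

    def test_tie_break_prefers_nb_log(self):
        nb = SaturationFit("negative_binomial", "log", 1, -0.1, 0.5, 0, 100.0,
                           0.01, True, 20)
        pois = SaturationFit("poisson", "log", 1, -0.1, None, 0, 100.0,
                             0.01, True, 20)
        assert select_best([pois, nb]) is nb

    def test_no_converged_candidate_raises(self):
        bad = SaturationFit("poisson", "log", 1, -0.1, None, 0, math.inf,
                            0.5, False, 20)
        with pytest.raises(RuntimeError):
            select_best([bad])


class TestSaturationRule:
    def test_closed_form_crossing(self):
        fit = log_fit(0.0, -0.3)
        point = fit.saturation_point(1.0)
        assert point.x_continuous == pytest.approx(0.0)
        assert point.n_sat == 1

    def test_identity_link_crossing(self):
        fit = SaturationFit("normal", "identity", 10.0, -1.5, None, 0, 0,
                            0.01, True, 20)
        point = fit.saturation_point(1.0)
        assert point.x_continuous == pytest.approx(6.0)
        assert point.n_sat == 6

    def test_threshold_monotonicity(self):
        fit = log_fit(3.0, -0.2)
        p1, p2 = fit.saturation_point(1.0), fit.saturation_point(2.0)
        assert p2.n_sat <= p1.n_sat
        assert fit.domain_at_saturation(2.0) <= fit.domain_at_saturation(1.0)

    def test_positive_slope_reports_not_reached(self):
        fit = log_fit(1.0, 0.05)
        assert fit.saturation_point() is None
        assert fit.domain_at_saturation() is None
        assert fit.total_domain_size() is None


class TestDomainSize:
    def test_single_term_half_geometric(self):
        # E[Y | x] = 0.5^x: saturation at x=1, one term, total 1.0
        fit = log_fit(0.0, math.log(0.5))
        assert fit.saturation_point(1.0).n_sat == 1
        assert fit.domain_at_saturation(1.0) == pytest.approx(0.5)
        assert fit.total_domain_size() == pytest.approx(1.0)

    def test_partial_sum_matches_geometric_closed_form(self):
        b0, b1 = 2.3, -0.17
        fit = log_fit(b0, b1)
        n = fit.saturation_point(1.0).n_sat
        r = math.exp(b1)
        closed = math.exp(b0) * (r - r ** (n + 1)) / (1 - r)
        assert fit.domain_at_saturation(1.0) == pytest.approx(closed, rel=1e-12)

    @pytest.mark.parametrize("b0,b1", [(2.0, -0.1), (3.5, -0.02), (0.5, -1.0)])
    def test_total_equals_numeric_summation(self, b0, b1):
        fit = log_fit(b0, b1)
        xs = np.arange(1, 10**6 + 1, dtype=float)
        numeric = np.exp(b0 + b1 * xs).sum()
        assert fit.total_domain_size() == pytest.approx(numeric, rel=1e-6)

    def test_identity_link_clamped_sum(self):
        fit = SaturationFit("normal", "identity", 5.0, -1.0, None, 0, 0,
                            0.01, True, 20)
        # predictions 4,3,2,1,0 -> total 10
        assert fit.total_domain_size() == pytest.approx(10.0)


class TestDesignCalculators:
    def test_binomial_probabilities(self):
        assert p_at_least_once(1.0, 3) == 1.0
        assert p_at_least_once(0.2, 14) == pytest.approx(0.956, abs=5e-4)
        assert p_at_least_once(0.2, 14) >= 0.95
        assert p_at_least_once(0.2, 11) == pytest.approx(0.914, abs=5e-4)
        assert p_at_least_once(0.2, 11) >= 0.90

    def test_inverse_sample_size(self):
        assert n_for_confidence(0.2, 0.95) == 14
        assert n_for_confidence(0.2, 0.90) == 11
        assert n_for_confidence(0.5, 0.5) == 1

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            p_at_least_once(0.0, 5)
        with pytest.raises(ValueError):
            n_for_confidence(0.2, 1.0)


class TestBatch:
    def test_batch_table_and_summary(self):
        datasets = {
            f"ex{i}": generate_dataset(
                DomainSpec(domain_size=60, n_respondents=25, seed=100 + i)
            )
            for i in range(3)
        }
        table, summary = batch_analyze(datasets)
        assert len(table) == 3
        assert set(table["example"]) == set(datasets)
        assert {"n_sat_y1", "n_sat_y2", "d_tot"} <= set(table.columns)
        row1 = summary[summary["threshold"] == 1.0].iloc[0]
        row2 = summary[summary["threshold"] == 2.0].iloc[0]
        # liberal threshold saturates no later than the strict one
        assert row2["median_n_sat"] <= row1["median_n_sat"]

    def test_single_dataset_median_is_its_n_sat(self):
        data = generate_dataset(DomainSpec(domain_size=40, n_respondents=25, seed=5))
        table, summary = batch_analyze({"only": data})
        n_sat = table.loc[0, "n_sat_y1"]
        assert summary.loc[summary["threshold"] == 1.0, "median_n_sat"].iloc[0] == n_sat


def test_fit_plot_smoke():
    import matplotlib

    matplotlib.use("Agg")
    x = np.arange(1, 21)
    y = np.rint(np.exp(2.0 - 0.15 * x)).astype(int)
    series = series_from(y)
    fit = SaturationModel(series).fit_best()
    ax = fit.plot(series)
    assert ax.get_xlabel() == "respondent position"
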