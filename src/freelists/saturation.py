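"""Accumulation-curve models, the saturation rule, and domain-size extrapolation.

The number of new items contributed by each successive respondent follows a
characteristic descending curve: the first respondent contributes their
whole list, later respondents mostly repeat what has been said.  We model
the new-item count Y at respondent position x with two-parameter count
regressions,

    log-link:       E[Y | x] = exp(b0 + b1 * x)
    identity-link:  E[Y | x] = b0 + b1 * x

fitted as ordinary least squares (normal, identity), Poisson (log), and
negative binomial (log and identity; NB2 dispersion estimated by maximum
likelihood).  Candidates are compared by AIC = 2k - 2*loglik, with k
counting the dispersion parameter for the negative binomial and the
residual variance for the normal model.

From the selected fit:

* the **saturation point** N_SAT is the smallest integer sample size at
  which the expected number of new items drops to a threshold (default 1
  new item per person), i.e. the ceiling of the continuous solution of
  E[Y | x] = threshold;
* the **domain size at saturation** D_SAT is the sum of predicted new
  items over x = 1..N_SAT;
* the **total domain size** D_TOT extrapolates to an infinite sample: for
  the log link the predictions form a geometric series with ratio
  r = exp(b1), so D_TOT = exp(b0) * r / (1 - r) when b1 < 0.

Two binomial design calculators round out the module: the probability of
seeing an item of prevalence p at least once in n independent interviews,
1 - (1-p)^n, and its inverse (smallest n reaching a target confidence).
These assume independence across items; heterogeneous salience makes them
optimistic, which is exactly what comparing them with the model-based
saturation points shows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .accumulation import NewItemSeries, new_item_series
from .dataset import FreeListDataset

__all__ = [
    "SaturationModel",
    "SaturationFit",
    "SaturationPoint",
    "fit_accumulation_models",
    "select_best",
    "p_at_least_once",
    "n_for_confidence",
    "batch_analyze",
]

#: candidate (family, link) pairs in deterministic tie-break order
CANDIDATES: tuple[tuple[str, str], ...] = (
    ("negative_binomial", "log"),
    ("poisson", "log"),
    ("negative_binomial", "identity"),
    ("normal", "identity"),
)

_MAX_ALPHA = 1e4
_MIN_ALPHA = 1e-8
#: slopes closer to zero than this are treated as flat (saturation not
#: reached) rather than solved for an astronomically distant crossing
_FLAT_SLOPE = 1e-10


@dataclass(frozen=True)
class SaturationPoint:
    """Solution of E[Y | x] = threshold for a declining fitted curve."""

    threshold: float
    x_continuous: float  #: continuous crossing point (2 d.p. in reports)
    n_sat: int  #: ceiling of x_continuous, at least 1


@dataclass(frozen=True)
class SaturationFit:
    """Results of one accumulation-model fit.

    Carries the fitted coefficients, dispersion (negative binomial only),
    log-likelihood, AIC and slope inference, and derives the saturation
    point and domain sizes.  ``converged`` is False when the optimizer
    failed; such fits are retained for reporting but never selected.
    """

    family: str
    link: str
    b0: float
    b1: float
    dispersion: float | None
    llf: float
    aic: float
    slope_pvalue: float
    converged: bool
    n_obs: int
    notes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def label(self) -> str:
        short = {"negative_binomial": "NB", "poisson": "Poisson", "normal": "Normal"}
        return f"{short[self.family]}-{self.link}"

    # -- prediction ------------------------------------------------------

    def predict(self, x) -> np.ndarray:
        """Expected new items at respondent position(s) x (fitted scale)."""
        x = np.asarray(x, dtype=float)
        eta = self.b0 + self.b1 * x
        return np.exp(eta) if self.link == "log" else eta

    # -- saturation ------------------------------------------------------

    def saturation_point(self, threshold: float = 1.0) -> SaturationPoint | None:
        """Smallest sample size with expected new items <= threshold.

        Returns None when the fitted slope is non-negative: the curve never
        declines to the threshold and saturation is "not reached".
        """
        if self.b1 >= -_FLAT_SLOPE:
            return None
        if self.link == "log":
            x_cont = (math.log(threshold) - self.b0) / self.b1
        else:
            x_cont = (threshold - self.b0) / self.b1
        n_sat = max(1, math.ceil(x_cont))
        if float(self.predict(1.0)) <= threshold:
            n_sat = 1
        return SaturationPoint(threshold, x_cont, n_sat)

    def domain_at_saturation(self, threshold: float = 1.0) -> float | None:
        """Predicted unique items accumulated through N_SAT (unrounded sum)."""
        point = self.saturation_point(threshold)
        if point is None:
            return None
        xs = np.arange(1, point.n_sat + 1)
        preds = self.predict(xs)
        if self.link == "identity":
            preds = np.clip(preds, 0.0, None)
        return float(preds.sum())

    def total_domain_size(self) -> float | None:
        """Predicted unique items at infinite sample size.

        Log link: closed-form geometric series exp(b0)*r/(1-r), r=exp(b1).
        Identity link: predictions clamped at zero and summed to the zero
        crossing.  None (not reached) when the slope is non-negative.
        """
        if self.b1 >= -_FLAT_SLOPE:
            return None
        if self.link == "log":
            r = math.exp(self.b1)
            return math.exp(self.b0) * r / (1.0 - r)
        x_zero = -self.b0 / self.b1  # predictions are positive below this
        xs = np.arange(1, max(1, math.floor(x_zero)) + 1)
        return float(np.clip(self.predict(xs), 0.0, None).sum())

    def plot(self, series: NewItemSeries | None = None, threshold: float = 1.0,
             ax=None):
        """Plot the fitted declining curve, optionally with the observed
        new-item counts, the threshold line and the saturation point."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        upper = len(series) if series is not None else self.n_obs
        point = self.saturation_point(threshold)
        if point is not None:
            upper = max(upper, point.n_sat + 2)
        xs = np.linspace(1, upper, 200)
        ax.plot(xs, self.predict(xs), label=f"fitted ({self.label})")
        if series is not None:
            ax.scatter(series.x, series.y, s=12, color="k", label="observed")
        ax.axhline(threshold, ls=":", color="grey")
        if point is not None:
            ax.axvline(point.n_sat, ls="--", color="grey",
                       label=f"N_SAT = {point.n_sat}")
        ax.set_xlabel("respondent position")
        ax.set_ylabel("new items")
        ax.legend()
        return ax

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Accumulation fit: {self.label}",
            f"  observations: {self.n_obs}",
            f"  b0 (intercept): {self.b0:.4f}",
            f"  b1 (slope/respondent): {self.b1:.4f}  (p = {self.slope_pvalue:.3g})",
        ]
        if self.dispersion is not None:
            lines.append(f"  dispersion (NB2 alpha): {self.dispersion:.4f}")
        lines.append(f"  loglik: {self.llf:.2f}   AIC: {self.aic:.2f}")
        point = self.saturation_point(1.0)
        if point is None:
            lines.append("  saturation (Y<=1): not reached (non-negative slope)")
        else:
            d_sat = self.domain_at_saturation(1.0)
            d_tot = self.total_domain_size()
            lines.append(
                f"  saturation (Y<=1): x = {point.x_continuous:.2f}, "
                f"N_SAT = {point.n_sat}"
            )
            lines.append(f"  D_SAT = {d_sat:.1f}   D_TOT = {d_tot:.1f}")
        if self.notes:
            lines.append("  notes: " + "; ".join(self.notes))
        return "\n".join(lines)


class SaturationModel:
    """Accumulation model for a new-item series.

    Parameters
    ----------
    series : NewItemSeries or FreeListDataset
        The per-respondent new-item counts; a dataset is converted with
        :func:`~freelists.accumulation.new_item_series`.

    Examples
    --------
    >>> model = SaturationModel(dataset)          # doctest: +SKIP
    >>> fit = model.fit_best()                    # doctest: +SKIP
    >>> fit.saturation_point().n_sat              # doctest: +SKIP
    """

    def __init__(self, series: NewItemSeries | FreeListDataset):
        if isinstance(series, FreeListDataset):
            series = new_item_series(series)
        if len(series) < 3:
            raise ValueError("need a series of length >= 3 to fit two parameters")
        self.series = series
        self._x = series.x.astype(float)
        self._y = series.y.astype(float)
        self._X = sm.add_constant(self._x)

    # -- individual fits -------------------------------------------------

    def fit(self, family: str = "negative_binomial", link: str = "log") -> SaturationFit:
        """Fit one (family, link) candidate; failures return a
        non-converged :class:`SaturationFit` with AIC = inf."""
        key = (family, link)
        if key not in CANDIDATES:
            raise ValueError(f"unsupported candidate {key}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if key == ("normal", "identity"):
                    return self._fit_ols()
                if key == ("poisson", "log"):
                    return self._fit_poisson()
                if key == ("negative_binomial", "log"):
                    return self._fit_nb_log()
                return self._fit_nb_identity()
        except Exception as exc:  # fit failures are recorded, not fatal
            return SaturationFit(
                family, link, math.nan, math.nan, None, -math.inf, math.inf,
                math.nan, False, len(self.series), (f"fit failed: {exc}",),
            )

    def fit_all(self) -> list[SaturationFit]:
        """All four candidates, in tie-break order."""
        return [self.fit(fam, link) for fam, link in CANDIDATES]

    def fit_best(self) -> SaturationFit:
        return select_best(self.fit_all())

    # -- implementation --------------------------------------------------

    def _fit_ols(self) -> SaturationFit:
        res = sm.OLS(self._y, self._X).fit()
        k = 3  # intercept, slope, residual variance
        return SaturationFit(
            "normal", "identity", float(res.params[0]), float(res.params[1]),
            None, float(res.llf), 2 * k - 2 * float(res.llf),
            float(res.pvalues[1]), True, len(self.series),
        )

    def _fit_poisson(self) -> SaturationFit:
        res = sm.GLM(self._y, self._X, family=sm.families.Poisson()).fit()
        k = 2
        return SaturationFit(
            "poisson", "log", float(res.params[0]), float(res.params[1]),
            None, float(res.llf), 2 * k - 2 * float(res.llf),
            float(res.pvalues[1]), bool(res.converged), len(self.series),
        )

    def _moment_alpha(self) -> float:
        # NB2 moment estimate: Var = mu + alpha * mu^2, pooled over the fit
        mu = np.clip(sm.GLM(self._y, self._X, family=sm.families.Poisson())
                     .fit().fittedvalues, 1e-8, None)
        num = ((self._y - mu) ** 2 - mu).sum()
        den = (mu ** 2).sum()
        return float(min(max(num / den, _MIN_ALPHA), _MAX_ALPHA))

    def _glm_nb(self, alpha: float, link) -> "sm.GLM":
        fam = sm.families.NegativeBinomial(alpha=alpha, link=link)
        return sm.GLM(self._y, self._X, family=fam)

    def _fit_nb_log(self) -> SaturationFit:
        notes: list[str] = []
        res = None
        try:
            ml = sm.NegativeBinomial(self._y, self._X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(ml.params)) and ml.mle_retvals.get("converged", False):
                alpha = float(max(ml.params[-1], _MIN_ALPHA))
                res = self._glm_nb(alpha, sm.families.links.Log()).fit()
            else:
                raise RuntimeError("joint ML did not converge")
        except Exception:
            # moment fallback for the dispersion, coefficients by GLM
            alpha = self._moment_alpha()
            notes.append("dispersion by moment fallback")
            res = self._glm_nb(alpha, sm.families.links.Log()).fit()
        k = 3
        return SaturationFit(
            "negative_binomial", "log", float(res.params[0]), float(res.params[1]),
            alpha, float(res.llf), 2 * k - 2 * float(res.llf),
            float(res.pvalues[1]), bool(res.converged), len(self.series),
            tuple(notes),
        )

    def _fit_nb_identity(self) -> SaturationFit:
        link = sm.families.links.Identity()
        start = sm.OLS(self._y, self._X).fit().params
        start = np.asarray(start, dtype=float)
        # keep starting mean positive over the observed range
        if (start[0] + start[1] * self._x).min() <= 0:
            start = np.array([max(self._y.mean(), 0.5), 0.0])

        def profile_nll(log_alpha: float) -> float:
            try:
                r = self._glm_nb(math.exp(log_alpha), link).fit(start_params=start)
                return -float(r.llf) if np.isfinite(r.llf) else 1e12
            except Exception:
                return 1e12

        opt = minimize_scalar(
            profile_nll, bounds=(math.log(_MIN_ALPHA), math.log(_MAX_ALPHA)),
            method="bounded", options={"xatol": 1e-6},
        )
        alpha = float(math.exp(opt.x))
        res = self._glm_nb(alpha, link).fit(start_params=start)
        k = 3
        return SaturationFit(
            "negative_binomial", "identity", float(res.params[0]),
            float(res.params[1]), alpha, float(res.llf),
            2 * k - 2 * float(res.llf), float(res.pvalues[1]),
            bool(res.converged) and np.isfinite(res.llf), len(self.series),
        )


def fit_accumulation_models(
    series: NewItemSeries | FreeListDataset,
) -> list[SaturationFit]:
    """Fit all four candidate accumulation models to a new-item series."""
    return SaturationModel(series).fit_all()


def select_best(candidates: Iterable[SaturationFit]) -> SaturationFit:
    """Minimum-AIC converged candidate; ties broken by the fixed candidate
    order (NB-log, Poisson-log, NB-identity, Normal-identity)."""
    order = {pair: i for i, pair in enumerate(CANDIDATES)}
    converged = [c for c in candidates if c.converged and math.isfinite(c.aic)]
    if not converged:
        raise RuntimeError("no accumulation model converged")
    return min(converged, key=lambda c: (c.aic, order[(c.family, c.link)]))


# ---------------------------------------------------------------------------
# binomial design calculators
# ---------------------------------------------------------------------------


def p_at_least_once(p: float, n: int) -> float:
    """Probability an item of prevalence p appears at least once in n
    independent interviews: 1 - (1-p)^n."""
    if not 0 < p <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - p) ** n


def n_for_confidence(p: float, confidence: float) -> int:
    """Smallest n with 1 - (1-p)^n >= confidence."""
    if not 0 < p < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    return max(1, math.ceil(math.log(1.0 - confidence) / math.log(1.0 - p)))


# ---------------------------------------------------------------------------
# batch analysis
# ---------------------------------------------------------------------------


def batch_analyze(
    datasets: Mapping[str, FreeListDataset],
    thresholds: Sequence[float] = (1.0, 2.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the best accumulation model per example and tabulate saturation
    and domain-size estimates, plus a median/range summary per threshold.

    Returns ``(table, summary)``: one row per example with N, mean and
    range of list lengths, unique items, the selected model, and per
    threshold N_SAT and D_SAT, with D_TOT from the same fit; and a summary
    frame of median and range of N_SAT over the examples where saturation
    is reached.
    """
    if not datasets:
        raise ValueError("no datasets")
    rows = []
    for name, data in datasets.items():
        series = new_item_series(data)
        best = SaturationModel(series).fit_best()
        lengths = data.list_lengths
        row: dict[str, object] = {
            "example": name,
            "N": data.n_respondents,
            "mean_L": round(data.mean_list_length, 1),
            "range_L": f"{min(lengths)}-{max(lengths)}",
            "unique_items": series.total_unique,
            "best_model": best.label,
            "slope_pvalue": best.slope_pvalue,
            "d_tot": best.total_domain_size(),
        }
        for th in thresholds:
            point = best.saturation_point(th)
            tag = f"{th:g}"
            row[f"n_sat_y{tag}"] = None if point is None else point.n_sat
            row[f"d_sat_y{tag}"] = (
                None if point is None else best.domain_at_saturation(th)
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    summary_rows = []
    for th in thresholds:
        col = table[f"n_sat_y{th:g}"].dropna()
        summary_rows.append(
            {
                "threshold": th,
                "n_examples_saturating": int(col.size),
                "median_n_sat": float(col.median()) if col.size else math.nan,
                "min_n_sat": int(col.min()) if col.size else None,
                "max_n_sat": int(col.max()) if col.size else None,
            }
        )
    return table, pd.DataFrame(summary_rows)
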