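"""Bell-shaped dose-response fitting and Emax/EC50 extraction.

Cytokine dose responses can be non-monotonic (rising then falling with
antigen dose).  Each curve is fitted with the bell-shaped function

    y(x) = Emin + [a + (b - a)/(1 + (c1/x)^n1) - Emin] / (1 + (c2/x)^n2)

by bounded multi-start least squares.  Emax and EC50 are *not* fit
parameters: they are read off a 10,000-point log-spaced evaluation of the
fitted line — Emax as its maximum, EC50 as the lowest dose at which the
curve first reaches half-maximum (Emin + (Emax - Emin)/2) on the rising
limb.  EC50 is excluded (reported absent) when the fitted Emax falls below
50 pg/ml, where ELISA noise makes the midpoint meaningless.

The fitter is exposed as a scikit-learn estimator (:class:`BellDoseResponse`)
so it composes with sklearn pipelines; :func:`fit_bell` and
:func:`extract_metrics` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BellDoseResponse",
    "BellFit",
    "ResponseMetrics",
    "bell_curve",
    "direct_response_metrics",
    "fit_bell",
    "extract_metrics",
    "rate_of_change",
    "normalise_metrics",
]

DEFAULT_GRID_POINTS = 10_000
DEFAULT_EXCLUSION_PG_ML = 50.0
_PARAM_NAMES = ("emin", "a", "b", "c1", "c2", "n1", "n2")


def bell_curve(x, emin, a, b, c1, c2, n1, n2):
    """Evaluate the bell function; x = 0 is handled by its analytic limit.

    For n2 > 0 the low-dose limit is ``emin``; for n2 < 0 it is ``a`` (the
    second factor tends to 1); for n2 = 0 the factor is constant 1/2.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    y = np.empty_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):
        xp = x[pos]
        rising = a + (b - a) / (1.0 + (c1 / xp) ** n1)
        y[pos] = emin + (rising - emin) / (1.0 + (c2 / xp) ** n2)
    if np.any(~pos):
        if n2 > 0:
            y0 = emin
        elif n2 < 0:
            y0 = a
        else:
            y0 = emin + (a - emin) / 2.0
        y[~pos] = y0
    return y[0] if scalar else y


@dataclass
class BellFit:
    """Converged bell-function parameters for one dose-response curve."""

    emin: float
    a: float
    b: float
    c1: float
    c2: float
    n1: float
    n2: float
    rss: float
    converged: bool
    dose_range: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __call__(self, x):
        return bell_curve(x, self.emin, self.a, self.b, self.c1, self.c2, self.n1, self.n2)


@dataclass
class ResponseMetrics:
    """Emax/EC50 read off the fitted line (grid metrics, not fit parameters)."""

    emax: float
    ec50: float | None
    emax_excluded: bool
    grid_points: int
    metadata: dict = field(default_factory=dict)


def direct_response_metrics(
    doses: np.ndarray,
    responses: np.ndarray,
    ec50_min_emax: float = 50.0,
) -> tuple[float, float | None]:
    """Model-free Emax/EC50 of one dose-response curve.

    Emax is the maximum response over the dose grid; EC50 is the dose at
    which the curve first crosses (baseline + Emax)/2 on the rising limb,
    located by linear interpolation (log-dose between positive doses).  The
    baseline is the response at the lowest dose.  EC50 is None when Emax is
    below ``ec50_min_emax`` or the curve never rises through half-maximum.

    Used symmetrically on measured and simulated curves by the calibration
    objective, so that extraction bias cancels between the two sides.
    """
    order = np.argsort(doses)
    d = np.asarray(doses, dtype=float)[order]
    v = np.asarray(responses, dtype=float)[order]
    emax = float(v.max())
    if emax < ec50_min_emax:
        return emax, None
    baseline = float(v[0])
    half = (emax + baseline) / 2.0
    imax = int(np.argmax(v))
    above = np.nonzero(v[: imax + 1] >= half)[0]
    if above.size == 0 or above[0] == 0:
        return emax, (float(d[0]) if above.size else None)
    i = int(above[0])
    d0, d1, v0, v1 = d[i - 1], d[i], v[i - 1], v[i]
    if v1 == v0:
        return emax, float(d1)
    frac = (half - v0) / (v1 - v0)
    if d0 > 0:
        ec50 = float(np.exp(np.log(d0) + frac * (np.log(d1) - np.log(d0))))
    else:
        ec50 = float(d0 + frac * (d1 - d0))
    return emax, ec50


class FitRefusedError(ValueError):
    """Too few distinct non-zero doses to fit the bell function."""


class BellDoseResponse(RegressorMixin, BaseEstimator):
    """Bell-shaped dose-response regressor (scikit-learn interface).

    Parameters
    ----------
    n_starts : int
        Number of multi-start seeds for the bounded least-squares fit (the
        bell objective is multi-modal in c1/c2/n2).
    grid_points : int
        Log-spaced evaluation points for Emax/EC50 extraction.
    exclusion_threshold : float
        Fitted-Emax level (pg/ml) below which EC50 is excluded.

    Attributes
    ----------
    emin_, a_, b_, c1_, c2_, n1_, n2_ : fitted bell parameters.
    rss_ : residual sum of squares at the optimum.
    converged_ : whether any start converged.
    emax_ : maximum of the fitted line over the dose range.
    ec50_ : first half-max crossing on the rising limb (None when excluded
        or when the curve never reaches half-maximum).
    ec50_excluded_ : True when ``emax_`` is below the exclusion threshold.
    """

    def __init__(
        self,
        n_starts: int = 12,
        grid_points: int = DEFAULT_GRID_POINTS,
        exclusion_threshold: float = DEFAULT_EXCLUSION_PG_ML,
    ):
        self.n_starts = n_starts
        self.grid_points = grid_points
        self.exclusion_threshold = exclusion_threshold

    # -- scikit-learn API ----------------------------------------------
    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).reshape(-1)
        responses = np.asarray(y, dtype=float).reshape(-1)
        if doses.shape != responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(doses < 0) or np.any(responses < 0):
            raise ValueError("doses and responses must be >= 0")
        nonzero = np.unique(doses[doses > 0])
        if nonzero.size < 5:
            raise FitRefusedError(
                f"need >= 5 distinct non-zero doses to fit, got {nonzero.size}"
            )
        self._fit_params(doses, responses, nonzero)
        self._extract(nonzero)
        return self

    def predict(self, X):
        self._check_fitted()
        return bell_curve(np.asarray(X, dtype=float), *self._theta)

    # -- internals ------------------------------------------------------
    @property
    def _theta(self):
        return (self.emin_, self.a_, self.b_, self.c1_, self.c2_, self.n1_, self.n2_)

    def _check_fitted(self):
        if not hasattr(self, "emin_"):
            raise AttributeError("estimator is not fitted")

    def _fit_params(self, doses, responses, nonzero):
        ymax = float(responses.max())
        if ymax == 0 or np.ptp(responses) < 1e-12 * max(ymax, 1.0):
            # flat data: the constant curve is exact
            r = float(responses.mean())
            self.emin_, self.a_, self.b_ = r, r, r
            self.c1_, self.c2_ = float(np.median(nonzero)), float(np.median(nonzero))
            self.n1_, self.n2_ = 1.0, 1.0
            self.rss_ = float(np.sum((responses - r) ** 2))
            self.converged_ = True
            return

        dmin, dmax = float(nonzero.min()), float(nonzero.max())
        lo = np.array([0.0, 0.0, 0.0, dmin / 100.0, dmin / 100.0, 0.2, -10.0])
        hi = np.array([ymax, 5 * ymax, 5 * ymax, dmax * 100.0, dmax * 100.0, 10.0, 10.0])

        def residuals(theta):
            return bell_curve(doses, *theta) - responses

        y0 = float(responses[np.argmin(doses)])
        q = np.exp(np.linspace(np.log(dmin), np.log(dmax), 5))
        starts = []
        for c1, c2, n2 in product((q[1], q[3]), (q[2], q[3], dmax * 3), (1.5, -1.5)):
            starts.append(np.array([min(y0, ymax), ymax, 0.8 * ymax, c1, c2, 1.5, n2]))
        starts = starts[: self.n_starts]

        # exploration with capped iterations, then one tight polish of the
        # selected start (the bell objective is multi-modal; full convergence
        # of every start is wasted work)
        candidates = []
        for x0 in starts:
            x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
            try:
                sol = least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-10, ftol=1e-10, max_nfev=80,
                )
            except Exception:
                continue
            candidates.append((float(np.sum(sol.fun**2)), sol))
        best = self._select_candidate(candidates, doses, responses, dmin, dmax)
        if best is not None:
            try:
                sol = least_squares(
                    residuals, best[1].x, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, max_nfev=400,
                )
                rss = float(np.sum(sol.fun**2))
                if rss <= best[0] + 1e-15:
                    best = (rss, sol)
            except Exception:
                pass
        if best is None:
            # no start converged: report the best constant as a flagged non-fit
            r = float(responses.mean())
            self.emin_, self.a_, self.b_ = r, r, r
            self.c1_ = self.c2_ = float(np.median(nonzero))
            self.n1_, self.n2_ = 1.0, 1.0
            self.rss_ = float(np.sum((responses - r) ** 2))
            self.converged_ = False
            return
        rss, sol = best
        (self.emin_, self.a_, self.b_, self.c1_, self.c2_, self.n1_, self.n2_) = (
            float(v) for v in sol.x
        )
        self.rss_ = rss
        self.converged_ = bool(sol.success)

    @staticmethod
    def _select_candidate(candidates, doses, responses, dmin, dmax):
        """Pick the winning multi-start solution.

        Among candidates whose RSS is statistically indistinguishable
        (within 1e-5 of the data's total sum of squares of the best), prefer
        the one whose smooth line extrapolates least above the observed
        maximum, then the lower RSS, then the smaller |n2|.  The 7-parameter
        bell can thread step-like data exactly while inventing a large peak
        between doses; such a peak has no data support and a
        near-equal-RSS monotone fit is the better summary.
        """
        if not candidates:
            return None
        rss_min = min(c[0] for c in candidates)
        ss_tot = float(np.sum((responses - responses.mean()) ** 2))
        eps = 1e-5 * ss_tot + 1e-12
        grid = np.exp(np.linspace(np.log(dmin), np.log(dmax), 2000))
        data_max = float(responses.max())
        scored = []
        for rss, sol in candidates:
            if rss > rss_min + eps:
                continue
            line_max = float(np.max(bell_curve(grid, *sol.x)))
            overshoot = max(0.0, line_max / max(data_max, 1e-12) - 1.0)
            scored.append(((round(overshoot, 6), rss, abs(float(sol.x[6]))), rss, sol))
        key, rss, sol = min(scored, key=lambda c: c[0])
        return rss, sol

    def _extract(self, nonzero):
        self.dose_range_ = (float(nonzero.min()), float(nonzero.max()))
        grid = np.exp(
            np.linspace(np.log(self.dose_range_[0]), np.log(self.dose_range_[1]), self.grid_points)
        )
        line = bell_curve(grid, *self._theta)
        imax = int(np.argmax(line))
        self.emax_ = float(line[imax])
        self.ec50_excluded_ = self.emax_ < self.exclusion_threshold
        self.ec50_ = None
        # half-max baseline: the curve's low-dose asymptote y(0) (equals the
        # emin parameter in the printed n2 > 0 orientation; the bell has a
        # mirror parameterisation with n2 < 0 where the roles of emin and a
        # swap, and y(0) is the orientation-independent baseline)
        base = float(bell_curve(0.0, *self._theta))
        if not self.ec50_excluded_ and self.emax_ - base > 1e-9 * max(self.emax_, 1.0):
            half = base + (self.emax_ - base) / 2.0
            above = np.nonzero(line[: imax + 1] >= half)[0]
            if above.size:
                self.ec50_ = float(grid[above[0]])


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_bell(
    doses: Sequence[float],
    responses: Sequence[float],
    n_starts: int = 8,
    metadata: dict | None = None,
) -> BellFit:
    """Fit the bell function to one dose-response curve."""
    est = BellDoseResponse(n_starts=n_starts).fit(doses, responses)
    return BellFit(
        emin=est.emin_,
        a=est.a_,
        b=est.b_,
        c1=est.c1_,
        c2=est.c2_,
        n1=est.n1_,
        n2=est.n2_,
        rss=est.rss_,
        converged=est.converged_,
        dose_range=est.dose_range_,
        metadata=metadata or {},
    )


def extract_metrics(
    fit: BellFit,
    dose_range: tuple[float, float] | None = None,
    grid_points: int = DEFAULT_GRID_POINTS,
    exclusion_threshold: float = DEFAULT_EXCLUSION_PG_ML,
) -> ResponseMetrics:
    """Read Emax and EC50 off the fitted line over a log-spaced grid.

    Emax is the grid maximum; EC50 the lowest grid dose at which the line
    first reaches Emin + (Emax - Emin)/2 on the rising limb; EC50 is absent
    (and the exclusion flag set) when Emax is below ``exclusion_threshold``.
    """
    lo, hi = dose_range or fit.dose_range
    if not (lo > 0 and hi > lo):
        raise ValueError("dose_range must be positive and increasing")
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), grid_points))
    line = fit(grid)
    imax = int(np.argmax(line))
    emax = float(line[imax])
    excluded = emax < exclusion_threshold
    ec50 = None
    base = float(fit(0.0))  # low-dose asymptote, orientation-independent
    if not excluded and emax - base > 1e-9 * max(emax, 1.0):
        half = base + (emax - base) / 2.0
        above = np.nonzero(line[: imax + 1] >= half)[0]
        if above.size:
            ec50 = float(grid[above[0]])
    return ResponseMetrics(
        emax=emax,
        ec50=ec50,
        emax_excluded=excluded,
        grid_points=grid_points,
        metadata=dict(fit.metadata),
    )


def rate_of_change(
    times: Sequence[float],
    emax: Sequence[float],
    reference_rate: float | None = None,
) -> np.ndarray:
    """Per-interval rate of change of Emax, taking Emax(0 h) = 0.

    rate over (t_{i-1}, t_i] = (Emax_i - Emax_{i-1}) / (t_i - t_{i-1}); the
    series is prepended with the point (0, 0).  If ``reference_rate`` is
    given (the no-co-stimulation rate at the first time point), rates are
    divided by it.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(emax, dtype=float)
    if t.shape != e.shape or t.size == 0:
        raise ValueError("times and emax must be non-empty and equal length")
    if np.any(np.diff(t) <= 0) or t[0] <= 0:
        raise ValueError("times must be strictly increasing and start after 0")
    rates = np.diff(np.concatenate([[0.0], e])) / np.diff(np.concatenate([[0.0], t]))
    if reference_rate is not None:
        if reference_rate == 0:
            raise ValueError("reference rate is zero; cannot normalise")
        rates = rates / reference_rate
    return rates


def normalise_metrics(
    table: pd.DataFrame,
    value_columns: Sequence[str] = ("emax_pg_ml", "ec50_ng_well"),
    experiment_column: str = "experiment",
    mode: str = "mean",
    reference: dict | None = None,
) -> pd.DataFrame:
    """Fold-change normalisation of extracted metrics within each experiment.

    ``mode="mean"`` divides each value by the mean of that readout across all
    conditions of the same experiment (removes technical scale differences
    between experiments, e.g. donor variability).  ``mode="reference"``
    divides by the value of a named standard condition, given as a
    column->value mapping (e.g. ``{"ligand": "none", "time_h": 4}``); the
    reference is resolved per experiment.  Both normalisations leave ratios
    between conditions unchanged.
    """
    if mode not in ("mean", "reference"):
        raise ValueError("mode must be 'mean' or 'reference'")
    out = table.copy()
    for col in value_columns:
        norm_col = f"{col}_norm"
        out[norm_col] = np.nan
        for exp, idx in out.groupby(experiment_column).groups.items():
            sub = out.loc[idx, col]
            if mode == "mean":
                denom = sub.mean(skipna=True)
            else:
                if not reference:
                    raise ValueError("reference mapping required for mode='reference'")
                mask = pd.Series(True, index=idx)
                for key, val in reference.items():
                    mask &= out.loc[idx, key] == val
                ref_vals = out.loc[idx][mask.to_numpy()][col]
                if ref_vals.empty:
                    raise ValueError(f"reference condition not found in experiment {exp!r}")
                denom = ref_vals.mean(skipna=True)
            if not denom or np.isnan(denom):
                raise ValueError(f"zero/undefined normalisation denominator in experiment {exp!r}")
            out.loc[idx, norm_col] = out.loc[idx, col] / denom
    return out
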