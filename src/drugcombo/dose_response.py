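"""Four-parameter log-logistic (LL4) dose-response fitting.

The curve family is

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with slope ``b`` (b > 0 gives viability decreasing with dose), lower
asymptote ``c``, upper asymptote ``d`` (viability of the untreated limit,
so f(0) = d) and inflection concentration ``e`` in uM (f(e) = (c + d)/2).

Fits carry a heteroskedasticity-consistent (sandwich) parameter covariance
so that viability predicted at any concentration — in particular a drug's
clinically sustained plasma concentration, which screens rarely test
directly — comes with a delta-method standard error.  Those (mean, SE)
pairs are the inputs of the semi-parametric bootstrap downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError, InputError, RangeError
from .panel import MonotherapyPanel, ViabilityEstimate

logger = logging.getLogger(__name__)

#: Minimum reported standard error, so bootstrap draws from zero-residual
#: fits remain well-defined.
SE_FLOOR = 1e-6

_EXP_CLIP = 700.0  # exp argument clip; beyond this the logistic saturates anyway


def ll4(x, b, c, d, e):
    """Evaluate the LL4 curve; x = 0 maps to the upper asymptote d."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        z = np.clip(b * (np.log(x) - np.log(e)), -_EXP_CLIP, _EXP_CLIP)
    out = c + (d - c) / (1.0 + np.exp(z))
    return np.where(x == 0, d, out)


def ll4_gradient(x, b, c, d, e):
    """Gradient of the LL4 curve w.r.t. (b, c, d, e); shape (..., 4).

    At x = 0 the curve equals d exactly, so the gradient is (0, 0, 1, 0).
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        s = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)) - np.log(e), 0.0)
    z = np.clip(b * s, -_EXP_CLIP, _EXP_CLIP)
    u = np.exp(z)
    denom = (1.0 + u) ** 2
    db = -(d - c) * u * s / denom
    dc = u / (1.0 + u)
    dd = 1.0 / (1.0 + u)
    de = (d - c) * u * b / (e * denom)
    grad = np.stack(np.broadcast_arrays(db, dc, dd, de), axis=-1)
    zero = x == 0
    if np.any(zero):
        grad = np.where(zero[..., None], np.array([0.0, 0.0, 1.0, 0.0]), grad)
    return grad


@dataclass
class LogLogisticFit:
    """A fitted LL4 curve for one (cell line, drug) pair.

    ``param_covariance`` is the 4x4 sandwich covariance of (b, c, d, e);
    symmetric positive semi-definite by construction.
    """

    b: float
    c: float
    d: float
    e: float
    param_covariance: np.ndarray
    n_points: int
    max_tested: float
    converged: bool = True
    degenerate: bool = False
    underdetermined: bool = False
    cov_singular: bool = False

    def __post_init__(self) -> None:
        self.param_covariance = np.asarray(self.param_covariance, dtype=float)
        if self.param_covariance.shape != (4, 4):
            raise InputError("param_covariance must be 4x4")
        if not (self.e > 0):
            raise InputError(f"inflection concentration must be > 0, got {self.e}")
        if not (self.max_tested > 0):
            raise InputError(f"max_tested must be > 0, got {self.max_tested}")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.b, self.c, self.d, self.e])

    def __call__(self, x):
        return ll4(x, self.b, self.c, self.d, self.e)


class LL4Regressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for one LL4 dose-response curve.

    Fits ``f(x) = c + (d - c) / (1 + exp(b (ln x - ln e)))`` to
    (concentration, viability) pairs by bounded least squares.

    Parameters
    ----------
    n_restarts : int
        Number of jittered restarts attempted when the first optimization
        does not converge; the fit with the best residual sum wins.
    cov_type : {"hc0", "hc1", "classical"}
        Parameter-covariance estimator.  ``"hc0"`` (default) is the
        sandwich estimator robust to heteroskedastic screen noise;
        ``"hc1"`` applies the n/(n-p) small-sample scale; ``"classical"``
        assumes homoskedastic errors.
    random_state : int
        Seed for restart jitter.

    Attributes
    ----------
    b_, c_, d_, e_ : float
        Fitted slope, lower asymptote, upper asymptote, inflection (uM).
    covariance_ : ndarray of shape (4, 4)
        Parameter covariance (symmetric PSD).
    converged_ : bool
    fit_ : LogLogisticFit
        The full fit record consumed by the rest of the pipeline.
    """

    def __init__(self, n_restarts: int = 3, cov_type: str = "hc0", random_state: int = 0):
        self.n_restarts = n_restarts
        self.cov_type = cov_type
        self.random_state = random_state

    # bounds: asymptotes allow raw-screen overshoot; e spans the tested
    # range with two decades of slack; |b| capped to keep the logistic sane
    @staticmethod
    def _bounds(doses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([-20.0, -0.5, -0.5, doses.min() / 100.0])
        hi = np.array([20.0, 1.5, 1.5, doses.max() * 100.0])
        return lo, hi

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise InputError("concentrations and viabilities must have equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InputError("non-finite dose or viability passed to LL4 fit")
        pos = x > 0
        distinct = np.unique(x[pos])
        if distinct.size < 2:
            raise FitError(
                f"LL4 fit needs >= 2 distinct positive concentrations, got {distinct.size}"
            )
        self.underdetermined_ = distinct.size < 4
        if self.underdetermined_:
            logger.warning(
                "fitting LL4 with only %d distinct doses; prefer measured-viability "
                "panels for few-dose designs", distinct.size,
            )

        self.x_, self.y_ = x, y
        self.max_tested_ = float(x.max())
        self.n_points_ = int(x.size)

        if np.ptp(y) == 0.0:  # constant data: flat curve, flagged degenerate
            val = float(y[0])
            self.b_, self.c_, self.d_, self.e_ = 1.0, val, val, float(np.median(distinct))
            self.covariance_ = np.zeros((4, 4))
            self.converged_ = True
            self.degenerate_ = True
            self.cov_singular_ = False
            self._finalize()
            return self
        self.degenerate_ = False

        lo, hi = self._bounds(distinct)
        d0 = float(np.clip(y.max(), lo[2], hi[2]))
        c0 = float(np.clip(y.min(), lo[1], hi[1]))
        half = (d0 + c0) / 2.0
        # dose whose mean response is nearest the half-range
        mean_by_dose = np.array([y[x == dose].mean() for dose in distinct])
        e0 = float(distinct[np.argmin(np.abs(mean_by_dose - half))])
        theta0 = np.array([1.0, c0, d0, e0])

        def residuals(theta):
            return ll4(x, *theta) - y

        def jac(theta):
            return ll4_gradient(x, *theta)

        rng = np.random.default_rng(self.random_state)
        best = None
        starts = [theta0]
        for _ in range(max(self.n_restarts - 1, 0)):
            jitter = theta0 * (1.0 + 0.3 * rng.standard_normal(4))
            starts.append(np.clip(jitter, lo + 1e-12, hi - 1e-12))
        for i, start in enumerate(starts):
            sol = least_squares(
                residuals, np.clip(start, lo, hi), jac=jac, bounds=(lo, hi), method="trf"
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if i == 0 and sol.success:
                break

        self.b_, self.c_, self.d_, self.e_ = (float(v) for v in best.x)
        self.converged_ = bool(best.success)
        if not self.converged_:
            logger.warning("LL4 optimizer did not converge after %d start(s)", len(starts))
        resid = residuals(best.x)
        self.covariance_, self.cov_singular_ = _sandwich_covariance(
            ll4_gradient(x, *best.x), resid, self.cov_type
        )
        self._finalize()
        return self

    def _finalize(self) -> None:
        self.fit_ = LogLogisticFit(
            b=self.b_, c=self.c_, d=self.d_, e=self.e_,
            param_covariance=self.covariance_,
            n_points=self.n_points_, max_tested=self.max_tested_,
            converged=self.converged_, degenerate=self.degenerate_,
            underdetermined=self.underdetermined_, cov_singular=self.cov_singular_,
        )

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return ll4(x, self.b_, self.c_, self.d_, self.e_)


def _sandwich_covariance(jacobian: np.ndarray, residuals: np.ndarray, cov_type: str):
    """Heteroskedasticity-consistent covariance of nonlinear LS parameters.

    HC0: (J'J)^-1 J' diag(r^2) J (J'J)^-1, with a pseudo-inverse (flagged)
    when the information matrix is singular; projected to symmetric PSD by
    flooring eigenvalues at zero.
    """
    if cov_type not in ("hc0", "hc1", "classical"):
        raise InputError(f"unknown covariance type {cov_type!r}")
    J = np.asarray(jacobian, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n, p = J.shape
    JtJ = J.T @ J
    singular = False
    try:
        bread = np.linalg.inv(JtJ)
        if not np.all(np.isfinite(bread)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        bread = np.linalg.pinv(JtJ)
        singular = True
        logger.warning("singular information matrix; using pseudo-inverse for covariance")
    if cov_type == "classical":
        dof = max(n - p, 1)
        cov = bread * float(r @ r) / dof
    else:
        meat = (J * (r ** 2)[:, None]).T @ J
        cov = bread @ meat @ bread
        if cov_type == "hc1":
            cov = cov * n / max(n - p, 1)
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    cov = (v * np.maximum(w, 0.0)) @ v.T
    return (cov + cov.T) / 2.0, singular


def fit_ll4(
    concentrations: Sequence[float],
    viabilities: Sequence[float],
    cov_type: str = "hc0",
    n_restarts: int = 3,
    random_state: int = 0,
) -> LogLogisticFit:
    """Fit an LL4 curve to one (cell line, drug)'s dose/viability pairs."""
    reg = LL4Regressor(n_restarts=n_restarts, cov_type=cov_type, random_state=random_state)
    reg.fit(concentrations, viabilities)
    return reg.fit_


def robust_param_covariance(
    fit: LogLogisticFit,
    concentrations: Sequence[float],
    viabilities: Sequence[float],
    cov_type: str = "hc0",
) -> np.ndarray:
    """Recompute the sandwich parameter covariance for a fit from raw data."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(viabilities, dtype=float)
    resid = fit(x) - y
    cov, singular = _sandwich_covariance(ll4_gradient(x, *fit.params), resid, cov_type)
    fit.cov_singular = singular
    return cov


def predict_viability(
    fit: LogLogisticFit, concentration: float, extrapolation_limit: float = 2.0
) -> ViabilityEstimate:
    """Predict viability (with delta-method SE) at a concentration in uM.

    Concentrations above the maximum tested dose are flagged as
    extrapolated; beyond ``extrapolation_limit`` x max tested the request
    is refused, mirroring the clinical admission criterion that relevant
    concentrations be no more than twice the tested range.
    """
    conc = float(concentration)
    if not (np.isfinite(conc) and conc >= 0):
        raise InputError(f"concentration must be finite and >= 0, got {conc}")
    if conc > extrapolation_limit * fit.max_tested:
        raise RangeError(
            f"concentration {conc:g} uM exceeds {extrapolation_limit:g} x max tested "
            f"({fit.max_tested:g} uM)"
        )
    mean = float(fit(conc))
    g = ll4_gradient(conc, *fit.params).reshape(4)
    se = float(np.sqrt(max(g @ fit.param_covariance @ g, 0.0)))
    return ViabilityEstimate(
        mean=mean, se=max(se, SE_FLOOR), source="fitted", extrapolated=conc > fit.max_tested
    )


def build_panel(
    fits: Mapping[tuple[str, str], LogLogisticFit],
    doses: Sequence[tuple[str, float]],
    extrapolation_limit: float = 2.0,
) -> MonotherapyPanel:
    """Build a monotherapy panel by evaluating fits at the requested doses.

    ``fits`` is keyed by (cell_line, drug); ``doses`` lists the
    (drug, concentration_uM) columns wanted.  Cells without a fit become
    explicit missing markers.  Orientation is viability.
    """
    if not doses:
        raise InputError("empty dose list: at least one (drug, concentration) is required")
    cell_lines = sorted({line for line, _ in fits})
    estimates: dict[tuple[str, str, float], ViabilityEstimate] = {}
    for drug, conc in doses:
        for line in cell_lines:
            fit = fits.get((line, drug))
            if fit is None:
                continue
            estimates[(line, drug, float(conc))] = predict_viability(
                fit, conc, extrapolation_limit
            )
    return MonotherapyPanel.from_estimates(
        estimates, cell_lines=cell_lines, doses=[(d, float(c)) for d, c in doses]
    )


def panel_from_observations(
    table: pd.DataFrame,
    doses: Sequence[tuple[str, float]],
    default_se: float | None = None,
) -> MonotherapyPanel:
    """Build a panel from measured viabilities (no curve fitting).

    The route for few-dose designs (e.g. 3-dose screens) where curve
    fitting is impractical: each requested (drug, concentration) must be
    measured exactly; replicate rows are averaged, with SE taken from the
    replicate spread (sd / sqrt(n)) or ``default_se`` for singletons.
    """
    if not doses:
        raise InputError("empty dose list")
    estimates: dict[tuple[str, str, float], ViabilityEstimate] = {}
    lines = sorted(table["cell_line"].unique())
    for drug, conc in doses:
        sub = table[(table["drug"] == drug) & (table["concentration_uM"] == float(conc))]
        for line, grp in sub.groupby("cell_line"):
            vals = grp["viability"].to_numpy(float)
            if vals.size > 1:
                se = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
            elif default_se is not None:
                se = float(default_se)
            else:
                se = SE_FLOOR
            estimates[(str(line), drug, float(conc))] = ViabilityEstimate(
                mean=float(vals.mean()), se=max(se, SE_FLOOR), source="measured"
            )
    return MonotherapyPanel.from_estimates(
        estimates, cell_lines=lines, doses=[(d, float(c)) for d, c in doses]
    )


# ---------------------------------------------------------------------------
# Fit-table serialization
# ---------------------------------------------------------------------------

_COV_COLS = [f"cov_{i}{j}" for i in range(4) for j in range(4)]


def fits_to_frame(fits: Mapping[tuple[str, str], LogLogisticFit]) -> pd.DataFrame:
    rows = []
    for (line, drug), fit in sorted(fits.items()):
        row = {
            "cell_line": line, "drug": drug,
            "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e,
            "max_tested_uM": fit.max_tested, "n_points": fit.n_points,
            "converged": fit.converged,
        }
        row.update(dict(zip(_COV_COLS, fit.param_covariance.ravel())))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> dict[tuple[str, str], LogLogisticFit]:
    fits = {}
    for _, row in df.iterrows():
        cov = np.array([row[c] for c in _COV_COLS]).reshape(4, 4)
        fits[(str(row["cell_line"]), str(row["drug"]))] = LogLogisticFit(
            b=row["b"], c=row["c"], d=row["d"], e=row["e"],
            param_covariance=cov, n_points=int(row["n_points"]),
            max_tested=row["max_tested_uM"], converged=bool(row["converged"]),
        )
    return fits


def fit_screen(
    table: pd.DataFrame, cov_type: str = "hc0", random_state: int = 0
) -> dict[tuple[str, str], LogLogisticFit]:
    """Fit LL4 curves for every (cell line, drug) pair in an observation table.

    Pairs whose fit fails (too few distinct doses) are skipped with a log
    message rather than aborting the screen.
    """
    fits: dict[tuple[str, str], LogLogisticFit] = {}
    n_failed = 0
    for (line, drug), grp in table.groupby(["cell_line", "drug"], sort=True):
        try:
            fits[(str(line), str(drug))] = fit_ll4(
                grp["concentration_uM"], grp["viability"],
                cov_type=cov_type, random_state=random_state,
            )
        except FitError:
            n_failed += 1
    if n_failed:
        logger.warning("skipped %d (cell line, drug) pair(s) with unfittable data", n_failed)
    return fits
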