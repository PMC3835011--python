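"""Parameter estimation, bootstrap confidence intervals and goodness of fit.

The four model parameters (a, b, t, m) are estimated by minimising the
sum-of-squares merit function between predicted and observed relative ERG
amplitude.  The hinge at the IOP threshold ``t`` makes the objective only
piecewise smooth, so a single local solve is unreliable; fitting therefore
uses bounded multi-start least squares with Latin-hypercube initial points
and keeps the lowest-SSE solution (ties broken by the smaller parameter
norm).

Confidence intervals come from a bootstrap: records are resampled with
replacement (case resampling, the default, robust to heteroscedastic ERG
noise) or residuals are resampled onto the fitted curve, the model is refit
per replicate, and percentile 2.5/97.5 limits are reported.

Goodness of fit is graded through the chi-square statistic
``chi2 = sum(((obs - pred) / sem)**2)`` and its upper-tail probability
``Q(chi2 | df)`` (regularised incomplete gamma).  Q below 0.001 is a poor
fit, between 0.001 and 0.1 (inclusive) acceptable, above 0.1 good.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import qmc

from .model import ModelParams, erg_model

__all__ = [
    "DEFAULT_BOUNDS",
    "FitResult",
    "GofResult",
    "BootstrapResult",
    "fit_model",
    "bootstrap_ci",
    "chi_square_gof",
    "grade_q",
    "predict_cohort",
    "prediction_sem",
]

PARAM_NAMES = ("a", "b", "t", "m")

# Parameter box: a in (0, 20], b in [-0.2, 0), t in [10, 120], m in [-5, 0].
# The open edges are closed off by a tiny epsilon so bounded solvers accept
# the box.
_EPS = 1e-9
DEFAULT_BOUNDS = {
    "a": (_EPS, 20.0),
    "b": (-0.2, -_EPS),
    "t": (10.0, 120.0),
    "m": (-5.0, 0.0),
}


def _bounds_arrays(bounds: dict) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([bounds[k][0] for k in PARAM_NAMES], dtype=float)
    hi = np.array([bounds[k][1] for k in PARAM_NAMES], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("each parameter bound must satisfy lower < upper")
    return lo, hi


def _extract(data) -> pd.DataFrame:
    """Coerce input records to a DataFrame sorted canonically.

    Requires ``iop_mmHg``, ``flow_pct`` and ``erg_pct`` columns;
    ``erg_sem_pct`` is optional.  Sorting makes every downstream result
    independent of the order records arrive in.
    """
    df = pd.DataFrame(data)
    for col in ("iop_mmHg", "flow_pct", "erg_pct"):
        if col not in df.columns:
            raise KeyError(f"missing required column: {col}")
    order = np.lexsort(
        (df["erg_pct"].to_numpy(), df["flow_pct"].to_numpy(), df["iop_mmHg"].to_numpy())
    )
    return df.iloc[order].reset_index(drop=True)


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit summary."""

    chi2: float
    df: int
    q: float
    grade: str

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "q": self.q, "grade": self.grade}


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap intervals for the four parameters."""

    ci: dict
    n_boot: int
    n_dropped: int
    seed: Optional[int]
    method: str
    samples: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_boot": self.n_boot,
            "n_dropped": self.n_dropped,
            "seed": self.seed,
            "method": self.method,
        }


@dataclass
class FitResult:
    """Outcome of a sum-of-squares model fit."""

    params: ModelParams
    sse: float
    residuals: np.ndarray
    n_points: int
    n_starts: int
    seed: Optional[int]
    t_at_bound: bool
    gof: Optional[GofResult] = None
    bootstrap: Optional[BootstrapResult] = None

    def to_dict(self) -> dict:
        out = {
            "params": {k: getattr(self.params, k) for k in PARAM_NAMES},
            "sse": self.sse,
            "n_points": self.n_points,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "t_at_bound": self.t_at_bound,
        }
        if self.gof is not None:
            out["gof"] = self.gof.to_dict()
        if self.bootstrap is not None:
            out["bootstrap"] = self.bootstrap.to_dict()
        return out


def _residual_fn(iop: np.ndarray, flow: np.ndarray, erg: np.ndarray):
    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, t, m = theta
        cons = flow * (a * np.exp(b * flow) + (1.0 - a * np.exp(100.0 * b)))
        stress = np.where(iop <= t, 0.0, m * (iop - t))
        pred = np.maximum(cons + stress, 0.0)
        return erg - pred

    return residuals


def _single_fit(residuals, x0, lo, hi, tol=1e-14):
    x0 = np.clip(x0, lo, hi)
    return optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        xtol=tol, ftol=tol, gtol=tol, max_nfev=2000,
    )


def _refit_replicate(res_fn, x_hat, lo, hi, t_jitter):
    """Refit one bootstrap replicate from threshold-perturbed warm starts.

    The SSE profile in the threshold t is piecewise smooth with knots at
    the data's IOP values, so a single warm start can stay trapped in the
    full-data solution's knot interval and understate the replicate spread
    of t (which in turn miscalibrates the intervals).  Starting also from
    t shifted one knot spacing down and up lets each replicate settle in
    its own interval.
    """
    best = None
    for dt in (0.0, -t_jitter, t_jitter):
        x0 = x_hat.copy()
        x0[2] = np.clip(x0[2] + dt, lo[2], hi[2])
        try:
            sol = _single_fit(res_fn, x0, lo, hi, tol=1e-12)
        except Exception:
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def fit_model(
    data,
    init: Optional[ModelParams] = None,
    bounds: Optional[dict] = None,
    n_starts: int = 16,
    seed: Optional[int] = None,
    compute_gof: bool = True,
) -> FitResult:
    """Fit (a, b, t, m) to flow/ERG records by multi-start least squares.

    Parameters
    ----------
    data:
        Records with columns ``iop_mmHg``, ``flow_pct``, ``erg_pct`` and,
        optionally, ``erg_sem_pct`` (anything :class:`pandas.DataFrame`
        accepts).  At least 5 records are required, spanning IOPs on both
        sides of any plausible threshold, else ``t`` is unidentifiable.
    init:
        Optional extra starting point, tried in addition to the
        Latin-hypercube starts.
    bounds:
        Per-parameter ``{name: (lo, hi)}`` box; defaults to
        :data:`DEFAULT_BOUNDS`.
    n_starts:
        Number of Latin-hypercube starting points (>= 1).
    seed:
        Seed for the start-point sampler; fixes the fit exactly.
    compute_gof:
        Attach a chi-square grade when per-point SEMs are present
        (df = n_points - 4, all four parameters fitted).

    Returns
    -------
    FitResult
        Lowest-SSE solution over all starts.  ``t_at_bound`` is set when
        the fitted threshold lies at the box edge or no record exceeds it,
        meaning the data do not constrain the mechanical-stress component.
    """
    df = _extract(data)
    if len(df) < 5:
        raise ValueError(f"need >= 5 records to fit 4 parameters, got {len(df)}")
    iop = df["iop_mmHg"].to_numpy(float)
    flow = df["flow_pct"].to_numpy(float)
    erg = df["erg_pct"].to_numpy(float)

    box = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    lo, hi = _bounds_arrays(box)
    residuals = _residual_fn(iop, flow, erg)

    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)
    if init is not None:
        starts = np.vstack([init.as_array(), starts])

    best = None
    n_failed = 0
    for x0 in starts:
        try:
            sol = _single_fit(residuals, x0, lo, hi)
        except Exception:
            n_failed += 1
            continue
        if not sol.success:
            n_failed += 1
            continue
        sse = float(2.0 * sol.cost)
        norm = float(np.linalg.norm(sol.x))
        key = (sse, norm)
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise RuntimeError(
            f"optimizer failed to converge from all {len(starts)} starts "
            f"({n_failed} failures); check data and bounds"
        )
    sol = best[1]
    params = ModelParams.from_array(sol.x)
    res = residuals(sol.x)
    sse = float(np.sum(res**2))

    t_hat = params.t
    t_at_bound = bool(
        np.isclose(t_hat, box["t"][0]) or np.isclose(t_hat, box["t"][1])
        or not np.any(iop > t_hat)
    )
    if t_at_bound:
        warnings.warn(
            "threshold t is unconstrained by the data (no records above the "
            "fitted threshold or t at its bound)",
            stacklevel=2,
        )

    gof = None
    if compute_gof and "erg_sem_pct" in df.columns and df["erg_sem_pct"].notna().all():
        sem = df["erg_sem_pct"].to_numpy(float)
        if np.all(sem > 0) and len(df) > 4:
            pred = erg - res
            gof = chi_square_gof(erg, pred, sem, n_free_params=4)

    return FitResult(
        params=params,
        sse=sse,
        residuals=res,
        n_points=len(df),
        n_starts=int(n_starts),
        seed=seed,
        t_at_bound=t_at_bound,
        gof=gof,
    )


def bootstrap_ci(
    data,
    fit: FitResult,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    method: str = "case",
    bounds: Optional[dict] = None,
) -> BootstrapResult:
    """Percentile 95 % bootstrap intervals for the fitted parameters.

    Each replicate resamples the records with replacement (``method="case"``)
    or resamples fitted residuals onto the fitted curve
    (``method="residual"``), then refits from the full-data solution, warm
    starting from three threshold offsets (see :func:`_refit_replicate`).
    Replicates whose refit fails are dropped and counted; more than 20 %
    dropped raises a warning.  Fully reproducible given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentile intervals")
    if method not in ("case", "residual"):
        raise ValueError(f"unknown bootstrap method: {method!r}")
    df = _extract(data)
    iop = df["iop_mmHg"].to_numpy(float)
    flow = df["flow_pct"].to_numpy(float)
    erg = df["erg_pct"].to_numpy(float)
    n = len(df)

    box = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    lo, hi = _bounds_arrays(box)
    x_hat = fit.params.as_array()
    fitted = erg - fit.residuals

    # knot spacing of the piecewise-smooth t profile ~ the IOP grid spacing
    iop_gaps = np.diff(np.unique(iop))
    t_jitter = 1.5 * float(np.median(iop_gaps)) if iop_gaps.size else 7.5

    rng = np.random.default_rng(seed)
    samples = np.full((n_boot, 4), np.nan)
    n_dropped = 0
    for i in range(n_boot):
        if method == "case":
            idx = rng.integers(0, n, size=n)
            res_fn = _residual_fn(iop[idx], flow[idx], erg[idx])
        else:
            res_star = rng.choice(fit.residuals, size=n, replace=True)
            res_fn = _residual_fn(iop, flow, fitted + res_star)
        sol = _refit_replicate(res_fn, x_hat, lo, hi, t_jitter)
        if sol is None:
            n_dropped += 1
            continue
        samples[i] = sol.x
    kept = samples[~np.isnan(samples).any(axis=1)]
    if n_dropped > 0.2 * n_boot:
        warnings.warn(
            f"{n_dropped}/{n_boot} bootstrap replicates failed to refit",
            stacklevel=2,
        )
    if len(kept) == 0:
        raise RuntimeError("every bootstrap replicate failed to refit")
    lo_q, hi_q = np.percentile(kept, [2.5, 97.5], axis=0)
    ci = {name: (float(l), float(h)) for name, l, h in zip(PARAM_NAMES, lo_q, hi_q)}
    result = BootstrapResult(
        ci=ci, n_boot=n_boot, n_dropped=n_dropped, seed=seed,
        method=method, samples=kept,
    )
    fit.bootstrap = result
    return result


def chi_square_gof(
    observed: Sequence[float],
    predicted: Sequence[float],
    sem: Sequence[float],
    n_free_params: int = 0,
) -> GofResult:
    """Chi-square test of model-versus-data discrepancy, graded by Q.

    ``chi2 = sum(((obs - pred) / sem)**2)`` with ``df = n - n_free_params``
    and ``Q = Q(df/2, chi2/2)`` the regularised upper incomplete gamma —
    the probability that a discrepancy this large arises by chance.  Use
    ``n_free_params=4`` when the parameters were fitted to these same data
    and 0 in pure-prediction (cross-cohort) mode.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    sem = np.asarray(sem, dtype=float)
    if not (obs.shape == pred.shape == sem.shape):
        raise ValueError("observed, predicted and sem must have equal length")
    if np.any(sem <= 0):
        raise ValueError("every SEM must be > 0 for the chi-square statistic")
    df = obs.size - int(n_free_params)
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    chi2 = float(np.sum(((obs - pred) / sem) ** 2))
    q = float(special.gammaincc(df / 2.0, chi2 / 2.0))
    return GofResult(chi2=chi2, df=df, q=q, grade=grade_q(q))


def grade_q(q: float) -> str:
    """Grade a Q probability: < 0.001 poor, 0.001–0.1 acceptable, > 0.1 good.

    Both boundary values grade acceptable.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"Q must lie in [0, 1], got {q}")
    if q < 0.001:
        return "poor"
    if q <= 0.1:
        return "acceptable"
    return "good"


def prediction_sem(data, params: ModelParams) -> np.ndarray:
    """Effective per-point SEM for prediction-mode chi-square tests.

    The model's input — relative blood flow — is itself a noisy measurement,
    so its uncertainty propagates into the predicted ERG.  Comparing
    observation and prediction against the ERG SEM alone is then
    over-dispersed.  This returns the errors-in-variables combination

    ``sqrt(erg_sem**2 + (dERG/dflow)**2 * flow_sem**2)``

    with the flow sensitivity evaluated numerically at each record's
    measured flow.  Requires ``erg_sem_pct`` and ``flow_sem_pct`` columns.
    """
    df = pd.DataFrame(data)
    for col in ("iop_mmHg", "flow_pct", "erg_sem_pct", "flow_sem_pct"):
        if col not in df.columns:
            raise KeyError(f"missing required column: {col}")
    flow = df["flow_pct"].to_numpy(float)
    iop = df["iop_mmHg"].to_numpy(float)
    h = 1e-4
    up = np.asarray(erg_model(flow + h, iop, params))
    dn = np.asarray(erg_model(np.maximum(flow - h, 0.0), iop, params))
    slope = (up - dn) / (2.0 * h)
    return np.sqrt(
        df["erg_sem_pct"].to_numpy(float) ** 2
        + slope**2 * df["flow_sem_pct"].to_numpy(float) ** 2
    )


def predict_cohort(data, params: ModelParams) -> np.ndarray:
    """Model-predicted ERG for each record, with parameters held fixed.

    This is the cross-cohort validation mode: no refitting, just a forward
    evaluation on the records' measured flow and IOP (order preserved).
    Pair with :func:`chi_square_gof` (``n_free_params=0``) for a
    cross-cohort Q grade.
    """
    df = pd.DataFrame(data)
    if df.empty:
        return np.array([], dtype=float)
    for col in ("iop_mmHg", "flow_pct"):
        if col not in df.columns:
            raise KeyError(f"missing required column: {col}")
    return np.asarray(
        erg_model(df["flow_pct"].to_numpy(float), df["iop_mmHg"].to_numpy(float), params)
    )
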