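"""Fitting pipeline for stopped-flow transients and k_obs profiles.

The experimental workflow this reproduces: averaged fluorescence-quench traces
are fitted with single or double exponentials with a floating endpoint, the
extra phase being accepted only if an extra-sum-of-squares F-test supports it;
the observed rates are then regressed against substrate concentration — a
hyperbolic dependence yields the alkylation rate k2, the dissociation constant
K_S and the intercept (k_m2 + k3), a decreasing dependence yields the summed
conformer-exchange rates; finally the intercept sum is split into k_m2 and k3
using the measured kcat, and single-turnover recovery traces report k3
directly.  Standard errors are propagated by the delta method throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from .scheme_model import ReactionConditions, SteadyStateParams

__all__ = [
    "Trace",
    "ExpFit",
    "OrderSelection",
    "KobsSeries",
    "KobsHyperbolicFit",
    "KobsDecreasingFit",
    "MicroRateEstimate",
    "SingleTurnoverK3",
    "MichaelisMentenFit",
    "FitError",
    "fit_exponential",
    "select_order",
    "fit_trace_auto",
    "fit_kobs_hyperbolic",
    "fit_kobs_decreasing",
    "extract_micro_rates",
    "single_turnover_k3",
    "fit_michaelis_menten",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails; carries best-so-far diagnostics."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class Trace:
    """A (possibly averaged) stopped-flow fluorescence time series."""

    time: np.ndarray
    signal: np.ndarray
    conditions: ReactionConditions | None = None
    n_averaged: int = 1
    dead_time_s: float = 0.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if self.time.size < 20:
            raise ValueError("a trace needs at least 20 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Samples at or after the instrument dead time."""
        m = self.time >= self.dead_time_s
        return self.time[m], self.signal[m]


@dataclass
class ExpFit:
    """Result of an exponential fit F(t) = endpoint + sum_i A_i exp(-k_i t)."""

    order: int
    amplitudes: tuple[float, ...]
    k_obs: tuple[float, ...]          # sorted descending for order 2
    endpoint: float
    sse: float
    dof: int
    se_amplitudes: tuple[float, ...]
    se_k_obs: tuple[float, ...]
    se_endpoint: float
    flags: list[str] = field(default_factory=list)
    n_points: int = 0

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.endpoint)
        for a, k in zip(self.amplitudes, self.k_obs):
            y = y + a * np.exp(-k * t)
        return y


@dataclass(frozen=True)
class OrderSelection:
    """Extra-sum-of-squares F-test between nested exponential fits."""

    order: int
    F: float
    p_value: float
    alpha: float
    warning: str | None = None


@dataclass
class KobsSeries:
    """Observed transient rates versus substrate concentration for one phase."""

    substrate_uM: np.ndarray
    kobs: np.ndarray
    se: np.ndarray | None = None
    phase: str = "fast"

    def __post_init__(self):
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.kobs = np.asarray(self.kobs, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.kobs.shape:
                raise ValueError("se must match kobs in length")
        if self.substrate_uM.shape != self.kobs.shape:
            raise ValueError("substrate and kobs must have equal length")
        if np.any(self.substrate_uM <= 0):
            raise ValueError("substrate concentrations must be positive")
        if len(np.unique(self.substrate_uM)) != self.substrate_uM.size:
            raise ValueError("substrate concentrations must be unique")
        if self.phase not in ("fast", "slow"):
            raise ValueError("phase must be 'fast' or 'slow'")


@dataclass
class KobsHyperbolicFit:
    """Fit of k_obs(S) = k2*S/(K_S + S) + (k_m2 + k3)."""

    k2: float
    K_S: float
    intercept: float
    se_k2: float
    se_K_S: float
    se_intercept: float
    sse: float
    flags: list[str] = field(default_factory=list)


@dataclass
class KobsDecreasingFit:
    """Fit of the two-step form k_obs(S) = k_lim + k_rev/(1 + S/K_app).

    The S -> 0 intercept, k_lim + k_rev, is the summed forward/backward rate of
    the substrate-independent transition; whether that is the free-enzyme
    conformer step (k0 + k_m0) or the Michaelis-complex step (k5 + k_m5) is a
    labelling choice left to the caller.
    """

    k_lim: float
    k_rev: float
    K_app: float
    se_k_lim: float
    se_k_rev: float
    se_K_app: float
    intercept: float
    se_intercept: float
    sse: float
    flags: list[str] = field(default_factory=list)


@dataclass
class MicroRateEstimate:
    """Microscopic rates extracted from a hyperbolic k_obs profile plus kcat."""

    k2: float
    K_S: float
    sum_km2_k3: float
    k_m2: float
    k3: float
    se_k2: float = 0.0
    se_K_S: float = 0.0
    se_sum_km2_k3: float = 0.0
    se_k_m2: float = 0.0
    se_k3: float = 0.0
    sum_k5_km5: float | None = None
    se_sum_k5_km5: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class SingleTurnoverK3:
    """Hydrolysis rate from a single-turnover fluorescence-recovery trace."""

    k3: float
    se: float
    fit: ExpFit


@dataclass
class MichaelisMentenFit:
    """Nonlinear regression of initial rates v = kcat*E*S/(Km + S)."""

    kcat: float
    Km: float
    se_kcat: float
    se_Km: float
    sse: float
    flags: list[str] = field(default_factory=list)

    @property
    def params(self) -> SteadyStateParams:
        return SteadyStateParams(kcat=self.kcat, Km=self.Km)


# ---------------------------------------------------------------------------
# Exponential fitting with multistart
# ---------------------------------------------------------------------------

# log-spaced rate candidates, 4 per decade over 1e-2..1e4 s^-1
_RATE_GRID = 10.0 ** np.arange(-2.0, 4.01, 0.25)


def _linear_amplitudes(t, y, ks):
    """Amplitudes/endpoint by linear least squares for fixed rates (varpro)."""
    X = np.column_stack([np.ones_like(t)] + [np.exp(-k * t) for k in ks])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _grid_start(t, y, order):
    best = None
    if order == 1:
        for k in _RATE_GRID:
            coef, sse = _linear_amplitudes(t, y, [k])
            if best is None or sse < best[2]:
                best = ([k], coef, sse)
    else:
        for i, k1 in enumerate(_RATE_GRID):
            for k2 in _RATE_GRID[:i]:
                coef, sse = _linear_amplitudes(t, y, [k1, k2])
                if best is None or sse < best[2]:
                    best = ([k1, k2], coef, sse)
    return best


def _fit_exp_arrays(t, y, order) -> ExpFit:
    n_par = 2 * order + 1
    if t.size < 3 * n_par:
        raise ValueError(
            f"need at least {3 * n_par} points for an order-{order} fit, got {t.size}"
        )
    ks, coef, sse0 = _grid_start(t, y, order)

    params = Parameters()
    params.add("endpoint", value=coef[0])
    for i, (k, a) in enumerate(zip(ks, coef[1:]), start=1):
        params.add(f"a{i}", value=a)
        params.add(f"k{i}", value=k, min=1e-9)

    def resid(p):
        model = np.full_like(t, p["endpoint"].value)
        for i in range(1, order + 1):
            model = model + p[f"a{i}"].value * np.exp(-p[f"k{i}"].value * t)
        return model - y

    try:
        out = minimize(resid, params, method="leastsq")
    except Exception as exc:  # pragma: no cover - lmfit raises rarely
        raise FitError(f"exponential fit failed: {exc}",
                       best={"k": ks, "coef": coef, "sse": sse0}) from exc
    extra_flags = []
    if not out.success:
        # a degenerate second phase (e.g. a truly single-exponential trace)
        # makes the covariance inestimable without invalidating the solution;
        # accept any polish that did not diverge from its grid start
        sse_out = float(np.sum(out.residual ** 2))
        if np.isfinite(sse_out) and sse_out <= sse0 * (1.0 + 1e-9):
            extra_flags.append("convergence_uncertain")
        else:
            raise FitError(f"exponential fit did not converge: {out.message}",
                           best={"k": ks, "coef": coef, "sse": sse0})

    p = out.params
    amps = [p[f"a{i}"].value for i in range(1, order + 1)]
    rates = [p[f"k{i}"].value for i in range(1, order + 1)]
    se_a = [p[f"a{i}"].stderr or np.inf for i in range(1, order + 1)]
    se_k = [p[f"k{i}"].stderr or np.inf for i in range(1, order + 1)]
    # phase convention: fastest phase first
    idx = np.argsort(rates)[::-1]
    amps = [amps[i] for i in idx]
    rates = [rates[i] for i in idx]
    se_a = [se_a[i] for i in idx]
    se_k = [se_k[i] for i in idx]

    sse = float(np.sum(out.residual ** 2))
    dof = t.size - n_par
    flags = extra_flags
    scale = float(np.max(np.abs(y - np.median(y)))) or 1.0
    for a, k, sk in zip(amps, rates, se_k):
        if abs(a) < 1e-6 * scale or (np.isfinite(sk) and sk > abs(k)) or not np.isfinite(sk):
            flags.append("rate_ill_determined")
        if abs(a) < 1e-6 * scale:
            flags.append("amplitude_near_zero")
    return ExpFit(order=order, amplitudes=tuple(amps), k_obs=tuple(rates),
                  endpoint=p["endpoint"].value, sse=sse, dof=dof,
                  se_amplitudes=tuple(se_a), se_k_obs=tuple(se_k),
                  se_endpoint=p["endpoint"].stderr or np.inf,
                  flags=sorted(set(flags)), n_points=int(t.size))


def fit_exponential(trace: Trace, order: int) -> ExpFit:
    """Least-squares exponential fit with floating endpoint.

    Starting values come from a log-spaced rate-grid multistart with amplitudes
    solved linearly; the best grid candidate is polished by Levenberg-
    Marquardt.  Points before the trace's dead time are excluded.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    t, y = trace.observed()
    return _fit_exp_arrays(t, y, order)


def select_order(fit1: ExpFit, fit2: ExpFit, alpha: float = 0.05) -> OrderSelection:
    """Extra-sum-of-squares F-test: is the second phase statistically needed?"""
    if fit1.n_points != fit2.n_points:
        raise ValueError("fits must be on the same trace")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    d_df = fit1.dof - fit2.dof
    if d_df <= 0:
        raise ValueError("the second fit must nest the first (more parameters)")
    if fit2.sse >= fit1.sse:
        warning = None
        if fit2.sse > fit1.sse:
            warning = ("order-2 fit has larger SSE than order-1; "
                       "keeping the simpler model")
        return OrderSelection(order=1, F=0.0, p_value=1.0, alpha=alpha,
                              warning=warning)
    if fit2.sse == 0.0:
        return OrderSelection(order=2, F=np.inf, p_value=0.0, alpha=alpha)
    F = ((fit1.sse - fit2.sse) / d_df) / (fit2.sse / fit2.dof)
    p = float(stats.f.sf(F, d_df, fit2.dof))
    return OrderSelection(order=2 if p < alpha else 1, F=float(F),
                          p_value=p, alpha=alpha)


def fit_trace_auto(trace: Trace, alpha: float = 0.05,
                   min_rate_ratio: float = 3.0,
                   min_amp_frac: float = 0.05) -> tuple[ExpFit, OrderSelection]:
    """Fit both exponential orders and pick one defensibly.

    The F-test alone is necessary but not sufficient: on very clean data it
    will accept a degenerate second phase (two nearly equal rates, or a
    near-zero amplitude) that absorbs tiny systematic curvature rather than a
    real kinetic phase.  Sums of exponentials closer than about a factor of
    three in rate are not practically resolvable, so the second phase is kept
    only when the F-test supports it AND the two rates are separated by
    ``min_rate_ratio`` AND each phase carries at least ``min_amp_frac`` of the
    total fitted amplitude and a finite rate standard error.
    """
    fit1 = fit_exponential(trace, 1)
    n_par2 = 5
    t_obs, _ = trace.observed()
    if t_obs.size < 3 * n_par2:
        return fit1, OrderSelection(order=1, F=0.0, p_value=1.0, alpha=alpha,
                                    warning="too few points for an order-2 fit")
    fit2 = fit_exponential(trace, 2)
    sel = select_order(fit1, fit2, alpha=alpha)
    if sel.order == 2:
        k1, k2 = fit2.k_obs
        amp_tot = sum(abs(a) for a in fit2.amplitudes)
        resolvable = (
            k2 > 0 and k1 / k2 >= min_rate_ratio
            and amp_tot > 0
            and min(abs(a) for a in fit2.amplitudes) >= min_amp_frac * amp_tot
            and "rate_ill_determined" not in fit2.flags
        )
        if not resolvable:
            sel = OrderSelection(order=1, F=sel.F, p_value=sel.p_value,
                                 alpha=alpha,
                                 warning="second phase not resolvable "
                                         "(degenerate rates or amplitude)")
    return (fit2 if sel.order == 2 else fit1), sel


# ---------------------------------------------------------------------------
# k_obs-vs-[S] regressions
# ---------------------------------------------------------------------------

def _weights(series: KobsSeries):
    if series.se is not None and np.all(series.se > 0):
        return 1.0 / series.se
    return np.ones_like(series.kobs)


def _trend(series: KobsSeries) -> float:
    if np.ptp(series.kobs) == 0:  # flat series: no trend either way
        return 0.0
    r, _ = stats.spearmanr(series.substrate_uM, series.kobs)
    return float(r)


def fit_kobs_hyperbolic(series: KobsSeries) -> KobsHyperbolicFit:
    """Fit k_obs(S) = k2*S/(K_S + S) + (k_m2 + k3).

    Inverse-variance weighted when the series carries standard errors.  When
    K_S lies beyond the sampled range the extrapolation inflates the standard
    errors of k2 and K_S; the fit is flagged rather than rejected.
    """
    if series.substrate_uM.size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if _trend(series) < -0.5:
        raise ValueError(
            "k_obs decreases with [S]; fit the decreasing (two-step) model instead"
        )
    S, y, w = series.substrate_uM, series.kobs, _weights(series)

    params = Parameters()
    span = max(float(y.max() - y.min()), 1e-9)
    params.add("k2", value=2.0 * span, min=0.0)
    params.add("K_S", value=float(np.median(S)), min=1e-9)
    params.add("c", value=max(float(y.min()), 0.0), min=0.0)

    def resid(p):
        model = p["k2"].value * S / (p["K_S"].value + S) + p["c"].value
        return (model - y) * w

    out = minimize(resid, params, method="leastsq")
    p = out.params
    sse = float(np.sum(((p["k2"].value * S / (p["K_S"].value + S) + p["c"].value) - y) ** 2))
    flags = []
    se_k2 = p["k2"].stderr if p["k2"].stderr is not None else np.inf
    se_KS = p["K_S"].stderr if p["K_S"].stderr is not None else np.inf
    se_c = p["c"].stderr if p["c"].stderr is not None else np.inf
    if p["K_S"].value > float(S.max()):
        flags.append("K_S_beyond_data_range")
    scale = max(float(np.max(np.abs(y))), 1e-12)
    if not np.isfinite(se_KS) or (p["K_S"].value > 0 and se_KS > p["K_S"].value) \
            or p["k2"].value < 1e-6 * scale:
        flags.append("K_S_ill_determined")
    if np.isfinite(se_k2) and p["k2"].value > 0 and se_k2 > 0.5 * p["k2"].value:
        flags.append("k2_weakly_identified")
    return KobsHyperbolicFit(k2=p["k2"].value, K_S=p["K_S"].value,
                             intercept=p["c"].value, se_k2=se_k2, se_K_S=se_KS,
                             se_intercept=se_c, sse=sse, flags=flags)


def fit_kobs_decreasing(series: KobsSeries) -> KobsDecreasingFit:
    """Fit the decreasing two-step form and report the S -> 0 intercept.

    k_obs(S) = k_lim + k_rev/(1 + S/K_app); the intercept k_lim + k_rev is the
    summed rate of the substrate-independent transition.
    """
    if series.substrate_uM.size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if _trend(series) > 0.5:
        raise ValueError(
            "k_obs increases with [S]; fit the hyperbolic model instead"
        )
    S, y, w = series.substrate_uM, series.kobs, _weights(series)

    params = Parameters()
    span = max(float(y.max() - y.min()), 1e-9)
    params.add("k_lim", value=max(float(y.min()), 1e-6), min=0.0)
    params.add("k_rev", value=span, min=0.0)
    params.add("K_app", value=float(np.median(S)), min=1e-9)

    def resid(p):
        model = p["k_lim"].value + p["k_rev"].value / (1.0 + S / p["K_app"].value)
        return (model - y) * w

    out = minimize(resid, params, method="leastsq")
    p = out.params
    model = p["k_lim"].value + p["k_rev"].value / (1.0 + S / p["K_app"].value)
    sse = float(np.sum((model - y) ** 2))
    se = {k: (p[k].stderr if p[k].stderr is not None else np.inf)
          for k in ("k_lim", "k_rev", "K_app")}
    # variance of the intercept sum includes the k_lim/k_rev covariance
    if out.covar is not None and out.var_names:
        names = list(out.var_names)
        cov = out.covar
        try:
            i, j = names.index("k_lim"), names.index("k_rev")
            var_sum = cov[i, i] + cov[j, j] + 2.0 * cov[i, j]
            se_intercept = math.sqrt(max(var_sum, 0.0))
        except ValueError:
            se_intercept = np.inf
    else:
        se_intercept = np.inf
    flags = []
    if p["k_rev"].value < 1e-9 * max(p["k_lim"].value, 1.0):
        flags.append("flat_series")
    return KobsDecreasingFit(k_lim=p["k_lim"].value, k_rev=p["k_rev"].value,
                             K_app=p["K_app"].value, se_k_lim=se["k_lim"],
                             se_k_rev=se["k_rev"], se_K_app=se["K_app"],
                             intercept=p["k_lim"].value + p["k_rev"].value,
                             se_intercept=se_intercept, sse=sse, flags=flags)


# ---------------------------------------------------------------------------
# Microscopic-rate extraction
# ---------------------------------------------------------------------------

def extract_micro_rates(k2: float, K_S: float, sum_km2_k3: float, kcat: float,
                        se_k2: float = 0.0, se_K_S: float = 0.0,
                        se_sum: float = 0.0, se_kcat: float = 0.0,
                        sum_k5_km5: float | None = None,
                        se_sum_k5_km5: float | None = None) -> MicroRateEstimate:
    """Split the intercept sum (k_m2 + k3) using the steady-state kcat.

    For the linear reduced scheme kcat = k2*k3/(k2 + k_m2 + k3), so with
    s = k_m2 + k3 known, k3 = kcat*(k2 + s)/k2 and k_m2 = s - k3.  By
    construction, feeding the extracted rates back into the kcat expression
    reproduces the input kcat exactly.  Standard errors are first-order
    (delta-method) propagations assuming independent inputs.
    """
    if k2 <= 0 or kcat <= 0 or sum_km2_k3 <= 0:
        raise ValueError("k2, kcat and sum_km2_k3 must be > 0")
    s = sum_km2_k3
    k3 = kcat * (k2 + s) / k2
    k_m2 = s - k3

    dk3_dkcat = (k2 + s) / k2
    dk3_dsum = kcat / k2
    dk3_dk2 = -kcat * s / k2 ** 2
    var_k3 = (dk3_dkcat * se_kcat) ** 2 + (dk3_dsum * se_sum) ** 2 \
        + (dk3_dk2 * se_k2) ** 2
    var_km2 = ((1.0 - dk3_dsum) * se_sum) ** 2 + (dk3_dkcat * se_kcat) ** 2 \
        + (dk3_dk2 * se_k2) ** 2

    flags = []
    if k_m2 < 0:
        flags.append("negative_k_m2_implied")
    return MicroRateEstimate(
        k2=k2, K_S=K_S, sum_km2_k3=s, k_m2=k_m2, k3=k3,
        se_k2=se_k2, se_K_S=se_K_S, se_sum_km2_k3=se_sum,
        se_k_m2=math.sqrt(var_km2), se_k3=math.sqrt(var_k3),
        sum_k5_km5=sum_k5_km5, se_sum_k5_km5=se_sum_k5_km5, flags=flags,
    )


# ---------------------------------------------------------------------------
# Single-turnover hydrolysis rate
# ---------------------------------------------------------------------------

def single_turnover_k3(trace: Trace, K_S: float | None = None) -> SingleTurnoverK3:
    """Hydrolysis rate from the fluorescence-recovery phase.

    Under single-turnover conditions ([E], [S] >> K_S, [E] >= [S]) essentially
    all substrate is bound, the alkylation burst is complete early, and the
    recovery of the quench reports ES -> E + P, i.e. k_obs ~= k3.  The fit is a
    single exponential starting at the fluorescence minimum.
    """
    if trace.conditions is None or trace.conditions.mode != "single_turnover":
        raise ValueError("single_turnover_k3 requires a single-turnover trace")
    if K_S is not None:
        if min(trace.conditions.E_total, trace.conditions.S_total) < 2.0 * K_S:
            warnings.warn(
                "enzyme/substrate below 2 x K_S; saturation is incomplete and "
                "the recovered rate will underestimate k3", stacklevel=2)
    t, y = trace.observed()
    # locate the quench minimum on a lightly smoothed signal (edge-padded so
    # the window does not bias the ends)
    if y.size >= 11:
        kern = np.ones(5) / 5.0
        ys = np.convolve(np.pad(y, 2, mode="edge"), kern, mode="valid")
    else:
        ys = y
    i0 = int(np.argmin(ys))
    i0 = min(i0, y.size - 20)  # keep enough points to fit
    i0 = max(i0, 0)
    fit = _fit_exp_arrays(t[i0:], y[i0:], order=1)
    # near the trough the decaying alkylation phase still mixes in; discard one
    # lifetime of the first estimate and refit on the clean recovery
    if np.isfinite(fit.k_obs[0]) and fit.k_obs[0] > 0:
        t_start = t[i0] + 1.0 / fit.k_obs[0]
        j0 = int(np.searchsorted(t, t_start))
        if t.size - j0 >= 20:
            fit = _fit_exp_arrays(t[j0:], y[j0:], order=1)
    flags = list(fit.flags)
    quench_depth = float(np.max(y) - np.min(y))
    if "amplitude_near_zero" in flags or (
            quench_depth > 0 and abs(fit.amplitudes[0]) < 0.05 * quench_depth):
        flags.append("no_recovery_detected")
        fit.flags = sorted(set(flags))
    return SingleTurnoverK3(k3=fit.k_obs[0], se=fit.se_k_obs[0], fit=fit)


# ---------------------------------------------------------------------------
# Steady-state initial-rate regression
# ---------------------------------------------------------------------------

def fit_michaelis_menten(substrate_uM, rate_uM_per_s, e_total: float,
                         se=None) -> MichaelisMentenFit:
    """Nonlinear Michaelis-Menten regression of initial rates."""
    S = np.asarray(substrate_uM, dtype=float)
    v = np.asarray(rate_uM_per_s, dtype=float)
    if S.size < 4:
        raise ValueError("need at least 4 concentrations")
    if e_total <= 0:
        raise ValueError("e_total must be > 0")
    w = np.ones_like(v)
    if se is not None:
        se = np.asarray(se, dtype=float)
        if np.all(se > 0):
            w = 1.0 / se

    params = Parameters()
    params.add("kcat", value=max(float(v.max()) / e_total, 1e-9), min=0.0)
    params.add("Km", value=float(np.median(S)), min=1e-9)

    def resid(p):
        return (p["kcat"].value * e_total * S / (p["Km"].value + S) - v) * w

    out = minimize(resid, params, method="leastsq")
    p = out.params
    model = p["kcat"].value * e_total * S / (p["Km"].value + S)
    flags = []
    se_kcat = p["kcat"].stderr if p["kcat"].stderr is not None else np.inf
    se_Km = p["Km"].stderr if p["Km"].stderr is not None else np.inf
    if not np.isfinite(se_Km) or se_Km > p["Km"].value:
        flags.append("Km_ill_determined")
    if float(S.min()) > 5.0 * p["Km"].value:
        flags.append("no_sub_Km_data")
    return MichaelisMentenFit(kcat=p["kcat"].value, Km=p["Km"].value,
                              se_kcat=se_kcat, se_Km=se_Km,
                              sse=float(np.sum((model - v) ** 2)), flags=flags)
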