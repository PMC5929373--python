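"""Synthetic stopped-flow data and packaged kinetic fixtures.

No public dataset of StEH1 stopped-flow traces exists, so every input the
fitting pipeline consumes is generated here from known ground truth: noisy
averaged fluorescence-quench traces (the alkylenzymes quench the intrinsic
protein fluorescence), k_obs-versus-[S] series produced by running the actual
fitting pipeline on generated traces, and Michaelis-Menten initial-rate
tables.  The packaged YAML fixtures carry the published microscopic rate
constants for each enzyme variant / substrate enantiomer pair, and the
published simulated (EVB) barrier sets consumed by the flux predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .scheme_model import (
    DEFAULT_KON,
    DEFAULT_TEMPERATURE,
    RateSet,
    ReactionConditions,
    relaxation_rates,
    simulate,
)
from .transient_fitting import (
    KobsSeries,
    Trace,
    fit_trace_auto,
)
from .flux_prediction import BranchBarriers

__all__ = [
    "NoiseModel",
    "ReportedValue",
    "FixtureSet",
    "FixtureUnavailableError",
    "gen_trace",
    "gen_kobs_series",
    "KobsGenResult",
    "gen_initial_rates",
    "kinetic_fixture",
    "barrier_fixture",
    "available_fixtures",
]

#: Default fluorescence baseline and quench depth of the synthetic signal.
#: Neither is quantified experimentally; the quench coefficient multiplies the
#: alkylenzyme *occupancy* (fraction of total enzyme) so the signal stays in
#: [F0 - q, F0].  Chosen to resemble published example traces; arbitrary.
DEFAULT_F0 = 1.0
DEFAULT_Q_ALKYL = 0.3

#: Stopped-flow dead time (s): samples before it are discarded.
DEFAULT_DEAD_TIME = 0.002


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, per sample, averaged over replicate traces.

    With ``relative=True`` (the default) ``sigma`` is expressed as a fraction
    of the deterministic trace's peak-to-trough amplitude, so a given noise
    level means the same signal-to-noise ratio at every substrate
    concentration; with ``relative=False`` it is an absolute standard
    deviation in signal units.  The default (sigma=0.05) gives a single-trace
    SNR of 20 and about 50 after the standard six-trace average.
    """

    sigma: float = 0.05
    seed: int = 0
    n_replicates: int = 6
    relative: bool = True

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _turnover_rate(rates: RateSet, cond: ReactionConditions) -> float:
    """Rough steady-state turnover velocity (µM/s), summed over both branches."""
    v = 0.0
    for k2, k_m2, k3, K_S in ((rates.k2, rates.k_m2, rates.k3, rates.K_S),
                              (rates.k2_prime, rates.k_m2_prime,
                               rates.k3_prime, rates.K_S_prime)):
        if k2 > 0 and k3 > 0:
            denom = k2 + k_m2 + k3
            kcat = k2 * k3 / denom
            Km = K_S * (k_m2 + k3) / denom
            v += cond.E_total * kcat * cond.S_total / (Km + cond.S_total)
    return v


def _auto_grid(rates: RateSet, cond: ReactionConditions,
               dead_time: float, n_points: int) -> np.ndarray:
    """Log-spaced sampling over ten lifetimes of the slowest relaxation.

    The window is capped where ~10% of the substrate would be consumed: the
    relaxation analysis (and the exponential description of the transient)
    presumes an approximately constant [S], so sampling into substrate
    depletion would distort the observed rates rather than inform them.
    """
    mags = relaxation_rates(rates, cond.S_total)
    nz = mags[mags > 1e-9 * mags.max()] if mags.max() > 0 else np.array([])
    if nz.size == 0:
        raise ValueError("all relaxation rates are zero; no timescale to sample")
    horizon = 10.0 / nz.min()
    if cond.mode == "multiple_turnover":
        v = _turnover_rate(rates, cond)
        if v > 0:
            horizon = min(horizon, 0.1 * cond.S_total / v)
    else:
        # the fluorescence recovery is driven by substrate exhaustion, which a
        # clamped-[S] relaxation analysis cannot see; its rate is the slow
        # eigenvalue of the committed ES <-> EA -> E + P subsystem
        lams = []
        for k2, k_m2, k3 in ((rates.k2, rates.k_m2, rates.k3),
                             (rates.k2_prime, rates.k_m2_prime, rates.k3_prime)):
            if k2 > 0 and k3 > 0:
                tr_ = k2 + k_m2 + k3
                lams.append((tr_ - np.sqrt(tr_ * tr_ - 4.0 * k2 * k3)) / 2.0)
        if lams:
            horizon = 10.0 / min(lams)
    return np.geomspace(max(dead_time, 1e-5), horizon, n_points)


def gen_trace(rates: RateSet, cond: ReactionConditions, noise: NoiseModel,
              t_grid=None, f0: float = DEFAULT_F0,
              q_alkyl: float = DEFAULT_Q_ALKYL, q_complex: float = 0.0,
              dead_time_s: float = DEFAULT_DEAD_TIME,
              n_points: int = 1000) -> Trace:
    """Simulate a fluorescence-quench trace with averaged Gaussian noise.

    The deterministic signal is F(t) = F0 - q_alkyl*(EA + E'A)/E_tot
    - q_complex*(ES + E'S)/E_tot; by default only the alkylenzymes quench
    (whether the Michaelis complexes also quench is untested experimentally,
    hence switchable).  ``noise.n_replicates`` independent noise realizations
    are averaged, mirroring the >= 6-trace averaging of the experiments.
    Deterministic per seed.
    """
    if t_grid is None:
        t_grid = _auto_grid(rates, cond, dead_time_s, n_points)
    t = np.asarray(t_grid, dtype=float)
    traj = simulate(rates, cond, np.concatenate([[0.0], t]))
    alkyl = (traj["EA"] + traj["EpA"])[1:]
    complexes = (traj["ES"] + traj["EpS"])[1:]
    det = f0 - q_alkyl * alkyl / cond.E_total - q_complex * complexes / cond.E_total

    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma
    if noise.relative:
        sigma *= float(det.max() - det.min())
    if sigma > 0:
        draws = rng.normal(0.0, sigma, size=(noise.n_replicates, t.size))
        signal = det + draws.mean(axis=0)
    else:
        signal = det.copy()
    return Trace(time=t, signal=signal, conditions=cond,
                 n_averaged=noise.n_replicates, dead_time_s=dead_time_s)


@dataclass
class KobsGenResult:
    """k_obs series generated by fitting simulated traces, plus any failures."""

    fast: KobsSeries
    slow: KobsSeries | None
    failures: dict[float, str] = field(default_factory=dict)


def gen_kobs_series(rates: RateSet, concentrations, noise: NoiseModel,
                    e_total: float | None = None, alpha: float = 0.05,
                    solubility_limit_uM: float | None = None,
                    **trace_kwargs) -> KobsGenResult:
    """Generate traces across a concentration series and fit each one.

    Each concentration gets its own derived seed; traces are fitted with one
    and two exponentials, the F-test picks the order, and the fast/slow phase
    rates are collected into :class:`KobsSeries` objects with their regression
    standard errors.  Per-concentration fit failures are reported, not raised.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if solubility_limit_uM is not None and concentrations.max() > solubility_limit_uM:
        warnings.warn(
            f"concentrations above the solubility-motivated bound "
            f"({solubility_limit_uM} uM) requested", stacklevel=2)
    if e_total is None:
        # far below the minimal pseudo-first-order requirement of S/10: the
        # quench signal is occupancy-normalized, so a low enzyme load costs no
        # amplitude but keeps [S] effectively constant through the transient
        e_total = float(concentrations.min()) / 100.0

    fast_S, fast_k, fast_se = [], [], []
    slow_S, slow_k, slow_se = [], [], []
    failures: dict[float, str] = {}
    for i, S in enumerate(concentrations):
        sub = replace(noise, seed=int((noise.seed + 7919 * (i + 1)) % 2**31))
        cond = ReactionConditions(E_total=e_total, S_total=float(S))
        try:
            trace = gen_trace(rates, cond, sub, **trace_kwargs)
            fit, sel = fit_trace_auto(trace, alpha=alpha)
        except (ValueError, RuntimeError) as exc:
            failures[float(S)] = str(exc)
            continue
        fast_S.append(S); fast_k.append(fit.k_obs[0]); fast_se.append(fit.se_k_obs[0])
        if sel.order == 2:
            slow_S.append(S); slow_k.append(fit.k_obs[1]); slow_se.append(fit.se_k_obs[1])

    if not fast_S:
        raise RuntimeError(f"every concentration failed to fit: {failures}")
    fast = KobsSeries(substrate_uM=np.array(fast_S), kobs=np.array(fast_k),
                      se=np.array(fast_se), phase="fast")
    slow = None
    if len(slow_S) >= 2:
        slow = KobsSeries(substrate_uM=np.array(slow_S), kobs=np.array(slow_k),
                          se=np.array(slow_se), phase="slow")
    return KobsGenResult(fast=fast, slow=slow, failures=failures)


def gen_initial_rates(kcat: float, Km: float, e_total: float, concentrations,
                      noise: NoiseModel) -> pd.DataFrame:
    """Michaelis-Menten initial-rate table with multiplicative noise.

    v = kcat*E*S/(Km + S); here ``noise.sigma`` acts as a *relative* error per
    replicate measurement (initial rates are ratio quantities, so their error
    scales with the rate), averaged over ``noise.n_replicates``.
    """
    if kcat <= 0 or Km <= 0 or e_total <= 0:
        raise ValueError("kcat, Km and e_total must be > 0")
    S = np.asarray(concentrations, dtype=float)
    v_true = kcat * e_total * S / (Km + S)
    rng = np.random.default_rng(noise.seed)
    if noise.sigma > 0:
        draws = v_true * (1.0 + rng.normal(0.0, noise.sigma,
                                           size=(noise.n_replicates, S.size)))
        v = draws.mean(axis=0)
        se = noise.sigma * v_true / np.sqrt(noise.n_replicates)
    else:
        v = v_true.copy()
        se = np.zeros_like(v_true)
    return pd.DataFrame({"substrate_uM": S, "rate_uM_per_s": v,
                         "se_uM_per_s": se})


# ---------------------------------------------------------------------------
# Packaged fixtures: published rate constants and barrier sets
# ---------------------------------------------------------------------------

class FixtureUnavailableError(LookupError):
    """A requested kinetic parameter was not reported for that enzyme/substrate."""


@dataclass(frozen=True)
class ReportedValue:
    value: float
    se: float
    note: str | None = None


@dataclass(frozen=True)
class FixtureSet:
    """Published kinetic parameters for one enzyme variant / substrate pair.

    Only values actually reported are populated; anything the source marks as
    unmeasurable (dashes, 'not saturating', 'too fast', upper bounds) stays
    unset and raises :class:`FixtureUnavailableError` on access.
    """

    variant: str
    substrate: str
    values: dict[str, ReportedValue]
    qualifiers: dict[str, str]
    regioselectivity: str | None
    provenance: str

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def get(self, name: str) -> ReportedValue:
        if name in self.values:
            return self.values[name]
        qual = self.qualifiers.get(name, "not measured")
        raise FixtureUnavailableError(
            f"{name} is not reported for {self.variant} / {self.substrate} "
            f"({qual})"
        )

    def rate_set(self, kon: float = DEFAULT_KON, k5_split: float = 0.5) -> RateSet:
        """Build a simulatable :class:`RateSet` from the reported values.

        Requires k2, k_m2, k3 and K_S.  Only the *sum* of the
        Michaelis-complex interconversion rates is ever reported; it is split
        ``k5_split`` : 1-k5_split (default 50/50 — a documented convention,
        not a measurement).  The alternative branch's chemistry is left at
        zero because its microscopic rates are not individually measurable.
        """
        k2 = self.get("k2").value
        k_m2 = self.get("k_m2").value
        k3 = self.get("k3").value
        K_S = self.get("K_S").value
        k5 = k_m5 = 0.0
        if "sum_k5_km5" in self.values:
            total = self.values["sum_k5_km5"].value
            k5 = k5_split * total
            k_m5 = (1.0 - k5_split) * total
        return RateSet(k2=k2, k_m2=k_m2, k3=k3, K_S=K_S,
                       k5=k5, k_m5=k_m5, kon=kon)


_VARIANTS = ("wild_type", "R-C1", "R-C1B1", "R-C1B1D33", "R-C1B1D33E6")
_SUBSTRATES = ("RR-1a", "SS-1a", "RR-1b", "SS-1b")


def _data_file(subdir: str, variant: str, substrate: str):
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {_VARIANTS}")
    if substrate not in _SUBSTRATES:
        raise ValueError(f"unknown substrate {substrate!r}; choose from {_SUBSTRATES}")
    res = resources.files("ehkin").joinpath(f"data/{subdir}/{variant}__{substrate}.yaml")
    if not res.is_file():
        raise FixtureUnavailableError(
            f"no packaged {subdir} fixture for {variant} / {substrate}")
    return yaml.safe_load(res.read_text())


def kinetic_fixture(variant: str, substrate: str) -> FixtureSet:
    """Load the published rate constants for one variant/substrate pair.

    Raises :class:`FixtureUnavailableError` when nothing numeric was reported
    (e.g. only an upper bound on kcat/Km exists for the least active variant).
    """
    doc = _data_file("rate_tables", variant, substrate)
    values = {k: ReportedValue(value=float(v["value"]), se=float(v["se"]),
                               note=v.get("note"))
              for k, v in (doc.get("values") or {}).items()}
    if not values:
        quals = doc.get("qualifiers") or {}
        raise FixtureUnavailableError(
            f"no numeric kinetic parameters reported for {variant} / {substrate}"
            + (f" (only: {quals})" if quals else "")
        )
    return FixtureSet(variant=doc["variant"], substrate=doc["substrate"],
                      values=values, qualifiers=doc.get("qualifiers") or {},
                      regioselectivity=doc.get("regioselectivity"),
                      provenance=doc["provenance"])


def barrier_fixture(variant: str, substrate: str, mode: int = 1,
                    temperature: float = DEFAULT_TEMPERATURE) -> BranchBarriers:
    """Load a simulated (EVB) barrier set for one binding mode.

    These published barrier values are inputs to the flux predictor; nothing
    here recomputes them.  Branch labels are the attacked epoxide carbons
    (C1 benzylic, C2 homobenzylic).
    """
    doc = _data_file("barriers", variant, substrate)
    key = f"mode{mode}"
    if key not in doc["modes"]:
        raise FixtureUnavailableError(f"no {key} barriers for {variant}/{substrate}")
    m = doc["modes"][key]
    labels = tuple(sorted(m))
    return BranchBarriers(
        labels=labels,
        dG_alk=tuple(m[c]["dG_alk"] for c in labels),
        dG_hyd=tuple(m[c]["dG_hyd"] for c in labels),
        se_alk=tuple(m[c]["se_alk"] for c in labels),
        se_hyd=tuple(m[c]["se_hyd"] for c in labels),
        temperature=temperature,
    )


def available_fixtures(complete_only: bool = False) -> list[tuple[str, str]]:
    """List (variant, substrate) pairs with packaged kinetic fixtures.

    ``complete_only`` restricts to rows carrying the full microscopic rate set
    (k2, k_m2, k3, K_S) needed to build a simulatable :class:`RateSet`.
    """
    out = []
    for v in _VARIANTS:
        for s in _SUBSTRATES:
            try:
                fx = kinetic_fixture(v, s)
            except FixtureUnavailableError:
                continue
            if complete_only and not all(k in fx for k in ("k2", "k_m2", "k3", "K_S")):
                continue
            out.append((v, s))
    return out
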