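"""Branch flux, regioselectivity and enantiomeric excess.

Two routes turn the branched mechanism into a product ratio:

* a Boltzmann partition over the activation free energies of the committing
  step (for this enzyme the hydrolysis of the alkylenzyme, which is
  rate-determining), f_i = exp(-dG_i/RT) / sum_j exp(-dG_j/RT); and
* direct integration of the branched ODE scheme to substrate exhaustion,
  reading the product pools P1/P2.

When de-alkylation is fast relative to hydrolysis (the alkylenzymes
pre-equilibrate through the Michaelis complexes) the two routes agree; the
Boltzmann route is then the analytic limit of the committed flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme_model import (
    DEFAULT_KON,
    DEFAULT_TEMPERATURE,
    R_KCAL,
    RateSet,
    ReactionConditions,
    eyring_rate,
    simulate,
)

__all__ = [
    "BranchBarriers",
    "BranchPrediction",
    "branch_fractions_from_barriers",
    "committed_flux_from_rates",
    "enantiomeric_excess",
    "fraction_interval",
    "rates_from_barriers",
]


@dataclass(frozen=True)
class BranchBarriers:
    """Per-branch activation free energies (kcal/mol) at one temperature.

    ``dG_alk`` is the barrier for alkylenzyme formation from the Michaelis
    complex; ``dG_hyd`` the barrier for hydrolysis of that alkylenzyme,
    relative to the alkylenzyme itself.
    """

    labels: tuple[str, ...]
    dG_alk: tuple[float, ...]
    dG_hyd: tuple[float, ...]
    temperature: float = DEFAULT_TEMPERATURE
    se_alk: tuple[float, ...] | None = None
    se_hyd: tuple[float, ...] | None = None

    def __post_init__(self):
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("branch labels must be unique")
        if len(self.dG_alk) != n or len(self.dG_hyd) != n:
            raise ValueError("barrier tuples must match the number of labels")
        if any(g <= 0 for g in self.dG_alk) or any(g <= 0 for g in self.dG_hyd):
            raise ValueError("barriers must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class BranchPrediction:
    """Flux fractions per product pool and the derived selectivity numbers."""

    labels: tuple[str, ...]
    fractions: tuple[float, ...]
    regioselectivity: float      # % of flux through the C1 branch
    ee: float | None             # % enantiomeric excess (two-pool systems)
    dominant: str

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 or f > 1 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")


def _prediction(labels, fractions, c1_label="C1") -> BranchPrediction:
    fractions = tuple(float(f) for f in fractions)
    if c1_label in labels:
        regio = 100.0 * fractions[labels.index(c1_label)]
    else:
        regio = 100.0 * fractions[0]
    ee = None
    if len(fractions) == 2:
        f1, f2 = fractions
        ee = abs(f1 - f2) / (f1 + f2) * 100.0 if (f1 + f2) > 0 else 0.0
    dominant = labels[int(np.argmax(fractions))]
    return BranchPrediction(labels=tuple(labels), fractions=fractions,
                            regioselectivity=regio, ee=ee, dominant=dominant)


def branch_fractions_from_barriers(b: BranchBarriers,
                                   committed: str = "hydrolysis",
                                   c1_label: str = "C1") -> BranchPrediction:
    """Boltzmann partition over the barriers of the committing step.

    With ``committed="hydrolysis"`` (the default: hydrolysis is the
    rate-determining step for this enzyme) the partition uses the hydrolysis
    barriers; ``committed="alkylation"`` instead partitions at the epoxide
    ring-opening step, appropriate when the alkylenzymes are hydrolyzed
    without returning to the Michaelis complexes.
    """
    if len(b.labels) < 2:
        raise ValueError("need at least two branches")
    if committed == "hydrolysis":
        dG = np.array(b.dG_hyd)
    elif committed == "alkylation":
        dG = np.array(b.dG_alk)
    else:
        raise ValueError("committed must be 'hydrolysis' or 'alkylation'")
    RT = R_KCAL * b.temperature
    w = np.exp(-(dG - dG.min()) / RT)
    return _prediction(b.labels, w / w.sum(), c1_label)


def fraction_interval(b: BranchBarriers, committed: str = "hydrolysis",
                      n_draws: int = 10_000, seed: int = 0,
                      ci: float = 0.95) -> dict[str, tuple[float, float]]:
    """Per-branch flux-fraction intervals from the barrier standard errors.

    Barriers are resampled as independent Gaussians (the barrier tables report
    SEMs but no selectivity interval); returns the central ``ci`` interval of
    each branch's fraction.
    """
    se = b.se_hyd if committed == "hydrolysis" else b.se_alk
    if se is None:
        raise ValueError("barrier standard errors are required for an interval")
    dG0 = np.array(b.dG_hyd if committed == "hydrolysis" else b.dG_alk)
    rng = np.random.default_rng(seed)
    draws = rng.normal(dG0, np.array(se), size=(n_draws, len(dG0)))
    RT = R_KCAL * b.temperature
    w = np.exp(-(draws - draws.min(axis=1, keepdims=True)) / RT)
    frac = w / w.sum(axis=1, keepdims=True)
    lo, hi = (1.0 - ci) / 2.0 * 100.0, (1.0 + ci) / 2.0 * 100.0
    return {lab: tuple(np.percentile(frac[:, i], [lo, hi]))
            for i, lab in enumerate(b.labels)}


def rates_from_barriers(b: BranchBarriers, K_S: float,
                        k5: float = 0.0, k_m5: float = 0.0,
                        dG_alkylenzyme: float = -2.0,
                        kon: float = DEFAULT_KON) -> RateSet:
    """Realize a two-branch barrier set as microscopic rate constants.

    ``dG_alkylenzyme`` is the assumed stability of each alkylenzyme relative
    to its Michaelis complex; it fixes the de-alkylation rates via
    k_m2 = k(dG_alk - dG_alkylenzyme).  The default, a shallow -2 kcal/mol on
    both branches, keeps de-alkylation fast relative to hydrolysis so that the
    branch point is committed at the hydrolysis step.  (The simulated reaction
    free energies for ring opening are known to be unphysically exothermic and
    are deliberately not used here.)
    """
    if len(b.labels) != 2:
        raise ValueError("a RateSet realizes exactly two branches")
    T = b.temperature
    k2 = eyring_rate(b.dG_alk[0], T)
    k2p = eyring_rate(b.dG_alk[1], T)
    k_m2 = eyring_rate(b.dG_alk[0] - dG_alkylenzyme, T)
    k_m2p = eyring_rate(b.dG_alk[1] - dG_alkylenzyme, T)
    k3 = eyring_rate(b.dG_hyd[0], T)
    k3p = eyring_rate(b.dG_hyd[1], T)
    return RateSet(k2=k2, k_m2=k_m2, k3=k3, K_S=K_S,
                   k2_prime=k2p, k_m2_prime=k_m2p, k3_prime=k3p,
                   k5=k5, k_m5=k_m5, kon=kon)


def committed_flux_from_rates(rates: RateSet, cond: ReactionConditions,
                              labels: tuple[str, str] = ("C1", "C2"),
                              conversion: float = 0.999,
                              c1_label: str = "C1",
                              max_time: float = 1e7) -> BranchPrediction:
    """Branch fractions from ODE integration to substrate exhaustion.

    Integrates the full scheme until at least ``conversion`` of the substrate
    has been turned over and reports final P1/(P1+P2), P2/(P1+P2).
    """
    if cond.mode != "multiple_turnover":
        raise ValueError("committed flux is defined for multiple-turnover runs")
    # first guess of the exhaustion timescale from the slower hydrolysis rate
    k_drain = max(rates.k3, rates.k3_prime)
    if k_drain <= 0:
        raise ValueError("at least one hydrolysis rate must be > 0")
    t_end = 10.0 * cond.S_total / (cond.E_total * k_drain)
    achieved = 0.0
    while t_end <= max_time:
        grid = np.concatenate([[0.0], np.geomspace(t_end * 1e-6, t_end, 300)])
        traj = simulate(rates, cond, grid)
        p1 = float(traj["P1"][-1])
        p2 = float(traj["P2"][-1])
        achieved = (p1 + p2) / cond.S_total
        if achieved >= conversion:
            total = p1 + p2
            return _prediction(labels, (p1 / total, p2 / total), c1_label)
        t_end *= 10.0
    raise RuntimeError(
        f"substrate conversion reached only {achieved:.4%} within the time "
        f"horizon ({max_time:g} s); no committed flux can be reported"
    )


def enantiomeric_excess(p: BranchPrediction) -> float:
    """Enantiomeric excess (%) of a two-product prediction."""
    if len(p.fractions) != 2:
        raise ValueError("enantiomeric excess requires exactly two product pools")
    f1, f2 = p.fractions
    return abs(f1 - f2) / (f1 + f2) * 100.0
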