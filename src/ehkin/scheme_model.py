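"""Branched kinetic scheme for epoxide hydrolase catalysis.

The potato epoxide hydrolase StEH1 opens *trans*-substituted epoxides through a
covalent alkylenzyme intermediate.  Because nucleophilic attack can occur at
either oxirane carbon, the mechanism branches: two enzyme conformers (E, E')
bind substrate into two Michaelis complexes (ES, E'S) which alkylate into two
non-interconvertible alkylenzymes whose hydrolyses release the two product
diol enantiomers (P1, P2).  This module encodes that scheme as

* a typed parameter container (:class:`RateSet`),
* a mass-action ODE system (:func:`simulate`),
* analytic steady-state expressions for the reduced linear scheme
  (:func:`steady_state_params`),
* relaxation (eigenvalue) analysis of the linearized enzyme subsystem under
  pseudo-first-order conditions (:func:`relaxation_rates`), and
* transition-state-theory conversion between rate constants and activation
  free energies (:func:`eyring_barrier` / :func:`eyring_rate`).

Units are fixed package-wide: seconds, s^-1, µM, kcal mol^-1 and kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KB",
    "H",
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_KON",
    "SPECIES",
    "RateSet",
    "ReactionConditions",
    "Trajectory",
    "SteadyStateParams",
    "FreeEnergyProfile",
    "simulate",
    "steady_state_params",
    "eyring_barrier",
    "eyring_rate",
    "relaxation_rates",
]

# Physical constants (SI for kB, h; gas constant in kcal/(mol K)).
KB = 1.380649e-23
H = 6.62607015e-34
R_KCAL = 1.98720425e-3

#: Assay temperature: pH 6.8 and 30 degC.
DEFAULT_TEMPERATURE = 303.15

#: Default association rate, near the diffusion limit (µM^-1 s^-1).  Binding is
#: realized explicitly so the rapid-equilibrium treatment of K_S is emergent,
#: not hard-coded.
DEFAULT_KON = 1000.0

#: Species order used throughout: free substrate, the six enzyme species and
#: the two product diol pools.
SPECIES = ("S", "E", "Ep", "ES", "EpS", "EA", "EpA", "P1", "P2")

_ENZYME_SPECIES = ("E", "Ep", "ES", "EpS", "EA", "EpA")


@dataclass(frozen=True)
class RateSet:
    """Microscopic rate constants of the branched scheme.

    Parameters follow the scheme's numbering: ``k2``/``k_m2`` alkylation and
    de-alkylation on the primary branch (unprimed conformer), ``k2_prime`` /
    ``k_m2_prime`` on the alternative branch, ``k3``/``k3_prime`` hydrolysis of
    each alkylenzyme (lumped through product release), ``k5``/``k_m5`` the
    ES <-> E'S interconversion, ``k0``/``k_m0`` the free-enzyme E <-> E'
    conformational step.  ``K_S`` and ``K_S_prime`` are substrate dissociation
    constants (µM); binding is realized with ``kon`` and koff = kon * K_S.
    """

    k2: float = 0.0
    k_m2: float = 0.0
    k3: float = 0.0
    K_S: float = 1.0
    k2_prime: float = 0.0
    k_m2_prime: float = 0.0
    k3_prime: float = 0.0
    K_S_prime: float | None = None
    k5: float = 0.0
    k_m5: float = 0.0
    k0: float = 0.0
    k_m0: float = 0.0
    kon: float = DEFAULT_KON

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None and f.name == "K_S_prime":
                # default: binding to E' indistinguishable from binding to E
                object.__setattr__(self, "K_S_prime", self.K_S)
                continue
            if not math.isfinite(v):
                raise ValueError(f"rate constant {f.name!r} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"rate constant {f.name!r} must be >= 0, got {v}")
        if self.K_S <= 0 or self.K_S_prime <= 0:
            raise ValueError("dissociation constants K_S and K_S_prime must be > 0")
        if self.kon <= 0:
            raise ValueError("association rate kon must be > 0")

    @property
    def koff(self) -> float:
        """Dissociation rate of ES (s^-1), kon * K_S."""
        return self.kon * self.K_S

    @property
    def koff_prime(self) -> float:
        """Dissociation rate of E'S (s^-1), kon * K_S_prime."""
        return self.kon * self.K_S_prime

    def reduced_linear(self) -> "RateSet":
        """Drop the alternative branch and conformer steps (three-step scheme)."""
        return replace(self, k2_prime=0.0, k_m2_prime=0.0, k3_prime=0.0,
                       k5=0.0, k_m5=0.0, k0=0.0, k_m0=0.0)


@dataclass(frozen=True)
class ReactionConditions:
    """Mixing conditions of a (virtual) stopped-flow experiment."""

    E_total: float
    S_total: float
    temperature: float = DEFAULT_TEMPERATURE
    mode: str = "multiple_turnover"

    def __post_init__(self):
        if self.mode not in ("multiple_turnover", "single_turnover"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.E_total > 0 and self.S_total > 0):
            raise ValueError("E_total and S_total must be > 0")
        if not (273.0 <= self.temperature <= 373.0):
            raise ValueError(f"temperature {self.temperature} K outside 273-373 K")
        if self.mode == "multiple_turnover" and self.E_total > self.S_total / 10.0:
            raise ValueError(
                "multiple-turnover conditions require E_total <= S_total/10 "
                f"(pseudo-first-order criterion); got E={self.E_total}, S={self.S_total}"
            )


@dataclass
class Trajectory:
    """Time courses of all species plus mass-balance diagnostics."""

    time: np.ndarray
    concentrations: dict[str, np.ndarray]
    enzyme_residual: float
    substrate_residual: float
    rates: RateSet = field(repr=False, default=None)
    conditions: ReactionConditions = field(repr=False, default=None)

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[species]

    @property
    def enzyme_total(self) -> np.ndarray:
        return sum(self.concentrations[s] for s in _ENZYME_SPECIES)

    @property
    def substrate_total(self) -> np.ndarray:
        c = self.concentrations
        return c["S"] + c["ES"] + c["EpS"] + c["EA"] + c["EpA"] + c["P1"] + c["P2"]


@dataclass(frozen=True)
class SteadyStateParams:
    """Steady-state Michaelis-Menten parameters of the reduced linear scheme."""

    kcat: float
    Km: float

    @property
    def kcat_over_Km(self) -> float:
        """Specificity constant in s^-1 mM^-1 (Km is carried in µM)."""
        return self.kcat / self.Km * 1000.0


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Free energies along one branch: RS, TS1, IS_alk, TS2, IS_TD (RS == 0)."""

    labels: tuple[str, ...]
    energies: tuple[float, ...]
    temperature: float = DEFAULT_TEMPERATURE
    standard_errors: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.labels) != len(self.energies):
            raise ValueError("labels and energies must have equal length")
        if self.energies[0] != 0.0:
            raise ValueError("the reference state (first energy) must be 0")
        # every TS must sit above both flanking minima
        e = self.energies
        for i in range(1, len(e) - 1, 2):
            if not (e[i] > e[i - 1] and e[i] > e[i + 1]):
                raise ValueError(
                    f"transition state {self.labels[i]!r} ({e[i]}) does not exceed "
                    "both flanking minima"
                )

    @classmethod
    def from_step_energies(cls, dG1_act: float, dG1_rxn: float,
                           dG2_act: float, dG2_rxn: float,
                           temperature: float = DEFAULT_TEMPERATURE,
                           standard_errors: tuple[float, ...] | None = None,
                           ) -> "FreeEnergyProfile":
        """Build the profile from per-step activation/reaction energies.

        The second step's energies are given relative to the alkylenzyme
        intermediate, as the barrier tables report them.
        """
        return cls(
            labels=("RS", "TS1", "IS_alk", "TS2", "IS_TD"),
            energies=(0.0, dG1_act, dG1_rxn, dG1_rxn + dG2_act, dG1_rxn + dG2_rxn),
            temperature=temperature,
            standard_errors=standard_errors,
        )


# ---------------------------------------------------------------------------
# ODE realization of the scheme
# ---------------------------------------------------------------------------

def _rhs_factory(r: RateSet):
    kon, koff, koffp = r.kon, r.koff, r.koff_prime
    k0, k_m0 = r.k0, r.k_m0
    k2, k_m2, k3 = r.k2, r.k_m2, r.k3
    k2p, k_m2p, k3p = r.k2_prime, r.k_m2_prime, r.k3_prime
    k5, k_m5 = r.k5, r.k_m5

    def rhs(t, y):
        s, e, ep, es, eps, ea, epa, p1, p2 = y
        bind = kon * s * e
        bindp = kon * s * ep
        return (
            -bind - bindp + koff * es + koffp * eps,
            -bind + koff * es - k0 * e + k_m0 * ep + k3 * ea,
            -bindp + koffp * eps + k0 * e - k_m0 * ep + k3p * epa,
            bind - (koff + k5 + k2) * es + k_m5 * eps + k_m2 * ea,
            bindp + k5 * es - (koffp + k_m5 + k2p) * eps + k_m2p * epa,
            k2 * es - (k_m2 + k3) * ea,
            k2p * eps - (k_m2p + k3p) * epa,
            k3 * ea,
            k3p * epa,
        )

    def jac(t, y):
        s, e, ep = y[0], y[1], y[2]
        J = np.zeros((9, 9))
        # dS/dt
        J[0, 0] = -kon * (e + ep)
        J[0, 1] = -kon * s
        J[0, 2] = -kon * s
        J[0, 3] = koff
        J[0, 4] = koffp
        # dE/dt
        J[1, 0] = -kon * e
        J[1, 1] = -kon * s - k0
        J[1, 2] = k_m0
        J[1, 3] = koff
        J[1, 5] = k3
        # dE'/dt
        J[2, 0] = -kon * ep
        J[2, 1] = k0
        J[2, 2] = -kon * s - k_m0
        J[2, 4] = koffp
        J[2, 6] = k3p
        # dES/dt
        J[3, 0] = kon * e
        J[3, 1] = kon * s
        J[3, 3] = -(koff + k5 + k2)
        J[3, 4] = k_m5
        J[3, 5] = k_m2
        # dE'S/dt
        J[4, 0] = kon * ep
        J[4, 2] = kon * s
        J[4, 3] = k5
        J[4, 4] = -(koffp + k_m5 + k2p)
        J[4, 6] = k_m2p
        # dEA/dt
        J[5, 3] = k2
        J[5, 5] = -(k_m2 + k3)
        # dE'A/dt
        J[6, 4] = k2p
        J[6, 6] = -(k_m2p + k3p)
        # products
        J[7, 5] = k3
        J[8, 6] = k3p
        return J

    return rhs, jac


def simulate(rates: RateSet, cond: ReactionConditions, t_grid,
             preequilibrate_conformers: bool = False,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate the branched scheme's mass-action ODEs on ``t_grid``.

    The initial state has all substrate free and all enzyme as E, unless
    ``preequilibrate_conformers`` is set, in which case the free enzyme is
    distributed over E/E' according to the k0/k_m0 equilibrium.

    Raises on non-finite parameters and on integrator failure; never returns
    silent NaNs.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t_grid must be a 1-D array with at least two points")
    if t[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    y0 = np.zeros(9)
    y0[0] = cond.S_total
    if preequilibrate_conformers and (rates.k0 + rates.k_m0) > 0:
        f_ep = rates.k0 / (rates.k0 + rates.k_m0)
        y0[1] = cond.E_total * (1.0 - f_ep)
        y0[2] = cond.E_total * f_ep
    else:
        y0[1] = cond.E_total

    rhs, jac = _rhs_factory(rates)
    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method=method,
                    jac=jac, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"stiff integration failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        raise RuntimeError("integrator produced non-finite concentrations")

    conc = {name: y[i] for i, name in enumerate(SPECIES)}
    e_tot = sum(conc[s] for s in _ENZYME_SPECIES)
    s_tot = (conc["S"] + conc["ES"] + conc["EpS"] + conc["EA"] + conc["EpA"]
             + conc["P1"] + conc["P2"])
    enz_res = float(np.max(np.abs(e_tot - cond.E_total)) / cond.E_total)
    sub_res = float(np.max(np.abs(s_tot - cond.S_total)) / cond.S_total)
    return Trajectory(time=t, concentrations=conc, enzyme_residual=enz_res,
                      substrate_residual=sub_res, rates=rates, conditions=cond)


# ---------------------------------------------------------------------------
# Analytic steady state of the reduced linear scheme
# ---------------------------------------------------------------------------

def steady_state_params(k2: float, k_m2: float, k3: float, K_S: float
                        ) -> SteadyStateParams:
    """kcat and Km of the linear E + S <-> ES -> EA -> E + P scheme.

    kcat = k2*k3/(k2 + k_m2 + k3) and Km = K_S*(k_m2 + k3)/(k2 + k_m2 + k3),
    assuming rapid substrate-binding equilibrium (K_S).
    """
    if k2 <= 0 or k3 <= 0:
        raise ValueError("k2 and k3 must be > 0")
    if K_S <= 0:
        raise ValueError("K_S must be > 0")
    if k_m2 < 0:
        raise ValueError("k_m2 must be >= 0")
    denom = k2 + k_m2 + k3
    return SteadyStateParams(kcat=k2 * k3 / denom, Km=K_S * (k_m2 + k3) / denom)


# ---------------------------------------------------------------------------
# Transition-state theory
# ---------------------------------------------------------------------------

def eyring_barrier(k: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Activation free energy (kcal/mol) of a rate constant.

    dG = R*T*ln(kB*T/(h*k)), transmission coefficient 1.
    """
    if k <= 0:
        raise ValueError("rate constant must be > 0")
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return R_KCAL * T * math.log(KB * T / (H * k))


def eyring_rate(dG: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Rate constant (s^-1) of an activation free energy; inverse of
    :func:`eyring_barrier`."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return KB * T / H * math.exp(-dG / (R_KCAL * T))


# ---------------------------------------------------------------------------
# Relaxation analysis
# ---------------------------------------------------------------------------

def relaxation_matrix(rates: RateSet, S: float) -> np.ndarray:
    """Rate matrix of the six enzyme species at clamped [S] (pseudo-first-order).

    State order: E, E', ES, E'S, EA, E'A.  Columns sum to zero (total enzyme
    is conserved), so one eigenvalue is exactly zero.
    """
    if S < 0:
        raise ValueError("substrate concentration must be >= 0")
    r = rates
    konS = r.kon * S
    return np.array([
        [-(konS + r.k0), r.k_m0, r.koff, 0.0, r.k3, 0.0],
        [r.k0, -(konS + r.k_m0), 0.0, r.koff_prime, 0.0, r.k3_prime],
        [konS, 0.0, -(r.koff + r.k5 + r.k2), r.k_m5, r.k_m2, 0.0],
        [0.0, konS, r.k5, -(r.koff_prime + r.k_m5 + r.k2_prime), 0.0, r.k_m2_prime],
        [0.0, 0.0, r.k2, 0.0, -(r.k_m2 + r.k3), 0.0],
        [0.0, 0.0, 0.0, r.k2_prime, 0.0, -(r.k_m2_prime + r.k3_prime)],
    ])


def relaxation_rates(rates: RateSet, S: float) -> np.ndarray:
    """Magnitudes of the relaxation eigenvalues at fixed [S], sorted descending.

    These are the observable rate constants of the pre-steady-state transient
    under pseudo-first-order conditions; the fitted k_obs of a stopped-flow
    trace should match a subset of them.
    """
    eig = np.linalg.eigvals(relaxation_matrix(rates, S))
    mags = np.sort(np.abs(eig.real))[::-1]
    return mags
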