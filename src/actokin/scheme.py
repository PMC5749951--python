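"""Reaction network and ODE integration for the actomyosin ATPase cycle.

The cycle is modelled with eight myosin-containing species — the
actin-detached branch {M, M·ATP, M·ADP·Pi, M·ADP} and the actin-attached
branch {AM, AM·ATP, AM·ADP·Pi, AM·ADP} — plus four free ligand pools
{ATP, ADP, Pi, A} where A counts free F-actin binding sites.  Plain rate
constants govern the detached branch, bold ("acto") constants the attached
one.

Representation choices (all configurable through :class:`SchemeDefaults`):

* ATP binding to myosin is a single effective second-order step with rate
  ``K1k2·[ATP]``; the collision equilibrium is not resolved in the detached
  branch.
* ATP binding to actomyosin is a rapid-equilibrium collision (dissociation
  constant ``1/K1``) followed by the isomerization ``k+2`` that dissociates
  the complex, so the observed dissociation rate saturates hyperbolically:
  ``k_obs = k+2·[ATP]/(1/K1 + [ATP])``.
* ATP hydrolysis on myosin is a reversible first-order step whose forward
  and reverse rates sum to the measured equilibration rate ``k3 + k-3``;
  the equilibrium constant (default 10, favouring M·ADP·Pi) sets the split.
* Actin activation of phosphate release is a weak rapid-equilibrium binding
  of M·ADP·Pi to actin (dissociation constant ``Kapp``) followed by product
  release at ``kcat``, which reproduces the Michaelis–Menten envelope
  ``v = kcat·[A]/(Kapp + [A])`` for the release flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .rates import LigandConditions, RateConstantSet, SchemeDefaults

__all__ = [
    "SPECIES",
    "MYOSIN_SPECIES",
    "ACTIN_SPECIES",
    "LIGANDS",
    "Reaction",
    "ReactionNetwork",
    "OccupancyTrajectory",
    "IntegrationError",
    "build_network",
    "simulate_cycle",
]

MYOSIN_SPECIES = ("M", "M.ATP", "M.ADP.Pi", "M.ADP",
                  "AM", "AM.ATP", "AM.ADP.Pi", "AM.ADP")
#: actin-attached myosin species (free actin sites tracked in pool "A")
ACTIN_SPECIES = ("AM", "AM.ATP", "AM.ADP.Pi", "AM.ADP")
LIGANDS = ("ATP", "ADP", "Pi", "A")
SPECIES = MYOSIN_SPECIES + LIGANDS


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator cannot meet its tolerances."""


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction."""

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"reaction {self.name}: rate {self.k} < 0")
        for s in self.reactants + self.products:
            if s not in SPECIES:
                raise ValueError(f"reaction {self.name}: unknown species {s!r}")


@dataclass
class ReactionNetwork:
    """Mass-action network over the fixed actomyosin species roster."""

    reactions: list[Reaction]
    label: str = ""
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n_r = len(self.reactions)
        n_s = len(SPECIES)
        idx = {s: i for i, s in enumerate(SPECIES)}
        self._stoich = np.zeros((n_s, n_r))
        self._orders = np.zeros((n_s, n_r))
        self._k = np.array([r.k for r in self.reactions], dtype=float)
        for j, r in enumerate(self.reactions):
            for s in r.reactants:
                self._stoich[idx[s], j] -= 1
                self._orders[idx[s], j] += 1
            for s in r.products:
                self._stoich[idx[s], j] += 1

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction fluxes (µM/s) at state vector ``y``."""
        yc = np.clip(y, 0.0, None)
        # product over reactant concentrations raised to their order
        # (order 0 contributes a factor of 1)
        conc = np.prod(yc[:, None] ** self._orders, axis=0)
        return self._k * conc

    def rhs(self, y: np.ndarray, clamp: np.ndarray | None = None) -> np.ndarray:
        dy = self._stoich @ self.fluxes(y)
        if clamp is not None:
            dy[clamp] = 0.0
        return dy

    def flux_audit(self, y: np.ndarray) -> pd.Series:
        """Named per-reaction fluxes at a state, for inspection."""
        return pd.Series(self.fluxes(y),
                         index=[r.name for r in self.reactions])


def _split_hydrolysis(ksum: float, keq: float) -> tuple[float, float]:
    kf = ksum * keq / (1.0 + keq)
    return kf, ksum - kf


def build_network(
    rates: RateConstantSet,
    defaults: SchemeDefaults | None = None,
    signal_precedence: dict[str, str] | None = None,
) -> ReactionNetwork:
    """Assemble the mass-action cycle from one construct's constants.

    Constants that are not available (``None``) delete the corresponding
    edges (zero flux); their names are recorded on the returned network.
    """
    defaults = defaults or SchemeDefaults(
        hydrolysis_equilibrium=rates.hydrolysis_equilibrium,
        k_pi_basal=rates.k_pi_basal,
    )
    prec = signal_precedence or {
        "k1k2_myosin": "mant",
        "kD_off": "intercept",
        "kAD_off": "chase_mant",
        "k1k2_acto": "pyrene",
    }
    r = rates.resolved(
        {k: v for k, v in prec.items()
         if isinstance(getattr(rates, k, None), dict)}
    )

    missing: list[str] = []

    def get(name: str) -> float:
        v = getattr(r, name)
        if v is None:
            missing.append(name)
            return 0.0
        return float(v)

    rx: list[Reaction] = []

    # --- actin-detached branch -------------------------------------------
    rx.append(Reaction("atp_binding_myosin", ("M", "ATP"), ("M.ATP",),
                       get("k1k2_myosin")))
    kf, kr = _split_hydrolysis(get("k3_plus_kminus3"),
                               defaults.hydrolysis_equilibrium)
    rx.append(Reaction("hydrolysis_fwd", ("M.ATP",), ("M.ADP.Pi",), kf))
    rx.append(Reaction("hydrolysis_rev", ("M.ADP.Pi",), ("M.ATP",), kr))
    rx.append(Reaction("pi_release_basal", ("M.ADP.Pi",), ("M.ADP", "Pi"),
                       get("k_pi_basal")))
    rx.append(Reaction("adp_release_myosin", ("M.ADP",), ("M", "ADP"),
                       get("kD_off")))
    rx.append(Reaction("adp_binding_myosin", ("M", "ADP"), ("M.ADP",),
                       get("kD_on")))

    # --- ATP-induced dissociation of actomyosin --------------------------
    k_coll = defaults.collision_on_acto_atp
    inv_k1 = get("inv_K1_acto")
    rx.append(Reaction("atp_collision_acto", ("AM", "ATP"), ("AM.ATP",),
                       k_coll if inv_k1 > 0 else 0.0))
    rx.append(Reaction("atp_collision_acto_rev", ("AM.ATP",), ("AM", "ATP"),
                       k_coll * inv_k1))
    rx.append(Reaction("acto_dissociation", ("AM.ATP",), ("A", "M.ATP"),
                       get("k2_acto")))

    # --- actin-activated product release ---------------------------------
    k_weak = defaults.collision_on_actin_weak
    kapp = get("Kapp")
    rx.append(Reaction("weak_actin_binding", ("M.ADP.Pi", "A"), ("AM.ADP.Pi",),
                       k_weak if kapp > 0 else 0.0))
    rx.append(Reaction("weak_actin_release", ("AM.ADP.Pi",), ("M.ADP.Pi", "A"),
                       k_weak * kapp))
    rx.append(Reaction("pi_release_acto", ("AM.ADP.Pi",), ("AM.ADP", "Pi"),
                       get("k_pi_actin_max")))

    # --- ADP exchange on actomyosin --------------------------------------
    rx.append(Reaction("adp_release_acto", ("AM.ADP",), ("AM", "ADP"),
                       get("kAD_off")))
    rx.append(Reaction("adp_binding_acto", ("AM", "ADP"), ("AM.ADP",),
                       get("kAD_on")))

    # --- actin attachment / detachment -----------------------------------
    rx.append(Reaction("actin_binding_rigor", ("M", "A"), ("AM",),
                       get("kA_on")))
    rx.append(Reaction("actin_release_rigor", ("AM",), ("M", "A"),
                       get("kA_off")))
    rx.append(Reaction("actin_binding_adp", ("M.ADP", "A"), ("AM.ADP",),
                       get("kDA_on")))
    rx.append(Reaction("actin_release_adp", ("AM.ADP",), ("M.ADP", "A"),
                       get("kDA_off")))

    return ReactionNetwork(rx, label=rates.construct_label,
                           missing=tuple(dict.fromkeys(missing)))


@dataclass
class OccupancyTrajectory:
    """Species occupancies (µM) on a time grid."""

    times: np.ndarray
    occupancies: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...] = SPECIES
    conditions: LigandConditions | None = None
    label: str = ""

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            j = self.species.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}; "
                           f"have {list(self.species)}") from None
        return self.occupancies[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancies, index=pd.Index(self.times, name="time_s"),
                            columns=list(self.species))

    def myosin_total(self) -> np.ndarray:
        cols = [self.species.index(s) for s in MYOSIN_SPECIES]
        return self.occupancies[:, cols].sum(axis=1)

    def actin_total(self) -> np.ndarray:
        cols = [self.species.index(s) for s in ACTIN_SPECIES + ("A",)]
        return self.occupancies[:, cols].sum(axis=1)


def initial_state(conditions: LigandConditions) -> np.ndarray:
    """Initial concentration vector implied by the mixing conditions."""
    y0 = np.zeros(len(SPECIES))
    idx = {s: i for i, s in enumerate(SPECIES)}
    m, a = conditions.myosin, conditions.actin
    if conditions.start_bound:
        bound = min(m, a)
        if conditions.start_with_adp:
            y0[idx["AM.ADP"]] = bound
        else:
            y0[idx["AM"]] = bound
        rest = m - bound
        if conditions.start_with_adp:
            y0[idx["M.ADP"]] = rest
        else:
            y0[idx["M"]] = rest
        y0[idx["A"]] = a - bound
    else:
        if conditions.start_with_adp:
            y0[idx["M.ADP"]] = m
        else:
            y0[idx["M"]] = m
        y0[idx["A"]] = a
    y0[idx["ATP"]] = conditions.atp
    y0[idx["ADP"]] += conditions.adp
    y0[idx["Pi"]] = conditions.pi
    return y0


def simulate_cycle(
    network: ReactionNetwork,
    conditions: LigandConditions,
    time_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OccupancyTrajectory:
    """Integrate the network ODEs over ``time_grid`` (seconds).

    With ``conditions.clamp_ligands`` the free ligand pools (ATP, ADP, Pi
    and free actin sites) are held at their initial values, giving the
    pseudo-first-order regime of a stopped-flow experiment with ligand
    excess.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("time grid must be 1-D with at least 2 points")
    if t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must start at 0 and be strictly increasing")
    if conditions.myosin <= 0:
        raise ValueError("conditions must contain a nonzero myosin pool")

    y0 = initial_state(conditions)
    clamp = None
    if conditions.clamp_ligands:
        which = (LIGANDS if conditions.clamp_ligands is True
                 else conditions.clamp_ligands)
        clamp = np.zeros(len(SPECIES), dtype=bool)
        for lig in which:
            if lig not in LIGANDS:
                raise ValueError(f"cannot clamp unknown ligand pool {lig!r}")
            clamp[SPECIES.index(lig)] = True

    sol = solve_ivp(
        lambda _t, y: network.rhs(y, clamp),
        (t[0], t[-1]),
        y0,
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integrator failed for {network.label or 'network'}: "
            f"{sol.message} (status {sol.status}, reached t={sol.t[-1] if len(sol.t) else 'none'})"
        )
    occ = sol.y.T
    traj = OccupancyTrajectory(
        times=t, occupancies=occ, conditions=conditions, label=network.label
    )
    a_clamped = clamp is not None and clamp[SPECIES.index("A")]
    _check_conservation(traj, y0, clamped=a_clamped)
    return traj


def _check_conservation(
    traj: OccupancyTrajectory, y0: np.ndarray, clamped: bool, rtol: float = 1e-6
) -> None:
    m0 = sum(y0[SPECIES.index(s)] for s in MYOSIN_SPECIES)
    m = traj.myosin_total()
    if m0 > 0 and np.max(np.abs(m - m0)) > rtol * m0:
        raise IntegrationError(
            f"myosin mass not conserved: max deviation "
            f"{np.max(np.abs(m - m0)):.3e} µM on total {m0} µM"
        )
    if not clamped:
        a0 = sum(y0[SPECIES.index(s)] for s in ACTIN_SPECIES + ("A",))
        a = traj.actin_total()
        if a0 > 0 and np.max(np.abs(a - a0)) > rtol * a0:
            raise IntegrationError(
                f"actin mass not conserved: max deviation "
                f"{np.max(np.abs(a - a0)):.3e} µM on total {a0} µM"
            )
    if np.min(traj.occupancies) < -1e-9:
        raise IntegrationError(
            f"negative occupancy {np.min(traj.occupancies):.3e} µM"
        )
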