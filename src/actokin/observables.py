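"""Projection of state occupancies onto stopped-flow observables.

Every observable is a linear readout ``signal(t) = baseline + Σ w_s · c_s(t)``
over the species of the cycle.  Weights are relative (unitless) fluorescence
or scattering coefficients: only their ordering carries meaning, amplitudes
are free parameters of the downstream exponential fits.

Shipped weight tables encode the qualitative photophysics of each probe:

* ``mant_fluorescence`` — mant-nucleotide FRET lights up when the labelled
  nucleotide is bound to myosin, so every nucleotide-occupied myosin state
  carries weight 1 and everything else 0.
* ``pyrene_actin`` — pyrene fluorescence is quenched by strong (rigor-like)
  myosin binding; free actin and weakly bound states are bright.
* ``tryptophan`` — the relay-loop tryptophan reports the post-hydrolysis
  (M·ADP·Pi) conformation with enhanced emission.
* ``light_scattering`` — scattering mass increases when myosin decorates
  actin; all attached species weigh alike.
* ``nadh_atpase`` — the coupled assay regenerates ATP from released ADP, so
  the observable is accumulated product (the free ADP + Pi-committed pool);
  its slope is the steady-state rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import SPECIES, OccupancyTrajectory

__all__ = [
    "ObservableModel",
    "SignalTrace",
    "default_observable",
    "OBSERVABLE_KINDS",
    "project_signal",
]

OBSERVABLE_KINDS = (
    "mant_fluorescence",
    "pyrene_actin",
    "tryptophan",
    "light_scattering",
    "nadh_atpase",
)

_DEFAULT_WEIGHTS: dict[str, dict[str, float]] = {
    "mant_fluorescence": {
        "M.ATP": 1.0, "M.ADP.Pi": 1.0, "M.ADP": 1.0,
        "AM.ATP": 1.0, "AM.ADP.Pi": 1.0, "AM.ADP": 1.0,
    },
    "pyrene_actin": {
        "A": 1.0, "AM.ATP": 0.15, "AM.ADP.Pi": 0.15,
        "AM": 0.0, "AM.ADP": 0.0,
    },
    "tryptophan": {
        "M": 1.0, "M.ATP": 1.05, "M.ADP.Pi": 1.25, "M.ADP": 1.05,
        "AM": 1.0, "AM.ATP": 1.05, "AM.ADP.Pi": 1.25, "AM.ADP": 1.05,
    },
    "light_scattering": {
        "AM": 1.0, "AM.ATP": 1.0, "AM.ADP.Pi": 1.0, "AM.ADP": 1.0,
        "A": 0.3,
    },
    "nadh_atpase": {"ADP": 1.0, "M.ADP": 1.0, "AM.ADP": 1.0},
}


@dataclass(frozen=True)
class ObservableModel:
    """Linear signal model: per-species weights plus a baseline offset."""

    kind: str
    weights: dict[str, float] = field(default_factory=dict)
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in OBSERVABLE_KINDS:
            raise ValueError(
                f"unknown observable kind {self.kind!r}; "
                f"choose from {OBSERVABLE_KINDS}"
            )
        for s, w in self.weights.items():
            if s not in SPECIES:
                raise ValueError(f"weight for unknown species {s!r}")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight for species {s!r}")

    def weight_vector(self, species: tuple[str, ...]) -> np.ndarray:
        return np.array([self.weights.get(s, 0.0) for s in species])


def default_observable(kind: str, baseline: float = 0.0) -> ObservableModel:
    """Shipped weight table for one observable kind."""
    if kind not in _DEFAULT_WEIGHTS:
        raise ValueError(
            f"unknown observable kind {kind!r}; choose from {OBSERVABLE_KINDS}"
        )
    return ObservableModel(kind=kind, weights=dict(_DEFAULT_WEIGHTS[kind]),
                           baseline=baseline)


@dataclass
class SignalTrace:
    """A time-stamped observable signal with experiment metadata."""

    times: np.ndarray
    signal: np.ndarray
    kind: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have the same shape")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, start: float, stop: float | None = None) -> "SignalTrace":
        stop = np.inf if stop is None else stop
        m = (self.times >= start) & (self.times <= stop)
        return SignalTrace(self.times[m], self.signal[m], self.kind,
                           dict(self.meta))


def project_signal(
    traj: OccupancyTrajectory, model: ObservableModel
) -> SignalTrace:
    """Project a trajectory onto an observable: baseline + Σ wᵢ·cᵢ(t)."""
    for s in model.weights:
        if s not in traj.species:
            raise ValueError(
                f"observable references species {s!r} absent from trajectory"
            )
    w = model.weight_vector(traj.species)
    sig = model.baseline + traj.occupancies @ w
    meta = {"observable": model.kind, "construct": traj.label}
    if traj.conditions is not None:
        c = traj.conditions
        meta.update(myosin_uM=c.myosin, actin_uM=c.actin, atp_uM=c.atp,
                    adp_uM=c.adp)
    return SignalTrace(traj.times.copy(), sig, kind=model.kind, meta=meta)
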