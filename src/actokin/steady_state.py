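"""Michaelis–Menten analysis of actin-activated steady-state ATPase data."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["AtpaseCurve", "MichaelisFit", "fit_michaelis"]


@dataclass
class AtpaseCurve:
    """Turnover rate (s⁻¹ per myosin head) against F-actin concentration."""

    actin: np.ndarray          # µM
    rate: np.ndarray           # s⁻¹ per head
    buffer: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.actin = np.asarray(self.actin, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.actin.shape != self.rate.shape:
            raise ValueError("actin and rate arrays must match in length")
        if np.any(self.actin < 0):
            raise ValueError("actin concentrations must be >= 0")


@dataclass(frozen=True)
class MichaelisFit:
    kcat: float          # s⁻¹
    Kapp: float          # µM
    kcat_se: float
    Kapp_se: float
    warnings: tuple[str, ...] = ()

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Kapp (µM⁻¹s⁻¹)."""
        return self.kcat / self.Kapp

    def evaluate(self, actin: np.ndarray) -> np.ndarray:
        a = np.asarray(actin, dtype=float)
        return self.kcat * a / (self.Kapp + a)


def fit_michaelis(
    curve: AtpaseCurve, subtract_basal: bool = False
) -> MichaelisFit:
    """Least-squares fit of v([A]) = kcat·[A]/(Kapp + [A]).

    With ``subtract_basal`` and a 0-µM point present, the basal (actin-free)
    rate is subtracted from all points before fitting; default off, matching
    the common convention of reporting the raw activated rate.
    """
    a, v = curve.actin, curve.rate.copy()
    if len(a) < 4:
        raise ValueError("need >= 4 actin concentrations to fit")
    if subtract_basal and np.any(a == 0):
        v = v - float(np.mean(v[a == 0]))

    kcat0 = float(np.max(v)) or 1.0
    kapp0 = float(np.median(a[a > 0])) if np.any(a > 0) else 1.0

    def model(x, kcat, kapp):
        return kcat * x / (kapp + x)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(
            model, a, v, p0=(kcat0, kapp0),
            bounds=((0, 0), (np.inf, np.inf)), maxfev=10000,
        )
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    kcat, kapp = float(popt[0]), float(popt[1])
    warns = []
    if np.max(a) < 2 * kapp:
        warns.append("no saturation in data; estimates have wide CIs")
    return MichaelisFit(kcat, kapp, float(se[0]), float(se[1]), tuple(warns))
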