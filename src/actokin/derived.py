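"""Derived kinetic and thermodynamic quantities of the actomyosin cycle.

From a :class:`~actokin.rates.RateConstantSet` this module computes the
equilibrium dissociation constants of the nucleotide and actin interactions,
the coupling ratios that quantify how F-actin reshapes nucleotide handling,
and the duty ratio — the fraction of the cycle a motor spends strongly bound
to F-actin when ADP release gates detachment:

* ``K_D  = k-D / k+D``      ADP affinity of myosin (µM)
* ``K_AD = k-AD / k+AD``    ADP affinity of actomyosin (µM)
* ``K_A  = k-A / k+A``      actin affinity of myosin (µM)
* ``K_DA = k-DA / k+DA``    actin affinity of myosin·ADP (µM)
* thermodynamic coupling     ``K_AD / K_D``
* kinetic coupling           ``k-AD / k-D``
* nucleotide selectivity     ``k+AD / K1k+2`` (acto branch)
* actin-affinity coupling    ``K_DA / K_A``
* duty ratio                 ``v([A]) / k-AD`` with ``v`` the Michaelis–
  Menten ATPase rate at the stated actin concentration and saturating ATP

A constant that was not experimentally accessible propagates as
:class:`Unavailable` with a traceable reason instead of silently vanishing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import pandas as pd

from .rates import RateConstantSet, builtin_precedence

__all__ = [
    "Unavailable",
    "DerivedConstants",
    "DutyRatio",
    "equilibrium_constants",
    "coupling_ratios",
    "duty_ratio",
    "duty_ratio_variants",
    "derive_all",
    "thermodynamic_box",
    "report_frame",
]


@dataclass(frozen=True)
class Unavailable:
    """Marker for a derived quantity that cannot be computed, with a reason."""

    reason: str

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return f"Unavailable({self.reason!r})"


Value = float | Unavailable


def _ratio(num: float | None, den: float | None, what: str,
           num_name: str, den_name: str) -> Value:
    if num is None:
        return Unavailable(f"{what}: {num_name} not measured")
    if den is None:
        return Unavailable(f"{what}: {den_name} not measured")
    if den == 0:
        return Unavailable(f"{what}: {den_name} is zero")
    return num / den


def _chain(v: Value, what: str) -> Value:
    """Propagate unavailability through a dependent quantity."""
    return Unavailable(f"{what}: depends on {v.reason}") if isinstance(
        v, Unavailable) else v


@dataclass
class DerivedConstants:
    """Equilibrium constants, coupling ratios and duty ratio of one construct."""

    construct_label: str
    K_D: Value = field(default_factory=lambda: Unavailable("not computed"))
    K_AD: Value = field(default_factory=lambda: Unavailable("not computed"))
    K_A: Value = field(default_factory=lambda: Unavailable("not computed"))
    K_DA: Value = field(default_factory=lambda: Unavailable("not computed"))
    thermo_coupling: Value = field(
        default_factory=lambda: Unavailable("not computed"))
    kinetic_coupling: Value = field(
        default_factory=lambda: Unavailable("not computed"))
    nucleotide_selectivity: Value = field(
        default_factory=lambda: Unavailable("not computed"))
    actin_affinity_coupling: Value = field(
        default_factory=lambda: Unavailable("not computed"))
    duty_ratio: Value = field(default_factory=lambda: Unavailable("not computed"))
    duty_actin_uM: float | None = None

    def as_dict(self) -> dict[str, Value]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "construct_label"}


def _pick(rates: RateConstantSet, name: str, key: str | None) -> float | None:
    """Resolve a constant, preferring ``key`` but falling back to the first
    available measurement when that signal was not recorded."""
    v = getattr(rates, name)
    if isinstance(v, Mapping):
        if key is not None and key in v and v[key] is not None:
            return v[key]
        return rates.value(name)
    return v


def equilibrium_constants(
    rates: RateConstantSet,
    precedence: Mapping[str, Mapping[str, str]] | None = None,
) -> DerivedConstants:
    """K_D, K_AD, K_A, K_DA as off/on ratios (µM)."""
    prec = precedence if precedence is not None else builtin_precedence()
    thermo = prec.get("thermo_coupling", {})
    kd_off = _pick(rates, "kD_off", thermo.get("kD_off"))
    kad_off = _pick(rates, "kAD_off", thermo.get("kAD_off"))
    d = DerivedConstants(construct_label=rates.construct_label)
    d.K_D = _ratio(kd_off, rates.value("kD_on"), "K_D", "k-D", "k+D")
    d.K_AD = _ratio(kad_off, rates.value("kAD_on"), "K_AD", "k-AD", "k+AD")
    d.K_A = _ratio(rates.value("kA_off"), rates.value("kA_on"),
                   "K_A", "k-A", "k+A")
    d.K_DA = _ratio(rates.value("kDA_off"), rates.value("kDA_on"),
                    "K_DA", "k-DA", "k+DA")
    return d


def coupling_ratios(
    rates: RateConstantSet,
    derived: DerivedConstants,
    precedence: Mapping[str, Mapping[str, str]] | None = None,
) -> DerivedConstants:
    """Populate the four coupling ratios on an equilibrium-constant set.

    The precedence table selects which measurement of a multiply-measured
    constant feeds each ratio (chase-derived release rates for the kinetic
    coupling, like-signal pairs for the nucleotide selectivity).
    """
    prec = precedence if precedence is not None else builtin_precedence()

    if isinstance(derived.K_AD, Unavailable):
        derived.thermo_coupling = _chain(derived.K_AD, "K_AD/K_D")
    elif isinstance(derived.K_D, Unavailable):
        derived.thermo_coupling = _chain(derived.K_D, "K_AD/K_D")
    else:
        derived.thermo_coupling = derived.K_AD / derived.K_D

    kin = prec.get("kinetic_coupling", {}).get(rates.construct_label, {})
    kad_off = _pick(rates, "kAD_off", kin.get("kAD_off"))
    kd_off = _pick(rates, "kD_off", kin.get("kD_off"))
    derived.kinetic_coupling = _ratio(kad_off, kd_off,
                                      "k-AD/k-D", "k-AD", "k-D")

    sel = prec.get("nucleotide_selectivity", {})
    k1k2 = _pick(rates, "k1k2_acto", sel.get("k1k2_acto"))
    derived.nucleotide_selectivity = _ratio(
        rates.value("kAD_on"), k1k2, "k+AD/K1k+2", "k+AD", "K1k+2 (acto)")

    if isinstance(derived.K_DA, Unavailable):
        derived.actin_affinity_coupling = _chain(derived.K_DA, "K_DA/K_A")
    elif isinstance(derived.K_A, Unavailable):
        derived.actin_affinity_coupling = _chain(derived.K_A, "K_DA/K_A")
    else:
        derived.actin_affinity_coupling = derived.K_DA / derived.K_A
    return derived


@dataclass(frozen=True)
class DutyRatio:
    value: float
    clipped: bool
    raw: float
    actin_uM: float


def duty_ratio(kcat: float, Kapp: float, actin: float,
               kAD_off: float) -> DutyRatio:
    """Attached-time fraction v([A])/k-AD at the stated actin concentration.

    ``v([A]) = kcat·[A]/(Kapp + [A])`` is the cycling flux; dividing by the
    actin-activated ADP release rate gives the fraction of cycle time spent
    in the strongly bound (ADP/rigor) states when ADP release gates
    detachment.  Ratios above 1 are clipped to 1.0 and flagged.
    """
    for name, v in (("kcat", kcat), ("Kapp", Kapp), ("actin", actin)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if kAD_off <= 0:
        raise ValueError("kAD_off must be > 0 (zero makes the ratio undefined)")
    v = kcat * actin / (Kapp + actin) if (Kapp + actin) > 0 else kcat
    raw = v / kAD_off
    return DutyRatio(value=min(raw, 1.0), clipped=raw > 1.0, raw=raw,
                     actin_uM=actin)


def duty_ratio_variants(
    rates: RateConstantSet, actin: float = 190.0
) -> dict[str, DutyRatio]:
    """Duty ratio computed with every available k-AD measurement."""
    out: dict[str, DutyRatio] = {}
    v = rates.kAD_off
    variants = v if isinstance(v, Mapping) else {"single": v}
    for key, kad in variants.items():
        if kad is not None and rates.kcat is not None and rates.Kapp is not None:
            out[key] = duty_ratio(rates.kcat, rates.Kapp, actin, kad)
    return out


def derive_all(
    rates: RateConstantSet,
    actin: float = 190.0,
    precedence: Mapping | None = None,
) -> DerivedConstants:
    """Full derived-constant set for one construct at the stated [actin]."""
    prec = precedence if precedence is not None else builtin_precedence()
    d = equilibrium_constants(rates, prec)
    d = coupling_ratios(rates, d, prec)
    duty_key = prec.get("duty_ratio", {}).get("kAD_off")
    kad = rates.value(
        "kAD_off", duty_key if isinstance(rates.kAD_off, Mapping) else None)
    if rates.kcat is None or rates.Kapp is None:
        d.duty_ratio = Unavailable("duty ratio: steady-state kcat/Kapp missing")
    elif kad is None or kad <= 0:
        d.duty_ratio = Unavailable("duty ratio: k-AD not measured")
    else:
        d.duty_ratio = duty_ratio(rates.kcat, rates.Kapp, actin, kad).value
    d.duty_actin_uM = actin
    return d


def thermodynamic_box(
    rates: RateConstantSet, precedence: Mapping | None = None
) -> dict[str, Value]:
    """Detailed-balance diagnostic for the actin/myosin/ADP box.

    For a self-consistent rate set the two routes around the box agree:
    K_AD/K_D (nucleotide axis) equals K_DA/K_A (actin axis).  The
    discrepancy factor is reported, never enforced — measured sets carry
    experimental error.
    """
    d = derive_all(rates, precedence=precedence)
    out: dict[str, Value] = {
        "K_AD_over_K_D": d.thermo_coupling,
        "K_DA_over_K_A": d.actin_affinity_coupling,
    }
    if isinstance(d.thermo_coupling, float) and isinstance(
            d.actin_affinity_coupling, float) and d.actin_affinity_coupling:
        f = d.thermo_coupling / d.actin_affinity_coupling
        out["discrepancy_factor"] = max(f, 1.0 / f)
    else:
        out["discrepancy_factor"] = Unavailable(
            "discrepancy: one of the couplings is unavailable")
    return out


def report_frame(
    constructs: Mapping[str, RateConstantSet],
    actin: float = 190.0,
    precedence: Mapping | None = None,
) -> pd.DataFrame:
    """Comparative table of derived signatures across constructs."""
    rows = {}
    for label, rates in constructs.items():
        d = derive_all(rates, actin=actin, precedence=precedence)
        eff = (rates.kcat / rates.Kapp
               if rates.kcat is not None and rates.Kapp else None)
        row = {"kcat_over_Kapp": eff}
        for k, v in d.as_dict().items():
            row[k] = v if not isinstance(v, Unavailable) else None
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")
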