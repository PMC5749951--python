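"""Rate-constant sets for the myosin / actomyosin ATPase cycle.

A :class:`RateConstantSet` carries every primary rate constant of one myosin
construct, in the units used throughout the package (concentrations in µM,
first-order rates in s⁻¹, second-order rates in µM⁻¹s⁻¹).  Constants measured
in the presence of F-actin ("acto" constants, bold in the kinetics
literature) are distinguished from the actin-detached ones by their field
names.

Several constants are typically measured with more than one stopped-flow
signal (tryptophan, mant nucleotides, pyrene-actin, light scattering); the
set stores the alternates and a precedence table decides which measurement a
given downstream calculation uses.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import yaml

__all__ = [
    "RateConstantSet",
    "LigandConditions",
    "SchemeDefaults",
    "load_constructs",
    "builtin_constructs",
    "builtin_precedence",
    "builtin_defaults",
]

#: fields that are second-order (µM⁻¹s⁻¹); everything else first-order (s⁻¹)
#: except ``inv_K05``, ``inv_K1_acto`` and ``Kapp`` which are concentrations (µM).
SECOND_ORDER_FIELDS = frozenset(
    {"k1k2_myosin", "k1k2_acto", "kD_on", "kAD_on", "kA_on", "kDA_on"}
)
CONCENTRATION_FIELDS = frozenset({"inv_K05", "inv_K1_acto", "Kapp"})


@dataclass(frozen=True)
class RateConstantSet:
    """All named rate constants of one myosin construct.

    ``None`` marks a constant that is not experimentally accessible for the
    construct; downstream derivations propagate the unavailability rather
    than guessing.  Fields holding a dict of alternate measurements are
    resolved through :meth:`value` with a signal key.
    """

    construct_label: str
    k1k2_myosin: float | Mapping[str, float | None] | None = None
    k3_plus_kminus3: float | None = None
    inv_K05: float | None = None
    k_pi_basal: float = 0.02
    k_pi_actin_max: float | None = None  # identified with kcat
    kD_on: float | None = None
    kD_off: float | Mapping[str, float | None] | None = None
    k1k2_acto: float | Mapping[str, float | None] | None = None
    k2_acto: float | None = None
    inv_K1_acto: float | None = None
    kAD_on: float | None = None
    kAD_off: float | Mapping[str, float | None] | None = None
    kA_on: float | None = None
    kA_off: float | None = None
    kDA_on: float | None = None
    kDA_off: float | None = None
    kcat: float | None = None
    Kapp: float | None = None
    hydrolysis_equilibrium: float = 10.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Mapping):
                for key, sub in v.items():
                    if sub is not None and sub < 0:
                        raise ValueError(
                            f"{self.construct_label}: rate constant "
                            f"{f.name}[{key}] = {sub} must be >= 0"
                        )
            elif isinstance(v, (int, float)) and v < 0:
                raise ValueError(
                    f"{self.construct_label}: rate constant {f.name} = {v} "
                    "must be >= 0"
                )
        if self.k_pi_actin_max is None and self.kcat is not None:
            object.__setattr__(self, "k_pi_actin_max", self.kcat)

    def value(self, name: str, signal: str | None = None) -> float | None:
        """Resolve one constant, picking ``signal`` among alternates.

        With no ``signal`` and several alternates, the first listed
        measurement is returned (the shipped data lists the preferred signal
        first).
        """
        v = getattr(self, name)
        if isinstance(v, Mapping):
            if signal is not None:
                if signal not in v:
                    raise KeyError(
                        f"{self.construct_label}: no {signal!r} measurement "
                        f"of {name}; have {sorted(v)}"
                    )
                return v[signal]
            for sub in v.values():
                if sub is not None:
                    return sub
            return None
        return v

    def resolved(self, precedence: Mapping[str, str] | None = None) -> "RateConstantSet":
        """Collapse every multi-measurement field to a single float.

        ``precedence`` maps field name → signal key; fields not listed fall
        back to the first available alternate.
        """
        precedence = precedence or {}
        updates = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Mapping):
                updates[f.name] = self.value(f.name, precedence.get(f.name))
        return replace(self, **updates) if updates else self


@dataclass(frozen=True)
class LigandConditions:
    """Initial concentrations (µM) and mixing metadata for one experiment."""

    myosin: float = 0.0
    actin: float = 0.0
    atp: float = 0.0
    adp: float = 0.0
    pi: float = 0.0
    #: True clamps all free pools (ATP, ADP, Pi, A); a tuple clamps only the
    #: named pools, e.g. ("ATP",) for pseudo-first-order ATP excess
    clamp_ligands: bool | tuple[str, ...] = False
    dead_time: float = 0.0015
    #: start with myosin pre-bound to actin (rigor complex), as in
    #: ATP-induced dissociation experiments
    start_bound: bool = False
    #: start with ADP pre-bound to the myosin pool (chasing experiments)
    start_with_adp: bool = False

    def __post_init__(self) -> None:
        for name in ("myosin", "actin", "atp", "adp", "pi"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")
        if self.dead_time < 0:
            raise ValueError("dead time must be >= 0")


@dataclass(frozen=True)
class SchemeDefaults:
    """Network parameters the experiments do not resolve individually."""

    hydrolysis_equilibrium: float = 10.0
    k_pi_basal: float = 0.02
    collision_on_acto_atp: float = 100.0
    collision_on_actin_weak: float = 10.0
    dead_time: float = 0.0015


def _load_yaml() -> dict:
    ref = importlib.resources.files("actokin.data") / "constructs.yaml"
    return yaml.safe_load(ref.read_text())


_CACHE: dict | None = None


def _raw() -> dict:
    global _CACHE
    if _CACHE is None:
        _CACHE = _load_yaml()
    return _CACHE


def load_constructs(path: str | None = None) -> dict[str, RateConstantSet]:
    """Load rate-constant sets from a YAML config (or the shipped table)."""
    if path is None:
        doc = _raw()
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    defaults = doc.get("defaults", {})
    out: dict[str, RateConstantSet] = {}
    for label, row in doc["constructs"].items():
        kwargs = dict(row)
        kwargs.setdefault("k_pi_basal", defaults.get("k_pi_basal", 0.02))
        kwargs.setdefault(
            "hydrolysis_equilibrium", defaults.get("hydrolysis_equilibrium", 10.0)
        )
        out[label] = RateConstantSet(construct_label=label, **kwargs)
    if len(out) != len(doc["constructs"]):
        raise ValueError("construct labels must be unique")
    return out


def builtin_constructs() -> dict[str, RateConstantSet]:
    """The shipped NM2C / R788K / R788E rate-constant sets."""
    return load_constructs(None)


def builtin_precedence() -> dict:
    """Signal-source precedence table for derived quantities."""
    return _raw()["precedence"]


def builtin_defaults() -> SchemeDefaults:
    d = _raw().get("defaults", {})
    return SchemeDefaults(
        hydrolysis_equilibrium=d.get("hydrolysis_equilibrium", 10.0),
        k_pi_basal=d.get("k_pi_basal", 0.02),
        collision_on_acto_atp=d.get("collision_on_acto_atp", 100.0),
        collision_on_actin_weak=d.get("collision_on_actin_weak", 10.0),
        dead_time=d.get("dead_time", 0.0015),
    )
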