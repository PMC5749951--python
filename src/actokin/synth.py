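"""Synthetic inputs with known ground truth for every pipeline stage.

Kinetics: transients are produced by integrating the reaction network,
projecting through an observable model, adding iid Gaussian noise and
discarding samples inside the instrument dead time.  Concentration series
emulate the standard stopped-flow experiment designs (named presets below),
one simulated transient per concentration, each fit for its observed rate.

Structures: an internal-coordinate peptide builder (standard backbone bond
lengths/angles, caller-chosen φ/ψ) provides templates; trajectories realize
planted properties — an end-to-end domain rotation, an H-bond occupancy
fraction, a Cα angle — exactly, plus optional Gaussian jitter on atoms not
involved in any plant.

Everything is reproducible from (specification, seed); ground truth is
embedded in output metadata so round-trip tests are self-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .observables import ObservableModel, SignalTrace, default_observable, project_signal
from .pdbio import CoordinateTrajectory, StructureModel
from .rates import LigandConditions, RateConstantSet, SchemeDefaults
from .scheme import build_network, simulate_cycle
from .steady_state import AtpaseCurve
from .transient import KobsSeries, fit_exponential

__all__ = [
    "NoiseSpec",
    "generate_transient",
    "generate_series",
    "SERIES_EXPERIMENTS",
    "generate_atpase_curve",
    "generate_trajectory",
    "measure_hydrolysis_rate",
    "build_peptide",
    "make_template_model",
    "make_shell_model",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive iid Gaussian noise plus instrument dead time.

    ``sd`` is in signal units, or a fraction of the noiseless amplitude when
    ``relative`` is set.  The same (spec, seed) always yields bit-identical
    output.
    """

    sd: float = 0.0
    seed: int = 0
    dead_time: float = 0.0015
    relative: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.dead_time < 0:
            raise ValueError("dead time must be >= 0")


# ---------------------------------------------------------------------------
# kinetic traces
# ---------------------------------------------------------------------------

def generate_transient(
    rates: RateConstantSet,
    conditions: LigandConditions,
    observable: ObservableModel | str,
    noise: NoiseSpec,
    time_grid: np.ndarray,
    defaults: SchemeDefaults | None = None,
) -> SignalTrace:
    """One noisy stopped-flow trace from a rate set under given conditions."""
    if isinstance(observable, str):
        observable = default_observable(observable)
    network = build_network(rates, defaults)
    traj = simulate_cycle(network, conditions, np.asarray(time_grid, float))
    trace = project_signal(traj, observable)
    clean = trace.signal.copy()
    sd = noise.sd
    if noise.relative:
        amp = float(np.ptp(clean))
        sd = noise.sd * (amp if amp > 0 else 1.0)
    if sd > 0:
        rng = np.random.default_rng(noise.seed)
        trace.signal = clean + rng.normal(0.0, sd, size=clean.shape)
    trace.meta.update(
        construct=rates.construct_label,
        noise_sd=sd,
        seed=noise.seed,
        dead_time=noise.dead_time,
    )
    if noise.dead_time > 0:
        trace = trace.window(noise.dead_time)
    return trace


@dataclass(frozen=True)
class SeriesExperiment:
    """One concentration-series experiment design."""

    name: str
    observable: str
    varied: str                       # conditions field that is scanned
    base: LigandConditions
    n_phases: int = 1
    #: analytic k_obs under pseudo-first-order conditions — the design's
    #: own prediction, used to scale the simulation window
    expected_kobs: object = None      # callable (rates, conc) -> float

    def conditions(self, conc: float) -> LigandConditions:
        return replace(self.base, **{self.varied: conc})


def _k(rates: RateConstantSet, name: str, signal: str | None = None) -> float:
    v = rates.value(name, signal)
    if v is None:
        raise ValueError(
            f"{rates.construct_label}: {name} not available; cannot design "
            "this series"
        )
    return v


SERIES_EXPERIMENTS: dict[str, SeriesExperiment] = {
    # mantATP binding to myosin: signal rise at K1k+2 · [ATP]
    "mant_atp_myosin": SeriesExperiment(
        name="mant_atp_myosin",
        observable="mant_fluorescence",
        varied="atp",
        base=LigandConditions(myosin=0.1, clamp_ligands=("ATP",)),
        expected_kobs=lambda r, s: _k(r, "k1k2_myosin", "mant") * s,
    ),
    # mantADP binding to myosin: k_obs = k+D·[ADP] + k-D.  Low myosin keeps
    # the pseudo-first-order condition valid down to sub-µM nucleotide, so
    # the window can straddle K_D where slope and intercept separate best.
    "mant_adp_myosin": SeriesExperiment(
        name="mant_adp_myosin",
        observable="mant_fluorescence",
        varied="adp",
        base=LigandConditions(myosin=0.02, clamp_ligands=("ADP",)),
        expected_kobs=lambda r, s: _k(r, "kD_on") * s
        + _k(r, "kD_off", "intercept"),
    ),
    # intrinsic tryptophan response to ATP: binding then hydrolysis
    "tryptophan_atp_myosin": SeriesExperiment(
        name="tryptophan_atp_myosin",
        observable="tryptophan",
        varied="atp",
        base=LigandConditions(myosin=0.2, clamp_ligands=("ATP",)),
        n_phases=2,
        expected_kobs=lambda r, s: min(
            _k(r, "k1k2_myosin", "mant") * s, _k(r, "k3_plus_kminus3")
        ),
    ),
    # ATP-induced dissociation of pyrene-actomyosin: hyperbolic in [ATP]
    "pyrene_atp_acto": SeriesExperiment(
        name="pyrene_atp_acto",
        observable="pyrene_actin",
        varied="atp",
        base=LigandConditions(myosin=0.1, actin=0.1, start_bound=True,
                              clamp_ligands=("ATP",)),
        expected_kobs=lambda r, s: _k(r, "k2_acto") * s
        / (_k(r, "inv_K1_acto") + s),
    ),
    # mantADP binding to actomyosin: k_obs = k+AD·[ADP] + k-AD.
    # Actin excess keeps the rigor complex intact so the detached-branch ADP
    # binding does not contaminate the signal.
    "mant_adp_acto": SeriesExperiment(
        name="mant_adp_acto",
        observable="mant_fluorescence",
        varied="adp",
        base=LigandConditions(myosin=0.02, actin=2.0, start_bound=True,
                              clamp_ligands=("ADP",)),
        expected_kobs=lambda r, s: _k(r, "kAD_on") * s
        + _k(r, "kAD_off", "chase_mant"),
    ),
    # actin binding to myosin by light scattering: k_obs = k+A·[A] + k-A
    "light_scattering_actin": SeriesExperiment(
        name="light_scattering_actin",
        observable="light_scattering",
        varied="actin",
        base=LigandConditions(myosin=0.05, clamp_ligands=("A",)),
        expected_kobs=lambda r, s: _k(r, "kA_on") * s + _k(r, "kA_off"),
    ),
}


def generate_series(
    rates: RateConstantSet,
    experiment: str | SeriesExperiment,
    concentrations: np.ndarray,
    noise: NoiseSpec,
    replicates: int = 1,
    n_samples: int = 400,
    defaults: SchemeDefaults | None = None,
) -> KobsSeries:
    """Simulate one transient per concentration and assemble a k_obs series.

    The simulation window is scaled to the design's predicted relaxation
    rate at each concentration (≈6 relaxation times).  ``replicates`` traces
    per concentration are fit and averaged.  All ground truth lands in the
    series metadata.
    """
    if isinstance(experiment, str):
        if experiment not in SERIES_EXPERIMENTS:
            raise KeyError(
                f"unknown experiment {experiment!r}; "
                f"choose from {sorted(SERIES_EXPERIMENTS)}"
            )
        experiment = SERIES_EXPERIMENTS[experiment]
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise ValueError("concentration list must not be empty")
    if np.any(concentrations <= 0):
        raise ValueError("series concentrations must be > 0")

    ss = np.random.SeedSequence(noise.seed)
    children = ss.spawn(len(concentrations) * replicates)
    kobs = np.empty(len(concentrations))
    sds = np.empty(len(concentrations))
    for i, conc in enumerate(concentrations):
        k_pred = float(experiment.expected_kobs(rates, conc))
        tmax = 6.0 / max(k_pred, 1e-3)
        grid = np.linspace(0.0, tmax, n_samples)
        vals = []
        for rep in range(replicates):
            child = children[i * replicates + rep]
            tr = generate_transient(
                rates,
                experiment.conditions(conc),
                experiment.observable,
                replace(noise, seed=child.generate_state(1)[0] % (2**31)),
                grid,
                defaults,
            )
            fit = fit_exponential(tr, n_phases=experiment.n_phases)
            vals.append(fit.k_obs)
        kobs[i] = float(np.mean(vals))
        sds[i] = float(np.std(vals)) if replicates > 1 else 0.0

    return KobsSeries(
        ligand=experiment.varied,
        concentrations=concentrations,
        k_obs=kobs,
        sd=sds if replicates > 1 else None,
        meta={
            "experiment": experiment.name,
            "construct": rates.construct_label,
            "observable": experiment.observable,
            "noise_sd": noise.sd,
            "seed": noise.seed,
            "replicates": replicates,
        },
    )


def measure_hydrolysis_rate(
    rates: RateConstantSet,
    noise: NoiseSpec,
    saturation_factor: float = 15.0,
    n_samples: int = 600,
) -> float:
    """ATP hydrolysis equilibration rate (k3 + k-3) from a saturating
    tryptophan transient.

    At [ATP] high enough that binding is ``saturation_factor`` times faster
    than hydrolysis, the two relaxations separate cleanly and the slow phase
    of a double-exponential fit reports k3 + k-3 directly — the plateau the
    concentration series approaches.  (The series itself is fit
    hyperbolically for the half-saturation analysis, but with binding
    represented as a single effective step its apparent maximum is biased
    upward where binding and hydrolysis rates are comparable; the saturating
    transient avoids that.)
    """
    ksum = _k(rates, "k3_plus_kminus3")
    k1k2 = _k(rates, "k1k2_myosin", "mant")
    atp = saturation_factor * ksum / k1k2
    cond = LigandConditions(myosin=0.2, atp=atp, clamp_ligands=("ATP",))
    grid = np.linspace(0.0, 6.0 / ksum, n_samples)
    tr = generate_transient(rates, cond, "tryptophan", noise, grid)
    fit = fit_exponential(tr, n_phases=2)
    return min(p.k_obs for p in fit.phases)


def generate_atpase_curve(
    kcat: float,
    Kapp: float,
    actin_grid: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
) -> AtpaseCurve:
    """Michaelis–Menten ATPase envelope v([A]) = kcat·[A]/(Kapp+[A]) + noise."""
    a = np.asarray(actin_grid, dtype=float)
    if np.any(a < 0):
        raise ValueError("actin concentrations must be >= 0")
    if kcat < 0 or Kapp < 0:
        raise ValueError("kcat and Kapp must be >= 0")
    v = kcat * a / (Kapp + a)
    sd = noise.sd * (kcat if noise.relative else 1.0)
    if sd > 0:
        rng = np.random.default_rng(noise.seed)
        v = v + rng.normal(0.0, sd, size=v.shape)
    return AtpaseCurve(
        actin=a, rate=v,
        meta={"kcat_true": kcat, "Kapp_true": Kapp, "noise_sd": sd,
              "seed": noise.seed},
    )


# ---------------------------------------------------------------------------
# synthetic structures
# ---------------------------------------------------------------------------

# standard backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.5
_OMEGA = 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF atom placement: position d with |cd|, angle(bcd), torsion(abcd)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + np.column_stack([bc, m, n]) @ d_local


def build_peptide(
    phi: list[float],
    psi: list[float],
    chain: str = "A",
    start_resnum: int = 1,
    resname: str = "ALA",
) -> StructureModel:
    """Poly-peptide backbone (N, CA, C, O) from φ/ψ internal coordinates.

    ``phi[0]`` is unused (the first residue has no φ); ``psi[-1]`` only
    places the terminal carbonyl oxygen.  The construction parameters are
    exactly recoverable by backbone dihedral analysis.
    """
    if len(phi) != len(psi):
        raise ValueError("phi and psi lists must have equal length")
    n_res = len(phi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")

    coords: list[np.ndarray] = []
    names: list[str] = []
    resnums: list[int] = []

    # first residue in a canonical frame
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone = [(N, CA, C)]
    for i in range(1, n_res):
        Np, CAp, Cp = backbone[-1]
        Ni = _place(Np, CAp, Cp, _B_C_N, _A_CA_C_N, psi[i - 1])
        CAi = _place(CAp, Cp, Ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        Ci = _place(Cp, Ni, CAi, _B_CA_C, _A_N_CA_C, phi[i])
        backbone.append((Ni, CAi, Ci))

    for i, (Ni, CAi, Ci) in enumerate(backbone):
        rn = start_resnum + i
        # carbonyl O sits opposite the next N: torsion ψ+180 about CA–C
        O = _place(Ni, CAi, Ci, _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        for nm, xyz in (("N", Ni), ("CA", CAi), ("C", Ci), ("O", O)):
            names.append(nm)
            resnums.append(rn)
            coords.append(xyz)

    n = len(names)
    elements = [nm[0] for nm in names]
    return StructureModel(
        serial=np.arange(1, n + 1),
        name=np.array(names, dtype=object),
        resname=np.array([resname] * n, dtype=object),
        resnum=np.array(resnums),
        chain=np.array([chain] * n, dtype=object),
        altloc=np.array([""] * n, dtype=object),
        coords=np.array(coords),
        occupancy=np.ones(n),
        bfactor=np.zeros(n),
        element=np.array(elements, dtype=object),
        het=np.zeros(n, dtype=bool),
    )


def _concat_models(parts: list[StructureModel]) -> StructureModel:
    out = StructureModel(
        serial=np.arange(1, sum(len(p) for p in parts) + 1),
        name=np.concatenate([p.name for p in parts]),
        resname=np.concatenate([p.resname for p in parts]),
        resnum=np.concatenate([p.resnum for p in parts]),
        chain=np.concatenate([p.chain for p in parts]),
        altloc=np.concatenate([p.altloc for p in parts]),
        coords=np.vstack([p.coords for p in parts]),
        occupancy=np.concatenate([p.occupancy for p in parts]),
        bfactor=np.concatenate([p.bfactor for p in parts]),
        element=np.concatenate([p.element for p in parts]),
        het=np.concatenate([p.het for p in parts]),
    )
    return out


def make_template_model(
    n_core: int = 20, n_domain: int = 12, offset: float = 30.0
) -> StructureModel:
    """Two α-helical segments in one chain: a core (residues 1..n_core) and
    a spatially separated mobile domain (residues 101..)."""
    helix = (-57.0, -47.0)
    core = build_peptide([helix[0]] * n_core, [helix[1]] * n_core,
                         start_resnum=1)
    domain = build_peptide([helix[0]] * n_domain, [helix[1]] * n_domain,
                           start_resnum=101)
    domain.coords = domain.coords + np.array([offset, 0.0, 0.0])
    return _concat_models([core, domain])


def make_shell_model(
    radius: float,
    n_atoms: int = 64,
    center: np.ndarray | None = None,
    seed: int = 0,
) -> StructureModel:
    """A spherical shell of protein atoms around a marker 'ligand' atom.

    The marker (HETATM ``CEN``, residue 999) defines the pocket center; the
    shell atoms all sit exactly ``radius`` Å away, so the inscribed-sphere
    radius equals ``radius`` for probe 0.
    """
    center = np.zeros(3) if center is None else np.asarray(center, float)
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_atoms, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    coords = np.vstack([center, center + radius * v])
    n = n_atoms + 1
    return StructureModel(
        serial=np.arange(1, n + 1),
        name=np.array(["CEN"] + [f"C{i}" for i in range(n_atoms)],
                      dtype=object),
        resname=np.array(["LIG"] + ["SHL"] * n_atoms, dtype=object),
        resnum=np.array([999] + list(range(1, n_atoms + 1))),
        chain=np.array(["A"] * n, dtype=object),
        altloc=np.array([""] * n, dtype=object),
        coords=coords,
        occupancy=np.ones(n),
        bfactor=np.zeros(n),
        element=np.array(["C"] * n, dtype=object),
        het=np.array([True] + [False] * n_atoms),
    )


def generate_trajectory(
    n_frames: int,
    template: StructureModel,
    planted: dict | None = None,
    seed: int = 0,
    jitter_sd: float = 0.0,
) -> CoordinateTrajectory:
    """Multi-frame coordinate set realizing planted properties exactly.

    ``planted`` may contain:

    * ``rotation``: ``{"selection": str, "degrees": float}`` — the selected
      domain rotates rigidly about a seeded random axis through its
      centroid, linearly interpolated so frame 0 is the template and the
      last frame carries the full rotation.
    * ``hbond``: ``{"donor": sel, "acceptor": sel, "occupancy": float,
      "bound_distance": 2.8, "unbound_distance": 4.5}`` — the acceptor atom
      is placed at the bound distance from the donor in exactly
      ``round(occupancy·n_frames)`` seeded-random frames.
    * ``angle``: ``{"residues": (i, j, k), "chain": str, "degrees": float}``
      — the Cα of residue *k* is repositioned so the i–j–k Cα angle equals
      the plant in every frame.

    Jitter (``jitter_sd`` Å, Gaussian) is applied only to atoms not involved
    in any plant, so the planted properties stay exact.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    planted = planted or {}
    rng = np.random.default_rng(seed)
    protected = np.zeros(len(template), dtype=bool)

    rot = planted.get("rotation")
    if rot is not None:
        rot_mask = template.select(rot["selection"])
        if not rot_mask.any():
            raise ValueError("rotation plant: empty selection")
        deg = float(rot["degrees"])
        if not 0.0 <= deg <= 180.0:
            raise ValueError("rotation plant: degrees must be in [0, 180]")
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        pivot = template.coords[rot_mask].mean(axis=0)
        protected |= rot_mask

    hb = planted.get("hbond")
    if hb is not None:
        dmask = template.select(hb["donor"])
        amask = template.select(hb["acceptor"])
        if dmask.sum() != 1 or amask.sum() != 1:
            raise ValueError(
                "hbond plant: donor and acceptor must each select one atom"
            )
        occ = float(hb["occupancy"])
        if not 0.0 <= occ <= 1.0:
            raise ValueError("hbond plant: occupancy must be in [0, 1]")
        d_bound = float(hb.get("bound_distance", 2.8))
        d_free = float(hb.get("unbound_distance", 4.5))
        di, ai = int(np.argmax(dmask)), int(np.argmax(amask))
        if di == ai:
            raise ValueError("hbond plant: donor and acceptor are one atom")
        n_bound = round(occ * n_frames)
        bound_frames = set(rng.permutation(n_frames)[:n_bound].tolist())
        direction = template.coords[ai] - template.coords[di]
        nd = np.linalg.norm(direction)
        direction = direction / nd if nd > 0 else np.array([1.0, 0.0, 0.0])
        protected[di] = protected[ai] = True

    ang = planted.get("angle")
    if ang is not None:
        i_r, j_r, k_r = ang["residues"]
        ch = ang.get("chain", template.chain[0])
        theta = math.radians(float(ang["degrees"]))
        if not 0.0 < float(ang["degrees"]) <= 180.0:
            raise ValueError("angle plant: degrees must be in (0, 180]")
        idx = {}
        for key, rn in (("i", i_r), ("j", j_r), ("k", k_r)):
            m = ((template.chain == ch) & (template.resnum == rn)
                 & (template.name == "CA"))
            if not m.any():
                raise ValueError(f"angle plant: no Cα for residue {rn}")
            idx[key] = int(np.argmax(m))
        if protected[[idx["i"], idx["j"], idx["k"]]].any():
            raise ValueError("angle plant overlaps another plant")
        pi_, pj, pk = (template.coords[idx[key]] for key in ("i", "j", "k"))
        u = pi_ - pj
        u /= np.linalg.norm(u)
        w = pk - pj
        w = w - (w @ u) * u
        nw = np.linalg.norm(w)
        if nw < 1e-9:
            w = np.cross(u, [0.0, 0.0, 1.0])
            if np.linalg.norm(w) < 1e-9:
                w = np.cross(u, [0.0, 1.0, 0.0])
            nw = np.linalg.norm(w)
        w /= nw
        r_k = np.linalg.norm(pk - pj)
        k_new = pj + r_k * (math.cos(theta) * u + math.sin(theta) * w)
        protected[[idx["i"], idx["j"], idx["k"]]] = True

    if hb is not None and rot is not None and (rot_mask[di] or rot_mask[ai]):
        raise ValueError("hbond plant overlaps the rotated domain")

    from scipy.spatial.transform import Rotation as _R

    frames: list[StructureModel] = []
    for f in range(n_frames):
        frame = template.copy()
        frame.model_id = f + 1
        if rot is not None:
            frac = 0.0 if n_frames == 1 else f / (n_frames - 1)
            R = _R.from_rotvec(np.radians(deg * frac) * axis).as_matrix()
            frame.coords[rot_mask] = (
                (frame.coords[rot_mask] - pivot) @ R.T + pivot
            )
        if ang is not None:
            frame.coords[idx["k"]] = k_new
        if hb is not None:
            dist = d_bound if f in bound_frames else d_free
            frame.coords[ai] = frame.coords[di] + dist * direction
        if jitter_sd > 0:
            free = ~protected
            frame.coords[free] += rng.normal(
                0.0, jitter_sd, size=(int(free.sum()), 3))
        frames.append(frame)
    return CoordinateTrajectory(frames)
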