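"""PDB coordinate models: reading, writing, and atom selections.

Coordinates and residue numbers follow the file verbatim (1-based author
numbering); nothing is renumbered.  Alternate locations are resolved by
keeping the highest-occupancy conformer (ties favour altloc 'A').
Multi-MODEL files yield a :class:`CoordinateTrajectory` whose frames share
one atom roster.

Selection strings follow ``chain:resnum[-resnum][@atomname]``; ``*`` matches
every residue of a chain, and comma-separated terms are OR-ed:
``"A:489@CA"``, ``"A:780-800"``, ``"A:*@CA,B:12"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "StructureModel",
    "CoordinateTrajectory",
    "read_structure",
    "write_structure",
    "parse_selection",
]

_SEL_RE = re.compile(
    r"^(?P<chain>[^:]+):(?P<lo>\*|-?\d+)(?:-(?P<hi>-?\d+))?"
    r"(?:@(?P<atom>\S+))?$"
)


@dataclass
class StructureModel:
    """One frame of atomic coordinates, stored as parallel arrays."""

    serial: np.ndarray
    name: np.ndarray       # atom names, str
    resname: np.ndarray
    resnum: np.ndarray     # int, author numbering
    chain: np.ndarray
    altloc: np.ndarray
    coords: np.ndarray     # (n, 3) Å
    occupancy: np.ndarray
    bfactor: np.ndarray
    element: np.ndarray
    het: np.ndarray        # bool, HETATM record
    model_id: int = 1

    def __post_init__(self) -> None:
        n = len(self.serial)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain, self.resnum, self.name, self.altloc))
        if len(set(keys)) != n:
            raise ValueError(
                "(chain, residue number, atom name, altloc) must be unique"
            )

    def __len__(self) -> int:
        return len(self.serial)

    # -- selection ---------------------------------------------------------
    def select(self, selection: str | np.ndarray | None) -> np.ndarray:
        """Boolean mask over atoms for a selection string (None = all)."""
        if selection is None:
            return np.ones(len(self), dtype=bool)
        if isinstance(selection, np.ndarray):
            return selection
        return parse_selection(self, selection)

    def subset(self, selection: str | np.ndarray | None) -> "StructureModel":
        m = self.select(selection)
        return StructureModel(
            self.serial[m], self.name[m], self.resname[m], self.resnum[m],
            self.chain[m], self.altloc[m], self.coords[m],
            self.occupancy[m], self.bfactor[m], self.element[m], self.het[m],
            self.model_id,
        )

    def atom_keys(self) -> list[tuple]:
        """(chain, resnum, atom name) per atom — the mapping identity."""
        return list(zip(self.chain, self.resnum, self.name))

    def heavy(self) -> np.ndarray:
        return self.element != "H"

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "StructureModel":
        """Rigidly transformed copy: x → R·x + t."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + translation
        return out

    def copy(self) -> "StructureModel":
        return StructureModel(
            self.serial.copy(), self.name.copy(), self.resname.copy(),
            self.resnum.copy(), self.chain.copy(), self.altloc.copy(),
            self.coords.copy(), self.occupancy.copy(), self.bfactor.copy(),
            self.element.copy(), self.het.copy(), self.model_id,
        )


@dataclass
class CoordinateTrajectory:
    """Ordered frames sharing one atom roster (MD-snapshot stand-ins)."""

    frames: list[StructureModel]
    times: np.ndarray | None = None  # arbitrary units

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        roster = self.frames[0].atom_keys()
        for i, f in enumerate(self.frames[1:], start=2):
            if f.atom_keys() != roster:
                raise ValueError(f"frame {i} atom roster differs from frame 1")
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> StructureModel:
        return self.frames[i]


def parse_selection(model: StructureModel, selection: str) -> np.ndarray:
    """Evaluate a ``chain:resnum[-resnum][@atom]`` selection to a mask."""
    mask = np.zeros(len(model), dtype=bool)
    for term in selection.split(","):
        term = term.strip()
        m = _SEL_RE.match(term)
        if m is None:
            raise ValueError(
                f"bad selection term {term!r}; expected "
                "'chain:resnum[-resnum][@atomname]'"
            )
        tm = model.chain == m.group("chain")
        if m.group("lo") != "*":
            lo = int(m.group("lo"))
            hi = int(m.group("hi")) if m.group("hi") else lo
            tm &= (model.resnum >= lo) & (model.resnum <= hi)
        if m.group("atom"):
            tm &= model.name == m.group("atom")
        mask |= tm
    return mask


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: str) -> None:
    """Reject malformed fixed-width ATOM/HETATM records with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(
                        f"{path}:{lineno}: ATOM/HETATM record shorter than "
                        "the coordinate columns"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable coordinate field "
                        f"in {line[30:54]!r}"
                    ) from None


def _resolve_altlocs(model: StructureModel) -> StructureModel:
    """Keep the highest-occupancy altloc per atom site; ties favour 'A'."""
    best: dict[tuple, int] = {}
    for i in range(len(model)):
        key = (model.chain[i], model.resnum[i], model.name[i])
        if key not in best:
            best[key] = i
            continue
        j = best[key]
        oi, oj = model.occupancy[i], model.occupancy[j]
        if oi > oj or (oi == oj and model.altloc[i] == "A"):
            best[key] = i
    keep = np.zeros(len(model), dtype=bool)
    keep[list(best.values())] = True
    out = model.subset(keep)
    out.altloc = np.full(len(out), "", dtype=object)
    return out


def _from_gemmi_model(gm: gemmi.Model, model_id: int) -> StructureModel:
    serial, name, resname, resnum, chain, altloc = [], [], [], [], [], []
    xyz, occ, bfac, element, het = [], [], [], [], []
    for ch in gm:
        for res in ch:
            for atom in res:
                serial.append(atom.serial)
                name.append(atom.name)
                resname.append(res.name)
                resnum.append(res.seqid.num)
                chain.append(ch.name)
                altloc.append(atom.altloc if atom.altloc != "\0" else "")
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occ.append(atom.occ)
                bfac.append(atom.b_iso)
                element.append(atom.element.name)
                het.append(res.het_flag == "H")
    if not serial:
        raise ValueError(f"model {model_id} contains no atoms")
    model = StructureModel(
        serial=np.array(serial),
        name=np.array(name, dtype=object),
        resname=np.array(resname, dtype=object),
        resnum=np.array(resnum),
        chain=np.array(chain, dtype=object),
        altloc=np.array(altloc, dtype=object),
        coords=np.array(xyz, dtype=float),
        occupancy=np.array(occ, dtype=float),
        bfactor=np.array(bfac, dtype=float),
        element=np.array(element, dtype=object),
        het=np.array(het, dtype=bool),
        model_id=model_id,
    )
    return _resolve_altlocs(model)


def read_structure(path: str) -> StructureModel | CoordinateTrajectory:
    """Read a PDB file; multi-MODEL files yield a trajectory.

    Altlocs are resolved to the highest-occupancy conformer.  A single-MODEL
    file returns the model directly.
    """
    _validate_pdb_text(str(path))
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no coordinate models found")
    models = [_from_gemmi_model(m, i + 1) for i, m in enumerate(st)]
    if len(models) == 1:
        return models[0]
    return CoordinateTrajectory(models)


def _to_gemmi(models: list[StructureModel]) -> gemmi.Structure:
    st = gemmi.Structure()
    for k, model in enumerate(models, start=1):
        gm = gemmi.Model(k)
        for ch_name in dict.fromkeys(model.chain):
            ch = gemmi.Chain(str(ch_name))
            m = model.chain == ch_name
            for rn in dict.fromkeys(model.resnum[m]):
                rm = m & (model.resnum == rn)
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(int(rn), " ")
                res.name = str(model.resname[np.argmax(rm)])
                res.het_flag = "H" if model.het[np.argmax(rm)] else "A"
                for i in np.nonzero(rm)[0]:
                    a = gemmi.Atom()
                    a.name = str(model.name[i])
                    a.serial = int(model.serial[i])
                    a.pos = gemmi.Position(*model.coords[i])
                    a.occ = float(model.occupancy[i])
                    a.b_iso = float(model.bfactor[i])
                    a.element = gemmi.Element(str(model.element[i]))
                    if model.altloc[i]:
                        a.altloc = str(model.altloc[i])
                    res.add_atom(a)
                ch.add_residue(res)
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(
    obj: StructureModel | CoordinateTrajectory, path: str
) -> None:
    """Write a model or trajectory as a (multi-MODEL) PDB file."""
    models = obj.frames if isinstance(obj, CoordinateTrajectory) else [obj]
    st = _to_gemmi(models)
    st.write_pdb(str(path))
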