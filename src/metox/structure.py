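"""Structure and ensemble parsing for methionine-environment analysis.

PDB input is handled through :mod:`biotite.structure.io.pdb`; this module
wraps it in a small, explicit data model and provides the atom selections
the solvent-environment descriptors are defined on: methionine sulfur
atoms, water oxygens, and Ser/Thr/Tyr side-chain hydroxyl oxygens.

All counting selections are heavy-atom based: a water molecule is
represented by its oxygen and a hydroxyl group by its oxygen, so results
do not depend on whether the input model carries hydrogens.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "Ensemble",
    "MethionineSite",
    "PDBParseError",
    "EmptyStructureError",
    "CongruenceError",
    "BoxError",
    "WATER_RESNAMES",
    "parse_structure",
    "parse_ensemble",
    "load_structure",
    "load_ensemble",
    "write_pdb",
    "select_methionines",
    "select_water_oxygens",
    "select_hydroxyl_oxygens",
    "strip_waters",
]

#: Residue names recognised as water by default (crystallographic and
#: common force-field solvent naming).
WATER_RESNAMES = frozenset({"HOH", "WAT", "SPC", "TIP3", "SOL", "T3P"})

#: Backbone atom names (heavy atoms plus backbone hydrogens) excluded from
#: methionine side-chain selections.
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HN"}
)

#: (residue name, atom name) pairs defining side-chain hydroxyl oxygens.
HYDROXYL_OXYGENS = frozenset({("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")})


class PDBParseError(ValueError):
    """Raised when PDB text cannot be parsed into a structure."""


class EmptyStructureError(PDBParseError):
    """Raised when a parsed structure contains no atoms."""


class CongruenceError(ValueError):
    """Raised when ensemble frames disagree in atom count or order."""


class BoxError(ValueError):
    """Raised for unsupported (non-orthorhombic) or degenerate boxes."""


@dataclass
class StructureModel:
    """A single structural model: parallel per-atom arrays plus a box.

    Atom order is stable; indices into these arrays are the atom handles
    used throughout the package.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    res_id: np.ndarray
    ins_code: np.ndarray
    altloc: np.ndarray
    occupancy: np.ndarray
    coords: np.ndarray
    box: Optional[np.ndarray] = None  # orthorhombic edge lengths (Å)
    hetero: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if self.hetero is None:
            self.hetero = np.zeros(len(self.coords), dtype=bool)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    def residue_label(self, index: int) -> str:
        """Residue number with its insertion code appended verbatim
        (Kabat-style labels such as ``100F`` survive untouched)."""
        return f"{self.res_id[index]}{self.ins_code[index].strip()}"

    def subset(self, mask: np.ndarray) -> "StructureModel":
        mask = np.asarray(mask)
        return StructureModel(
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            res_name=self.res_name[mask],
            chain_id=self.chain_id[mask],
            res_id=self.res_id[mask],
            ins_code=self.ins_code[mask],
            altloc=self.altloc[mask],
            occupancy=self.occupancy[mask],
            coords=self.coords[mask],
            box=None if self.box is None else self.box.copy(),
            hetero=self.hetero[mask],
        )


@dataclass
class Ensemble:
    """A conformational ensemble over one fixed topology."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: Optional[float] = None  # ps, metadata only

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise CongruenceError("frames must be an (n_frames, n_atoms, 3) array")
        if self.frames.shape[0] < 1:
            raise CongruenceError("an ensemble needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise CongruenceError(
                f"frames carry {self.frames.shape[1]} atoms but the topology "
                f"has {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class MethionineSite:
    """One methionine residue and the atom handles its descriptors need."""

    chain_id: str
    residue_label: str
    sulfur_index: int
    sidechain_indices: tuple

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_label}"


# ---------------------------------------------------------------------------
# parsing


def _validate_coordinate_fields(text: str) -> None:
    """Pre-scan ATOM/HETATM records so malformed coordinates are reported
    with their line number instead of an opaque downstream error."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            raw = line.ljust(66)
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fragment = raw[lo:hi].strip()
                try:
                    float(fragment)
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field {fragment!r} on line {lineno}"
                    ) from None


def _orthorhombic_edges(box_matrix: Optional[np.ndarray]) -> Optional[np.ndarray]:
    if box_matrix is None:
        return None
    box_matrix = np.asarray(box_matrix, dtype=float)
    diag = np.diag(box_matrix)
    off = box_matrix - np.diag(diag)
    if np.any(np.abs(off) > 1e-3 * max(1.0, float(np.max(np.abs(diag))))):
        raise BoxError("only orthorhombic boxes are supported (triclinic CRYST1)")
    # placeholder CRYST1 cells (1 1 1) mean "no box"
    if np.all(diag <= 1.1):
        return None
    if np.any(diag <= 0):
        raise BoxError("box edge lengths must be positive")
    return diag.copy()


def _resolve_altlocs(
    chain_id: np.ndarray,
    res_id: np.ndarray,
    ins_code: np.ndarray,
    atom_name: np.ndarray,
    altloc: np.ndarray,
    occupancy: np.ndarray,
) -> np.ndarray:
    """Boolean mask keeping one atom per (chain, resnum, icode, atom name).

    The highest-occupancy conformer wins; ties go to the alphabetically
    first altloc identifier (blank sorts first).
    """
    best: dict = {}
    for i in range(len(atom_name)):
        key = (chain_id[i], int(res_id[i]), ins_code[i], atom_name[i])
        prev = best.get(key)
        if prev is None:
            best[key] = i
            continue
        better = (occupancy[i], _altloc_rank(altloc[i])) > (
            occupancy[prev],
            _altloc_rank(altloc[prev]),
        )
        if better:
            best[key] = i
    mask = np.zeros(len(atom_name), dtype=bool)
    mask[sorted(best.values())] = True
    return mask


def _altloc_rank(alt: str) -> float:
    # higher rank wins a tie; 'A' (and blank) beat later letters
    alt = alt.strip()
    return 0.0 if not alt else -float(ord(alt))


def _from_atom_array(arr: "struc.AtomArray") -> StructureModel:
    altloc = (
        arr.altloc_id
        if "altloc_id" in arr.get_annotation_categories()
        else np.full(arr.array_length(), " ")
    )
    return StructureModel(
        atom_name=np.asarray(arr.atom_name),
        element=np.asarray(arr.element),
        res_name=np.asarray(arr.res_name),
        chain_id=np.asarray(arr.chain_id),
        res_id=np.asarray(arr.res_id, dtype=int),
        ins_code=np.asarray(arr.ins_code),
        altloc=np.asarray(altloc),
        occupancy=np.asarray(arr.occupancy, dtype=float),
        coords=np.asarray(arr.coord, dtype=float),
        box=_orthorhombic_edges(arr.box),
        hetero=np.asarray(arr.hetero, dtype=bool),
    )


def _read_pdb_stack(source: str) -> "struc.AtomArrayStack":
    if not any(line.startswith(("ATOM  ", "HETATM")) for line in source.splitlines()):
        raise EmptyStructureError("PDB input contains no atoms")
    _validate_coordinate_fields(source)
    try:
        pdb_file = PDBFile.read(io.StringIO(source))
        stack = pdb_file.get_structure(altloc="all", extra_fields=["occupancy"])
    except PDBParseError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise PDBParseError(f"could not parse PDB input: {exc}") from exc
    if stack.array_length() == 0:
        raise EmptyStructureError("PDB input contains no atoms")
    return stack


def parse_structure(source: str) -> StructureModel:
    """Parse PDB-format text into a single :class:`StructureModel`.

    If the input carries multiple MODEL records, the first model is used.
    Alternate locations are resolved to one conformer per atom and an
    orthorhombic CRYST1 cell, when present, populates ``box``.
    """
    stack = _read_pdb_stack(source)
    model = _from_atom_array(stack[0])
    mask = _resolve_altlocs(
        model.chain_id,
        model.res_id,
        model.ins_code,
        model.atom_name,
        model.altloc,
        model.occupancy,
    )
    return model.subset(mask)


def parse_ensemble(source: str, frame_interval: Optional[float] = None) -> Ensemble:
    """Parse multi-model PDB text into an :class:`Ensemble`.

    Every model must carry the same atoms in the same order; a
    single-model file degenerates to a one-frame ensemble. Altloc
    resolution is applied once on the topology and the same atom subset
    is used for every frame.
    """
    try:
        stack = _read_pdb_stack(source)
    except PDBParseError as exc:
        message = str(exc).lower()
        if "model" in message and "atom" in message:
            raise CongruenceError(str(exc)) from exc
        raise
    topology = _from_atom_array(stack[0])
    mask = _resolve_altlocs(
        topology.chain_id,
        topology.res_id,
        topology.ins_code,
        topology.atom_name,
        topology.altloc,
        topology.occupancy,
    )
    topology = topology.subset(mask)
    frames = np.asarray(stack.coord, dtype=float)[:, mask, :]
    return Ensemble(topology=topology, frames=frames, frame_interval=frame_interval)


def load_structure(path: str) -> StructureModel:
    with open(path) as handle:
        return parse_structure(handle.read())


def load_ensemble(
    topology_path: str,
    trajectory_path: Optional[str] = None,
    frame_interval: Optional[float] = None,
) -> Ensemble:
    """Load an ensemble from a multi-model PDB, or from a topology PDB
    plus a DCD/XTC trajectory (read through mdtraj, converted to Å)."""
    with open(topology_path) as handle:
        text = handle.read()
    if trajectory_path is None:
        return parse_ensemble(text, frame_interval=frame_interval)
    import mdtraj

    topology = parse_structure(text)
    traj = mdtraj.load(trajectory_path, top=topology_path)
    if traj.n_atoms != topology.n_atoms:
        raise CongruenceError(
            f"trajectory has {traj.n_atoms} atoms, topology {topology.n_atoms}"
        )
    frames = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Å
    if traj.unitcell_lengths is not None and topology.box is None:
        topology = replace(topology, box=np.asarray(traj.unitcell_lengths[0]) * 10.0)
    if frame_interval is None and traj.timestep:
        frame_interval = float(traj.timestep)
    return Ensemble(topology=topology, frames=frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# writing (used by the synthetic-fixture generator and the CLI)


def _to_atom_array(model: StructureModel, coords: Optional[np.ndarray] = None):
    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else model.coords, dtype=np.float32)
    arr.atom_name = model.atom_name
    arr.element = model.element
    arr.res_name = model.res_name
    arr.chain_id = model.chain_id
    arr.res_id = model.res_id
    arr.ins_code = model.ins_code
    arr.hetero = model.hetero
    arr.set_annotation("occupancy", model.occupancy.astype(float))
    if model.box is not None:
        arr.box = np.diag(model.box)
    return arr


def write_pdb(model_or_ensemble) -> str:
    """Serialise a structure or ensemble to PDB text (multi-model for
    ensembles)."""
    pdb_file = PDBFile()
    if isinstance(model_or_ensemble, Ensemble):
        ens = model_or_ensemble
        n = ens.topology.n_atoms
        stack = struc.AtomArrayStack(ens.n_frames, n)
        template = _to_atom_array(ens.topology)
        for cat in template.get_annotation_categories():
            stack.set_annotation(cat, template.get_annotation(cat))
        stack.coord = ens.frames.astype(np.float32)
        if ens.topology.box is not None:
            stack.box = np.repeat(
                np.diag(ens.topology.box)[None, :, :], ens.n_frames, axis=0
            )
        pdb_file.set_structure(stack)
    else:
        pdb_file.set_structure(_to_atom_array(model_or_ensemble))
    buffer = io.StringIO()
    pdb_file.write(buffer)
    return buffer.getvalue()


# ---------------------------------------------------------------------------
# selections


def _residue_groups(model: StructureModel) -> Iterable[tuple]:
    """Yield (key, index array) per residue, in file order."""
    keys = [
        (model.chain_id[i], int(model.res_id[i]), model.ins_code[i], model.res_name[i])
        for i in range(model.n_atoms)
    ]
    seen: dict = {}
    for i, key in enumerate(keys):
        seen.setdefault(key, []).append(i)
    for key, indices in seen.items():
        yield key, np.asarray(indices, dtype=int)


def select_methionines(
    model: StructureModel, treat_mse_as_met: bool = True
) -> list[MethionineSite]:
    """One :class:`MethionineSite` per MET residue carrying its side-chain
    sulfur, ordered by chain then residue number/insertion code.

    Selenomethionine (MSE) is treated as methionine with SE in the SD
    role unless ``treat_mse_as_met`` is disabled. A methionine missing
    its sulfur atom is skipped with a warning, never fatal.
    """
    met_names = {"MET"} | ({"MSE"} if treat_mse_as_met else set())
    sites = []
    for (chain, resnum, icode, resname), indices in _residue_groups(model):
        if resname not in met_names:
            continue
        names = model.atom_name[indices]
        sulfur_local = np.flatnonzero((names == "SD") | (names == "SE"))
        label = f"{resnum}{icode.strip()}"
        if sulfur_local.size == 0:
            warnings.warn(
                f"methionine {chain}:{label} has no SD/SE sulfur atom; site skipped",
                stacklevel=2,
            )
            logger.warning("skipping methionine %s:%s without sulfur", chain, label)
            continue
        sidechain = [
            int(i) for i in indices if model.atom_name[i] not in BACKBONE_ATOMS
        ]
        sites.append(
            MethionineSite(
                chain_id=str(chain),
                residue_label=label,
                sulfur_index=int(indices[sulfur_local[0]]),
                sidechain_indices=tuple(sidechain),
            )
        )
    sites.sort(key=lambda s: (s.chain_id, _label_sort_key(s.residue_label)))
    return sites


def _label_sort_key(label: str) -> tuple:
    digits = "".join(ch for ch in label if ch.isdigit() or ch == "-")
    suffix = label[len(digits):]
    return (int(digits), suffix)


def select_water_oxygens(
    model: StructureModel, water_resnames: Iterable[str] = WATER_RESNAMES
) -> np.ndarray:
    """Indices of water oxygen atoms (one per water molecule)."""
    water_set = set(water_resnames)
    is_water = np.isin(model.res_name, sorted(water_set))
    is_oxygen = (model.element == "O") | (
        (model.element == "") & np.char.startswith(model.atom_name.astype(str), "O")
    )
    return np.flatnonzero(is_water & is_oxygen)


def select_hydroxyl_oxygens(model: StructureModel) -> np.ndarray:
    """Indices of Ser OG, Thr OG1 and Tyr OH side-chain oxygens."""
    mask = np.zeros(model.n_atoms, dtype=bool)
    for resname, atom in HYDROXYL_OXYGENS:
        mask |= (model.res_name == resname) & (model.atom_name == atom)
    return np.flatnonzero(mask)


def strip_waters(
    model: StructureModel, water_resnames: Iterable[str] = WATER_RESNAMES
) -> np.ndarray:
    """Boolean mask of non-water atoms (the protein context for SASA)."""
    return ~np.isin(model.res_name, sorted(set(water_resnames)))
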