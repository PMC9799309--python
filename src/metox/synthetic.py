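"""Synthetic solvated-methionine fixtures with known ground truth.

The generator builds a single idealised methionine residue and places
water oxygens and Ser/Thr/Tyr hydroxyl groups at controlled distances
from the side-chain sulfur, either safely inside or safely outside the
counting shell, so the expected WCN and #OH counts are known exactly by
construction. A margin around the shell boundary guarantees that the
closed-ball (≤) versus open-ball (<) convention can never change a
fixture's truth, and a minimum interatomic distance keeps the SASA
geometry sane.

An optional "cage" fills the space around the side chain with carbon
atoms, mimicking a buried protein interior: cage atoms occlude surface
area but are neither waters nor hydroxyls, so they change SASA without
touching the counts. Ensembles are built by translating selected waters
(or hydroxyl groups) between a fixed inside position and a fixed outside
position according to a per-frame schedule, which keeps the topology
constant while the per-frame ground truth follows the schedule.

No physical realism is claimed for the placements; the point is exact,
independent bookkeeping against which the descriptor code can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure import Ensemble, StructureModel

__all__ = [
    "ProbeSpec",
    "ProbeTruth",
    "EnsembleTruth",
    "PackingError",
    "build_probe",
    "build_ensemble",
]


class PackingError(RuntimeError):
    """Raised when the requested atoms cannot be packed without clashes."""


#: Idealised methionine heavy-atom geometry (Å), translated so the
#: side-chain sulfur SD sits at the origin. Standard bond lengths,
#: approximate tetrahedral angles; no force-field realism claimed.
_MET_TEMPLATE = {
    "N": (-2.108, 3.050, 2.840),
    "CA": (-0.650, 3.050, 2.840),
    "C": (-0.100, 4.470, 2.840),
    "O": (1.110, 4.650, 2.840),
    "CB": (-0.110, 2.270, 1.630),
    "CG": (-0.620, 0.840, 1.490),
    "SD": (0.000, 0.000, 0.000),
    "CE": (-0.750, -1.650, 0.040),
}

_INNER_FLOOR = 2.8  # Å, closest allowed approach of a counted oxygen to SD
_MIN_DIST = 2.4  # Å, global minimum interatomic distance during placement

# minimal heavy-atom stubs carrying each hydroxyl oxygen; offsets are the
# bonded partners' positions relative to the oxygen along the outward axis
_HYDROXYL_STUBS = {
    "SER": ("OG", [("CB", 1.43), ("CA", 2.95)]),
    "THR": ("OG1", [("CB", 1.43), ("CA", 2.95)]),
    "TYR": ("OH", [("CZ", 1.38), ("CE1", 2.77)]),
}


@dataclass
class ProbeSpec:
    """Recipe for one solvated methionine probe.

    ``*_in`` atoms land at SD distances in ``[2.8, shell_radius - jitter]``,
    ``*_out`` atoms in ``[shell_radius + jitter, shell_radius + 10]``.
    ``water_resnames`` are cycled over the water molecules, so mixed
    solvent naming can be exercised. With ``cage=True`` the region
    ``[cage_rmin, cage_rmax]`` around the side-chain centroid is filled
    with as many clash-free carbon atoms as a fixed sampling budget
    finds, burying the side chain.
    """

    n_waters_in: int = 0
    n_waters_out: int = 0
    n_ser_in: int = 0
    n_thr_in: int = 0
    n_tyr_in: int = 0
    n_hydroxyl_out: int = 0
    shell_radius: float = 6.0
    jitter: float = 0.05
    seed: int = 0
    water_resnames: tuple = ("HOH",)
    cage: bool = False
    cage_rmin: float = 2.9
    cage_rmax: float = 6.0
    cage_attempts: int = 6000
    box: Optional[tuple] = None

    def __post_init__(self) -> None:
        counts = (
            self.n_waters_in,
            self.n_waters_out,
            self.n_ser_in,
            self.n_thr_in,
            self.n_tyr_in,
            self.n_hydroxyl_out,
        )
        if min(counts) < 0:
            raise ValueError("atom counts must be non-negative")
        if self.shell_radius <= _INNER_FLOOR:
            raise ValueError("shell_radius must exceed the 2.8 Å inner floor")


@dataclass(frozen=True)
class ProbeTruth:
    """Exact expected shell counts for a probe."""

    wcn: int
    oh: int


@dataclass(frozen=True)
class EnsembleTruth:
    """Exact per-frame shell counts for a scheduled ensemble."""

    wcn_per_frame: tuple
    oh_per_frame: tuple

    @property
    def wcn_mean(self) -> float:
        return float(np.mean(self.wcn_per_frame))

    @property
    def oh_mean(self) -> float:
        return float(np.mean(self.oh_per_frame))


class _AtomList:
    """Accumulates atoms and enforces the minimum-distance constraint."""

    def __init__(self) -> None:
        self.atom_name: list = []
        self.element: list = []
        self.res_name: list = []
        self.chain_id: list = []
        self.res_id: list = []
        self.hetero: list = []
        self.coords: list = []

    def add(self, name, element, resname, chain, resid, coord, hetero=False) -> int:
        self.atom_name.append(name)
        self.element.append(element)
        self.res_name.append(resname)
        self.chain_id.append(chain)
        self.res_id.append(resid)
        self.hetero.append(hetero)
        self.coords.append(np.asarray(coord, dtype=float))
        return len(self.coords) - 1

    def clashes(self, points: np.ndarray, min_dist: float = _MIN_DIST) -> bool:
        if not self.coords:
            return False
        existing = np.asarray(self.coords)
        points = np.atleast_2d(points)
        d2 = ((existing[None, :, :] - points[:, None, :]) ** 2).sum(axis=2)
        return bool((d2 < min_dist**2).any())

    def to_model(self, box=None) -> StructureModel:
        n = len(self.coords)
        return StructureModel(
            atom_name=np.asarray(self.atom_name),
            element=np.asarray(self.element),
            res_name=np.asarray(self.res_name),
            chain_id=np.asarray(self.chain_id),
            res_id=np.asarray(self.res_id, dtype=int),
            ins_code=np.asarray([""] * n),
            altloc=np.asarray([" "] * n),
            occupancy=np.ones(n),
            coords=np.asarray(self.coords),
            box=None if box is None else np.asarray(box, dtype=float),
            hetero=np.asarray(self.hetero, dtype=bool),
        )


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_shell_position(
    rng: np.random.Generator,
    atoms: _AtomList,
    lo: float,
    hi: float,
    partners: Sequence[tuple] = (),
    max_tries: int = 4000,
) -> tuple:
    """A clash-free position with SD distance in [lo, hi], plus partner
    positions stacked outward along the radial direction."""
    if hi < lo:
        raise PackingError(f"empty placement interval [{lo:.2f}, {hi:.2f}]")
    for _ in range(max_tries):
        direction = _random_direction(rng)
        distance = rng.uniform(lo, hi)
        position = distance * direction
        partner_positions = [position + offset * direction for _, offset in partners]
        candidate = np.vstack([position] + partner_positions) if partners else position
        if not atoms.clashes(candidate):
            return position, partner_positions
    raise PackingError(
        f"could not place an atom in the SD-distance range [{lo:.2f}, {hi:.2f}] "
        "without steric overlap; fewer atoms or a larger shell is needed"
    )


def _add_methionine(atoms: _AtomList) -> None:
    for name, coord in _MET_TEMPLATE.items():
        atoms.add(name, name[0], "MET", "H", 100, coord)


def _add_hydroxyl(
    atoms: _AtomList, rng, resname: str, resid: int, lo: float, hi: float
) -> np.ndarray:
    oxygen_name, partners = _HYDROXYL_STUBS[resname]
    position, partner_positions = _sample_shell_position(rng, atoms, lo, hi, partners)
    atoms.add(oxygen_name, "O", resname, "S", resid, position)
    for (partner_name, _), coord in zip(partners, partner_positions):
        atoms.add(partner_name, "C", resname, "S", resid, coord)
    return position


def _fill_cage(atoms: _AtomList, rng, spec: ProbeSpec) -> int:
    sidechain = np.asarray(
        [_MET_TEMPLATE[name] for name in ("CB", "CG", "SD", "CE")]
    )
    centroid = sidechain.mean(axis=0)
    placed = 0
    for _ in range(spec.cage_attempts):
        direction = _random_direction(rng)
        radius = spec.cage_rmin + (spec.cage_rmax - spec.cage_rmin) * rng.uniform() ** (
            1.0 / 3.0
        )
        position = centroid + radius * direction
        if atoms.clashes(position):
            continue
        atoms.add("C", "C", "CAG", "X", 900 + placed, position, hetero=True)
        placed += 1
    return placed


def build_probe(spec: ProbeSpec) -> tuple[StructureModel, ProbeTruth]:
    """Build one probe structure and its exact expected shell counts."""
    rng = np.random.default_rng(spec.seed)
    atoms = _AtomList()
    _add_methionine(atoms)
    margin = max(spec.jitter, 0.05)
    inner = (_INNER_FLOOR, spec.shell_radius - margin)
    outer = (spec.shell_radius + margin, spec.shell_radius + 10.0)

    resid = 200
    for resname, count in (
        ("SER", spec.n_ser_in),
        ("THR", spec.n_thr_in),
        ("TYR", spec.n_tyr_in),
    ):
        for _ in range(count):
            _add_hydroxyl(atoms, rng, resname, resid, *inner)
            resid += 1
    for _ in range(spec.n_hydroxyl_out):
        _add_hydroxyl(atoms, rng, "SER", resid, *outer)
        resid += 1

    water_id = 1
    for k in range(spec.n_waters_in):
        resname = spec.water_resnames[k % len(spec.water_resnames)]
        position, _ = _sample_shell_position(rng, atoms, *inner)
        atoms.add("O", "O", resname, "W", water_id, position, hetero=True)
        water_id += 1
    for k in range(spec.n_waters_out):
        resname = spec.water_resnames[k % len(spec.water_resnames)]
        position, _ = _sample_shell_position(rng, atoms, *outer)
        atoms.add("O", "O", resname, "W", water_id, position, hetero=True)
        water_id += 1

    if spec.cage:
        _fill_cage(atoms, rng, spec)

    truth = ProbeTruth(
        wcn=spec.n_waters_in,
        oh=spec.n_ser_in + spec.n_thr_in + spec.n_tyr_in,
    )
    return atoms.to_model(box=spec.box), truth


def build_ensemble(
    spec: ProbeSpec,
    waters_in_per_frame: Sequence[int],
    hydroxyls_in_per_frame: Optional[Sequence[int]] = None,
) -> tuple[Ensemble, EnsembleTruth]:
    """Build a fixed-topology ensemble whose per-frame counts follow a
    schedule exactly.

    ``waters_in_per_frame[k]`` waters sit inside the shell in frame
    ``k``; the remaining scheduled waters are translated to their
    outside position. ``hydroxyls_in_per_frame`` does the same with
    scheduled SER hydroxyl groups, on top of the static hydroxyls from
    ``spec``. Static atoms (methionine, cage, ``spec`` waters and
    hydroxyls) never move.
    """
    schedule = [int(k) for k in waters_in_per_frame]
    if not schedule:
        raise ValueError("the schedule needs at least one frame")
    if min(schedule) < 0:
        raise ValueError("scheduled water counts must be non-negative")
    oh_schedule = (
        [int(k) for k in hydroxyls_in_per_frame]
        if hydroxyls_in_per_frame is not None
        else [0] * len(schedule)
    )
    if len(oh_schedule) != len(schedule):
        raise ValueError("water and hydroxyl schedules differ in length")

    n_water_slots = max(schedule)
    n_oh_slots = max(oh_schedule) if oh_schedule else 0

    rng = np.random.default_rng(spec.seed)
    atoms = _AtomList()
    _add_methionine(atoms)
    margin = max(spec.jitter, 0.05)
    inner = (_INNER_FLOOR, spec.shell_radius - margin)
    outer = (spec.shell_radius + margin, spec.shell_radius + 10.0)

    # static hydroxyls requested by the ProbeSpec
    resid = 200
    for resname, count in (
        ("SER", spec.n_ser_in),
        ("THR", spec.n_thr_in),
        ("TYR", spec.n_tyr_in),
    ):
        for _ in range(count):
            _add_hydroxyl(atoms, rng, resname, resid, *inner)
            resid += 1
    for _ in range(spec.n_hydroxyl_out):
        _add_hydroxyl(atoms, rng, "SER", resid, *outer)
        resid += 1

    # scheduled hydroxyl slots: sample an inside and an outside pose for
    # the whole stub; both poses are kept clash-free against everything
    oxygen_name, partners = _HYDROXYL_STUBS["SER"]
    oh_slots = []  # (atom indices, in-coords, out-coords)
    for _ in range(n_oh_slots):
        pos_in, part_in = _sample_shell_position(rng, atoms, *inner, partners)
        idx = [atoms.add(oxygen_name, "O", "SER", "S", resid, pos_in)]
        for (pname, _), coord in zip(partners, part_in):
            idx.append(atoms.add(pname, "C", "SER", "S", resid, coord))
        pos_out, part_out = _sample_shell_position(rng, atoms, *outer, partners)
        oh_slots.append(
            (
                idx,
                np.vstack([pos_in] + part_in),
                np.vstack([pos_out] + part_out),
            )
        )
        resid += 1

    # scheduled water slots, same in/out trick
    water_slots = []
    water_id = 1
    for k in range(n_water_slots):
        resname = spec.water_resnames[k % len(spec.water_resnames)]
        pos_in, _ = _sample_shell_position(rng, atoms, *inner)
        idx = atoms.add("O", "O", resname, "W", water_id, pos_in, hetero=True)
        pos_out, _ = _sample_shell_position(rng, atoms, *outer)
        water_slots.append((idx, pos_in, pos_out))
        water_id += 1
    for k in range(spec.n_waters_out):
        resname = spec.water_resnames[k % len(spec.water_resnames)]
        position, _ = _sample_shell_position(rng, atoms, *outer)
        atoms.add("O", "O", resname, "W", water_id, position, hetero=True)
        water_id += 1

    if spec.cage:
        _fill_cage(atoms, rng, spec)

    for n_in in schedule:
        if n_in > n_water_slots:
            raise ValueError("schedule exceeds the number of water slots")
    for n_in in oh_schedule:
        if n_in > n_oh_slots:
            raise ValueError("schedule exceeds the number of hydroxyl slots")

    base = atoms.to_model(box=spec.box)
    frames = np.empty((len(schedule), base.n_atoms, 3))
    for f, (n_wat, n_oh) in enumerate(zip(schedule, oh_schedule)):
        coords = base.coords.copy()
        for slot, (idx, pos_in, pos_out) in enumerate(water_slots):
            coords[idx] = pos_in if slot < n_wat else pos_out
        for slot, (idx, stub_in, stub_out) in enumerate(oh_slots):
            coords[np.asarray(idx)] = stub_in if slot < n_oh else stub_out
        frames[f] = coords

    static_oh = spec.n_ser_in + spec.n_thr_in + spec.n_tyr_in
    truth = EnsembleTruth(
        wcn_per_frame=tuple(schedule),
        oh_per_frame=tuple(static_oh + n for n in oh_schedule),
    )
    topology = base.subset(np.ones(base.n_atoms, dtype=bool))
    topology.coords = frames[0].copy()
    if spec.box is not None:
        topology.box = np.asarray(spec.box, dtype=float)
    return Ensemble(topology=topology, frames=frames), truth
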