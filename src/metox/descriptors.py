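"""Per-methionine solvent-environment descriptors.

Four quantities characterise how accessible a methionine side chain is to
oxidants:

* **sSASA** — solvent-accessible surface area of the side chain computed
  on a single (static) structure, via the Shrake–Rupley quadrature;
* **dSASA** — the same area averaged over the frames of a conformational
  ensemble;
* **WCN** — 2-shell water coordination number: mean number of water
  molecules (represented by their oxygen) within 6 Å of the side-chain
  sulfur;
* **#OH** — mean number of Ser/Thr/Tyr side-chain hydroxyl groups
  (represented by their oxygen) within the same 6 Å shell.

SASA is computed with all solvent stripped — it is a property of the
protein surface — whereas WCN explicitly counts the solvent, so shell
counts are taken with waters present. Absolute areas are converted to
percentages of a per-residue maximum-allowed area so a single relative
threshold applies across residue types.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import (
    Ensemble,
    MethionineSite,
    StructureModel,
    WATER_RESNAMES,
    select_hydroxyl_oxygens,
    select_water_oxygens,
    strip_waters,
)

__all__ = [
    "DescriptorParams",
    "DescriptorRecord",
    "VDW_RADII",
    "MAX_SASA_THEORETICAL",
    "MAX_SASA_EMPIRICAL",
    "count_within_radius",
    "fibonacci_sphere",
    "shrake_rupley",
    "sidechain_sasa",
    "relative_sasa",
    "ensemble_descriptors",
    "records_to_frame",
    "TABLE_COLUMNS",
]

#: Element-keyed van der Waals radii (Å). A conventional single-atom set;
#: configurable through :class:`DescriptorParams`.
VDW_RADII: dict = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
_DEFAULT_RADIUS = 1.70

#: Maximum allowed solvent accessibility per residue (Å²), theoretical
#: normalisation of Tien et al. (2013). Used to express areas in percent.
MAX_SASA_THEORETICAL: dict = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.4, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
MAX_SASA_THEORETICAL["MSE"] = MAX_SASA_THEORETICAL["MET"]

#: Empirical alternative normalisation from the same reference.
MAX_SASA_EMPIRICAL: dict = {
    "ALA": 121.0, "ARG": 265.0, "ASN": 187.0, "ASP": 187.0, "CYS": 148.0,
    "GLU": 214.0, "GLN": 214.0, "GLY": 97.0, "HIS": 216.0, "ILE": 195.0,
    "LEU": 191.0, "LYS": 230.0, "MET": 203.0, "PHE": 228.0, "PRO": 154.0,
    "SER": 143.0, "THR": 163.0, "TRP": 264.0, "TYR": 255.0, "VAL": 165.0,
}
MAX_SASA_EMPIRICAL["MSE"] = MAX_SASA_EMPIRICAL["MET"]


@dataclass
class DescriptorParams:
    """Tunables of the descriptor computation.

    shell_radius
        Radius (Å) of the solvation shell around the sulfur; 6 Å spans
        roughly two hydration shells.
    probe_radius
        Solvent probe radius (Å) for SASA; 1.4 Å models a water molecule.
    sphere_points
        Quadrature points per atom for Shrake–Rupley; 960 keeps the
        quadrature error well under a percent.
    """

    shell_radius: float = 6.0
    probe_radius: float = 1.4
    sphere_points: int = 960
    use_pbc: bool = True
    radii_set: Mapping[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    max_sasa_reference: Mapping[str, float] = field(
        default_factory=lambda: dict(MAX_SASA_THEORETICAL)
    )
    water_resnames: frozenset = WATER_RESNAMES

    def __post_init__(self) -> None:
        if self.shell_radius <= 0:
            raise ValueError("shell_radius must be positive")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if self.sphere_points < 32:
            raise ValueError("sphere_points must be at least 32")

    def radius_of(self, element: str) -> float:
        return float(self.radii_set.get(str(element).upper(), _DEFAULT_RADIUS))


@dataclass
class DescriptorRecord:
    """Per-site descriptor values, absolute and relative."""

    site: MethionineSite
    sSASA_abs: float
    sSASA_rel: float
    dSASA_abs: float
    dSASA_rel: float
    WCN: float
    OH: float
    n_frames: int


TABLE_COLUMNS = [
    "molecule_id",
    "chain",
    "residue_label",
    "sSASA_abs",
    "sSASA_rel",
    "dSASA_abs",
    "dSASA_rel",
    "WCN",
    "OH",
    "n_frames",
]


# ---------------------------------------------------------------------------
# shell counting


def count_within_radius(
    frame: np.ndarray,
    center_index: int,
    candidates: Sequence[int],
    radius: float,
    box: Optional[np.ndarray] = None,
) -> int:
    """Number of candidate atoms within ``radius`` (closed ball, ≤) of the
    center atom, under the minimum-image convention if a box is given.

    The ≤ convention makes the measure-zero boundary case deterministic.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    candidates = np.asarray(candidates, dtype=int)
    candidates = candidates[candidates != center_index]
    if candidates.size == 0:
        return 0
    diff = frame[candidates] - frame[center_index]
    if box is not None:
        box = np.asarray(box, dtype=float)
        if np.any(box < 2.0 * radius):
            raise ValueError(
                f"box edges {box} are smaller than twice the shell radius "
                f"{radius}; the shell would overlap its own periodic image"
            )
        diff -= box * np.round(diff / box)
    dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return int(np.count_nonzero(dist <= radius))


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


_SPHERE_CACHE: dict = {}


def _sphere(n: int) -> np.ndarray:
    if n not in _SPHERE_CACHE:
        _SPHERE_CACHE[n] = fibonacci_sphere(n)
    return _SPHERE_CACHE[n]


def shrake_rupley(
    frame: np.ndarray,
    radii: np.ndarray,
    params: Optional[DescriptorParams] = None,
    targets: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Each atom is inflated by the probe radius and covered with
    ``params.sphere_points`` quasi-uniform test points; a point is
    accessible when it lies outside every neighbouring inflated sphere.
    The accessible fraction times the inflated-sphere area gives the
    atom's SASA. With ``targets`` given, only those atoms are evaluated
    (all atoms still act as occluders); other entries are zero.
    """
    params = params or DescriptorParams()
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all atom radii must be positive")
    n = frame.shape[0]
    if targets is None:
        targets = range(n)
    probe = params.probe_radius
    inflated = radii + probe
    unit = _sphere(params.sphere_points)
    tree = cKDTree(frame)
    max_reach = float(inflated.max())
    areas = np.zeros(n, dtype=float)
    for i in targets:
        r_i = inflated[i]
        neighbors = tree.query_ball_point(frame[i], r_i + max_reach)
        neighbors = [j for j in neighbors if j != i]
        points = frame[i] + r_i * unit
        accessible = np.ones(len(points), dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(frame[j] - frame[i])
            if d < 1e-6:
                warnings.warn(
                    f"atoms {i} and {j} share coordinates; degenerate geometry",
                    stacklevel=2,
                )
            if d >= r_i + inflated[j]:
                continue
            diff = points - frame[j]
            accessible &= np.einsum("ij,ij->i", diff, diff) >= inflated[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * r_i * r_i * accessible.mean()
    return areas


def sidechain_sasa(
    model: StructureModel,
    site: MethionineSite,
    params: Optional[DescriptorParams] = None,
    coords: Optional[np.ndarray] = None,
) -> float:
    """SASA (Å²) of one methionine side chain in its protein context.

    All solvent is stripped before the calculation; ``coords`` overrides
    the topology coordinates so ensemble frames reuse one topology.
    """
    params = params or DescriptorParams()
    if not site.sidechain_indices:
        raise ValueError(f"site {site.label} has no side-chain atoms")
    frame = model.coords if coords is None else np.asarray(coords, dtype=float)
    protein_mask = strip_waters(model, params.water_resnames)
    protein_indices = np.flatnonzero(protein_mask)
    index_map = {int(g): k for k, g in enumerate(protein_indices)}
    local_targets = [index_map[i] for i in site.sidechain_indices if i in index_map]
    if not local_targets:
        raise ValueError(f"side chain of {site.label} vanished after water stripping")
    sub_coords = frame[protein_indices]
    radii = np.array([params.radius_of(e) for e in model.element[protein_indices]])
    areas = shrake_rupley(sub_coords, radii, params, targets=local_targets)
    return float(areas[local_targets].sum())


def relative_sasa(
    abs_area: float, resname: str, params: Optional[DescriptorParams] = None
) -> float:
    """Express an absolute area as percent of the residue's maximum
    allowed area. Values above 100% are possible if the reference
    maximum is exceeded and are flagged with a warning."""
    params = params or DescriptorParams()
    reference = params.max_sasa_reference
    if resname not in reference:
        known = ", ".join(sorted(reference))
        raise KeyError(
            f"no maximum-SASA reference for residue {resname!r}; known: {known}"
        )
    rel = 100.0 * abs_area / float(reference[resname])
    if rel > 100.0:
        warnings.warn(
            f"relative SASA {rel:.1f}% exceeds the reference maximum for {resname}",
            stacklevel=2,
        )
    return rel


# ---------------------------------------------------------------------------
# ensemble averaging


def ensemble_descriptors(
    ensemble: Ensemble,
    sites: Sequence[MethionineSite],
    params: Optional[DescriptorParams] = None,
    static_model: Optional[StructureModel] = None,
) -> list[DescriptorRecord]:
    """Time-averaged descriptors for every site of an ensemble.

    WCN and #OH are arithmetic means over frames of the per-frame shell
    counts; dSASA is the mean per-frame side-chain SASA (waters stripped
    each frame); sSASA comes from ``static_model`` when supplied,
    otherwise from the topology's reference coordinates (the first
    frame). Frames are weighted equally.
    """
    params = params or DescriptorParams()
    if ensemble.n_frames < 1:
        raise ValueError("ensemble has no frames")
    topology = ensemble.topology
    water_idx = select_water_oxygens(topology, params.water_resnames)
    hydroxyl_idx = select_hydroxyl_oxygens(topology)
    box = topology.box if params.use_pbc else None

    static = static_model if static_model is not None else topology
    records = []
    for site in sites:
        resname = str(topology.res_name[site.sulfur_index])
        water_counts = np.empty(ensemble.n_frames)
        oh_counts = np.empty(ensemble.n_frames)
        dsasa_frames = np.empty(ensemble.n_frames)
        for f in range(ensemble.n_frames):
            frame = ensemble.frames[f]
            water_counts[f] = count_within_radius(
                frame, site.sulfur_index, water_idx, params.shell_radius, box
            )
            oh_counts[f] = count_within_radius(
                frame, site.sulfur_index, hydroxyl_idx, params.shell_radius, box
            )
            dsasa_frames[f] = sidechain_sasa(topology, site, params, coords=frame)
        if static_model is not None:
            static_sites = {
                (s.chain_id, s.residue_label): s
                for s in _matching_sites(static, sites)
            }
            s_site = static_sites[(site.chain_id, site.residue_label)]
            ssasa = sidechain_sasa(static, s_site, params)
            s_resname = str(static.res_name[s_site.sulfur_index])
        else:
            ssasa = sidechain_sasa(topology, site, params, coords=ensemble.frames[0])
            s_resname = resname
        dsasa = float(dsasa_frames.mean())
        records.append(
            DescriptorRecord(
                site=site,
                sSASA_abs=ssasa,
                sSASA_rel=relative_sasa(ssasa, s_resname, params),
                dSASA_abs=dsasa,
                dSASA_rel=relative_sasa(dsasa, resname, params),
                WCN=float(water_counts.mean()),
                OH=float(oh_counts.mean()),
                n_frames=ensemble.n_frames,
            )
        )
    return records


def _matching_sites(model: StructureModel, sites: Sequence[MethionineSite]):
    from .structure import select_methionines

    return select_methionines(model)


def records_to_frame(
    records: Sequence[DescriptorRecord], molecule_id: str = "molecule"
) -> pd.DataFrame:
    """Flatten descriptor records into the table contract consumed by the
    classifier and evaluation stages."""
    rows = [
        {
            "molecule_id": molecule_id,
            "chain": r.site.chain_id,
            "residue_label": r.site.residue_label,
            "sSASA_abs": r.sSASA_abs,
            "sSASA_rel": r.sSASA_rel,
            "dSASA_abs": r.dSASA_abs,
            "dSASA_rel": r.dSASA_rel,
            "WCN": r.WCN,
            "OH": r.OH,
            "n_frames": r.n_frames,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
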