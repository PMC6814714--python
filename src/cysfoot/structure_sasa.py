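"""Solvent-accessible surface area and salt-bridge geometry from PDB structures.

SASA is computed with the Shrake-Rupley sphere-point method: each atom's van
der Waals sphere is inflated by the probe radius (1.4 Å, a water molecule),
test points are distributed quasi-uniformly on the inflated sphere, and the
accessible area is the exposed-point fraction times the sphere area. The
cysteine side chain (CB + SG, plus attached hydrogens when present) is the
reporting unit for thiol accessibility; multi-model PDB files are treated as
coordinate frames of a trajectory, supporting per-frame SASA and
salt-bridge distance series.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "VDW_RADII",
    "AtomRecord",
    "StructureModel",
    "SASAResult",
    "read_structure",
    "write_structure",
    "shrake_rupley",
    "cys_side_chain_sasa",
    "salt_bridge_distance",
    "labeling_sasa_correlation",
    "sphere_points",
]

logger = logging.getLogger(__name__)

#: Bondi-type van der Waals radii, Å.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_RADIUS = 1.70

#: Side-chain charged-group heavy atoms for salt-bridge distances.
CHARGED_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}

_CYS_SIDE_CHAIN = {"CB", "SG", "HB1", "HB2", "HB3", "HG", "HG1"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure (coordinates of the first frame, Å)."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    xyz: tuple[float, float, float]
    element: str
    vdw_radius: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.xyz):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: non-positive radius")


@dataclass
class StructureModel:
    """Atoms plus one or more coordinate frames.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; single-structure input
    has one frame. Annotation arrays are parallel to the atom axis.
    """

    names: np.ndarray
    residue_names: np.ndarray
    chains: np.ndarray
    residue_numbers: np.ndarray
    elements: np.ndarray
    radii: np.ndarray
    coords: np.ndarray
    serials: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        n = self.coords.shape[1]
        for arr_name in ("names", "residue_names", "chains",
                         "residue_numbers", "elements", "radii"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length != atom count {n}")
        if self.serials is None:
            self.serials = np.arange(1, n + 1)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                residue_name=str(self.residue_names[i]),
                chain=str(self.chains[i]),
                residue_number=int(self.residue_numbers[i]),
                xyz=tuple(self.coords[0, i]),
                element=str(self.elements[i]),
                vdw_radius=float(self.radii[i]),
            )
            for i in range(self.n_atoms)
        ]


def _assign_radii(elements: np.ndarray) -> np.ndarray:
    radii = np.empty(len(elements), dtype=float)
    unknown = set()
    for i, el in enumerate(elements):
        el_up = str(el).strip().upper()
        if el_up in VDW_RADII:
            radii[i] = VDW_RADII[el_up]
        else:
            radii[i] = DEFAULT_RADIUS
            if el_up:
                unknown.add(el_up)
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}: default radius "
            f"{DEFAULT_RADIUS} Å assigned"
        )
    return radii


def read_structure(
    path: str | Path,
    *,
    chain: str | None = None,
    strip_hetero: bool = True,
    strip_waters: bool = True,
) -> StructureModel:
    """Read a PDB file; multi-model files become coordinate frames.

    Waters and (optionally) other hetero records are stripped; unknown
    elements get the default radius with a warning.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()  # AtomArrayStack, frames = models
    except Exception as exc:
        raise ValueError(f"{path}: PDB parse error: {exc}") from exc
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms")

    mask = np.ones(stack.array_length(), dtype=bool)
    if strip_waters:
        mask &= ~struc.filter_solvent(stack)
    if strip_hetero:
        mask &= ~stack.hetero
    if chain is not None:
        mask &= stack.chain_id == chain
    stack = stack[..., mask]
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms left after filtering")

    elements = stack.element
    return StructureModel(
        names=np.asarray(stack.atom_name),
        residue_names=np.asarray(stack.res_name),
        chains=np.asarray(stack.chain_id),
        residue_numbers=np.asarray(stack.res_id),
        elements=np.asarray(elements),
        radii=_assign_radii(elements),
        coords=np.asarray(stack.coord, dtype=float),
    )


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a (multi-model) PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = []
    for f in range(model.n_frames):
        arr = struc.AtomArray(model.n_atoms)
        arr.coord = model.coords[f]
        arr.atom_name = model.names
        arr.res_name = model.residue_names
        arr.chain_id = model.chains
        arr.res_id = model.residue_numbers
        arr.element = model.elements
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (Fibonacci/golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SASAResult:
    """Per-atom and per-residue side-chain accessible areas, Å²."""

    atom_sasa: np.ndarray  # (n_frames, n_atoms)
    residue_side_chain_sasa: dict[tuple[str, int, str], np.ndarray]
    probe_radius: float
    n_points: int


def _sasa_one_frame(
    coords: np.ndarray,
    radii_ext: np.ndarray,
    points: np.ndarray,
) -> np.ndarray:
    """Shrake-Rupley exposed areas for one coordinate frame.

    ``radii_ext`` are vdW radii already inflated by the probe.
    """
    n = len(coords)
    areas = np.empty(n)
    tree = cKDTree(coords)
    max_r = radii_ext.max()
    # all pairs that can possibly intersect
    neighbors = tree.query_ball_tree(tree, 2.0 * max_r)
    for i in range(n):
        ri = radii_ext[i]
        nbrs = [j for j in neighbors[i]
                if j != i
                and np.dot(coords[j] - coords[i], coords[j] - coords[i])
                < (ri + radii_ext[j]) ** 2]
        if not nbrs:
            areas[i] = 4.0 * math.pi * ri * ri
            continue
        pts = coords[i] + ri * points  # (P, 3)
        nb_xyz = coords[nbrs]  # (M, 3)
        nb_r2 = radii_ext[nbrs] ** 2
        d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < nb_r2[None, :]).any(axis=1)
        areas[i] = 4.0 * math.pi * ri * ri * (1.0 - buried.mean())
    return areas


def shrake_rupley(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SASAResult:
    """Per-atom SASA for every frame of a structure.

    For each atom, ``n_points`` test points are placed on a sphere of radius
    r_vdw + probe; points inside any neighbor's inflated sphere are buried,
    and SASA = exposed fraction × 4π(r_vdw + probe)².
    """
    if model.n_atoms < 1:
        raise ValueError("structure has no atoms")
    if probe_radius < 0 or n_points < 1:
        raise ValueError("invalid probe radius or point count")
    points = sphere_points(n_points)
    radii_ext = model.radii + probe_radius
    atom_sasa = np.stack([
        _sasa_one_frame(model.coords[f], radii_ext, points)
        for f in range(model.n_frames)
    ])

    residue_sasa: dict[tuple[str, int, str], np.ndarray] = {}
    for key in _residue_keys(model):
        chain, resnum, resname = key
        side = _side_chain_mask(model, chain, resnum)
        residue_sasa[key] = atom_sasa[:, side].sum(axis=1)
    return SASAResult(
        atom_sasa=atom_sasa,
        residue_side_chain_sasa=residue_sasa,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def _residue_keys(model: StructureModel) -> list[tuple[str, int, str]]:
    seen: dict[tuple[str, int, str], None] = {}
    for c, rn, rname in zip(model.chains, model.residue_numbers,
                            model.residue_names):
        seen.setdefault((str(c), int(rn), str(rname)), None)
    return list(seen)


_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3", "HA2", "HA3"}


def _side_chain_mask(model: StructureModel, chain: str, resnum: int) -> np.ndarray:
    in_res = (model.chains.astype(str) == chain) & (model.residue_numbers == resnum)
    side = np.array([n not in _BACKBONE for n in model.names.astype(str)])
    return in_res & side


def cys_side_chain_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    sasa: SASAResult | None = None,
) -> dict[tuple[str, int], np.ndarray]:
    """Side-chain (CB + SG + attached H) SASA per cysteine, per frame.

    Returns a mapping (chain, residue_number) → array of length n_frames.
    Emits a warning and returns empty when the structure has no cysteines.
    """
    if sasa is None:
        sasa = shrake_rupley(model, probe_radius, n_points)
    out: dict[tuple[str, int], np.ndarray] = {}
    names = model.names.astype(str)
    for chain, resnum, resname in _residue_keys(model):
        if resname != "CYS":
            continue
        in_res = (model.chains.astype(str) == chain) & (
            model.residue_numbers == resnum
        )
        side = in_res & np.isin(names, list(_CYS_SIDE_CHAIN))
        out[(chain, resnum)] = sasa.atom_sasa[:, side].sum(axis=1)
    if not out:
        warnings.warn("structure contains no cysteine residues")
    return out


def salt_bridge_distance(
    model: StructureModel,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
    *,
    rupture_cutoff: float = 4.5,
    rupture_dwell: int = 1,
) -> tuple[np.ndarray, int | None]:
    """Per-frame minimum distance between two residues' charged groups, Å.

    Residues are addressed as (chain, residue_number) and must be of
    salt-bridge-capable types (ASP/GLU vs LYS/ARG/HIS). Returns the distance
    series and the first frame index at which the bridge has remained beyond
    ``rupture_cutoff`` for ``rupture_dwell`` consecutive frames (None if it
    never ruptures). Symmetric in its residue arguments.
    """
    idx_a, atoms_a = _charged_atoms(model, residue_a)
    idx_b, atoms_b = _charged_atoms(model, residue_b)
    xyz_a = model.coords[:, idx_a]  # (F, Ma, 3)
    xyz_b = model.coords[:, idx_b]
    d = np.sqrt(
        ((xyz_a[:, :, None, :] - xyz_b[:, None, :, :]) ** 2).sum(axis=3)
    )
    series = d.reshape(model.n_frames, -1).min(axis=1)

    rupture_frame: int | None = None
    run = 0
    for f, dist in enumerate(series):
        run = run + 1 if dist > rupture_cutoff else 0
        if run >= rupture_dwell:
            rupture_frame = f - rupture_dwell + 1
            break
    return series, rupture_frame


def _charged_atoms(
    model: StructureModel, residue: tuple[str, int]
) -> tuple[np.ndarray, tuple[str, ...]]:
    chain, resnum = residue
    in_res = (model.chains.astype(str) == str(chain)) & (
        model.residue_numbers == int(resnum)
    )
    if not in_res.any():
        raise ValueError(f"residue {residue} not found")
    resname = str(model.residue_names[in_res][0])
    if resname not in CHARGED_GROUP_ATOMS:
        raise ValueError(
            f"residue {residue} ({resname}) is not salt-bridge capable; "
            f"expected one of {sorted(CHARGED_GROUP_ATOMS)}"
        )
    wanted = CHARGED_GROUP_ATOMS[resname]
    names = model.names.astype(str)
    idx = np.where(in_res & np.isin(names, wanted))[0]
    if len(idx) == 0:
        raise ValueError(
            f"residue {residue} ({resname}) lacks charged-group atoms "
            f"{wanted}"
        )
    return idx, wanted


def labeling_sasa_correlation(
    ratios: dict[int, float] | Sequence[tuple[int, float]],
    sasa: dict[int, float],
) -> tuple[float, float, int]:
    """Pearson r and Spearman ρ between labeling ratios and per-site SASA.

    ``ratios`` maps residue index → labeling ratio (SiteEstimate.ratio);
    ``sasa`` maps residue index → side-chain SASA in Å². Computed over the
    shared site set, which must have at least 3 sites.
    """
    from scipy import stats

    if not isinstance(ratios, dict):
        ratios = dict(ratios)
    shared = sorted(set(ratios) & set(sasa))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared sites, got {len(shared)}")
    x = np.array([ratios[s] for s in shared])
    y = np.array([sasa[s] for s in shared])
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman, len(shared)
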