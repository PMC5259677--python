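"""Density-map and structure I/O plus the shared geometric primitives.

All geometry is expressed in physical ångströms.  A voxel with index
``(i, j, k)`` occupies the cube whose *center* sits at
``origin + (i + 0.5, j + 0.5, k + 0.5) * voxel_size`` — the voxel-center
convention keeps surface fitting free of half-voxel bias.

MRC/CCP4 reading and writing is delegated to :mod:`gemmi`; PDB SHEET
records are likewise parsed by gemmi.  A sidecar JSON strand list
(``{"sheet_id": ..., "strands": [[{"chain": ..., "resseq": ...}, ...], ...]}``)
is accepted as an alternative strand source for structures whose SHEET
records are incomplete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "Point3",
    "DensityMap",
    "RigidTransform",
    "StrandAnnotation",
    "DegenerateMapError",
    "read_density_map",
    "write_density_map",
    "read_strands",
    "apply_transform",
]

#: Alias for a single 3-D point in Å — a shape-``(3,)`` float array.
#: Polylines and point lists are shape-``(n, 3)`` arrays throughout.
Point3 = np.ndarray


class DegenerateMapError(ValueError):
    """Raised for maps with no occupied voxels (all-zero or over-thresholded)."""


@dataclass
class DensityMap:
    """A 3-D scalar density on a regular grid.

    Parameters
    ----------
    values
        Density per voxel, indexed ``values[i, j, k]`` along (x, y, z).
    voxel_size
        Å per voxel along each axis (all > 0).
    origin
        Physical position (Å) of the corner of voxel ``(0, 0, 0)``.
    threshold
        Absolute density value above which a voxel counts as occupied.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("density grid must be 3-D with dimensions >= 1")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def occupied_mask(self) -> np.ndarray:
        return self.values > self.threshold

    def occupied_points(self) -> np.ndarray:
        """Physical centers (Å) of all above-threshold voxels, shape (n, 3)."""
        idx = np.argwhere(self.occupied_mask())
        if len(idx) == 0:
            raise DegenerateMapError("map has no voxels above threshold")
        return self.origin + (idx + 0.5) * self.voxel_size

    def occupied_values(self) -> np.ndarray:
        return self.values[self.occupied_mask()].astype(float)

    def point_of_index(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p' = R p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def from_rotation(cls, R: np.ndarray) -> "RigidTransform":
        return cls(R, np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def apply_transform(points: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Apply a rigid transform to one point or an ``(n, 3)`` array of points."""
    return t.apply(points)


@dataclass
class StrandAnnotation:
    """Ordered Cα lists for the strands of one β-sheet.

    ``strands[i]`` is an ``(n_i, 3)`` array of Cα coordinates in sheet order;
    ``residue_ids[i]`` the matching ``(chain, resseq)`` labels.
    """

    sheet_id: str
    strands: list[np.ndarray]
    residue_ids: list[list[tuple[str, int]]] = field(default_factory=list)

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.strands)


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O

def read_density_map(
    path: str | Path,
    threshold: float = 0.3,
    threshold_policy: str = "fraction",
) -> DensityMap:
    """Read an MRC/CCP4 volume into a :class:`DensityMap`.

    ``threshold_policy`` is ``"fraction"`` (threshold is a fraction of the map
    maximum, the default for simulated maps) or ``"absolute"`` (threshold is a
    raw density value, required for experimental maps whose scale is
    instrument-dependent).
    """
    ccp4 = gemmi.read_ccp4_map(str(path))
    grid = ccp4.grid
    values = np.array(grid, copy=True).astype(np.float32)
    uc = grid.unit_cell
    shape = values.shape
    voxel_size = np.array([uc.a / shape[0], uc.b / shape[1], uc.c / shape[2]])
    # MRC-2014 ORIGIN words (50-52); fall back to NXSTART-based origin.
    origin = np.array([ccp4.header_float(i) for i in (50, 51, 52)])
    if np.all(origin == 0.0):
        start = np.array(
            [ccp4.header_i32(5), ccp4.header_i32(6), ccp4.header_i32(7)], dtype=float
        )
        origin = start * voxel_size
    vmax = float(values.max())
    if vmax <= 0:
        raise DegenerateMapError(f"{path}: map is empty (max density {vmax})")
    if threshold_policy == "fraction":
        abs_threshold = threshold * vmax
    elif threshold_policy == "absolute":
        abs_threshold = threshold
    else:
        raise ValueError(f"unknown threshold_policy {threshold_policy!r}")
    dmap = DensityMap(values, voxel_size, origin, threshold=abs_threshold)
    if not dmap.occupied_mask().any():
        raise DegenerateMapError(f"{path}: no voxels above threshold {abs_threshold}")
    return dmap


def write_density_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a :class:`DensityMap` as an MRC-2014 file (P1, origin in header)."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    nx, ny, nz = dmap.shape
    vx, vy, vz = dmap.voxel_size
    grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Strand annotations

def _ca_coords_for_range(
    chain: gemmi.Chain, first: int, last: int
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    coords, ids = [], []
    for res in chain:
        if first <= res.seqid.num <= last:
            ca = res.find_atom("CA", "*")
            if ca is not None:
                coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
                ids.append((chain.name, res.seqid.num))
    return np.asarray(coords, dtype=float), ids


def read_strands(
    path: str | Path,
    sheet_id: str,
    strand_list: str | Path | None = None,
    min_residues: int = 3,
) -> StrandAnnotation:
    """Extract ordered strand Cα lists for one sheet of a PDB structure.

    Strand membership comes from the structure's SHEET records, or from a
    sidecar JSON file when ``strand_list`` is given.  Strands with fewer
    than ``min_residues`` Cα atoms are dropped (the observed-trace
    construction needs at least three consecutive Cα atoms).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    ranges: list[tuple[str, int, int]] = []

    if strand_list is not None:
        data = json.loads(Path(strand_list).read_text())
        if data.get("sheet_id") != sheet_id:
            raise KeyError(
                f"sheet {sheet_id!r} not found in strand list {strand_list}"
            )
        for strand in data["strands"]:
            chain = strand[0]["chain"]
            nums = [r["resseq"] for r in strand]
            ranges.append((chain, min(nums), max(nums)))
    else:
        sheet = next((sh for sh in st.sheets if sh.name == sheet_id), None)
        if sheet is None:
            available = [sh.name for sh in st.sheets]
            raise KeyError(
                f"sheet {sheet_id!r} not found in {path} (available: {available})"
            )
        for s in sheet.strands:
            ranges.append(
                (s.start.chain_name, s.start.res_id.seqid.num, s.end.res_id.seqid.num)
            )

    strands, residue_ids = [], []
    for chain_name, first, last in ranges:
        chain = model.find_chain(chain_name)
        if chain is None:
            continue
        coords, ids = _ca_coords_for_range(chain, first, last)
        if len(coords) < min_residues:
            continue  # too short to define an observed trace
        strands.append(coords)
        residue_ids.append(ids)
    if not strands:
        raise ValueError(f"sheet {sheet_id!r} in {path} has no usable strands")
    return StrandAnnotation(sheet_id=sheet_id, strands=strands, residue_ids=residue_ids)
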