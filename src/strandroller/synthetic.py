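"""Synthetic β-barrel models with known ground truth, rendered to density.

The generator places Cα atoms at a 3.3 Å rise along helical paths on an
elliptical cylinder.  Every path keeps a constant angle (the tilt α) with
the cylinder axis, consecutive paths are offset so the perpendicular
interstrand spacing is d (4.8 Å by default), and the first and last
strands end up adjacent — a closed barrel.  For a circular barrel this
fixes the radius: the circumference must hold n strands at horizontal
spacing d / cos α, so

    a = n d / (2 π cos α).

Density is simulated as a sum of isotropic Gaussians whose width follows
the common simulation convention of a Fourier amplitude falling to 1/e at
spatial frequency 1/resolution, i.e. real-space σ = resolution / (π √2).
At the 10 Å resolution and 1 Å/voxel sampling used throughout, adjacent
strands blur into a single shell of density — the regime the detector is
built for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import gemmi
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import ellipe

from .io_core import DensityMap

__all__ = [
    "CA_RISE",
    "BarrelSpec",
    "GroundTruth",
    "derive_semi_axis",
    "generate_ideal_barrel",
    "simulate_density",
    "write_ca_pdb",
    "write_fixture_suite",
    "FIXTURE_N_STRANDS",
    "FIXTURE_TILTS",
]

CA_RISE = 3.3  # Å between consecutive Calpha atoms along a beta-strand

FIXTURE_N_STRANDS = (6, 8, 12, 16, 22)
FIXTURE_TILTS = (35.0, 45.0, 55.0)


def _ellipse_perimeter_factor(ratio: float) -> float:
    """Perimeter of an ellipse with semi-axes (1, ratio): 4 E(e^2)."""
    return float(4.0 * ellipe(1.0 - ratio * ratio))


def derive_semi_axis(n_strands: int, tilt_deg: float, d: float, ratio: float = 1.0) -> float:
    """Major semi-axis of a closed barrel: perimeter = n d / cos(tilt)."""
    perimeter = n_strands * d / np.cos(np.radians(tilt_deg))
    return perimeter / _ellipse_perimeter_factor(ratio)


@dataclass
class BarrelSpec:
    """Geometry of one ideal barrel.

    Leave ``a`` unset to derive the semi-axis from the closure constraint;
    ``b`` defaults to ``a`` (circular).  ``end_raggedness`` is the maximum
    random axial offset (Å) applied per strand, drawn uniformly with
    ``seed``.
    """

    n_strands: int = 8
    tilt_deg: float = 45.0
    residues_per_strand: int = 10
    d: float = 4.8
    a: float | None = None
    b: float | None = None
    end_raggedness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strands < 4:
            raise ValueError("a barrel needs at least 4 strands")
        if not 0.0 <= self.tilt_deg < 90.0:
            raise ValueError("tilt must lie in [0, 90) degrees")
        if self.d <= 0:
            raise ValueError("interstrand distance must be positive")
        ratio = 1.0 if self.b is None or self.a is None else self.b / self.a
        if self.a is None:
            self.a = derive_semi_axis(self.n_strands, self.tilt_deg, self.d, ratio)
            if self.b is not None:
                # b was given as an absolute length: honour the ratio instead
                ratio = self.b / self.a
                self.a = derive_semi_axis(self.n_strands, self.tilt_deg, self.d, ratio)
        if self.b is None:
            self.b = self.a
        if self.a <= 0 or self.b <= 0:
            raise ValueError("semi-axes must be positive")
        perimeter = self.a * _ellipse_perimeter_factor(self.b / self.a)
        target = self.n_strands * self.d / np.cos(np.radians(self.tilt_deg))
        if abs(perimeter - target) > 0.01 * target:
            raise ValueError(
                f"closure violated: perimeter {perimeter:.2f} Å vs required "
                f"{target:.2f} Å for {self.n_strands} strands at {self.tilt_deg}°"
            )

    @classmethod
    def elliptical(cls, ratio: float, **kwargs) -> "BarrelSpec":
        """Spec with semi-axis ratio b/a < 1 satisfying the closure constraint."""
        tmp = cls(**{**kwargs, "a": None, "b": None})
        a = derive_semi_axis(tmp.n_strands, tmp.tilt_deg, tmp.d, ratio)
        return cls(**{**kwargs, "a": a, "b": a * ratio})


@dataclass
class GroundTruth:
    """A generated barrel with everything the evaluation needs."""

    spec: BarrelSpec
    ca_atoms: list[np.ndarray]  # per-strand ordered Calpha coordinates
    observed_traces: list = field(default_factory=list)
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def all_atoms(self) -> np.ndarray:
        return np.vstack(self.ca_atoms)

    def to_json(self, path: str | Path) -> None:
        spec = asdict(self.spec)
        payload = {
            "spec": spec,
            "ca_atoms": [np.round(s, 6).tolist() for s in self.ca_atoms],
            "observed_traces": [
                np.round(t.control_points, 6).tolist() for t in self.observed_traces
            ],
            "axis_direction": self.axis_direction.tolist(),
            "axis_point": self.axis_point.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Barrel generation

def _arc_tables(a: float, b: float, n: int = 8192):
    """Dense parametric-angle/arc-length/azimuth tables for one ellipse."""
    psi = np.linspace(0.0, 2.0 * np.pi, n + 1)
    x, y = a * np.cos(psi), b * np.sin(psi)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return psi, s


def _theta_of_z(a: float, b: float, psi0: float, tilt_deg: float, z_grid: np.ndarray) -> np.ndarray:
    """Integrate the constant-tilt path: g(ψ) dψ/dz = tan α with the local
    azimuthal speed g(ψ) = sqrt(a² sin²ψ + b² cos²ψ)."""
    tan_a = np.tan(np.radians(tilt_deg))
    psi = np.empty_like(z_grid)
    psi[0] = psi0
    if tan_a == 0.0:
        psi[:] = psi0
        return psi

    def g(p):
        return np.hypot(a * np.sin(p), b * np.cos(p))

    for i in range(1, len(z_grid)):
        dz = z_grid[i] - z_grid[i - 1]
        # RK4 on dψ/dz = tanα / g(ψ)
        p = psi[i - 1]
        k1 = tan_a / g(p)
        k2 = tan_a / g(p + 0.5 * dz * k1)
        k3 = tan_a / g(p + 0.5 * dz * k2)
        k4 = tan_a / g(p + dz * k3)
        psi[i] = p + dz * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    return psi


def generate_ideal_barrel(spec: BarrelSpec) -> GroundTruth:
    """Place Cα atoms along constant-tilt helical paths on the barrel.

    Strand k starts at azimuthal arc position k·h (h = d / cos α) at
    mid-height; atoms advance 3.3 Å along the path (3.3 cos α axially).
    Strand direction alternates, as in an antiparallel barrel; a per-strand
    random axial offset models ragged ends.  Deterministic given the seed.
    """
    from .evaluate import build_observed_trace

    a, b = spec.a, spec.b
    h = spec.d / np.cos(np.radians(spec.tilt_deg))
    psi_tab, s_tab = _arc_tables(a, b)
    perimeter = s_tab[-1]
    rng = np.random.default_rng(spec.seed)

    n_res = spec.residues_per_strand
    dz = CA_RISE * np.cos(np.radians(spec.tilt_deg))
    z_vals = (np.arange(n_res) - (n_res - 1) / 2.0) * dz

    ca_atoms = []
    for k in range(spec.n_strands):
        s_k = (k * h) % perimeter
        psi0 = float(np.interp(s_k, s_tab, psi_tab))
        z_k = z_vals.copy()
        if spec.end_raggedness > 0:
            z_k = z_k + rng.uniform(-spec.end_raggedness, spec.end_raggedness)
        psi = _theta_of_z(a, b, psi0, spec.tilt_deg, z_k)
        pts = np.column_stack([a * np.cos(psi), b * np.sin(psi), z_k])
        if k % 2 == 1:  # antiparallel alternation
            pts = pts[::-1]
        ca_atoms.append(pts)

    observed = [build_observed_trace(cas) for cas in ca_atoms]
    return GroundTruth(spec=spec, ca_atoms=ca_atoms, observed_traces=observed)


# ---------------------------------------------------------------------------
# Density simulation

def simulate_density(
    atoms: np.ndarray,
    resolution: float = 10.0,
    apix: float = 1.0,
    padding: float = 8.0,
    threshold_fraction: float = 0.3,
    normalize: bool = True,
    grid_bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> DensityMap:
    """Render point scatterers to a density map at a stated resolution.

    Each atom contributes an isotropic Gaussian with real-space
    σ = resolution / (π √2); the grid covers the atoms plus ``padding`` Å
    on each side and the map is normalised to a maximum of 1.  Atoms are
    deposited with trilinear weights before a single Gaussian convolution,
    which keeps the simulation linear in its input.
    """
    atoms = np.atleast_2d(np.asarray(atoms, dtype=float))
    if len(atoms) < 1:
        raise ValueError("need at least one atom")
    if resolution <= 2.0 * apix:
        raise ValueError(
            f"resolution {resolution} Å must exceed twice the sampling "
            f"({2 * apix} Å) to satisfy Nyquist"
        )
    if grid_bounds is not None:
        lo, hi = grid_bounds
    else:
        lo = atoms.min(axis=0) - padding
        hi = atoms.max(axis=0) + padding
    origin = np.floor(lo / apix) * apix
    shape = np.ceil((hi - origin) / apix).astype(int) + 1
    grid = np.zeros(shape, dtype=np.float64)

    # trilinear deposition onto voxel centers at origin + (idx + 0.5) * apix
    f = (atoms - origin) / apix - 0.5
    i0 = np.floor(f).astype(int)
    frac = f - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                idx = i0 + (dx, dy, dz)
                np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), w)

    sigma = resolution / (np.pi * np.sqrt(2.0))
    grid = gaussian_filter(grid, sigma=sigma / apix, mode="constant", truncate=5.0)
    if normalize:
        vmax = grid.max()
        if vmax > 0:
            grid /= vmax
    return DensityMap(
        grid.astype(np.float32),
        np.full(3, apix),
        origin,
        threshold=threshold_fraction,
    )


# ---------------------------------------------------------------------------
# PDB output and the deterministic fixture suite

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


def write_ca_pdb(
    ca_atoms: list[np.ndarray], path: str | Path, sheet_id: str = "BRL"
) -> None:
    """Write per-strand Cα lists as a PDB with one chain per strand and
    SHEET records naming ``sheet_id``."""
    st = gemmi.Structure()
    st.name = "synthetic beta-barrel"
    model = gemmi.Model("1")
    sheet = gemmi.Sheet(sheet_id)
    for k, strand in enumerate(ca_atoms):
        chain_name = _CHAIN_IDS[k % len(_CHAIN_IDS)]
        chain = gemmi.Chain(chain_name)
        for ri, p in enumerate(strand, start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(ri, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, p))
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        s = gemmi.Sheet.Strand()
        s.start = gemmi.AtomAddress(chain_name, gemmi.SeqId(1, " "), "ALA", "")
        s.end = gemmi.AtomAddress(chain_name, gemmi.SeqId(len(strand), " "), "ALA", "")
        s.sense = 0 if k == 0 else -1
        sheet.strands.append(s)
    st.add_model(model)
    st.sheets.append(sheet)
    st.setup_entities()
    st.write_pdb(str(path))


def fixture_specs(base_seed: int = 0) -> list[tuple[str, BarrelSpec]]:
    """The deterministic (name, spec) grid behind the fixture suite."""
    out = []
    idx = 0
    for n in FIXTURE_N_STRANDS:
        for tilt in FIXTURE_TILTS:
            for shape in ("circ", "ell"):
                seed = base_seed + idx
                if shape == "circ":
                    spec = BarrelSpec(
                        n_strands=n, tilt_deg=tilt, residues_per_strand=10, seed=seed
                    )
                else:
                    spec = BarrelSpec.elliptical(
                        ratio=0.8,
                        n_strands=n,
                        tilt_deg=tilt,
                        residues_per_strand=10,
                        end_raggedness=1.0,
                        seed=seed,
                    )
                out.append((f"barrel_n{n:02d}_t{int(tilt)}_{shape}", spec))
                idx += 1
    return out


def write_fixture_suite(
    out_dir: str | Path,
    resolution: float = 10.0,
    apix: float = 1.0,
    base_seed: int = 0,
) -> dict:
    """Emit the (map, PDB, ground-truth JSON) fixture triples plus manifest.

    The grid spans n in {6, 8, 12, 16, 22} strands, tilt in {35°, 45°, 55°},
    circular and elliptical (b/a = 0.8) shapes — 30 fixtures, byte-identical
    across reruns with the same seed.
    """
    from .io_core import write_density_map

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, spec in fixture_specs(base_seed):
        truth = generate_ideal_barrel(spec)
        dmap = simulate_density(truth.all_atoms, resolution=resolution, apix=apix)
        write_density_map(dmap, out_dir / f"{name}.mrc")
        write_ca_pdb(truth.ca_atoms, out_dir / f"{name}.pdb")
        truth.to_json(out_dir / f"{name}_truth.json")
        entries.append(
            {
                "name": name,
                "map": f"{name}.mrc",
                "pdb": f"{name}.pdb",
                "truth": f"{name}_truth.json",
                "n_strands": spec.n_strands,
                "tilt_deg": spec.tilt_deg,
                "shape": "circular" if spec.a == spec.b else "elliptical",
                "seed": spec.seed,
            }
        )
    manifest = {
        "resolution": resolution,
        "apix": apix,
        "base_seed": base_seed,
        "fixtures": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
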