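"""Recursive β-trace generation on the barrel surface model.

A β-trace is produced by tilting the barrel axis by α and projecting the
tilted line onto the discrete surface: stepping along the path, the local
direction keeps angle α with the axis, i.e. dθ/dz = tan α / r(z, θ) with
r the local surface radius.  The next trace starts a horizontal arc
distance

    h = d / cos α,   d = 4.8 Å

around the mid-height cross-section from the previous one, and traces are
added until the loop would close on the first trace.  Sampling tilt angles
every 5° between 35° and 55° with three translations per tilt yields
fifteen candidate sets per barrel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .barrel_model import BarrelSurfaceModel, surface_lookup
from .io_core import RigidTransform

__all__ = [
    "DEFAULT_TILTS",
    "GenerationParams",
    "BetaTrace",
    "TraceSet",
    "horizontal_spacing",
    "generate_initial_trace",
    "generate_trace_set",
    "generate_all",
    "write_trace_set_json",
    "write_trace_set_pdb",
]

DEFAULT_TILTS = (35.0, 40.0, 45.0, 50.0, 55.0)
INTERSTRAND_DISTANCE = 4.8  # Å, hydrogen-bond constrained


@dataclass
class GenerationParams:
    """Knobs of the trace-generation sweep.

    ``tilt_deg_values`` are the candidate strand tilt angles (degrees from
    the barrel axis); ``n_translations`` evenly spaced azimuthal phase
    offsets are tried per tilt; ``d`` is the interstrand spacing in Å;
    ``sample_step`` the arc-length spacing of points along each trace;
    ``tilt_sign`` the handedness of the azimuthal advance.
    """

    tilt_deg_values: tuple[float, ...] = DEFAULT_TILTS
    n_translations: int = 3
    d: float = INTERSTRAND_DISTANCE
    sample_step: float = 1.0
    tilt_sign: int = 1

    def __post_init__(self) -> None:
        if any(not (0.0 < t < 90.0) for t in self.tilt_deg_values):
            raise ValueError("tilt angles must lie in (0, 90) degrees")
        if self.d <= 0 or self.sample_step <= 0 or self.n_translations < 1:
            raise ValueError("d, sample_step must be > 0 and n_translations >= 1")
        if self.tilt_sign not in (-1, 1):
            raise ValueError("tilt_sign must be +1 or -1")


@dataclass
class BetaTrace:
    points: np.ndarray  # ordered (n, 3) polyline, Å
    index: int = 0
    low_confidence: bool = False  # surface-gap fallback dominated the samples


@dataclass
class TraceSet:
    traces: list[BetaTrace]
    tilt_deg: float
    translation_offset: float
    frame: str = "axis"  # "axis" (aligned) or "map" (original)


def horizontal_spacing(tilt_deg: float, d: float = INTERSTRAND_DISTANCE) -> float:
    """Azimuthal arc offset between consecutive traces: h = d / cos(tilt)."""
    if not 0.0 <= tilt_deg < 90.0:
        raise ValueError("tilt angle must lie in [0, 90) degrees")
    return d / np.cos(np.radians(tilt_deg))


# ---------------------------------------------------------------------------
# Path integration on the surface

def _integrate_path(
    model: BarrelSurfaceModel,
    z_start: float,
    az_start: float,
    tilt_deg: float,
    sample_step: float,
    sign: int,
    z_stop: float,
) -> tuple[list[np.ndarray], int, int]:
    """March along the surface from (z_start, az_start) toward ``z_stop``
    keeping angle ``tilt_deg`` with the axis.  Returns the sampled points
    (excluding the start), the sample count and fallback count."""
    alpha = np.radians(tilt_deg)
    dz_step = sample_step * np.cos(alpha)
    direction = 1.0 if z_stop >= z_start else -1.0
    arc_step = sign * sample_step * np.sin(alpha) * direction
    z, az = z_start, az_start
    pts: list[np.ndarray] = []
    n_fallback = 0
    n_samples = 0
    while True:
        remaining = (z_stop - z) * direction
        if remaining <= 1e-9:
            break
        dz = min(dz_step, remaining)
        scale = dz / dz_step if dz_step > 0 else 1.0
        _, r, _, fb = surface_lookup(model, z, az, with_info=True)
        az = az + scale * arc_step / max(r, 1e-6)
        z = z + direction * dz
        p, _, _, fb2 = surface_lookup(model, z, az, with_info=True)
        pts.append(p)
        n_samples += 1
        n_fallback += int(fb or fb2)
    return pts, n_samples, n_fallback


def generate_initial_trace(
    model: BarrelSurfaceModel,
    tilt_deg: float,
    azimuth0: float,
    params: GenerationParams | None = None,
    z_anchor: float | None = None,
    index: int = 0,
) -> BetaTrace:
    """One β-trace across the full axial extent of the surface.

    The path is anchored at ``(z_anchor, azimuth0)`` (mid-height by
    default) and integrated down to z_min and up to z_max so that the
    anchor azimuth is exact where the inter-trace spacing is enforced.
    """
    params = params or GenerationParams()
    if len(model.slices) < 2:
        raise ValueError("surface model must span at least 2 slices")
    if z_anchor is None:
        z_anchor = 0.5 * (model.z_min + model.z_max)
    p0, _, _, fb0 = surface_lookup(model, z_anchor, azimuth0, with_info=True)
    down, n_dn, f_dn = _integrate_path(
        model, z_anchor, azimuth0, tilt_deg, params.sample_step,
        params.tilt_sign, model.z_min,
    )
    up, n_up, f_up = _integrate_path(
        model, z_anchor, azimuth0, tilt_deg, params.sample_step,
        params.tilt_sign, model.z_max,
    )
    pts = list(reversed(down)) + [p0] + up
    n_samples = n_dn + n_up + 1
    n_fallback = f_dn + f_up + int(fb0)
    return BetaTrace(
        points=np.asarray(pts),
        index=index,
        low_confidence=n_fallback > 0.5 * n_samples,
    )


def _mid_surface_arc_table(model: BarrelSurfaceModel, n: int = 1024):
    """Cumulative arc length vs azimuth along the mid-height cross-section.

    Uses the mid slice's refined ellipse (fit to the selected surface
    points, so it sits on the density ridge rather than mid-annulus); the
    smooth curve avoids the length inflation a jagged voxel ring would add.
    """
    fit = model.mid_slice().fit
    psi = np.linspace(0.0, 2.0 * np.pi, n + 1)
    pts = fit.point_at(psi)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    rel = pts - fit.center
    az = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    return s, az, float(s[-1])


def generate_trace_set(
    model: BarrelSurfaceModel,
    tilt_deg: float,
    translation_offset: float,
    params: GenerationParams | None = None,
) -> TraceSet:
    """All β-traces of a closed barrel for one (tilt, phase) choice.

    Consecutive trace anchors advance by the horizontal spacing h along the
    mid-height cross-section; generation stops before the cumulative
    advance comes within h/2 of closing the loop, which yields
    round(P / h) traces on an ideal barrel of perimeter P.
    """
    params = params or GenerationParams()
    h = horizontal_spacing(tilt_deg, params.d)
    s_tab, az_tab, perimeter = _mid_surface_arc_table(model)
    if h >= perimeter:
        raise ValueError(
            f"horizontal spacing {h:.2f} Å exceeds barrel perimeter "
            f"{perimeter:.2f} Å (barrel too small for tilt {tilt_deg}°)"
        )
    traces = []
    k = 0
    while k * h < perimeter - h / 2.0:
        s_k = (translation_offset + params.tilt_sign * k * h) % perimeter
        az_k = float(np.interp(s_k, s_tab, az_tab))
        traces.append(
            generate_initial_trace(model, tilt_deg, az_k, params, index=k)
        )
        k += 1
    return TraceSet(
        traces=traces,
        tilt_deg=tilt_deg,
        translation_offset=translation_offset,
        frame="axis",
    )


def generate_all(
    model: BarrelSurfaceModel,
    params: GenerationParams | None = None,
    back_transform: RigidTransform | None = None,
) -> list[TraceSet]:
    """The full candidate sweep: one trace set per (tilt, translation).

    Translations are evenly spaced offsets {0, h/n, ...} of the horizontal
    spacing at each tilt; defaults (5 tilts x 3 translations) produce the
    fifteen candidate sets.  With ``back_transform`` given, every set is
    returned in the original map frame.
    """
    params = params or GenerationParams()
    sets = []
    for tilt in params.tilt_deg_values:
        h = horizontal_spacing(tilt, params.d)
        for i in range(params.n_translations):
            offset = i * h / params.n_translations
            tset = generate_trace_set(model, tilt, offset, params)
            if back_transform is not None:
                tset = TraceSet(
                    traces=[
                        BetaTrace(
                            points=back_transform.apply(t.points),
                            index=t.index,
                            low_confidence=t.low_confidence,
                        )
                        for t in tset.traces
                    ],
                    tilt_deg=tset.tilt_deg,
                    translation_offset=tset.translation_offset,
                    frame="map",
                )
            sets.append(tset)
    return sets


# ---------------------------------------------------------------------------
# Output writers

def write_trace_set_json(sets: list[TraceSet], path: str | Path) -> None:
    payload = {
        "sets": [
            {
                "tilt_deg": s.tilt_deg,
                "translation_offset": round(s.translation_offset, 6),
                "frame": s.frame,
                "traces": [np.round(t.points, 4).tolist() for t in s.traces],
            }
            for s in sets
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_trace_set_pdb(tset: TraceSet, path: str | Path) -> None:
    """Write one trace set as a Cα-pseudoatom PDB, one chain per trace."""
    import gemmi

    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    st = gemmi.Structure()
    st.name = "beta traces"
    model = gemmi.Model("1")
    for t in tset.traces:
        chain = gemmi.Chain(chains[t.index % len(chains)])
        for ri, p in enumerate(t.points, start=1):
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(ri, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, p))
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
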