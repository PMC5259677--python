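"""End-to-end orchestration: density map in, candidate trace sets out."""

from __future__ import annotations

from dataclasses import dataclass

from .barrel_model import (
    AxisResult,
    BarrelSurfaceModel,
    build_surface,
    center_map,
    find_axis,
)
from .io_core import DensityMap, RigidTransform
from .trace_gen import GenerationParams, TraceSet, generate_all

__all__ = ["DetectionResult", "detect"]


@dataclass
class DetectionResult:
    axis: AxisResult
    surface: BarrelSurfaceModel
    trace_sets: list[TraceSet]  # in the original map frame
    to_axis_frame: RigidTransform  # map frame -> axis-aligned frame


def detect(
    dmap: DensityMap,
    params: GenerationParams | None = None,
    coarse_step_deg: float = 5.0,
    refine_step_deg: float = 1.0,
    slice_thickness: float | None = None,
    n_angular_bins: int = 72,
    max_axis_points: int = 4000,
) -> DetectionResult:
    """Run the full detection chain on one segmented barrel density map.

    The map is centered, the barrel axis found by exhaustive search and
    aligned with +z, the discrete surface model built from cross-sections,
    and the candidate β-trace sets generated and returned in the original
    map frame.
    """
    params = params or GenerationParams()
    centered, t_center = center_map(dmap)
    axis = find_axis(
        centered,
        coarse_step_deg=coarse_step_deg,
        refine_step_deg=refine_step_deg,
        max_points=max_axis_points,
    )
    to_axis = axis.transform.compose(t_center)
    surface = build_surface(
        centered, axis, slice_thickness=slice_thickness, n_angular_bins=n_angular_bins
    )
    sets = generate_all(surface, params, back_transform=to_axis.inverse())
    return DetectionResult(
        axis=axis, surface=surface, trace_sets=sets, to_axis_frame=to_axis
    )
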