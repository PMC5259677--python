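"""Accuracy protocol for detected β-traces.

The observed β-trace of a strand is the polyline through the geometric
centers of every three consecutive Cα atoms, capped by the two terminal Cα
atoms.  Detected and observed traces are compared with a symmetric two-way
curve distance

    D_k = ( mean_i d(i, S'_k) + mean_j d(j, S_k) ) / 2

where ``d`` is the point-to-polyline projection distance (distance to the
nearer polyline end when the foot of the projection falls outside), both
curves being resampled at a uniform arc-length step.  Sets of traces are
put in one-to-one correspondence by the optimal assignment minimising the
summed D_k, the overall distance D is the mean over matched pairs, and an
amino acid counts as detected when its Cα lies strictly within a cutoff
(default 2.5 Å, about half the interstrand spacing) of the matched
detected trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ObservedTrace",
    "Matching",
    "EvaluationReport",
    "resample_polyline",
    "build_observed_trace",
    "directed_point_distance",
    "pair_two_way_distance",
    "match_traces",
    "overall_distance",
    "aa_coverage",
    "evaluate_set",
    "evaluate_sets",
    "select_best_set",
    "load_benchmark_table",
    "aggregate_benchmark",
]

DEFAULT_SAMPLE_STEP = 1.0  # Å, arc-length resampling step for distance sums
DEFAULT_COVERAGE_CUTOFF = 2.5  # Å, about half the beta-strand spacing


@dataclass
class ObservedTrace:
    """Central line of one β-strand derived from its Cα atoms."""

    points: np.ndarray  # resampled polyline used in distance sums
    control_points: np.ndarray  # ends + sliding-window centers
    source_strand: list | None = None


@dataclass
class Matching:
    """One-to-one correspondence between detected and observed traces."""

    pairs: list[tuple[int, int]]
    unmatched_detected: list[int]
    unmatched_observed: list[int]
    distance_matrix: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.pairs)


@dataclass
class EvaluationReport:
    per_pair: list[float]
    overall: float
    n_detected_strands: int
    n_observed_strands: int
    aa_detected: int
    aa_total: int
    tilt_deg: float | None = None
    translation_offset: float | None = None
    matching: Matching | None = None

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.aa_detected / self.aa_total if self.aa_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_detected_strands": self.n_detected_strands,
            "n_observed_strands": self.n_observed_strands,
            "two_way_distance": self.overall,
            "per_pair_distance": list(self.per_pair),
            "aa_detected": self.aa_detected,
            "aa_total": self.aa_total,
            "coverage_percent": self.coverage_percent,
            "tilt_deg": self.tilt_deg,
            "translation_offset": self.translation_offset,
        }


# ---------------------------------------------------------------------------
# Polyline primitives

def resample_polyline(points: np.ndarray, step: float = DEFAULT_SAMPLE_STEP) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing.

    Both end points are retained; the number of samples is chosen so the
    actual spacing never exceeds ``step``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[[0, -1]].copy()
    n = max(2, int(np.ceil(total / step)) + 1)
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])


def build_observed_trace(ca: np.ndarray, step: float = DEFAULT_SAMPLE_STEP,
                         source_strand: list | None = None) -> ObservedTrace:
    """Observed β-trace: window-of-three Cα centers capped by the end Cα atoms."""
    ca = np.asarray(ca, dtype=float)
    if len(ca) < 3:
        raise ValueError("an observed trace needs at least 3 Calpha atoms")
    centers = (ca[:-2] + ca[1:-1] + ca[2:]) / 3.0
    control = np.vstack([ca[0], centers, ca[-1]])
    return ObservedTrace(
        points=resample_polyline(control, step),
        control_points=control,
        source_strand=source_strand,
    )


def _point_segment_setup(polyline: np.ndarray):
    poly = np.asarray(polyline, dtype=float)
    starts = poly[:-1]
    deltas = poly[1:] - poly[:-1]
    lengths2 = np.einsum("ij,ij->i", deltas, deltas)
    return starts, deltas, np.where(lengths2 > 0, lengths2, 1.0)


def points_to_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance of each query point to the nearest point on a polyline."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    starts, deltas, lengths2 = _point_segment_setup(polyline)
    w = pts[:, None, :] - starts[None, :, :]
    t = np.clip(np.einsum("nmj,mj->nm", w, deltas) / lengths2[None, :], 0.0, 1.0)
    foot = starts[None, :, :] + t[..., None] * deltas[None, :, :]
    return np.linalg.norm(pts[:, None, :] - foot, axis=2).min(axis=1)


def directed_point_distance(p: np.ndarray, trace: np.ndarray) -> float:
    """Projection distance from one point to a polyline.

    Projections falling outside a segment use the nearer segment end, so a
    point beyond the trace terminus is measured to that terminus.
    """
    return float(points_to_polyline_distance(np.asarray(p, dtype=float)[None, :], trace)[0])


def pair_two_way_distance(
    s: np.ndarray,
    s_prime: np.ndarray,
    step: float | None = DEFAULT_SAMPLE_STEP,
) -> float:
    """Symmetric two-way distance D_k between two polylines.

    With ``step`` set (the default), both curves are resampled at that
    arc-length step first; pass ``step=None`` to use the points as given.
    """
    s = np.asarray(s, dtype=float)
    s_prime = np.asarray(s_prime, dtype=float)
    a = resample_polyline(s, step) if step is not None else s
    b = resample_polyline(s_prime, step) if step is not None else s_prime
    # sums run over the resampled points; distances are measured to the
    # original curve so corner-cutting by resampling cannot bias them
    forward = points_to_polyline_distance(a, s_prime).mean()
    backward = points_to_polyline_distance(b, s).mean()
    return float((forward + backward) / 2.0)


# ---------------------------------------------------------------------------
# Set-level comparison

def _as_polylines(traces) -> list[np.ndarray]:
    out = []
    for t in traces:
        out.append(np.asarray(getattr(t, "points", t), dtype=float))
    return out


def match_traces(
    detected, observed, step: float | None = DEFAULT_SAMPLE_STEP
) -> Matching:
    """Optimal one-to-one matching (minimum summed D_k) between two trace sets.

    The assignment of size ``T = min(n_detected, n_observed)`` is computed
    exactly on the pairwise two-way-distance matrix.
    """
    det = _as_polylines(detected)
    obs = _as_polylines(observed)
    if not det or not obs:
        raise ValueError("both trace sets must be nonempty")
    det_r = [resample_polyline(p, step) if step is not None else p for p in det]
    obs_r = [resample_polyline(p, step) if step is not None else p for p in obs]
    dmat = np.empty((len(det_r), len(obs_r)))
    for i in range(len(det_r)):
        for j in range(len(obs_r)):
            fwd = points_to_polyline_distance(det_r[i], obs[j]).mean()
            bwd = points_to_polyline_distance(obs_r[j], det[i]).mean()
            dmat[i, j] = 0.5 * (fwd + bwd)
    rows, cols = linear_sum_assignment(dmat)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    matched_d = {i for i, _ in pairs}
    matched_o = {j for _, j in pairs}
    return Matching(
        pairs=pairs,
        unmatched_detected=[i for i in range(len(det_r)) if i not in matched_d],
        unmatched_observed=[j for j in range(len(obs_r)) if j not in matched_o],
        distance_matrix=dmat,
    )


def overall_distance(per_pair) -> float:
    """Overall two-way distance D: the mean of matched per-pair distances."""
    per_pair = np.asarray(per_pair, dtype=float)
    if per_pair.size == 0:
        raise ValueError("overall distance is undefined for an empty matching")
    return float(per_pair.mean())


def aa_coverage(
    strand_cas,
    matching: Matching,
    detected,
    cutoff: float = DEFAULT_COVERAGE_CUTOFF,
) -> tuple[int, int]:
    """Count strand Cα atoms lying strictly within ``cutoff`` of their
    matched detected trace.

    The total counts every Cα of every observed strand, including strands
    whose observed trace was left unmatched (those contribute no detections).
    """
    det = _as_polylines(detected)
    obs_to_det = {j: i for i, j in matching.pairs}
    aa_total = sum(len(cas) for cas in strand_cas)
    aa_detected = 0
    for j, cas in enumerate(strand_cas):
        if j not in obs_to_det:
            continue
        d = points_to_polyline_distance(np.asarray(cas, dtype=float), det[obs_to_det[j]])
        aa_detected += int((d < cutoff).sum())
    return aa_detected, aa_total


def evaluate_set(
    trace_set,
    observed: list[ObservedTrace],
    strand_cas=None,
    step: float = DEFAULT_SAMPLE_STEP,
    cutoff: float = DEFAULT_COVERAGE_CUTOFF,
) -> EvaluationReport:
    """Full report (matching, D, coverage) for one set of detected traces."""
    detected = _as_polylines(getattr(trace_set, "traces", trace_set))
    obs_lines = _as_polylines(observed)
    matching = match_traces(detected, obs_lines, step=step)
    per_pair = [float(matching.distance_matrix[i, j]) for i, j in matching.pairs]
    if strand_cas is None:
        aa_detected, aa_total = 0, 0
    else:
        aa_detected, aa_total = aa_coverage(strand_cas, matching, detected, cutoff=cutoff)
    return EvaluationReport(
        per_pair=per_pair,
        overall=overall_distance(per_pair),
        n_detected_strands=len(detected),
        n_observed_strands=len(obs_lines),
        aa_detected=aa_detected,
        aa_total=aa_total,
        tilt_deg=getattr(trace_set, "tilt_deg", None),
        translation_offset=getattr(trace_set, "translation_offset", None),
        matching=matching,
    )


def evaluate_sets(sets, observed, strand_cas=None, **kwargs) -> list[EvaluationReport]:
    return [evaluate_set(s, observed, strand_cas, **kwargs) for s in sets]


def select_best_set(sets, observed, strand_cas=None, **kwargs):
    """Evaluate every candidate trace set and return the one with smallest D.

    Ties are broken toward the lower tilt angle, then the lower translation
    offset.  Returns ``(best_set, best_report, all_reports)``.
    """
    if not sets:
        raise ValueError("need at least one trace set")
    reports = evaluate_sets(sets, observed, strand_cas, **kwargs)

    def key(i):
        r = reports[i]
        return (r.overall, r.tilt_deg or 0.0, r.translation_offset or 0.0)

    best = min(range(len(sets)), key=key)
    return sets[best], reports[best], reports


# ---------------------------------------------------------------------------
# Published benchmark tables

_BENCHMARK_FILES = {
    "small": "benchmark_small_simulated.csv",
    "large": "benchmark_large_simulated.csv",
    "cryoem": "benchmark_cryoem.csv",
}


def load_benchmark_table(which: str) -> pd.DataFrame:
    """Load one of the published per-case benchmark tables.

    ``which`` is ``"small"`` (simulated maps of barrels with < 15 strands),
    ``"large"`` (> 15 strands) or ``"cryoem"`` (experimental maps).
    """
    try:
        fname = _BENCHMARK_FILES[which]
    except KeyError:
        raise KeyError(f"unknown benchmark table {which!r}") from None
    with resources.files("strandroller.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def aggregate_benchmark(df: pd.DataFrame) -> dict:
    """Aggregate a per-case report table the way the benchmark summaries do.

    Returns the mean and standard deviation of the per-case two-way
    distances, pooled amino-acid counts and coverage percentage, and the
    number of cases whose detected strand count equals the observed one.
    """
    aa_det = int(df["aa_detected"].sum())
    aa_tot = int(df["aa_total"].sum())
    return {
        "n_cases": int(len(df)),
        "mean_two_way_distance": float(df["two_way_distance"].mean()),
        "std_two_way_distance": float(df["two_way_distance"].std(ddof=1)),
        "aa_detected": aa_det,
        "aa_total": aa_tot,
        "coverage_percent": 100.0 * aa_det / aa_tot if aa_tot else 0.0,
        "n_strand_count_exact": int((df["n_detected"] == df["n_observed"]).sum()),
    }
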