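"""Synapse-level measurements: PreAZ extraction, PSD area estimation,
cleft widths, AZ shape classification.

The PreAZ is the part of the reconstructed bouton membrane covered by the
presynaptic density annotation: membrane points strictly within 30 nm
(in-plane, per section — matching the contour-based annotation workflow) of
a density contour line.  The PSD area is estimated from the PreAZ area and
the ratio of the summed contour-line lengths of the two densities,

    SA_PSD = SA_PreAZ * l_PSD / l_PreAZ,

which is exact when the two membrane specializations run parallel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geometry import point_segment_distance_2d, polyline_length, polyline_segments
from .sectioning import ContourStack

NM2_PER_UM2 = 1e6

PREAZ_DISTANCE_NM = 30.0    # strict < threshold for membrane coverage
HORSESHOE_CONVEXITY_DEFICIT = 0.35


class MetricsError(ValueError):
    pass


@dataclass
class AZMeasurement:
    l_preaz_nm: float
    l_psd_nm: float
    sa_preaz_um2: float
    sa_psd_um2: float
    shape_class: str | None = None
    n_az_per_bouton: int = 1


@dataclass
class CleftMeasurement:
    lateral_1: float
    lateral_2: float
    central: float
    subject_id: str | None = None
    perpendicularity_ok: bool = True

    @property
    def lateral_mean(self) -> float:
        return 0.5 * (self.lateral_1 + self.lateral_2)


def points_within_density(
    points_xyz: np.ndarray,
    stack: ContourStack,
    label: str = "preaz_density",
    threshold: float = PREAZ_DISTANCE_NM,
) -> np.ndarray:
    """Strict per-section in-plane proximity test.

    A point belongs to the covered membrane iff the section containing its z
    has a density polyline within *strictly less than* ``threshold`` nm of
    its (x, y) position.  Points at exactly the threshold are excluded.
    """
    pts = np.atleast_2d(points_xyz)
    out = np.zeros(len(pts), dtype=bool)
    for s in stack.sections:
        if s.lost:
            continue
        lines = s.polylines.get(label, [])
        if not lines:
            continue
        in_sec = (pts[:, 2] >= s.z_lo) & (pts[:, 2] < s.z_hi)
        if not in_sec.any():
            continue
        segs = np.concatenate([polyline_segments(l) for l in lines if len(l) >= 2], axis=0)
        d = point_segment_distance_2d(pts[in_sec, :2], segs)
        sub = out[in_sec]
        sub |= d < threshold
        out[in_sec] = sub
    return out


def density_contour_length(stack: ContourStack, label: str = "preaz_density") -> float:
    """Summed in-plane arc length of all density contour lines, nm."""
    total = 0.0
    for s in stack.sections:
        for line in s.polylines.get(label, []):
            total += polyline_length(line)
    return total


def extract_preaz(bouton_mesh, stack: ContourStack) -> tuple[float, float, np.ndarray]:
    """PreAZ surface area (µm²) and contour length l_PreAZ (nm).

    Each bouton-mesh face is credited with the fraction of its vertices that
    lie strictly within 30 nm (in-plane, in their own section) of a
    presynaptic density contour; sa_preaz is the coverage-weighted face-area
    sum.  Returns (sa_preaz_um2, l_preaz_nm, face_mask) where face_mask
    marks faces with majority coverage.  With no density annotation the area
    is 0 (reported with a warning, not raised).
    """
    faces = np.asarray(bouton_mesh.faces)
    if density_contour_length(stack, "preaz_density") == 0.0:
        import warnings

        warnings.warn("no presynaptic density contours in stack; PreAZ area is 0")
        return 0.0, 0.0, np.zeros(len(faces), dtype=bool)
    l_pre = density_contour_length(stack, "preaz_density")
    verts = np.asarray(bouton_mesh.vertices)
    vmask = points_within_density(verts, stack, "preaz_density")
    coverage = vmask[faces].mean(axis=1)
    sa = float((bouton_mesh.area_faces * coverage).sum()) / NM2_PER_UM2
    return sa, l_pre, coverage > 0.5


def estimate_psd_area(sa_preaz_um2: float, l_psd_nm: float, l_preaz_nm: float) -> float:
    """PSD surface area from the PreAZ area scaled by the contour-length
    ratio of the two densities; requires l_preaz > 0."""
    if l_preaz_nm <= 0:
        raise MetricsError("l_preaz is zero: PSD/PreAZ length ratio undefined")
    return sa_preaz_um2 * l_psd_nm / l_preaz_nm


def psd_area_from_contours(stack: ContourStack) -> float:
    """Independent PSD estimate by direct tracing: summed contour-line
    length × section thickness (a band-area estimate, µm²)."""
    total = 0.0
    for s in stack.sections:
        for line in s.polylines.get("psd_density", []):
            total += polyline_length(line) * s.thickness
    return total / NM2_PER_UM2


def measure_cleft(
    profiles: list[CleftMeasurement],
) -> tuple[list[CleftMeasurement], int]:
    """Filter cleft profiles by the perpendicularity criterion.

    Returns (retained profiles, number excluded).  Only profiles from
    perpendicularly cut synapses enter the subject-level aggregation.
    """
    kept = [p for p in profiles if p.perpendicularity_ok]
    return kept, len(profiles) - len(kept)


def aggregate_cleft_by_subject(
    profiles: list[CleftMeasurement],
) -> dict[str, dict[str, float]]:
    """Per-subject mean of lateral_mean and central, then a grand mean ± SD
    across subjects."""
    kept, _ = measure_cleft(profiles)
    by_subject: dict[str, list[CleftMeasurement]] = {}
    for p in kept:
        by_subject.setdefault(p.subject_id or "subject0", []).append(p)
    out = {}
    for sid, ps in by_subject.items():
        out[sid] = {
            "lateral": float(np.mean([p.lateral_mean for p in ps])),
            "central": float(np.mean([p.central for p in ps])),
            "n": len(ps),
        }
    return out


def classify_az_shape(
    patch_vertices: np.ndarray, patch_faces: np.ndarray
) -> str:
    """Topological shape class of an AZ patch.

    The patch is projected on its best-fit plane and merged into one
    region; classification is by boundary topology and convexity:
    no holes and convex enough -> macular; no holes but a convexity
    deficit > 0.35 -> horseshoe; one dominant central hole -> ring;
    small interior holes -> perforated.
    """
    if len(patch_faces) == 0:
        raise MetricsError("empty AZ patch")
    verts = np.asarray(patch_vertices, dtype=float)
    ctr = verts.mean(axis=0)
    centred = verts - ctr
    # best-fit plane by PCA; project on the two dominant axes
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    uv = centred @ vt[:2].T
    tris = [Polygon(uv[f]) for f in patch_faces]
    tris = [t if t.is_valid else t.buffer(0) for t in tris]
    region = unary_union(tris)
    # small positive buffer to weld numerically-adjacent triangles
    weld = max(np.sqrt(region.area) * 1e-3, 1e-9)
    region = region.buffer(weld).buffer(-weld)
    if region.geom_type == "MultiPolygon":
        region = max(region.geoms, key=lambda g: g.area)
    outer = Polygon(region.exterior)
    # triangulation slivers project as sub-percent pinholes; ignore them
    holes = [
        Polygon(i) for i in region.interiors if Polygon(i).area / outer.area >= 0.01
    ]
    hole_area = sum(h.area for h in holes)
    if holes:
        if len(holes) == 1 and hole_area / outer.area >= 0.15:
            return "ring"
        return "perforated"
    hull = region.convex_hull
    if 1.0 - region.area / hull.area > HORSESHOE_CONVEXITY_DEFICIT:
        return "horseshoe"
    return "macular"
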