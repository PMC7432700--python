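"""Observation models: serial ultrathin sectioning (TEM mode) and
anisotropic voxel sampling (FIB-SEM mode).

``section_scene`` cuts a ground-truth scene into an ordered stack of
annotated sections: closed polygons for the bouton, its postsynaptic target
and mitochondria, open polylines for the pre/postsynaptic densities (the
annotation protocol draws a contour *line* along the membrane, whose arc
length is the l PreAZ / l PSD of the area estimator), and point marks for
vesicles.  Sections are 55 ± 5 nm by default with optional per-section loss
and in-plane misalignment; z-intervals are half-open [z_lo, z_hi) and a
sphere tangent to a boundary plane belongs to the lower section.

``voxelize_scene`` rasterises the scene on a (5, 5, 50) nm grid by default —
the anisotropic FIB-SEM voxel — or (5, 5, 5) in isotropic mode, and
``detect_vesicles_voxel`` is a deliberately simple connected-component
detector whose merging of touching vesicles is the partial-volume bias the
pipeline quantifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import chain_segments
from .scene_synth import Scene, SceneError

LABELS = ("bouton", "target", "mito")
DENSITY_LABELS = ("preaz_density", "psd_density")


@dataclass(frozen=True)
class SectionPlan:
    thickness_nominal: float = 55.0   # nm
    thickness_jitter: float = 5.0     # nm, uniform +-
    z0: float | None = None           # origin offset; default: just below the scene
    loss_probability: float = 0.0
    misalignment_sd: float = 0.0      # nm, per-section in-plane translation noise

    def __post_init__(self):
        if self.thickness_nominal <= 0:
            raise SceneError("thickness_nominal must be positive")
        if not 0 <= self.thickness_jitter < self.thickness_nominal:
            raise SceneError("thickness_jitter must be < thickness_nominal")
        if not 0 <= self.loss_probability < 1:
            raise SceneError("loss_probability must be in [0, 1)")
        if self.misalignment_sd < 0:
            raise SceneError("misalignment_sd must be nonnegative")


@dataclass
class VesicleMark:
    center_xy: np.ndarray       # (2,) nm, in-section
    measured_diameter: float    # chord diameter at the section mid-plane, nm
    dense_core: bool
    docked: bool
    section_index: int
    track_id: int               # ground truth only; -1 if unknown


@dataclass
class Section:
    index: int
    z_lo: float
    z_hi: float
    lost: bool = False
    polygons: dict[str, list[np.ndarray]] = field(default_factory=dict)
    polylines: dict[str, list[np.ndarray]] = field(default_factory=dict)
    marks: list[VesicleMark] = field(default_factory=list)
    shift_true: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def thickness(self) -> float:
        return self.z_hi - self.z_lo

    @property
    def z_mid(self) -> float:
        return 0.5 * (self.z_lo + self.z_hi)


@dataclass
class CleftProfile:
    """One cleft-width measurement protocol record for an AZ: widths at the
    two lateral edges and the centre of the densities."""

    az_index: int
    lateral_1: float
    lateral_2: float
    central: float
    perpendicularity_ok: bool


@dataclass
class ContourStack:
    sections: list[Section]
    alignment_state: str = "raw"        # raw | aligned
    cleft_profiles: list[CleftProfile] = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    translations: np.ndarray | None = None  # per-section shifts applied by alignment

    def __post_init__(self):
        zs = [s.z_lo for s in self.sections]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise SceneError("sections must be strictly ordered in z")

    def density_segments_3d(self, label: str = "preaz_density") -> np.ndarray:
        """All density polyline segments as 3D segments at their section
        mid-plane z; shape (k, 2, 3)."""
        segs = []
        for s in self.sections:
            for line in s.polylines.get(label, []):
                if len(line) < 2:
                    continue
                v3 = np.column_stack([line, np.full(len(line), s.z_mid)])
                segs.append(np.stack([v3[:-1], v3[1:]], axis=1))
        if not segs:
            return np.empty((0, 2, 3))
        return np.concatenate(segs, axis=0)

    def to_json(self) -> str:
        doc = {
            "schema": "synmorph/stack",
            "version": 1,
            "alignment_state": self.alignment_state,
            "meta": self.meta,
            "cleft_profiles": [
                {
                    "az_index": c.az_index,
                    "lateral_1": c.lateral_1,
                    "lateral_2": c.lateral_2,
                    "central": c.central,
                    "perpendicularity_ok": c.perpendicularity_ok,
                }
                for c in self.cleft_profiles
            ],
            "sections": [
                {
                    "index": s.index,
                    "z_lo": s.z_lo,
                    "z_hi": s.z_hi,
                    "lost": s.lost,
                    # closed polygons: first vertex repeated as last
                    "polygons": {
                        k: [np.vstack([p, p[:1]]).tolist() for p in v]
                        for k, v in s.polygons.items()
                    },
                    "polylines": {k: [p.tolist() for p in v] for k, v in s.polylines.items()},
                    "marks": [
                        {
                            "center_xy": m.center_xy.tolist(),
                            "measured_diameter": m.measured_diameter,
                            "dense_core": m.dense_core,
                            "docked": m.docked,
                            "track_id": m.track_id,
                        }
                        for m in s.marks
                    ],
                }
                for s in self.sections
            ],
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ContourStack":
        doc = json.loads(text)
        if doc.get("schema") != "synmorph/stack":
            raise SceneError("not a synmorph stack document")
        sections = []
        for sd in doc["sections"]:
            polys = {}
            for k, v in sd["polygons"].items():
                out = []
                for p in v:
                    arr = np.asarray(p, dtype=float)
                    if len(arr) >= 2 and np.allclose(arr[0], arr[-1]):
                        arr = arr[:-1]
                    out.append(arr)
                polys[k] = out
            sec = Section(
                index=sd["index"],
                z_lo=sd["z_lo"],
                z_hi=sd["z_hi"],
                lost=sd["lost"],
                polygons=polys,
                polylines={
                    k: [np.asarray(p, dtype=float) for p in v]
                    for k, v in sd["polylines"].items()
                },
                marks=[
                    VesicleMark(
                        center_xy=np.asarray(m["center_xy"], dtype=float),
                        measured_diameter=m["measured_diameter"],
                        dense_core=m["dense_core"],
                        docked=m["docked"],
                        section_index=sd["index"],
                        track_id=m.get("track_id", -1),
                    )
                    for m in sd["marks"]
                ],
            )
            sections.append(sec)
        return cls(
            sections=sections,
            alignment_state=doc["alignment_state"],
            cleft_profiles=[CleftProfile(**c) for c in doc["cleft_profiles"]],
            meta=doc.get("meta", {}),
        )


def _cross_section_closed(mesh: trimesh.Trimesh, z: float) -> list[np.ndarray]:
    """Closed 2D contours of a mesh at plane z (open fragments dropped)."""
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[0, 0, 1.0], plane_origin=[0, 0, z]
    )
    if len(segs) == 0:
        return []
    chains = chain_segments(segs[:, :, :2], tol=1e-3)
    return [v for v, closed in chains if closed and len(v) >= 3]


def _cross_section_open(vertices: np.ndarray, faces: np.ndarray, z: float) -> list[np.ndarray]:
    """2D polylines where an open surface patch crosses plane z."""
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    segs = trimesh.intersections.mesh_plane(
        mesh, plane_normal=[0, 0, 1.0], plane_origin=[0, 0, z]
    )
    if len(segs) == 0:
        return []
    chains = chain_segments(segs[:, :, :2], tol=1e-3)
    return [v for v, _closed in chains if len(v) >= 2]


def _ellipse_polygon(m, z: float, n: int = 64) -> np.ndarray | None:
    """Cross-section of an axis-aligned ellipsoid with plane z."""
    cz = m.center[2]
    czax = m.semi_axes[2]
    rel = (z - cz) / czax
    if abs(rel) >= 1.0:
        return None
    scale = np.sqrt(1.0 - rel * rel)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [
            m.center[0] + m.semi_axes[0] * scale * np.cos(ang),
            m.center[1] + m.semi_axes[1] * scale * np.sin(ang),
        ]
    )


def section_scene(scene: Scene, plan: SectionPlan, seed: int = 0) -> ContourStack:
    """Cut a scene into an annotated serial-section stack.

    Deterministic for fixed (scene, plan, seed).  Thickness jitter, section
    loss and misalignment are applied when configured.
    """
    rng = np.random.default_rng(seed)
    mesh = scene.mesh
    zmin, zmax = float(mesh.bounds[0][2]), float(mesh.bounds[1][2])
    if scene.vesicles:
        vz = np.array([v.center[2] for v in scene.vesicles])
        vr = np.array([v.radius for v in scene.vesicles])
        zmin = min(zmin, float((vz - vr).min()))
        zmax = max(zmax, float((vz + vr).max()))
    if zmax - zmin <= 0:
        raise SceneError("scene bounding box has zero height")

    # one empty margin section at each end so a fully contained object can be
    # recognised as complete (its first/last contours lie strictly inside)
    z0 = plan.z0 if plan.z0 is not None else zmin - 1.6 * plan.thickness_nominal
    edges = [z0]
    while edges[-1] < zmax + 1.1 * plan.thickness_nominal:
        t = plan.thickness_nominal + rng.uniform(-plan.thickness_jitter, plan.thickness_jitter)
        edges.append(edges[-1] + t)
    lost_flags = rng.random(len(edges) - 1) < plan.loss_probability
    shifts = (
        rng.normal(0.0, plan.misalignment_sd, size=(len(edges) - 1, 2))
        if plan.misalignment_sd > 0
        else np.zeros((len(edges) - 1, 2))
    )

    target_meshes = [
        trimesh.Trimesh(vertices=v, faces=f, process=False)
        for v, f in zip(scene.target_vertices, scene.target_faces)
    ]

    centers = np.array([v.center for v in scene.vesicles]).reshape(-1, 3)
    radii = np.array([v.radius for v in scene.vesicles])

    sections: list[Section] = []
    for k in range(len(edges) - 1):
        z_lo, z_hi = edges[k], edges[k + 1]
        sec = Section(index=k, z_lo=z_lo, z_hi=z_hi, lost=bool(lost_flags[k]))
        sec.shift_true = shifts[k]
        if sec.lost:
            sections.append(sec)
            continue
        zm = sec.z_mid
        polys: dict[str, list[np.ndarray]] = {}
        lines: dict[str, list[np.ndarray]] = {}
        polys["bouton"] = _cross_section_closed(mesh, zm)
        tlist = []
        for tm in target_meshes:
            tlist.extend(_cross_section_closed(tm, zm))
        if tlist:
            polys["target"] = tlist
        mlist = []
        for m in scene.mitochondria:
            e = _ellipse_polygon(m, zm)
            if e is not None:
                mlist.append(e)
        if mlist:
            polys["mito"] = mlist
        pre, psd = [], []
        for p in scene.az_patches:
            pre.extend(_cross_section_open(p.preaz_vertices, p.preaz_faces, zm))
            psd.extend(_cross_section_open(p.psd_vertices, p.psd_faces, zm))
        if pre:
            lines["preaz_density"] = pre
        if psd:
            lines["psd_density"] = psd

        if len(centers):
            # half-open slabs: a sphere tangent to a boundary plane belongs
            # to the lower section (strict > on the lower edge test)
            hit = np.flatnonzero((centers[:, 2] - radii < z_hi) & (centers[:, 2] + radii > z_lo))
            for i in hit:
                dz = abs(zm - centers[i, 2])
                chord = 2.0 * np.sqrt(max(radii[i] ** 2 - dz**2, 0.0))
                v = scene.vesicles[i]
                sec.marks.append(
                    VesicleMark(
                        center_xy=centers[i, :2].copy(),
                        measured_diameter=float(chord),
                        dense_core=v.dense_core,
                        docked=v.docked,
                        section_index=k,
                        track_id=v.track_id,
                    )
                )
        # apply misalignment
        if np.any(shifts[k]):
            s2 = shifts[k]
            polys = {lab: [p + s2 for p in ps] for lab, ps in polys.items()}
            lines = {lab: [p + s2 for p in ps] for lab, ps in lines.items()}
            for m in sec.marks:
                m.center_xy = m.center_xy + s2
        sec.polygons = polys
        sec.polylines = lines
        sections.append(sec)

    profiles = []
    for i, p in enumerate(scene.az_patches):
        noise = scene.params.cleft_spec.noise_sd
        profiles.append(
            CleftProfile(
                az_index=i,
                lateral_1=float(p.cleft_lateral + rng.normal(0, noise)),
                lateral_2=float(p.cleft_lateral + rng.normal(0, noise)),
                central=float(p.cleft_central + rng.normal(0, noise)),
                perpendicularity_ok=bool(rng.random() < 0.85),
            )
        )

    state = "raw" if plan.misalignment_sd > 0 else "aligned"
    return ContourStack(
        sections=sections,
        alignment_state=state,
        cleft_profiles=profiles,
        meta={
            "plan": {
                "thickness_nominal": plan.thickness_nominal,
                "thickness_jitter": plan.thickness_jitter,
                "loss_probability": plan.loss_probability,
                "misalignment_sd": plan.misalignment_sd,
            },
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# FIB-SEM style voxel sampling

LABEL_CODES = {"background": 0, "bouton": 1, "vesicle": 2, "density": 3}


@dataclass
class VoxelVolume:
    spacing: tuple[float, float, float]   # nm, (x, y, z); (5, 5, 50) anisotropic default
    origin: np.ndarray                    # nm, corner of voxel (0,0,0)
    labels: np.ndarray                    # (nx, ny, nz) uint8

    def voxel_centers_nm(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(indices) + 0.5) * np.asarray(self.spacing)

    @property
    def voxel_volume_nm3(self) -> float:
        return float(np.prod(self.spacing))

    def save_raw(self, path_prefix: str) -> None:
        """Raw grid + JSON metadata sidecar."""
        self.labels.tofile(path_prefix + ".raw")
        with open(path_prefix + ".json", "w") as fh:
            json.dump(
                {
                    "dtype": str(self.labels.dtype),
                    "shape": list(self.labels.shape),
                    "spacing_nm": list(self.spacing),
                    "origin_nm": self.origin.tolist(),
                    "label_codes": LABEL_CODES,
                },
                fh,
                sort_keys=True,
            )


def voxelize_scene(
    scene: Scene,
    spacing: tuple[float, float, float] = (5.0, 5.0, 50.0),
    labels: tuple[str, ...] = ("bouton", "vesicle", "density"),
    margin: float = 25.0,
) -> VoxelVolume:
    """Rasterise by voxel-centre membership.

    Later labels overwrite earlier ones where they overlap (a vesicle voxel
    wins over a bouton voxel, as in a label image).
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise SceneError("voxel spacing must be positive")
    mesh = scene.mesh
    lo = mesh.bounds[0] - margin
    hi = mesh.bounds[1] + margin
    extent = hi - lo
    if any(s > e for s, e in zip(spacing, extent)):
        raise SceneError("voxel spacing larger than scene extent")
    shape = np.ceil(extent / spacing).astype(int)
    grid = np.zeros(tuple(shape), dtype=np.uint8)

    xs = lo[0] + (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = lo[1] + (np.arange(shape[1]) + 0.5) * spacing[1]
    zs = lo[2] + (np.arange(shape[2]) + 0.5) * spacing[2]

    if "bouton" in labels:
        # column-wise star-shape membership, vectorised per z-slab
        pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
        for kz, z in enumerate(zs):
            p3 = np.column_stack([pts, np.full(len(pts), z)])
            inside = scene.contains(p3)
            grid[:, :, kz][inside.reshape(shape[0], shape[1])] = LABEL_CODES["bouton"]

    if "vesicle" in labels:
        for v in scene.vesicles:
            c, r = v.center, v.radius
            i0 = np.maximum(np.floor((c - r - lo) / spacing).astype(int), 0)
            i1 = np.minimum(np.ceil((c + r - lo) / spacing).astype(int) + 1, shape)
            if np.any(i0 >= i1):
                continue
            gx = xs[i0[0] : i1[0]]
            gy = ys[i0[1] : i1[1]]
            gz = zs[i0[2] : i1[2]]
            dx2 = (gx - c[0])[:, None, None] ** 2
            dy2 = (gy - c[1])[None, :, None] ** 2
            dz2 = (gz - c[2])[None, None, :] ** 2
            mask = dx2 + dy2 + dz2 <= r * r
            sub = grid[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
            sub[mask] = LABEL_CODES["vesicle"]

    if "density" in labels:
        for p in scene.az_patches:
            idx = np.floor((p.preaz_vertices - lo) / spacing).astype(int)
            ok = np.all((idx >= 0) & (idx < shape), axis=1)
            for i, j, k in idx[ok]:
                grid[i, j, k] = LABEL_CODES["density"]

    return VoxelVolume(spacing=spacing, origin=np.asarray(lo, dtype=float), labels=grid)


def detect_vesicles_voxel(vol: VoxelVolume, min_voxels: int = 2) -> np.ndarray:
    """Connected-component vesicle detection (26-connectivity).

    One detection per connected component of vesicle-labelled voxels;
    touching vesicles merge into a single detection — that merging is the
    partial-volume bias anisotropic sampling is expected to worsen.
    Returns detected centres, (n, 3) nm.
    """
    from scipy import ndimage

    mask = vol.labels == LABEL_CODES["vesicle"]
    if not mask.any():
        return np.empty((0, 3))
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    if len(keep) == 0:
        return np.empty((0, 3))
    coms = ndimage.center_of_mass(mask, lab, index=keep)
    return vol.origin + (np.asarray(coms) + 0.5) * np.asarray(vol.spacing)
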