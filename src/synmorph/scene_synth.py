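"""Ground-truth synthetic synaptic scenes.

A scene is a geometric stand-in for one presynaptic bouton and its synaptic
contacts: a closed bouton surface, one to three active-zone (AZ) patches on
that surface (presynaptic density, PreAZ, with a matching postsynaptic
density, PSD, across the cleft), a population of synaptic vesicles with a
known pool structure, and mitochondria.  All coordinates are in nanometres;
reporting layers convert to µm²/µm³.

The bouton is a prolate spheroid with a smooth random radial perturbation —
an *en passant* swelling along the axon axis (z).  The transverse and axial
semi-axes are solved numerically so that the triangulated surface hits the
requested surface area *and* volume simultaneously (real boutons have far
more surface per volume than a sphere).  Vesicles are placed by stratified
rejection sampling so that the per-pool counts are exact by construction,
with the perimeter of each vesicle (minimal distance from its centre to the
nearest AZ patch minus its radius) verified by exhaustive point-to-triangle
distance before acceptance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import point_triangle_distance, triangle_areas

NM2_PER_UM2 = 1e6
NM3_PER_UM3 = 1e9

POOL_NAMES = ("p10", "p10_20", "intermediate", "rp", "resting")

# perimeter bin edges, nm: p10 <= 10 < p10_20 <= 20 < intermediate < 60 <= rp <= 200 < resting
POOL_EDGES = {
    "p10": (0.0, 10.0),
    "p10_20": (10.0, 20.0),
    "intermediate": (20.0, 60.0),
    "rp": (60.0, 200.0),
    "resting": (200.0, np.inf),
}


class SceneError(ValueError):
    """Invalid scene parameters."""


class PackingInfeasibleError(RuntimeError):
    """Raised when a requested configuration cannot be realised; the message
    names the binding constraint."""

    def __init__(self, constraint: str, detail: str = ""):
        self.constraint = constraint
        super().__init__(f"infeasible scene: binding constraint '{constraint}' {detail}".rstrip())


@dataclass(frozen=True)
class PoolSpec:
    """Target fractions of the total vesicle pool per perimeter bin.

    The paper's pools are the putative readily releasable pool (perimeter
    p <= 10 nm strict, p <= 20 nm loose), the recycling pool (60-200 nm) and
    the resting pool (> 200 nm); the unnamed (20, 60) nm gap is carried
    explicitly as "intermediate".  ``docked_fraction`` is the fraction of
    p10 vesicles placed in membrane contact (p = 0) and flagged docked.
    """

    frac_p10: float = 0.01
    frac_p10_20: float = 0.01
    frac_20_60: float = 0.04
    frac_rp: float = 0.12
    frac_resting: float = 0.82
    docked_fraction: float = 0.3

    def __post_init__(self):
        fr = self.fractions
        if any(f < 0 for f in fr.values()):
            raise SceneError("pool fractions must be nonnegative")
        if abs(sum(fr.values()) - 1.0) > 1e-6:
            raise SceneError("pool fractions must sum to 1")
        if not 0.0 <= self.docked_fraction <= 1.0:
            raise SceneError("docked_fraction must be in [0, 1]")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "p10": self.frac_p10,
            "p10_20": self.frac_p10_20,
            "intermediate": self.frac_20_60,
            "rp": self.frac_rp,
            "resting": self.frac_resting,
        }

    def counts_for_total(self, total: int) -> dict[str, int]:
        """Integer per-bin counts by largest-remainder rounding (sums to total)."""
        fr = self.fractions
        raw = {k: fr[k] * total for k in POOL_NAMES}
        counts = {k: int(np.floor(raw[k])) for k in POOL_NAMES}
        short = total - sum(counts.values())
        order = sorted(POOL_NAMES, key=lambda k: raw[k] - counts[k], reverse=True)
        for k in order[:short]:
            counts[k] += 1
        return counts


@dataclass(frozen=True)
class CleftSpec:
    """Synaptic cleft widths (nm): measured at the two lateral edges and the
    centre of the densities, plus a per-measurement Gaussian noise SD."""

    lateral_width: float = 20.0
    central_width: float = 22.0
    noise_sd: float = 2.0

    def __post_init__(self):
        if self.lateral_width <= 0 or self.central_width <= 0:
            raise SceneError("cleft widths must be positive")
        if self.noise_sd < 0:
            raise SceneError("cleft noise_sd must be nonnegative")


@dataclass(frozen=True)
class SceneParams:
    bouton_kind: str = "en_passant"           # or "end_terminal"
    bouton_surface_area_target: float = 6.09e6   # nm^2
    bouton_volume_target: float = 0.63e9         # nm^3
    n_az: int = 1
    az_area_targets: tuple[float, ...] = (0.23e6,)   # nm^2 per AZ (PreAZ)
    psd_area_targets: tuple[float, ...] | None = None  # nm^2; default = az targets
    az_shape: str = "macular"   # macular | perforated | horseshoe | ring
    total_sv: int = 1519
    pool_spec: PoolSpec = field(default_factory=PoolSpec)
    sv_diameter_range: tuple[float, float] = (30.0, 40.0)
    n_dense_core: int = 3
    n_mitochondria: int = 4
    mito_volume_fraction_target: float = 0.12
    cleft_spec: CleftSpec = field(default_factory=CleftSpec)
    target_kind: str = "spine"  # spine | shaft | astrocytic_process
    perturbation: float = 0.015
    overlap_tolerance: float = 4.0   # nm of allowed vesicle-vesicle overlap
    rng_seed: int = 0

    def __post_init__(self):
        if self.bouton_kind not in ("en_passant", "end_terminal"):
            raise SceneError(f"unknown bouton_kind {self.bouton_kind!r}")
        if self.az_shape not in ("macular", "perforated", "horseshoe", "ring"):
            raise SceneError(f"unknown az_shape {self.az_shape!r}")
        if self.target_kind not in ("spine", "shaft", "astrocytic_process"):
            raise SceneError(f"unknown target_kind {self.target_kind!r}")
        if self.n_az not in (1, 2, 3):
            raise SceneError("n_az must be 1, 2 or 3")
        if len(self.az_area_targets) != self.n_az:
            raise SceneError("az_area_targets length must equal n_az")
        if self.psd_area_targets is not None and len(self.psd_area_targets) != self.n_az:
            raise SceneError("psd_area_targets length must equal n_az")
        for v in (
            self.bouton_surface_area_target,
            self.bouton_volume_target,
            *self.az_area_targets,
        ):
            if v <= 0:
                raise SceneError("all geometric targets must be positive")
        if self.total_sv < 0 or self.n_mitochondria < 0 or self.n_dense_core < 0:
            raise SceneError("counts must be nonnegative")
        if not 0.0 <= self.mito_volume_fraction_target < 1.0:
            raise SceneError("mito_volume_fraction_target must be in [0, 1)")
        d_lo, d_hi = self.sv_diameter_range
        if not 0 < d_lo <= d_hi:
            raise SceneError("sv_diameter_range must be a positive interval")


@dataclass
class AZPatch:
    """One active zone: PreAZ patch on the bouton surface and the PSD across
    the cleft (the PreAZ patch scaled tangentially and translated outward, a
    parallel-membrane construction)."""

    preaz_face_indices: np.ndarray      # indices into the bouton mesh faces
    preaz_vertices: np.ndarray          # (v, 3) submesh
    preaz_faces: np.ndarray             # (f, 3)
    psd_vertices: np.ndarray
    psd_faces: np.ndarray
    true_preaz_area: float              # nm^2, measured on the submesh
    true_psd_area: float                # nm^2
    center: np.ndarray                  # patch centre on the bouton surface
    outward_normal: np.ndarray
    cleft_lateral: float                # nm, nominal
    cleft_central: float
    shape: str

    @property
    def preaz_triangles(self) -> np.ndarray:
        return self.preaz_vertices[self.preaz_faces]

    @property
    def psd_triangles(self) -> np.ndarray:
        return self.psd_vertices[self.psd_faces]


@dataclass
class GroundTruthVesicle:
    center: np.ndarray     # (3,) nm
    radius: float          # nm
    pool: str | None       # one of POOL_NAMES; None for dense-core vesicles
    docked: bool
    dense_core: bool
    az_index: int          # nearest AZ
    perimeter_true: float  # nm, exhaustive 3D distance to nearest PreAZ minus radius
    track_id: int


@dataclass
class Ellipsoid:
    center: np.ndarray
    semi_axes: np.ndarray  # (3,)

    @property
    def volume(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    def contains(self, points: np.ndarray, inflate: float = 0.0) -> np.ndarray:
        u = (np.atleast_2d(points) - self.center) / (self.semi_axes + inflate)
        return (u**2).sum(axis=1) <= 1.0


class _RadialField:
    """Smooth random radial modulation of the unit shape: a handful of
    Gaussian-like lobes on the sphere, normalised to peak amplitude eps."""

    def __init__(self, lobes_u: np.ndarray, lobes_w: np.ndarray, eps: float, norm: float):
        self.lobes_u = np.asarray(lobes_u, dtype=float)
        self.lobes_w = np.asarray(lobes_w, dtype=float)
        self.eps = float(eps)
        self.norm = float(norm)

    @classmethod
    def random(cls, rng: np.random.Generator, eps: float, n_lobes: int = 6) -> "_RadialField":
        u = rng.normal(size=(n_lobes, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        w = rng.normal(size=n_lobes)
        probe = trimesh.creation.icosphere(subdivisions=3, radius=1.0).vertices
        raw = cls._raw(probe, u, w)
        norm = max(float(np.abs(raw).max()), 1e-12)
        return cls(u, w, eps, norm)

    @staticmethod
    def _raw(dirs: np.ndarray, u: np.ndarray, w: np.ndarray) -> np.ndarray:
        dots = dirs @ u.T                      # (n, k)
        return (np.exp((dots - 1.0) / 0.35) * w).sum(axis=1)

    def factor(self, dirs: np.ndarray) -> np.ndarray:
        """Radial multiplier 1 + eps*g(direction), |g| <= ~1."""
        if self.eps == 0.0:
            return np.ones(len(np.atleast_2d(dirs)))
        raw = self._raw(np.atleast_2d(dirs), self.lobes_u, self.lobes_w)
        return 1.0 + self.eps * raw / self.norm


@dataclass
class Scene:
    params: SceneParams
    semi_axis_a: float                 # transverse, nm
    semi_axis_c: float                 # axial (z), nm
    field: _RadialField
    bouton_vertices: np.ndarray
    bouton_faces: np.ndarray
    az_patches: list[AZPatch]
    vesicles: list[GroundTruthVesicle]
    mitochondria: list[Ellipsoid]
    target_vertices: list[np.ndarray]  # one closed target surface per AZ
    target_faces: list[np.ndarray]

    _mesh: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            self._mesh = trimesh.Trimesh(
                vertices=self.bouton_vertices, faces=self.bouton_faces, process=False
            )
        return self._mesh

    @property
    def surface_area_nm2(self) -> float:
        return float(self.mesh.area)

    @property
    def volume_nm3(self) -> float:
        return float(self.mesh.volume)

    @property
    def mito_volume_fraction(self) -> float:
        if not self.mitochondria:
            return 0.0
        return sum(m.volume for m in self.mitochondria) / self.volume_nm3

    def pool_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in POOL_NAMES}
        for v in self.vesicles:
            if v.pool is not None:
                counts[v.pool] += 1
        return counts

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Exact star-shape membership test (margin > 0 shrinks conservatively)."""
        pts = np.atleast_2d(points)
        a = self.semi_axis_a - 1.35 * margin
        c = self.semi_axis_c - 1.35 * margin
        if a <= 0 or c <= 0:
            return np.zeros(len(pts), dtype=bool)
        u = pts / np.array([a, a, c])
        rn = np.linalg.norm(u, axis=1)
        dirs = u / np.maximum(rn, 1e-12)[:, None]
        limit = self.field.factor(dirs)
        if margin > 0:  # guard against perturbation slopes
            limit = limit - abs(self.field.eps) * 0.5
        return rn <= limit

    def to_json(self) -> str:
        def arr(x):
            return np.asarray(x).tolist()

        doc = {
            "schema": "synmorph/scene",
            "version": 1,
            "params": _params_to_dict(self.params),
            "semi_axis_a": self.semi_axis_a,
            "semi_axis_c": self.semi_axis_c,
            "field": {
                "lobes_u": arr(self.field.lobes_u),
                "lobes_w": arr(self.field.lobes_w),
                "eps": self.field.eps,
                "norm": self.field.norm,
            },
            "bouton": {"vertices": arr(self.bouton_vertices), "faces": arr(self.bouton_faces)},
            "az_patches": [
                {
                    "preaz_face_indices": arr(p.preaz_face_indices),
                    "preaz_vertices": arr(p.preaz_vertices),
                    "preaz_faces": arr(p.preaz_faces),
                    "psd_vertices": arr(p.psd_vertices),
                    "psd_faces": arr(p.psd_faces),
                    "true_preaz_area": p.true_preaz_area,
                    "true_psd_area": p.true_psd_area,
                    "center": arr(p.center),
                    "outward_normal": arr(p.outward_normal),
                    "cleft_lateral": p.cleft_lateral,
                    "cleft_central": p.cleft_central,
                    "shape": p.shape,
                }
                for p in self.az_patches
            ],
            "vesicles": [
                {
                    "center": arr(v.center),
                    "radius": v.radius,
                    "pool": v.pool,
                    "docked": v.docked,
                    "dense_core": v.dense_core,
                    "az_index": v.az_index,
                    "perimeter_true": v.perimeter_true,
                    "track_id": v.track_id,
                }
                for v in self.vesicles
            ],
            "mitochondria": [
                {"center": arr(m.center), "semi_axes": arr(m.semi_axes)}
                for m in self.mitochondria
            ],
            "targets": [
                {"vertices": arr(v), "faces": arr(f)}
                for v, f in zip(self.target_vertices, self.target_faces)
            ],
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Scene":
        doc = json.loads(text)
        if doc.get("schema") != "synmorph/scene":
            raise SceneError("not a synmorph scene document")
        params = _params_from_dict(doc["params"])
        fld = _RadialField(
            np.array(doc["field"]["lobes_u"]),
            np.array(doc["field"]["lobes_w"]),
            doc["field"]["eps"],
            doc["field"]["norm"],
        )
        patches = [
            AZPatch(
                preaz_face_indices=np.array(p["preaz_face_indices"], dtype=int),
                preaz_vertices=np.array(p["preaz_vertices"]),
                preaz_faces=np.array(p["preaz_faces"], dtype=int),
                psd_vertices=np.array(p["psd_vertices"]),
                psd_faces=np.array(p["psd_faces"], dtype=int),
                true_preaz_area=p["true_preaz_area"],
                true_psd_area=p["true_psd_area"],
                center=np.array(p["center"]),
                outward_normal=np.array(p["outward_normal"]),
                cleft_lateral=p["cleft_lateral"],
                cleft_central=p["cleft_central"],
                shape=p["shape"],
            )
            for p in doc["az_patches"]
        ]
        vesicles = [
            GroundTruthVesicle(
                center=np.array(v["center"]),
                radius=v["radius"],
                pool=v["pool"],
                docked=v["docked"],
                dense_core=v["dense_core"],
                az_index=v["az_index"],
                perimeter_true=v["perimeter_true"],
                track_id=v["track_id"],
            )
            for v in doc["vesicles"]
        ]
        mitos = [
            Ellipsoid(np.array(m["center"]), np.array(m["semi_axes"]))
            for m in doc["mitochondria"]
        ]
        return cls(
            params=params,
            semi_axis_a=doc["semi_axis_a"],
            semi_axis_c=doc["semi_axis_c"],
            field=fld,
            bouton_vertices=np.array(doc["bouton"]["vertices"]),
            bouton_faces=np.array(doc["bouton"]["faces"], dtype=int),
            az_patches=patches,
            vesicles=vesicles,
            mitochondria=mitos,
            target_vertices=[np.array(t["vertices"]) for t in doc["targets"]],
            target_faces=[np.array(t["faces"], dtype=int) for t in doc["targets"]],
        )

    def save_ply(self, path) -> None:
        """Export the bouton surface (and AZ patches) for inspection."""
        self.mesh.export(path, file_type="ply")


def _params_to_dict(p: SceneParams) -> dict:
    d = dataclasses.asdict(p)
    d["pool_spec"] = dataclasses.asdict(p.pool_spec)
    d["cleft_spec"] = dataclasses.asdict(p.cleft_spec)
    return d


def _params_from_dict(d: dict) -> SceneParams:
    d = dict(d)
    d["pool_spec"] = PoolSpec(**d["pool_spec"])
    d["cleft_spec"] = CleftSpec(**d["cleft_spec"])
    d["az_area_targets"] = tuple(d["az_area_targets"])
    if d.get("psd_area_targets") is not None:
        d["psd_area_targets"] = tuple(d["psd_area_targets"])
    d["sv_diameter_range"] = tuple(d["sv_diameter_range"])
    return SceneParams(**d)


# ---------------------------------------------------------------------------
# bouton shape fitting


def _prolate_area(a: float, c: float) -> float:
    if abs(c - a) < 1e-9 * a:
        return 4 * np.pi * a * a
    e = np.sqrt(1 - (a / c) ** 2)
    return 2 * np.pi * a * a * (1 + (c / (a * e)) * np.arcsin(e))


def _fit_bouton(
    fld: _RadialField, area_target: float, volume_target: float
) -> tuple[float, float, trimesh.Trimesh]:
    """Solve transverse/axial semi-axes so the perturbed mesh hits both the
    surface-area and the volume target (exactly for volume, to float
    precision for area via a 1D root find on the aspect ratio)."""
    from scipy.optimize import brentq

    unit = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    dirs = unit.vertices
    factors = fld.factor(dirs)
    base_verts = dirs * factors[:, None]
    base = trimesh.Trimesh(vertices=base_verts, faces=unit.faces, process=False)
    v0 = base.volume

    def build(q: float) -> trimesh.Trimesh:
        a = (volume_target / (v0 * q)) ** (1.0 / 3.0)
        verts = base_verts * np.array([a, a, a * q])
        return trimesh.Trimesh(vertices=verts, faces=unit.faces, process=False)

    def resid(q: float) -> float:
        return build(q).area - area_target

    sphere_area = build(1.0).area
    if area_target < sphere_area:
        raise PackingInfeasibleError(
            "surface_to_volume_ratio",
            f"(surface target {area_target:.3g} nm^2 below the spherical minimum "
            f"{sphere_area:.3g} nm^2 for volume {volume_target:.3g} nm^3)",
        )
    q_hi = 2.0
    while resid(q_hi) < 0 and q_hi < 1e4:
        q_hi *= 2.0
    q = brentq(resid, 1.0, q_hi, xtol=1e-10, rtol=1e-12)
    mesh = build(q)
    a = (volume_target / (v0 * q)) ** (1.0 / 3.0)
    return a, a * q, mesh


# ---------------------------------------------------------------------------
# AZ patches


def _patch_face_mask(
    mesh: trimesh.Trimesh,
    center: np.ndarray,
    frame: tuple[np.ndarray, np.ndarray],
    rho: float,
    shape: str,
) -> np.ndarray:
    cent = mesh.triangles_center
    d3 = np.linalg.norm(cent - center, axis=1)
    mask = d3 < rho
    if shape == "macular":
        return mask
    t1, t2 = frame
    rel = cent - center
    x = rel @ t1
    y = rel @ t2
    r_loc = np.hypot(x, y)
    ang = np.arctan2(y, x)
    if shape == "ring":
        return mask & (r_loc > 0.55 * rho)
    if shape == "horseshoe":
        return mask & ~((r_loc < 0.5 * rho) | (np.abs(ang) < np.pi / 3))
    if shape == "perforated":
        hole = np.zeros_like(mask)
        for hx in (-0.4 * rho, 0.4 * rho):
            hole |= np.hypot(x - hx, y) < 0.24 * rho
        return mask & ~hole
    raise SceneError(f"unknown az_shape {shape!r}")


def _make_az_patch(
    mesh: trimesh.Trimesh,
    direction: np.ndarray,
    a: float,
    c: float,
    fld: _RadialField,
    area_target: float,
    psd_target: float,
    shape: str,
    cleft: CleftSpec,
) -> AZPatch:
    direction = direction / np.linalg.norm(direction)
    center = np.array([a, a, c]) * direction * fld.factor(direction[None, :])[0]
    # local tangent frame at the patch centre
    n_out = center / np.array([a**2, a**2, c**2])
    n_out = n_out / np.linalg.norm(n_out)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n_out @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(ref, n_out)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n_out, t1)

    areas = mesh.area_faces

    def realized(rho: float) -> float:
        return float(areas[_patch_face_mask(mesh, center, (t1, t2), rho, shape)].sum())

    rho_lo, rho_hi = 1.0, 2 * max(a, 200.0)
    while realized(rho_hi) < area_target:
        rho_hi *= 1.6
        if rho_hi > 20 * max(a, c):
            raise PackingInfeasibleError("az_area", "(AZ target exceeds available surface)")
    for _ in range(60):
        mid = 0.5 * (rho_lo + rho_hi)
        if realized(mid) < area_target:
            rho_lo = mid
        else:
            rho_hi = mid
    rho = 0.5 * (rho_lo + rho_hi)
    fmask = _patch_face_mask(mesh, center, (t1, t2), rho, shape)
    face_idx = np.flatnonzero(fmask)
    if len(face_idx) == 0:
        raise PackingInfeasibleError("az_area", "(empty AZ patch)")
    sub_faces_global = mesh.faces[face_idx]
    used = np.unique(sub_faces_global)
    remap = -np.ones(len(mesh.vertices), dtype=int)
    remap[used] = np.arange(len(used))
    pre_verts = mesh.vertices[used]
    pre_faces = remap[sub_faces_global]
    pre_area = float(areas[face_idx].sum())

    k = np.sqrt(psd_target / pre_area)
    psd_verts = center + k * (pre_verts - center) + n_out * cleft.central_width
    psd_area = float(
        triangle_areas(psd_verts[pre_faces]).sum()
    )

    return AZPatch(
        preaz_face_indices=face_idx,
        preaz_vertices=pre_verts,
        preaz_faces=pre_faces,
        psd_vertices=psd_verts,
        psd_faces=pre_faces.copy(),
        true_preaz_area=pre_area,
        true_psd_area=psd_area,
        center=center,
        outward_normal=n_out,
        cleft_lateral=cleft.lateral_width,
        cleft_central=cleft.central_width,
        shape=shape,
    )


def _target_surface(patch: AZPatch, kind: str) -> tuple[np.ndarray, np.ndarray]:
    radius = {"spine": 300.0, "shaft": 600.0, "astrocytic_process": 150.0}[kind]
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=radius)
    center = patch.center + patch.outward_normal * (patch.cleft_central + radius)
    return sphere.vertices + center, sphere.faces


# ---------------------------------------------------------------------------
# vesicle placement


class _PatchDistance:
    """Exhaustive distance from points to the nearest PreAZ patch."""

    def __init__(self, patches: list[AZPatch]):
        tris = []
        owner = []
        for i, p in enumerate(patches):
            t = p.preaz_triangles
            tris.append(t)
            owner.append(np.full(len(t), i))
        self.tris = np.concatenate(tris, axis=0)
        self.owner = np.concatenate(owner)
        self.areas = triangle_areas(self.tris)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d, idx = point_triangle_distance(points, self.tris)
        return d, self.owner[idx]

    def sample_surface(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Random points on the patch surface with inward normals."""
        p = self.areas / self.areas.sum()
        ti = rng.choice(len(self.tris), size=n, p=p)
        tri = self.tris[ti]
        r1 = np.sqrt(rng.random(n))
        r2 = rng.random(n)
        pts = (
            (1 - r1)[:, None] * tri[:, 0]
            + (r1 * (1 - r2))[:, None] * tri[:, 1]
            + (r1 * r2)[:, None] * tri[:, 2]
        )
        nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        # make it inward: the bouton interior is on the side of the origin-ish
        flip = np.einsum("nk,nk->n", nrm, pts) > 0
        nrm[flip] *= -1
        return pts, nrm


def _bin_of(p: float) -> str:
    if p <= 10.0:
        return "p10"
    if p <= 20.0:
        return "p10_20"
    if p < 60.0:
        return "intermediate"
    if p <= 200.0:
        return "rp"
    return "resting"


class _VesiclePacker:
    """Hard-sphere acceptance with a uniform cell grid for neighbour lookup."""

    def __init__(self, rng, overlap_tol, cell: float = 100.0):
        self.n = 0
        self._centers = np.empty((256, 3))
        self._radii = np.empty(256)
        self.overlap_tol = overlap_tol
        self.cell = cell
        self._grid: dict[tuple[int, int, int], list[int]] = {}

    def _key(self, center) -> tuple[int, int, int]:
        return tuple(np.floor(np.asarray(center) / self.cell).astype(int))

    def fits(self, center: np.ndarray, radius: float) -> bool:
        if self.n == 0:
            return True
        kx, ky, kz = self._key(center)
        idx: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    idx.extend(self._grid.get((kx + dx, ky + dy, kz + dz), ()))
        if not idx:
            return True
        ii = np.asarray(idx)
        d = np.linalg.norm(self._centers[ii] - center, axis=1)
        return bool(np.all(d >= self._radii[ii] + radius - self.overlap_tol))

    def add(self, center: np.ndarray, radius: float) -> None:
        if self.n == len(self._radii):
            self._centers = np.vstack([self._centers, np.empty_like(self._centers)])
            self._radii = np.concatenate([self._radii, np.empty_like(self._radii)])
        self._centers[self.n] = center
        self._radii[self.n] = radius
        self._grid.setdefault(self._key(center), []).append(self.n)
        self.n += 1


def _place_vesicles(
    scene: Scene, rng: np.random.Generator
) -> list[GroundTruthVesicle]:
    params = scene.params
    counts = params.pool_spec.counts_for_total(params.total_sv)
    n_docked = int(round(params.pool_spec.docked_fraction * counts["p10"]))
    pd = _PatchDistance(scene.az_patches)
    packer = _VesiclePacker(rng, params.overlap_tolerance)
    d_lo, d_hi = params.sv_diameter_range
    out: list[GroundTruthVesicle] = []
    track = 0

    def mito_free(pts: np.ndarray, r: float) -> np.ndarray:
        ok = np.ones(len(pts), dtype=bool)
        for m in scene.mitochondria:
            ok &= ~m.contains(pts, inflate=r)
        return ok

    def accept(center, radius, p_exact, az_idx, pool, docked, dense_core):
        nonlocal track
        out.append(
            GroundTruthVesicle(
                center=np.asarray(center, dtype=float),
                radius=float(radius),
                pool=pool,
                docked=docked,
                dense_core=dense_core,
                az_index=int(az_idx),
                perimeter_true=float(max(p_exact, 0.0)),
                track_id=track,
            )
        )
        packer.add(np.asarray(center, dtype=float), float(radius))
        track += 1

    max_attempts = 600 * max(params.total_sv, 1) + 20000
    margin_pad = 2.0

    # --- dense-core vesicles first (largest spheres need free pockets) ---
    placed = 0
    attempts = 0
    while placed < params.n_dense_core:
        attempts += 1
        if attempts > 40000:
            raise PackingInfeasibleError("dense_core_placement")
        r = rng.uniform(35.0, 45.0)
        a_in = scene.semi_axis_a - 1.35 * (r + margin_pad) - abs(scene.field.eps) * scene.semi_axis_a
        c_in = scene.semi_axis_c - 1.35 * (r + margin_pad) - abs(scene.field.eps) * scene.semi_axis_a
        if a_in <= 0 or c_in <= 0:
            raise PackingInfeasibleError("bouton_size", "(dense-core radius exceeds bouton)")
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pt = u * rng.random() ** (1 / 3) * np.array([a_in, a_in, c_in])
        d, az = pd.query(pt[None, :])
        if not mito_free(pt[None, :], r)[0] or not packer.fits(pt, r):
            continue
        accept(pt, r, d[0] - r, az[0], None, False, True)
        placed += 1

    # --- near bins: construct by inward offset from a random patch point ---
    near_quota = {
        "p10": counts["p10"] - n_docked,
        "p10_20": counts["p10_20"],
        "intermediate": counts["intermediate"],
    }
    # docked first: tangent to the membrane specialization, p = 0
    attempts = 0
    placed_docked = 0
    while placed_docked < n_docked:
        attempts += 1
        if attempts > max_attempts:
            raise PackingInfeasibleError("docked_placement")
        q, n_in = pd.sample_surface(rng, 1)
        r = rng.uniform(d_lo, d_hi) / 2.0
        center = q[0] + n_in[0] * r
        d, az = pd.query(center[None, :])
        p_exact = d[0] - r
        if p_exact > 1.0:  # foot slipped off the patch edge
            continue
        if not mito_free(center[None, :], r)[0] or not packer.fits(center, r):
            continue
        accept(center, r, p_exact, az[0], "p10", True, False)
        placed_docked += 1

    from scipy.spatial import cKDTree

    r_max = d_hi / 2.0
    r_min = d_lo / 2.0
    tree = {"obj": None, "n": 0}

    def overlap_prefilter(pts: np.ndarray, radii: np.ndarray) -> np.ndarray:
        """Cheap pass that only removes definite overlaps (the exact
        grid check in ``packer.fits`` runs on the survivors)."""
        if packer.n == 0:
            return np.ones(len(pts), dtype=bool)
        if tree["obj"] is None or packer.n - tree["n"] > 128:
            tree["obj"] = cKDTree(packer._centers[: packer.n])
            tree["n"] = packer.n
        d1, _ = tree["obj"].query(pts, k=1)
        return d1 >= radii + r_min - packer.overlap_tol

    # --- AZ-proximal bins (p <= 60 nm): structured shell packing ---
    # The Table-1 counts put the readily-releasable and intermediate bins at
    # local packing densities beyond the random-sequential-adsorption jamming
    # limit, so candidates are drawn from blue-noise sites on the patch
    # surface at stratified depths rather than fully at random; depth below
    # the membrane equals r + p, which keeps the sphere contained as long as
    # the depth stays below the local curvature radius.
    pitch = 0.5 * (d_lo + d_hi) - params.overlap_tolerance + 1.0
    raw_pts, raw_nrm = pd.sample_surface(rng, 6000)
    site_pos: list[np.ndarray] = []
    site_nrm: list[np.ndarray] = []
    grid: dict[tuple[int, int, int], list[int]] = {}
    inv = 1.0 / pitch
    for i in range(len(raw_pts)):
        key = tuple(np.floor(raw_pts[i] * inv).astype(int))
        close = False
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        if np.linalg.norm(raw_pts[i] - site_pos[j]) < pitch:
                            close = True
                            break
        if not close:
            grid.setdefault(key, []).append(len(site_pos))
            site_pos.append(raw_pts[i])
            site_nrm.append(raw_nrm[i])
    sites = np.asarray(site_pos)
    site_normals = np.asarray(site_nrm)

    for bin_name in ("p10", "p10_20", "intermediate"):
        lo, hi = POOL_EDGES[bin_name]
        need = near_quota[bin_name]
        if need == 0:
            continue
        guard = 0.25
        n_layers = max(1, int(np.floor((hi - lo) / pitch)) + (1 if bin_name == "intermediate" else 0))
        sub = np.linspace(lo, hi, n_layers + 1)
        placed = 0
        stalled = 0
        for _pass in range(60):
            placed_at_start = placed
            combos = [(s, l) for s in range(len(sites)) for l in range(n_layers)]
            rng.shuffle(combos)
            for s, l in combos:
                if placed >= need:
                    break
                r = rng.uniform(d_lo, d_hi) / 2.0
                p_t = rng.uniform(sub[l] + guard, sub[l + 1] - guard)
                jit = rng.uniform(-0.25, 0.25, size=3) * pitch
                jit -= (jit @ site_normals[s]) * site_normals[s]
                center = sites[s] + jit + site_normals[s] * (r + p_t)
                d, az = pd.query(center[None, :])
                p_exact = d[0] - r
                if not (lo < p_exact < hi if bin_name == "intermediate" else lo < p_exact <= hi):
                    continue
                if not mito_free(center[None, :], r)[0]:
                    continue
                if packer.fits(center, r):
                    accept(center, r, p_exact, az[0], bin_name, False, False)
                    placed += 1
            if placed >= need:
                break
            stalled = stalled + 1 if placed == placed_at_start else 0
            if stalled >= 2:
                break  # two whole passes placed nothing: the shell is jammed
        if placed < need:
            raise PackingInfeasibleError(
                f"pool_{bin_name}",
                f"(placed {placed}/{need}; AZ area too small for the requested count)",
            )

    # --- recycling + resting pools: uniform sampling inside the eroded bouton ---
    far_quota = {"rp": counts["rp"], "resting": counts["resting"]}
    attempts = 0
    stalled = 0
    a_in = scene.semi_axis_a - 1.35 * (r_max + margin_pad) - abs(scene.field.eps) * scene.semi_axis_a
    c_in = scene.semi_axis_c - 1.35 * (r_max + margin_pad) - abs(scene.field.eps) * scene.semi_axis_a
    if (a_in <= 0 or c_in <= 0) and (far_quota["rp"] or far_quota["resting"]):
        raise PackingInfeasibleError("bouton_size", "(vesicle radius exceeds bouton)")
    while far_quota["rp"] > 0 or far_quota["resting"] > 0:
        attempts += 1
        if attempts > 12000 or stalled >= 25:
            missing = [k for k, v in far_quota.items() if v > 0]
            raise PackingInfeasibleError(
                f"pool_{missing[0]}",
                f"(unfilled quota {far_quota}; bouton volume cannot host the requested pools)",
            )
        before = far_quota["rp"] + far_quota["resting"]
        batch = 2048
        u = rng.normal(size=(batch, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rad = rng.random(batch) ** (1.0 / 3.0)
        pts = u * rad[:, None] * np.array([a_in, a_in, c_in])
        radii = rng.uniform(d_lo, d_hi, size=batch) / 2.0
        keep = overlap_prefilter(pts, radii)
        keep &= mito_free(pts, float(radii.mean()))
        idx = np.flatnonzero(keep)
        if len(idx):
            d, az = pd.query(pts[idx])
            p_exact = d - radii[idx]
            for j in range(len(idx)):
                p = p_exact[j]
                if 60.0 <= p <= 200.0 and far_quota["rp"] > 0:
                    pool = "rp"
                elif p > 200.0 and far_quota["resting"] > 0:
                    pool = "resting"
                else:
                    continue
                i = idx[j]
                if packer.fits(pts[i], radii[i]):
                    accept(pts[i], radii[i], p, az[j], pool, False, False)
                    far_quota[pool] -= 1
                if far_quota["rp"] == 0 and far_quota["resting"] == 0:
                    break
        after = far_quota["rp"] + far_quota["resting"]
        stalled = stalled + 1 if after == before else 0

    return out


def _place_mitochondria(
    a: float, c: float, volume_nm3: float, params: SceneParams, rng: np.random.Generator
) -> list[Ellipsoid]:
    n = params.n_mitochondria
    if n == 0 or params.mito_volume_fraction_target == 0.0:
        return []
    v_each = params.mito_volume_fraction_target * volume_nm3 / n
    am = (3.0 * v_each / (16.0 * np.pi)) ** (1.0 / 3.0)  # aspect 1:4 by default
    am = min(am, 0.55 * a)
    cm = 3.0 * v_each / (4.0 * np.pi * am**2)
    z_max = 0.78 * c - cm
    if z_max < 0:
        raise PackingInfeasibleError("mitochondria", "(mitochondrion longer than bouton)")
    if n == 1:
        zs = np.array([0.0])
    else:
        zs = np.linspace(-z_max, z_max, n)
        if n > 1 and (zs[1] - zs[0]) < 2.05 * cm:
            raise PackingInfeasibleError("mitochondria", "(mitochondria overlap on the axis)")
    mitos = []
    for z in zs:
        for jitter_scale in (0.25, 0.0):
            jitter = rng.uniform(-1, 1, size=2) * jitter_scale * max(a - am, 0.0)
            m = Ellipsoid(
                center=np.array([jitter[0], jitter[1], z]), semi_axes=np.array([am, am, cm])
            )
            if _ellipsoid_inside(m, a, c, margin=2.0 + 1.2 * params.perturbation * a):
                mitos.append(m)
                break
        else:
            raise PackingInfeasibleError(
                "mitochondria", "(mitochondrion does not fit inside the bouton)"
            )
    return mitos


def _ellipsoid_inside(m: Ellipsoid, scene_a: float, scene_c: float, margin: float = 2.0) -> bool:
    """Conservative check that an axis-aligned ellipsoid sits inside the
    unperturbed bouton spheroid (sampled over its surface)."""
    u = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    v = np.linspace(0, np.pi, 9)
    uu, vv = np.meshgrid(u, v)
    pts = np.column_stack(
        [
            (m.semi_axes[0] * np.sin(vv) * np.cos(uu)).ravel(),
            (m.semi_axes[1] * np.sin(vv) * np.sin(uu)).ravel(),
            (m.semi_axes[2] * np.cos(vv)).ravel(),
        ]
    ) + m.center
    q = pts / np.array([scene_a - margin, scene_a - margin, scene_c - margin])
    return bool((np.linalg.norm(q, axis=1) <= 1.0).all())


def generate_scene(params: SceneParams) -> Scene:
    """Generate a ground-truth scene; deterministic for a fixed seed.

    Raises :class:`PackingInfeasibleError` naming the binding constraint when
    the requested configuration cannot be realised.
    """
    rng = np.random.default_rng(params.rng_seed)
    fld = _RadialField.random(rng, params.perturbation)
    a, c, mesh = _fit_bouton(
        fld, params.bouton_surface_area_target, params.bouton_volume_target
    )

    psd_targets = params.psd_area_targets or params.az_area_targets
    phis = rng.uniform(0, 2 * np.pi) + np.arange(params.n_az) * (2 * np.pi / max(params.n_az, 1))
    z_fracs = [0.0, 0.22, -0.22][: params.n_az]
    patches = []
    for i in range(params.n_az):
        direction = np.array(
            [np.cos(phis[i]), np.sin(phis[i]), z_fracs[i]]
        )
        patches.append(
            _make_az_patch(
                mesh,
                direction,
                a,
                c,
                fld,
                params.az_area_targets[i],
                psd_targets[i],
                params.az_shape,
                params.cleft_spec,
            )
        )

    scene = Scene(
        params=params,
        semi_axis_a=a,
        semi_axis_c=c,
        field=fld,
        bouton_vertices=np.asarray(mesh.vertices),
        bouton_faces=np.asarray(mesh.faces),
        az_patches=patches,
        vesicles=[],
        mitochondria=[],
        target_vertices=[],
        target_faces=[],
        _mesh=mesh,
    )
    scene.mitochondria = _place_mitochondria(a, c, scene.volume_nm3, params, rng)
    if params.total_sv > 0 or params.n_dense_core > 0:
        scene.vesicles = _place_vesicles(scene, rng)

    for p in patches:
        tv, tf = _target_surface(p, params.target_kind)
        scene.target_vertices.append(tv)
        scene.target_faces.append(tf)

    _validate_scene(scene)
    return scene


def _validate_scene(scene: Scene) -> None:
    p = scene.params
    rel_area = abs(scene.surface_area_nm2 - p.bouton_surface_area_target) / p.bouton_surface_area_target
    rel_vol = abs(scene.volume_nm3 - p.bouton_volume_target) / p.bouton_volume_target
    if rel_area > 0.02 or rel_vol > 0.02:
        raise PackingInfeasibleError(
            "bouton_geometry", f"(area off by {rel_area:.1%}, volume by {rel_vol:.1%})"
        )
    for i, patch in enumerate(scene.az_patches):
        rel = abs(patch.true_preaz_area - p.az_area_targets[i]) / p.az_area_targets[i]
        if rel > 0.02:
            raise PackingInfeasibleError("az_area", f"(AZ {i} off by {rel:.1%})")
    counts = scene.pool_counts()
    want = p.pool_spec.counts_for_total(p.total_sv)
    if counts != want:
        raise PackingInfeasibleError("pool_counts", f"(realized {counts} != target {want})")
    if p.n_mitochondria > 0 and p.mito_volume_fraction_target > 0:
        if abs(scene.mito_volume_fraction - p.mito_volume_fraction_target) > 0.02:
            raise PackingInfeasibleError("mito_volume_fraction")


# ---------------------------------------------------------------------------
# Table-1 presets (human temporal lobe neocortex layers L4 and L5)

_PRESETS = {
    "L4_TLN": dict(
        bouton_surface_area_target=2.50e6,
        bouton_volume_target=0.16e9,
        az_area_targets=(0.13e6,),
        psd_area_targets=(0.13e6,),
        total_sv=1821,
        pools=dict(p10=20, p10_20=29, intermediate=138, rp=382, resting=1252),
        cleft=CleftSpec(lateral_width=14.11, central_width=16.47, noise_sd=2.0),
        n_mitochondria=2,
        docked_fraction=0.3,
        # ~49 RRP(p20) vesicles crowd a 0.13 µm² AZ: near-contact packing with
        # visible membrane flattening, so allow a deeper sphere overlap here
        overlap_tolerance=8.0,
    ),
    "L5_TLN": dict(
        bouton_surface_area_target=6.09e6,
        bouton_volume_target=0.63e9,
        az_area_targets=(0.23e6,),
        psd_area_targets=(0.28e6,),
        total_sv=1519,
        pools=dict(p10=5, p10_20=10, intermediate=58, rp=182, resting=1264),
        cleft=CleftSpec(lateral_width=17.24, central_width=19.05, noise_sd=2.2),
        n_mitochondria=4,
        docked_fraction=0.4,
        overlap_tolerance=4.0,
    ),
}


def preset_from_table1(layer: str, rng_seed: int = 0, **overrides) -> SceneParams:
    """Scene parameters whose targets equal the human L4/L5 temporal-lobe
    neocortex column means (surface area, volume, AZ/PSD area, total vesicle
    count, pool structure, cleft widths)."""
    if layer not in _PRESETS:
        raise SceneError(f"unknown layer {layer!r}; choose from {sorted(_PRESETS)}")
    cfg = _PRESETS[layer]
    total = cfg["total_sv"]
    pools = cfg["pools"]
    assert sum(pools.values()) == total
    pool_spec = PoolSpec(
        frac_p10=pools["p10"] / total,
        frac_p10_20=pools["p10_20"] / total,
        frac_20_60=pools["intermediate"] / total,
        frac_rp=pools["rp"] / total,
        frac_resting=pools["resting"] / total,
        docked_fraction=cfg["docked_fraction"],
    )
    kwargs = dict(
        bouton_kind="en_passant",
        bouton_surface_area_target=cfg["bouton_surface_area_target"],
        bouton_volume_target=cfg["bouton_volume_target"],
        n_az=1,
        az_area_targets=cfg["az_area_targets"],
        psd_area_targets=cfg["psd_area_targets"],
        az_shape="macular",
        total_sv=total,
        pool_spec=pool_spec,
        cleft_spec=cfg["cleft"],
        n_mitochondria=cfg["n_mitochondria"],
        mito_volume_fraction_target=0.12,
        target_kind="spine",
        overlap_tolerance=cfg["overlap_tolerance"],
        rng_seed=rng_seed,
    )
    kwargs.update(overrides)
    return SceneParams(**kwargs)
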