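import numpy as np
import pytest

from helpers import circle
from synmorph.metrics import (
    CleftMeasurement,
    MetricsError,
    classify_az_shape,
    estimate_psd_area,
    extract_preaz,
    measure_cleft,
    points_within_density,
)
from synmorph.reconstruct import loft_surface
from synmorph.sectioning import ContourStack, Section


class TestPsdEstimator:
    def test_direct_application(self):
        assert estimate_psd_area(0.2, 300.0, 200.0) == pytest.approx(0.3)

    def test_identity_when_lengths_equal(self):
        assert estimate_psd_area(0.173, 250.0, 250.0) == pytest.approx(0.173)

    def test_zero_preaz_length_raises(self):
        with pytest.raises(MetricsError):
            estimate_psd_area(0.2, 300.0, 0.0)

    def test_exact_to_machine_precision(self):
        sa, lp, lq = 0.123456789, 431.25, 317.5
        assert estimate_psd_area(sa, lp, lq) == sa * lp / lq

    def test_homogeneity_under_length_scaling(self):
        """Scaling all lengths by k scales the area estimate by k^2 through
        sa_preaz while the length ratio is invariant."""
        sa, lp, lq, k = 0.2, 300.0, 200.0, 3.7
        base = estimate_psd_area(sa, lp, lq)
        scaled = estimate_psd_area(sa * k**2, lp * k, lq * k)
        assert scaled == pytest.approx(base * k**2, rel=1e-12)

    def test_recovers_true_psd_on_parallel_membrane_scene(self, l5_scene, l5_stack):
        """With the true PreAZ area and measured contour lengths, the
        estimator lands within 5% of the ground-truth PSD patch area."""
        from synmorph.metrics import density_contour_length

        l_pre = density_contour_length(l5_stack, "preaz_density")
        l_psd = density_contour_length(l5_stack, "psd_density")
        patch = l5_scene.az_patches[0]
        est = estimate_psd_area(patch.true_preaz_area / 1e6, l_psd, l_pre)
        assert est == pytest.approx(patch.true_psd_area / 1e6, rel=0.05)


class TestThirtyNanometreRule:
    def _stack_with_vertical_density(self):
        sec = Section(
            index=0,
            z_lo=0.0,
            z_hi=55.0,
            polylines={"preaz_density": [np.array([[0.0, -500.0], [0.0, 500.0]])]},
        )
        return ContourStack(sections=[sec], alignment_state="aligned")

    def test_strict_inclusion_at_29_30_31(self):
        stack = self._stack_with_vertical_density()
        pts = np.array([[29.0, 0.0, 10.0], [30.0, 0.0, 10.0], [31.0, 0.0, 10.0]])
        mask = points_within_density(pts, stack)
        assert mask.tolist() == [True, False, False]

    def test_point_outside_section_excluded(self):
        stack = self._stack_with_vertical_density()
        pts = np.array([[0.0, 0.0, 80.0]])   # z beyond the only section
        assert not points_within_density(pts, stack).any()

    def test_no_density_returns_zero_area_with_warning(self):
        st = ContourStack(
            sections=[
                Section(index=0, z_lo=0, z_hi=55, polygons={"bouton": [circle(300.0)]}),
                Section(index=1, z_lo=55, z_hi=110, polygons={"bouton": [circle(300.0)]}),
                Section(index=2, z_lo=110, z_hi=165, polygons={}),
            ],
            alignment_state="aligned",
        )
        res = loft_surface(st, "bouton")
        with pytest.warns(UserWarning):
            sa, l_pre, _ = extract_preaz(res.mesh, st)
        assert sa == 0.0 and l_pre == 0.0

    def test_spherical_cap_fixture_within_three_percent(self):
        """A polar cap annotated with density arcs at a 10 nm radial offset:
        the extracted membrane area matches the closed-form cap area."""
        R, theta, t = 500.0, np.pi / 3, 10.0
        z_cap = R * np.cos(theta)
        sections = []
        k = 0
        z = -R - 1.5 * t
        while z < R + t:
            zm = z + t / 2
            polys, lines = {}, {}
            if abs(zm) < R:
                r = np.sqrt(R**2 - zm**2)
                polys = {"bouton": [circle(r, n=512)]}
                if zm >= z_cap - 1e-9:
                    lines = {"preaz_density": [circle(r + 10.0, n=512)]}
            sections.append(
                Section(index=k, z_lo=z, z_hi=z + t, polygons=polys, polylines=lines)
            )
            z += t
            k += 1
        stack = ContourStack(sections=sections, alignment_state="aligned")
        res = loft_surface(stack, "bouton")
        sa, _, _ = extract_preaz(res.mesh, stack)
        cap_area = 2 * np.pi * R * (R - z_cap) / 1e6
        assert sa == pytest.approx(cap_area, rel=0.03)

    def test_preaz_never_exceeds_total_surface(self, l5_stack):
        res = loft_surface(l5_stack, "bouton")
        sa, _, _ = extract_preaz(res.mesh, l5_stack)
        assert 0 < sa <= res.surface_area_um2


class TestCleft:
    def test_lateral_mean_arithmetic(self):
        m = CleftMeasurement(lateral_1=16.0, lateral_2=18.0, central=30.0)
        assert m.lateral_mean == pytest.approx(17.0)
        assert m.central == pytest.approx(30.0)

    def test_l5_cleft_widths_recovered_within_five_percent(self, l5_scene):
        """Repeated sectioning of an L5-preset synapse recovers the
        configured lateral width (17.24 nm) at the subject level."""
        from synmorph.sectioning import SectionPlan, section_scene

        profiles = []
        for seed in range(20):
            st = section_scene(l5_scene, SectionPlan(), seed=500 + seed)
            profiles.extend(
                CleftMeasurement(c.lateral_1, c.lateral_2, c.central,
                                 perpendicularity_ok=c.perpendicularity_ok)
                for c in st.cleft_profiles
            )
        kept, _ = measure_cleft(profiles)
        lat = np.mean([p.lateral_mean for p in kept])
        cen = np.mean([p.central for p in kept])
        assert lat == pytest.approx(17.24, rel=0.05)
        assert cen == pytest.approx(19.05, rel=0.05)

    def test_non_perpendicular_profiles_excluded_and_counted(self):
        profiles = [
            CleftMeasurement(16, 18, 30, perpendicularity_ok=True),
            CleftMeasurement(10, 12, 20, perpendicularity_ok=False),
            CleftMeasurement(17, 17, 25, perpendicularity_ok=True),
        ]
        kept, n_excl = measure_cleft(profiles)
        assert len(kept) == 2
        assert n_excl == 1


def _disk_patch(n_rings=8, n_ang=32, r=100.0):
    """Fan-triangulated planar disk."""
    verts = [[0.0, 0.0, 0.0]]
    faces = []
    for i in range(1, n_rings + 1):
        for j in range(n_ang):
            a = 2 * np.pi * j / n_ang
            verts.append([r * i / n_rings * np.cos(a), r * i / n_rings * np.sin(a), 0.0])
    def vid(i, j):
        return 1 + (i - 1) * n_ang + (j % n_ang)
    for j in range(n_ang):
        faces.append([0, vid(1, j), vid(1, j + 1)])
    for i in range(1, n_rings):
        for j in range(n_ang):
            faces.append([vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)])
            faces.append([vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)])
    return np.array(verts), np.array(faces)


def _annulus_patch(r_in=60.0, r_out=100.0, n_rings=5, n_ang=48, sector=None):
    verts, faces = [], []
    radii = np.linspace(r_in, r_out, n_rings)
    angs = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    if sector is not None:
        angs = angs[(angs > sector / 2) | (angs > 2 * np.pi - 1e-9)]
        angs = np.linspace(sector / 2, 2 * np.pi - sector / 2, n_ang)
    for r in radii:
        for a in angs:
            verts.append([r * np.cos(a), r * np.sin(a), 0.0])
    n_a = len(angs)
    closed = sector is None
    for i in range(n_rings - 1):
        rng_j = range(n_a) if closed else range(n_a - 1)
        for j in rng_j:
            a0 = i * n_a + j
            a1 = i * n_a + (j + 1) % n_a
            b0 = (i + 1) * n_a + j
            b1 = (i + 1) * n_a + (j + 1) % n_a
            faces.append([a0, b0, b1])
            faces.append([a0, b1, a1])
    return np.array(verts), np.array(faces)


class TestShapeClassification:
    def test_disk_is_macular(self):
        v, f = _disk_patch()
        assert classify_az_shape(v, f) == "macular"

    def test_annulus_is_ring(self):
        v, f = _annulus_patch()
        assert classify_az_shape(v, f) == "ring"

    def test_c_shape_is_horseshoe(self):
        v, f = _annulus_patch(sector=2 * np.pi / 3)
        assert classify_az_shape(v, f) == "horseshoe"

    def test_empty_patch_raises(self):
        with pytest.raises(MetricsError):
            classify_az_shape(np.empty((0, 3)), np.empty((0, 3), dtype=int))

    @pytest.mark.parametrize("shape", ["macular", "ring", "horseshoe", "perforated"])
    def test_generator_shapes_recovered(self, shape):
        """Patches generated with a requested topology classify back to it."""
        from conftest import small_params
        from synmorph.scene_synth import generate_scene

        scene = generate_scene(
            small_params(az_shape=shape, total_sv=0, n_dense_core=0,
                         az_area_targets=(0.12e6,), psd_area_targets=(0.12e6,),
                         rng_seed=21)
        )
        p = scene.az_patches[0]
        assert classify_az_shape(p.preaz_vertices, p.preaz_faces) == shape
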