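import numpy as np
import pytest

from conftest import small_params
from synmorph.scene_synth import (
    PackingInfeasibleError,
    PoolSpec,
    Scene,
    SceneError,
    _bin_of,
    _PatchDistance,
    generate_scene,
    preset_from_table1,
)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            dict(n_az=4, az_area_targets=(1e5,) * 4),
            dict(bouton_surface_area_target=-1.0),
            dict(az_area_targets=(1e5, 1e5)),  # length != n_az
            dict(sv_diameter_range=(40.0, 30.0)),
            dict(mito_volume_fraction_target=1.5),
        ],
    )
    def test_invalid_params_raise(self, overrides):
        with pytest.raises(SceneError):
            small_params(**overrides)

    def test_pool_fractions_must_sum_to_one(self):
        with pytest.raises(SceneError):
            PoolSpec(frac_p10=0.5, frac_p10_20=0.5, frac_20_60=0.5, frac_rp=0.0, frac_resting=0.0)

    def test_unknown_layer(self):
        with pytest.raises(SceneError):
            preset_from_table1("L9_TLN")


class TestTable1Presets:
    """The presets carry the human temporal-lobe neocortex column means."""

    def test_l5_surface_area_target(self):
        p = preset_from_table1("L5_TLN")
        assert p.bouton_surface_area_target == pytest.approx(6.09e6)
        assert p.bouton_volume_target == pytest.approx(0.63e9)

    def test_l4_totals(self):
        p = preset_from_table1("L4_TLN")
        assert p.total_sv == 1821
        assert p.az_area_targets[0] == pytest.approx(0.13e6)

    def test_l5_pool_counts_round_to_reported_integers(self):
        p = preset_from_table1("L5_TLN")
        counts = p.pool_spec.counts_for_total(p.total_sv)
        assert counts == {"p10": 5, "p10_20": 10, "intermediate": 58, "rp": 182, "resting": 1264}
        assert sum(counts.values()) == 1519

    def test_l4_pool_counts(self):
        p = preset_from_table1("L4_TLN")
        counts = p.pool_spec.counts_for_total(p.total_sv)
        assert counts == {"p10": 20, "p10_20": 29, "intermediate": 138, "rp": 382, "resting": 1252}

    def test_cleft_widths(self):
        assert preset_from_table1("L5_TLN").cleft_spec.lateral_width == pytest.approx(17.24)
        assert preset_from_table1("L4_TLN").cleft_spec.central_width == pytest.approx(16.47)


class TestGeneratedScene:
    def test_realized_geometry_matches_targets(self, small_scene):
        p = small_scene.params
        assert small_scene.surface_area_nm2 == pytest.approx(p.bouton_surface_area_target, rel=0.02)
        assert small_scene.volume_nm3 == pytest.approx(p.bouton_volume_target, rel=0.02)
        assert small_scene.az_patches[0].true_preaz_area == pytest.approx(
            p.az_area_targets[0], rel=0.02
        )

    def test_pool_counts_exact(self, small_scene):
        want = small_scene.params.pool_spec.counts_for_total(small_scene.params.total_sv)
        assert small_scene.pool_counts() == want

    def test_ground_truth_perimeters_fall_in_labeled_bins(self, small_scene):
        """Exhaustive 3D distance to the assigned patch minus radius must land
        in the labeled bin for every vesicle."""
        pd = _PatchDistance(small_scene.az_patches)
        vs = [v for v in small_scene.vesicles if v.pool is not None]
        centers = np.array([v.center for v in vs])
        radii = np.array([v.radius for v in vs])
        d, _ = pd.query(centers)
        p = np.maximum(d - radii, 0.0)
        for pi, v in zip(p, vs):
            assert _bin_of(float(pi)) == v.pool
            assert abs(pi - v.perimeter_true) < 1e-6

    def test_vesicles_inside_bouton_and_disjoint(self, small_scene):
        vs = small_scene.vesicles
        centers = np.array([v.center for v in vs])
        radii = np.array([v.radius for v in vs])
        # docked vesicles touch the membrane; everything is at least inside
        # the surface itself
        assert small_scene.contains(centers).all()
        tol = small_scene.params.overlap_tolerance
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        rsum = radii[:, None] + radii[None, :]
        np.fill_diagonal(d, np.inf)
        assert (d >= rsum - tol - 1e-9).all()

    @pytest.mark.parametrize("target", [0.10, 0.18])
    def test_mito_fraction_recovered(self, target):
        scene = generate_scene(
            small_params(mito_volume_fraction_target=target, n_mitochondria=2, total_sv=0,
                         n_dense_core=0, rng_seed=3)
        )
        assert abs(scene.mito_volume_fraction - target) <= 0.02

    def test_empty_vesicle_case(self):
        scene = generate_scene(small_params(total_sv=0, n_dense_core=0, rng_seed=5))
        assert scene.vesicles == []
        assert scene.surface_area_nm2 > 0

    def test_docked_count(self, small_scene):
        counts = small_scene.params.pool_spec.counts_for_total(small_scene.params.total_sv)
        n_docked = sum(1 for v in small_scene.vesicles if v.docked)
        expect = round(small_scene.params.pool_spec.docked_fraction * counts["p10"])
        assert n_docked == expect

    def test_determinism_byte_identical_json(self):
        a = generate_scene(small_params(rng_seed=11)).to_json()
        b = generate_scene(small_params(rng_seed=11)).to_json()
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_scene(small_params(rng_seed=11)).to_json()
        b = generate_scene(small_params(rng_seed=12)).to_json()
        assert a != b

    def test_json_round_trip(self, small_scene):
        text = small_scene.to_json()
        back = Scene.from_json(text)
        assert back.to_json() == text

    def test_infeasible_packing_names_constraint(self):
        # a bouton too small for any vesicle to sit > 200 nm from the AZ:
        # the resting-pool quota can never fill
        with pytest.raises(PackingInfeasibleError) as exc:
            generate_scene(
                small_params(
                    bouton_surface_area_target=0.12e6,
                    bouton_volume_target=0.002e9,
                    az_area_targets=(0.01e6,),
                    psd_area_targets=(0.01e6,),
                    total_sv=60,
                    pool_spec=PoolSpec(0.02, 0.02, 0.06, 0.1, 0.8, 0.0),
                    n_mitochondria=0,
                    mito_volume_fraction_target=0.0,
                    n_dense_core=0,
                )
            )
        assert "pool_" in str(exc.value)

    def test_surface_to_volume_infeasibility(self):
        # surface below the spherical minimum for the requested volume
        with pytest.raises(PackingInfeasibleError) as exc:
            generate_scene(small_params(bouton_surface_area_target=0.5e6))
        assert "surface_to_volume" in str(exc.value)


class TestMultipleAZ:
    def test_three_az_patches(self):
        scene = generate_scene(
            small_params(
                n_az=3,
                az_area_targets=(0.05e6, 0.04e6, 0.03e6),
                psd_area_targets=(0.05e6, 0.04e6, 0.03e6),
                total_sv=50,
                n_dense_core=0,
                rng_seed=9,
            )
        )
        assert len(scene.az_patches) == 3
        for i, t in enumerate((0.05e6, 0.04e6, 0.03e6)):
            assert scene.az_patches[i].true_preaz_area == pytest.approx(t, rel=0.02)
        # vesicle az assignment is to the nearest patch
        pd = _PatchDistance(scene.az_patches)
        for v in scene.vesicles:
            d, owner = pd.query(v.center[None, :])
            assert owner[0] == v.az_index
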