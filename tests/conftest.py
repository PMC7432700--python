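import pytest

from synmorph.scene_synth import (
    CleftSpec,
    PoolSpec,
    SceneParams,
    generate_scene,
    preset_from_table1,
)
from synmorph.sectioning import SectionPlan, section_scene


def small_params(**overrides) -> SceneParams:
    """A scaled-down bouton (fast to generate) with every feature present."""
    base = dict(
        bouton_surface_area_target=1.8e6,
        bouton_volume_target=0.12e9,
        n_az=1,
        az_area_targets=(0.08e6,),
        psd_area_targets=(0.09e6,),
        total_sv=200,
        pool_spec=PoolSpec(
            frac_p10=0.03,
            frac_p10_20=0.05,
            frac_20_60=0.10,
            frac_rp=0.22,
            frac_resting=0.60,
            docked_fraction=0.5,
        ),
        n_dense_core=2,
        n_mitochondria=1,
        mito_volume_fraction_target=0.12,
        cleft_spec=CleftSpec(lateral_width=17.0, central_width=20.0, noise_sd=1.5),
        rng_seed=42,
    )
    base.update(overrides)
    return SceneParams(**base)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_params())


@pytest.fixture(scope="session")
def small_stack(small_scene):
    return section_scene(small_scene, SectionPlan(), seed=3)


@pytest.fixture(scope="session")
def l5_scene():
    return generate_scene(preset_from_table1("L5_TLN", rng_seed=7))


@pytest.fixture(scope="session")
def l5_stack(l5_scene):
    return section_scene(l5_scene, SectionPlan(), seed=17)
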