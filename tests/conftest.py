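import pytest

from welldose import Conditions, MediumSpec, ParticleSpec, make_geometry


@pytest.fixture
def char_25():
    """Characterization conditions: water-like at 25 degC."""
    return Conditions.from_user(25.0, 0.89)


@pytest.fixture
def cond_37():
    """Incubation conditions: water-like at 37 degC."""
    return Conditions.from_user(37.0, 0.6913)


@pytest.fixture
def medium():
    """DMEM-like medium at 37 degC."""
    return MediumSpec.from_user(1.0, 0.74, 37.0)


@pytest.fixture
def geom_96_caco2():
    """96-well-like well with 0.2 mL medium and a differentiated Caco-2 band."""
    return make_geometry(0.32, medium_volume=0.2, wall_band_height=0.54)


@pytest.fixture
def geom_96_flat():
    """Same well, undifferentiated cell model (no wall band)."""
    return make_geometry(0.32, medium_volume=0.2, wall_band_height=0.0)


@pytest.fixture
def spec_100nm(char_25):
    """Average-mode 100 nm particles with agglomerate density 1.3 g/cm^3."""
    return ParticleSpec(
        input_mode="diameter",
        values=((100.0, 1.0),),
        effective_density=1.3,
        characterization=char_25,
    )
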