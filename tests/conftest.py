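import pytest

from twigwood import SectionSpec, TissueLabel, generate_section

#: Cohort-average tissue composition (all eight wood tissues present).
AVERAGE_FRACTIONS = {
    TissueLabel.FIBRE_WALL: 0.32,
    TissueLabel.FIBRE_LUMEN: 0.13,
    TissueLabel.AXIAL_PARENCHYMA: 0.14,
    TissueLabel.RAY_PARENCHYMA: 0.21,
    TissueLabel.VESSEL_LUMEN: 0.13,
    TissueLabel.VESSEL_WALL: 0.04,
    TissueLabel.CONDUIT15: 0.02,
    TissueLabel.MUCILAGE_CANAL: 0.01,
}

#: Composition without mucilage canals (absent in most real species); used
#: for the sampling-theory checks where every structure is disc- or
#: band-sized well below the grid spacing.
NO_CANAL_FRACTIONS = {
    TissueLabel.FIBRE_WALL: 0.32,
    TissueLabel.FIBRE_LUMEN: 0.13,
    TissueLabel.AXIAL_PARENCHYMA: 0.145,
    TissueLabel.RAY_PARENCHYMA: 0.21,
    TissueLabel.VESSEL_LUMEN: 0.13,
    TissueLabel.VESSEL_WALL: 0.04,
    TissueLabel.CONDUIT15: 0.025,
}


@pytest.fixture(scope="session")
def average_section():
    """An 800x800 px section at 1 um/px with the average composition."""
    spec = SectionSpec(AVERAGE_FRACTIONS, image_size_px=(800, 800), rng_seed=1)
    return generate_section(spec)


@pytest.fixture(scope="session")
def sampling_section():
    """A large (2000x2000 px) section for grid-sampling statistics."""
    spec = SectionSpec(NO_CANAL_FRACTIONS, image_size_px=(2000, 2000), rng_seed=11)
    return generate_section(spec)
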