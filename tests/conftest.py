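import numpy as np
import pandas as pd
import pytest

from patternherit import simulate as sim


def ped_frame(rows):
    """Build a pedigree frame from (id, sire, dam) tuples ('' = unknown)."""
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


@pytest.fixture(scope="session")
def nuclear_pedigree():
    """Two unrelated non-inbred parents with two full-sib offspring."""
    return ped_frame(
        [("s", "", ""), ("d", "", ""), ("o1", "s", "d"), ("o2", "s", "d")]
    )


@pytest.fixture(scope="session")
def fixture_pedigrees():
    """Small pedigrees (<= 8 members) covering the standard relationship cases."""
    return {
        "parent_offspring": ped_frame(
            [("s", "", ""), ("d", "", ""), ("o", "s", "d")]
        ),
        "full_sibs": ped_frame(
            [("s", "", ""), ("d", "", ""), ("o1", "s", "d"), ("o2", "s", "d")]
        ),
        "half_sibs": ped_frame(
            [("s", "", ""), ("d1", "", ""), ("d2", "", ""),
             ("o1", "s", "d1"), ("o2", "s", "d2")]
        ),
        "full_sib_mating": ped_frame(
            [("s", "", ""), ("d", "", ""), ("a", "s", "d"), ("b", "s", "d"),
             ("i", "a", "b")]
        ),
        "three_generations": ped_frame(
            [("g1", "", ""), ("g2", "", ""), ("g3", "", ""), ("g4", "", ""),
             ("p1", "g1", "g2"), ("p2", "g3", "g4"), ("o1", "p1", "p2"),
             ("o2", "p1", "p2")]
        ),
        "single_known_parent": ped_frame(
            [("d", "", ""), ("o", "", "d")]
        ),
    }


@pytest.fixture(scope="session")
def study_dataset():
    """One simulated study-shaped dataset with known truth (h2 = 0.3)."""
    cfg = sim.BreedingDesignConfig(seed=2)
    pedigree, covariates = sim.simulate_pedigree(cfg)
    truth = sim.SimulationTruth(
        traits={t: sim.TraitTruth.from_h2(0.3) for t in sim.TRAITS}
    )
    records = sim.simulate_records(pedigree, covariates, truth, seed=3)
    return pedigree, records, truth


@pytest.fixture(scope="session")
def rendered_swatch():
    """A noiseless two-class swatch with known contrast 0.7."""
    params = sim.RenderParams(
        mean_brightness=0.5, class_gap=0.7, anisotropy=1.0, n_classes=2,
        image_height=120, image_width=120, noise_sd=0.0, seed=4,
    )
    return sim.render_swatch(params), params
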