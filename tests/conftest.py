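import numpy as np
import pytest

from lungquant.exemplars import ROIPatch, fit_exemplar_model
from lungquant.phantom import NoduleSpec, PhantomSpec, implant_nodule, make_lung_phantom

NINE_LEVELS = np.linspace(-950.0, 100.0, 9)


def make_level_rois(n_per_level=12, sd=5.0, seed=0):
    """ROIs drawn around nine well-separated HU plateaus."""
    rng = np.random.default_rng(seed)
    rois = []
    for lv in NINE_LEVELS:
        for _ in range(n_per_level):
            rois.append(ROIPatch(rng.normal(lv, sd, (9, 9))))
    return rois


@pytest.fixture(scope="session")
def nine_level_model():
    """An exemplar model trained on nine clean HU plateaus."""
    return fit_exemplar_model(make_level_rois(), seed=0)


@pytest.fixture(scope="session")
def phantom64():
    """A 64^3 phantom with an implanted part-solid nodule and its truths."""
    ph = make_lung_phantom(PhantomSpec(shape=(64, 64, 64), rng_seed=7))
    spec = NoduleSpec(center=(19, 33, 32), radius_mm=5.0, lepidic_fraction=0.4)
    volume, nodule = implant_nodule(ph.volume, ph.lung, spec, rng_seed=7)
    return ph, spec, volume, nodule
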