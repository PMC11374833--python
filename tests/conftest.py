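import numpy as np
import pandas as pd
import pytest

from cortexmx import pipeline as pl
from cortexmx import synthetic as syn
from cortexmx.geometry import LayerModel


@pytest.fixture(scope="session")
def model_a46() -> LayerModel:
    return syn.FieldSpec(area_label="A46").layer_model()


@pytest.fixture(scope="session")
def model_a17() -> LayerModel:
    return syn.FieldSpec(area_label="A17").layer_model()


@pytest.fixture(scope="session")
def small_field() -> syn.FieldData:
    """One deterministic A46 field at reduced density."""
    pop = syn.population_preset("A46", count_mode="fixed").scaled(0.25, 0.0)
    return syn.generate_field(syn.FieldSpec(seed=11), pop)


@pytest.fixture(scope="session")
def rendered_field() -> syn.FieldData:
    """Sparse A17 field with images for all image-based stages."""
    pop = syn.population_preset("A17", count_mode="fixed").scaled(0.08, 0.0)
    spec = syn.FieldSpec(area_label="A17", seed=21, pixel_size=2.0)
    channels = list(pl.FIBER_MARKERS + pl.VESSEL_MARKERS) + ["DAPI", "NeuN", "GFAP"]
    return syn.generate_field(spec, pop, render_channels=channels)


@pytest.fixture(scope="session")
def annotated_cohort() -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Three-case two-area cohort, annotated; returns (cells, truth, fields)."""
    fields, _ = syn.generate_cohort(n_cases=3, seed=7, count_mode="fixed")
    cells = pl.annotate_cohort(fields)
    truth = pd.concat([f.ground_truth for f in fields], ignore_index=True)
    return cells, truth, fields


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
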