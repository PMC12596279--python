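import numpy as np
import pandas as pd
import pytest

from islesar.core import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_table():
    return CountTable(
        [[3, 0, 5], [1, 2, 0], [0, 0, 7]],
        ["s1", "s2", "s3"],
        ["a1", "a2", "a3"],
    )


@pytest.fixture
def tiny_samples():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "island_id": ["i1", "i1", "i2"],
            "compartment": ["detritus", "water", "detritus"],
            "locus": ["18S", "18S", "18S"],
            "replicate_index": [1, 1, 1],
        }
    )


@pytest.fixture
def tiny_islands():
    return pd.DataFrame(
        {
            "island_id": ["i1", "i2"],
            "detritus_weight_mg": [500.0, 2500.0],
            "water_volume_ml": [30.0, 120.0],
            "diameter_cm": [35.0, 48.0],
            "height_cm": [25.0, 40.0],
            "complexity": [20, 31],
            "invertebrate_number": [3, 6],
            "invertebrate_weight_mg": [12.0, 40.0],
            "pH": [6.4, 6.0],
            "temperature_C": [24.5, 25.5],
            "dissolved_oxygen_mg_l": [4.2, 3.1],
            "nitrate_conc": [0.4, 0.2],
            "percent_carbon": [44.0, 47.0],
            "percent_nitrogen": [1.4, 1.7],
        }
    )
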