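"""Shared fixtures: small synthetic cohorts built once per session."""

import numpy as np
import pandas as pd
import pytest

import microsig as ms


@pytest.fixture(scope="session")
def null_cohort():
    """Four imbalanced groups, no planted effects."""
    cfg = ms.SimulationConfig(
        seed=101,
        n_samples_per_group={"A": 40, "B": 20, "C": 12, "D": 8},
        n_otus=120, depth_range=(1500, 3000))
    return ms.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong effect on one family in group B."""
    cfg = ms.SimulationConfig(
        seed=202,
        n_samples_per_group={"A": 30, "B": 30, "C": 15, "D": 15},
        n_otus=120, depth_range=(2000, 4000),
        planted_taxa=[ms.PlantedEffect("f__Family05", "B", fold_change=8.0,
                                       presence_shift=0.2)])
    return ms.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_table():
    """Hand-built 3-sample x 4-OTU table with known taxonomy."""
    taxonomy = {
        "O1": "k__Bacteria; p__P1; c__C1; o__O1; f__FX; g__G1; s__",
        "O2": "k__Bacteria; p__P1; c__C1; o__O1; f__FX; g__G2; s__",
        "O3": "k__Bacteria; p__P1; c__C1; o__O1; f__FX; g__; s__",
        "O4": "k__Bacteria; p__P2; c__C2; o__O2; f__FY; g__G3; s__",
    }
    counts = np.array([[3, 7, 5, 5],
                       [10, 0, 0, 10],
                       [1, 1, 1, 17]])
    return ms.CountTable(["s1", "s2", "s3"], ["O1", "O2", "O3", "O4"],
                         counts, taxonomy)


@pytest.fixture(scope="session")
def metadata_frame():
    rng = np.random.default_rng(5)
    n = 40
    return pd.DataFrame({
        "ethnicity": ["A"] * 14 + ["B"] * 14 + ["C"] * 6 + ["D"] * 6,
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "age": rng.uniform(18, 55, n).round(1),
        "bmi": rng.normal(25, 4, n).round(2).clip(12, 55),
        "body_site": "fecal",
        "country": "USA",
    }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
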