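"""Shared fixtures: hand-designed filter-cascade tables and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from txcompare.data_model import IsoformTable, SampleTable, compute_isoform_percentages
from txcompare.simulate import SimulationConfig, simulate_experiment


def make_sample_table(n_control: int, n_test: int, model_label: str = "MODEL") -> SampleTable:
    rows = [(f"C{i + 1}", "control", "LIVER", 0, f"r{i + 1}") for i in range(n_control)]
    rows += [(f"T{i + 1}", "test", model_label, 0, f"r{i + 1}") for i in range(n_test)]
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "group", "model_label", "time_point_h", "replicate_id"])
    )


@pytest.fixture(scope="session")
def cascade_fixture():
    """5-gene / 12-isoform table in which every cascade step removes at least one
    planned isoform; the expected removals are enumerated by hand.

    10 control samples (C1..C10) and 3 test samples (T1..T3). The decisive
    values, derived from the counts below:

    * B2 (gene G2): 0.5 expected counts in every test sample against test
      library sizes ~1e6 -> mean test CPM ~0.47 < 1 -> low-expression removal;
      its usage difference (28.6 points) and detection are both clean.
    * C3, C4 (gene G3): usage differences 1.14 and 1.39 points <= 10 ->
      similar-usage removal; counts >= 29000 keep them clear of the CPM floor.
    * D2 (gene G4): zero in 3 of 10 control samples (30% > 20%) -> detection
      removal; usage difference 19.2 points keeps it past similar-usage.
    * E2 (gene G5): zero in 1 of 3 test samples, n=3 < 5 -> all-samples rule;
      usage difference 23.3 points keeps it past similar-usage.
    * B1, D1, E1: lone survivors of their genes -> single-isoform prune.
    * Survivors: A1, A2 (gene G1, usage difference 43.3) and C1, C2 (gene G3,
      28.6 and 26.1).
    """
    control = {
        # isoform: (value in C1..C7, value in C8..C10)
        "A1": (200000, 200000),
        "A2": (300000, 300000),
        "B1": (50000, 50000),
        "B2": (20000, 20000),
        "C1": (100000, 100000),
        "C2": (100000, 100000),
        "C3": (50000, 50000),
        "C4": (30000, 30000),
        "D1": (100000, 100000),
        "D2": (300000, 0),
        "E1": (100000, 100000),
        "E2": (20000, 20000),
    }
    test = {
        # isoform: (T1, T2, T3)
        "A1": (250000, 250000, 250000),
        "A2": (50000, 50000, 50000),
        "B1": (100000, 100000, 100000),
        "B2": (0.5, 0.5, 0.5),
        "C1": (200000, 200000, 200000),
        "C2": (30000, 30000, 30000),
        "C3": (52000, 52000, 52000),
        "C4": (29000, 29000, 29000),
        "D1": (100000, 100000, 100000),
        "D2": (50000, 50000, 50000),
        "E1": (100000, 100000, 100000),
        "E2": (150000, 150000, 0),
    }
    samples = [f"C{i + 1}" for i in range(10)] + ["T1", "T2", "T3"]
    data = {}
    for s_idx, s in enumerate(samples):
        col = []
        for iso in control:
            if s.startswith("C"):
                col.append(control[iso][0] if s_idx < 7 else control[iso][1])
            else:
                col.append(test[iso][s_idx - 10])
        data[s] = col
    counts = pd.DataFrame(data, index=list(control))
    parent = pd.Series(
        {i: f"G{'ABCDE'.index(i[0]) + 1}" for i in counts.index}, index=counts.index
    )
    iso = compute_isoform_percentages(IsoformTable(counts, parent))
    expected = {
        "low_expression": {"B2"},
        "similar_usage": {"C3", "C4"},
        "detection": {"D2", "E2"},
        "single_isoform_prune": {"B1", "D1", "E1"},
        "survivors": {"A1", "A2", "C1", "C2"},
    }
    return iso, make_sample_table(10, 3), expected


@pytest.fixture(scope="session")
def default_sim():
    """One experiment under the study conditions (24 vs 3, 2000 genes)."""
    return simulate_experiment(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def null_sim():
    """Global-null experiment: no DE, no DTU."""
    return simulate_experiment(SimulationConfig(seed=0, frac_de=0.0, frac_dtu=0.0))


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast experiment for structural tests."""
    return simulate_experiment(
        SimulationConfig(seed=3, n_genes=300, n_control=8, n_test=4)
    )
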