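import numpy as np
import pandas as pd
import pytest

from methylgc import (
    BetaMatrix,
    SampleSheet,
    SimulationDesign,
    simulate_dataset,
)
from methylgc.datatypes import RAND36_CATEGORIES


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(n_probes=600, seed=42)


@pytest.fixture(scope="session")
def small_study(small_design):
    """A compact synthetic study shared across read-only tests."""
    beta, annot, samples, assay, truth = simulate_dataset(small_design)
    return {"beta": beta, "annot": annot, "samples": samples,
            "assay": assay, "truth": truth, "design": small_design}


def make_sample_sheet(n_case=6, n_control=6, batches=2, seed=0,
                      groups=None) -> SampleSheet:
    """Minimal valid sample sheet for unit tests."""
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = ["case"] * n_case + ["control"] * n_control
    n = len(groups)
    ids = [f"s{i:02d}" for i in range(n)]
    df = pd.DataFrame({
        "group": groups,
        "age": rng.uniform(30, 60, n).round(1),
        "bmi": rng.uniform(19, 28, n).round(1),
        "batch": [f"b{i % batches}" for i in range(n)],
    }, index=pd.Index(ids, name="sample_id"))
    cp = rng.dirichlet([30, 20, 10, 10, 15], n)
    for j in range(5):
        df[f"cellprop_c{j}"] = cp[:, j]
    for c in RAND36_CATEGORIES:
        df[c] = rng.uniform(10, 90, n).round(1)
    return SampleSheet(df)


def make_beta(values, probes=None, samples=None, detection=None) -> BetaMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    p, n = values.shape
    probes = probes or [f"cg{i:05d}" for i in range(p)]
    samples = samples or [f"s{i:02d}" for i in range(n)]
    df = pd.DataFrame(values, index=probes, columns=samples)
    det = (pd.DataFrame(detection, index=probes, columns=samples)
           if detection is not None else None)
    return BetaMatrix(df, det)
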