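import numpy as np
import pytest

from epireverse.meth_io import MethylationMatrix, SampleSheet
from epireverse.synthetic_methylome import (
    SimulationDesign,
    simulate_annotation,
    simulate_cohort,
    simulate_truth,
)
import pandas as pd


@pytest.fixture(scope="session")
def small_cohort():
    """800-CpG paper-shaped cohort (6 young / 6 old control / 8 old treated)."""
    design = SimulationDesign(n_cpgs=800, seed=11)
    annotation = simulate_annotation(design)
    truth = simulate_truth(design, annotation)
    matrix, samples, truth = simulate_cohort(design, annotation, truth)
    return design, matrix, samples, annotation, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic cohort: zero noise, full reversal at full strength."""
    design = SimulationDesign(
        n_cpgs=600, seed=5, noise_sd=0.0,
        reversal_fraction=1.0, reversal_strength=1.0)
    annotation = simulate_annotation(design)
    truth = simulate_truth(design, annotation)
    matrix, samples, truth = simulate_cohort(design, annotation, truth)
    return design, matrix, samples, annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(beta, prefix_cpg="cg", prefix_sample="S"):
    beta = np.asarray(beta, dtype=float)
    # sample ids start at 1 to line up with make_sheet
    return MethylationMatrix(
        [f"{prefix_cpg}{i}" for i in range(beta.shape[0])],
        [f"{prefix_sample}{j + 1}" for j in range(beta.shape[1])],
        beta,
    )


def make_sheet(groups, ages=None, lifespan=3.8):
    """groups: mapping group -> n samples; ages default 0.5 young / 2.5 old."""
    rows = []
    i = 0
    for group, n in groups.items():
        for _ in range(n):
            i += 1
            age = (0.5 if group == "young" else 2.5) if ages is None else ages[i - 1]
            rows.append({"sample_id": f"S{i}", "age_years": age, "group": group,
                         "species": "rat", "max_lifespan_years": lifespan})
    return SampleSheet(pd.DataFrame(rows))
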