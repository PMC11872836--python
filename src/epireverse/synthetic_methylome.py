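"""Synthetic aging-methylome cohorts with a planted, partially reversible signal.

The generative model is linear on the logit-beta scale (a package invention;
it keeps betas bounded and makes effect sizes unit-free):

    logit(beta_ij) = m_j + a_j * Age'_i + r_j * T_i + eps_ij

where Age' is age standardized to [0,1] over [age_young, age_old], T_i is 1
for old_treated samples, eps ~ Normal(0, noise_sd), and a_j is +delta for
age-affected CpGs in gain contexts (BivProm/TSS/PRC2 states or islands),
-delta in loss contexts (HET/Quies states or intergenic CpGs), 0 otherwise.
Reversed CpGs get r_j = -reversal_strength * a_j * Age'(age_old), so at full
strength the treatment exactly cancels the age effect in treated samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .meth_io import CpGAnnotation, MethylationMatrix, SampleSheet

STATE_VOCABULARY = ("TSS", "BivProm", "PRC2", "Enh", "Tx", "HET", "Quies")

DEFAULT_STATE_PROPORTIONS = {
    "TSS": 0.08, "BivProm": 0.08, "PRC2": 0.09, "Enh": 0.15,
    "Tx": 0.20, "HET": 0.20, "Quies": 0.20,
}

GAIN_STATES = frozenset({"BivProm", "TSS", "PRC2"})
LOSS_STATES = frozenset({"HET", "Quies"})

# conditional probabilities given chromatin state
ISLAND_PROB = {
    "TSS": 0.70, "BivProm": 0.80, "PRC2": 0.60, "Enh": 0.15,
    "Tx": 0.10, "HET": 0.03, "Quies": 0.03,
}
_REGIONS = ("promoter", "exon", "intron", "intergenic", "5'UTR", "3'UTR")
REGION_PROBS = {
    "TSS":     (0.60, 0.05, 0.05, 0.05, 0.20, 0.05),
    "BivProm": (0.65, 0.05, 0.05, 0.05, 0.15, 0.05),
    "PRC2":    (0.40, 0.10, 0.15, 0.20, 0.10, 0.05),
    "Enh":     (0.05, 0.10, 0.45, 0.30, 0.03, 0.07),
    "Tx":      (0.05, 0.30, 0.40, 0.10, 0.05, 0.10),
    "HET":     (0.02, 0.05, 0.18, 0.70, 0.02, 0.03),
    "Quies":   (0.02, 0.05, 0.18, 0.70, 0.02, 0.03),
}

BETA_CLIP = (0.001, 0.999)  # array betas are never exactly 0/1


@dataclass
class SimulationDesign:
    """Parameters of a synthetic cohort; all effects are on the logit scale."""

    n_cpgs: int = 5000
    state_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_PROPORTIONS))
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"young": 6, "old_control": 6, "old_treated": 8})
    age_young: float = 0.5
    age_old: float = 2.5
    species: str = "rat"
    max_lifespan_years: float = 3.8
    age_effect_fraction: float = 0.2
    delta_age: float = 1.0
    reversal_fraction: float = 0.6
    reversal_strength: float = 1.0
    noise_sd: float = 0.15
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("age_effect_fraction", "reversal_fraction", "reversal_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        unknown = set(self.state_proportions) - set(STATE_VOCABULARY)
        if unknown:
            raise ValueError(f"unknown chromatin states: {sorted(unknown)}")
        total = sum(self.state_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"state_proportions must sum to 1, got {total}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if not self.age_old > self.age_young > 0:
            raise ValueError("require 0 < age_young < age_old")
        if self.max_lifespan_years <= self.age_old:
            raise ValueError("max lifespan must exceed the oldest age")


class Cohort(NamedTuple):
    matrix: MethylationMatrix
    samples: SampleSheet
    annotation: CpGAnnotation
    truth: pd.DataFrame


def simulate_annotation(design: SimulationDesign, seed: int | None = None) -> CpGAnnotation:
    """Draw a synthetic CpG annotation with state-dependent island/region structure."""
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_cpgs
    states = list(design.state_proportions)
    probs = np.array([design.state_proportions[s] for s in states], dtype=float)
    state = rng.choice(states, size=n, p=probs / probs.sum())

    island = np.zeros(n, dtype=bool)
    region = np.empty(n, dtype=object)
    for s in states:
        mask = state == s
        k = int(mask.sum())
        if k == 0:
            continue
        island[mask] = rng.random(k) < ISLAND_PROB[s]
        region[mask] = rng.choice(_REGIONS, size=k, p=np.asarray(REGION_PROBS[s]))

    tss = np.empty(n, dtype=int)
    for rc, lo, hi, p_up in (
        ("promoter", 1, 1000, 0.8),
        ("5'UTR", 1, 1000, 0.0),
        ("exon", 200, 20000, 0.0),
        ("intron", 1000, 50000, 0.0),
        ("3'UTR", 1000, 100000, 0.0),
        ("intergenic", 5000, 2000000, 0.5),
    ):
        mask = region == rc
        k = int(mask.sum())
        if k == 0:
            continue
        mag = rng.integers(lo, hi + 1, size=k)
        sign = np.where(rng.random(k) < p_up, -1, 1)
        tss[mask] = sign * mag

    chrom = np.array([f"chr{c}" for c in rng.integers(1, 21, size=n)])
    start = rng.integers(10_000, 100_000_000, size=n)
    n_genes = max(n // 10, 1)
    gene = np.array([f"G{g:05d}" for g in rng.integers(0, n_genes, size=n)])
    frame = pd.DataFrame({
        "cpg_id": [f"cg{j:07d}" for j in range(n)],
        "chrom": chrom,
        "start": start,
        "end": start + 2,
        "nearest_gene": gene,
        "tss_distance": tss,
        "region_class": region.astype(str),
        "island": island,
        "chromatin_state": state,
    })
    return CpGAnnotation(frame)


def effect_direction(annotation: CpGAnnotation) -> np.ndarray:
    """Per-CpG age-drift direction implied by chromatin context.

    'gain' for gain states or islands, 'loss' for loss states or intergenic
    CpGs (gain contexts take precedence), 'none' otherwise.
    """
    df = annotation.frame
    gain = df["chromatin_state"].isin(GAIN_STATES) | df["island"]
    loss = ~gain & (df["chromatin_state"].isin(LOSS_STATES)
                    | (df["region_class"] == "intergenic"))
    out = np.full(len(df), "none", dtype=object)
    out[gain.to_numpy()] = "gain"
    out[loss.to_numpy()] = "loss"
    return out


def simulate_truth(design: SimulationDesign, annotation: CpGAnnotation,
                   seed: int | None = None) -> pd.DataFrame:
    """Assign age effects and reversal flags; the ground truth for tests.

    Age-affected CpGs are drawn from those with a context-defined direction,
    so every affected CpG has a well-defined gain/loss sign.
    """
    design.validate()
    rng = np.random.default_rng((design.seed if seed is None else seed) + 104729)
    direction = effect_direction(annotation)
    candidates = np.flatnonzero(direction != "none")
    n_affected = min(round(design.age_effect_fraction * design.n_cpgs), candidates.size)
    affected = rng.choice(candidates, size=n_affected, replace=False)
    has_effect = np.zeros(design.n_cpgs, dtype=bool)
    has_effect[affected] = True
    n_reversed = round(design.reversal_fraction * n_affected)
    reversed_idx = rng.choice(affected, size=n_reversed, replace=False)
    is_reversed = np.zeros(design.n_cpgs, dtype=bool)
    is_reversed[reversed_idx] = True
    return pd.DataFrame({
        "cpg_id": annotation.cpg_ids,
        "has_age_effect": has_effect,
        "age_direction": np.where(has_effect, direction, "none"),
        "is_reversed": is_reversed,
    })


def _sample_sheet(design: SimulationDesign) -> SampleSheet:
    rows = []
    prefixes = {"young": "Y", "old_control": "OC", "old_treated": "OT"}
    for group, size in design.group_sizes.items():
        age = design.age_young if group == "young" else design.age_old
        for i in range(size):
            rows.append({
                "sample_id": f"{prefixes[group]}{i + 1:02d}",
                "age_years": age,
                "group": group,
                "species": design.species,
                "max_lifespan_years": design.max_lifespan_years,
            })
    return SampleSheet(pd.DataFrame(rows))


def simulate_cohort(
    design: SimulationDesign,
    annotation: CpGAnnotation | None = None,
    truth: pd.DataFrame | None = None,
    sample_seed: int | None = None,
) -> tuple[MethylationMatrix, SampleSheet, pd.DataFrame]:
    """Simulate betas for a 3-group cohort under the planted-reversal model.

    Passing a pre-built ``annotation``/``truth`` pair with a distinct
    ``sample_seed`` yields independent animals from the same CpG effects
    (e.g. a clock training set matched to a test cohort).
    """
    design.validate()
    if annotation is None:
        annotation = simulate_annotation(design)
    if truth is None:
        truth = simulate_truth(design, annotation)
    sheet = _sample_sheet(design)
    rng = np.random.default_rng(
        (design.seed if sample_seed is None else sample_seed) + 15485863)

    n = design.n_cpgs
    sign = np.where(truth["age_direction"] == "gain", 1.0,
                    np.where(truth["age_direction"] == "loss", -1.0, 0.0))
    a = np.where(truth["has_age_effect"], design.delta_age * sign, 0.0)
    # Age' at age_old is 1.0, so full-strength reversal cancels the age term.
    r = np.where(truth["is_reversed"], -design.reversal_strength * a, 0.0)
    m = design.baseline_mean + design.baseline_sd * rng.standard_normal(n)

    ages = sheet.ages()
    age_std = (ages - design.age_young) / (design.age_old - design.age_young)
    treated = np.array([g == "old_treated" for g in sheet.frame["group"]], dtype=float)

    logit = (m[:, None] + np.outer(a, age_std) + np.outer(r, treated))
    if design.noise_sd > 0:
        logit = logit + design.noise_sd * rng.standard_normal(logit.shape)
    beta = np.clip(expit(logit), *BETA_CLIP)
    matrix = MethylationMatrix(annotation.cpg_ids, sheet.sample_ids, beta)
    return matrix, sheet, truth


def simulate_all(design: SimulationDesign) -> Cohort:
    """Annotation + cohort in one call (the CLI entry point)."""
    annotation = simulate_annotation(design)
    truth = simulate_truth(design, annotation)
    matrix, sheet, truth = simulate_cohort(design, annotation, truth)
    return Cohort(matrix, sheet, annotation, truth)


def simulate_clock_training(
    n_samples: int = 40,
    n_cpgs: int = 2000,
    n_causal: int = 20,
    noise_sd: float = 0.1,
    delta: float = 2.0,
    age_range: tuple[float, float] = (0.2, 3.5),
    seed: int = 0,
) -> tuple[MethylationMatrix, np.ndarray]:
    """Continuous-age dataset for clock parameter-recovery experiments.

    A random subset of CpGs carries a +/- ``delta`` logit-scale age slope;
    the rest are noise. Returns the matrix and the true ages in years.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n_samples)
    age_std = (ages - age_range[0]) / (age_range[1] - age_range[0])
    a = np.zeros(n_cpgs)
    causal = rng.choice(n_cpgs, size=n_causal, replace=False)
    a[causal] = rng.choice([-delta, delta], size=n_causal)
    m = rng.standard_normal(n_cpgs)
    logit = m[:, None] + np.outer(a, age_std)
    logit += noise_sd * rng.standard_normal(logit.shape)
    beta = np.clip(expit(logit), *BETA_CLIP)
    matrix = MethylationMatrix(
        [f"cg{j:07d}" for j in range(n_cpgs)],
        [f"S{i + 1:03d}" for i in range(n_samples)],
        beta,
    )
    return matrix, ages
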