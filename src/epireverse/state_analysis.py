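"""Chromatin-state-level methylation scoring and the reversal analysis.

Per state and sample we take the trimmed mean beta over the state's CpGs,
then test the state-level means between groups. Using sample-level state
means (n = samples) as the analysis unit avoids treating CpGs as replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import welch_t, z_from_p
from .meth_io import CpGAnnotation, MethylationMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_TRIM = 0.05
MIN_CPGS_PER_STATE = 10

STATE_CLASSES = ("gain_reversed", "loss_mitigated", "concordant", "neutral")


def trimmed_mean(values, trim_fraction: float = DEFAULT_TRIM) -> float:
    """Mean after dropping ``floor(trim*n)`` smallest and largest values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("trimmed_mean of empty input")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    g = int(trim_fraction * v.size)
    if v.size - 2 * g < 1:
        raise ValueError("trimming leaves no values")
    if g == 0:
        return float(v.mean())
    v = np.sort(v)
    return float(v[g:v.size - g].mean())


@dataclass
class StateSummary:
    """Per-state trimmed means (states x samples) and group-contrast Z table."""

    per_sample: pd.DataFrame = field(repr=False)
    table: pd.DataFrame = field(repr=False)

    def eligible(self) -> pd.DataFrame:
        return self.table[self.table["eligible"]]


def _columnwise_trimmed_mean(block: np.ndarray, trim: float) -> np.ndarray:
    """Trimmed mean of each column of a CpGs-x-samples block (vectorized)."""
    n = block.shape[0]
    g = int(trim * n)
    if n - 2 * g < 1:
        raise ValueError("trimming leaves no values")
    if g == 0:
        return block.mean(axis=0)
    s = np.sort(block, axis=0)
    return s[g:n - g].mean(axis=0)


def state_effects(
    matrix: MethylationMatrix,
    annotation: CpGAnnotation,
    sample_sheet: SampleSheet,
    trim: float = DEFAULT_TRIM,
    min_cpgs: int = MIN_CPGS_PER_STATE,
) -> StateSummary:
    """Trimmed-mean state methylation per sample plus age/treatment Z per state.

    Signs are oriented so positive z_age = higher methylation in old than
    young, positive z_treat = higher in treated than old control. States with
    fewer than ``min_cpgs`` CpGs (or degenerate variance) are flagged
    ineligible and excluded from downstream correlation.
    """
    ann = annotation.indexed()
    missing = [c for c in matrix.cpg_ids if c not in ann.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} matrix CpGs missing from annotation, e.g. {missing[:5]}"
        )
    states_per_cpg = ann.loc[matrix.cpg_ids, "chromatin_state"].to_numpy()

    sample_ids = matrix.sample_ids
    young = [sample_ids.index(s) for s in sample_sheet.ids_for_group("young")]
    ctrl = [sample_ids.index(s) for s in sample_sheet.ids_for_group("old_control")]
    trt = [sample_ids.index(s) for s in sample_sheet.ids_for_group("old_treated")]

    rows = []
    per_sample = {}
    for state in sorted(set(states_per_cpg)):
        block = matrix.beta[states_per_cpg == state]
        means = _columnwise_trimmed_mean(block, trim)
        per_sample[state] = means
        n_cpgs = block.shape[0]
        flags = []
        try:
            t_age, _, p_age = welch_t(means[ctrl], means[young])
            z_age = float(z_from_p(p_age, np.sign(t_age)))
        except ValueError:
            z_age, flags = 0.0, flags + ["degenerate_age"]
        try:
            t_trt, _, p_trt = welch_t(means[trt], means[ctrl])
            z_treat = float(z_from_p(p_trt, np.sign(t_trt)))
        except ValueError:
            z_treat, flags = 0.0, flags + ["degenerate_treat"]
        eligible = n_cpgs >= min_cpgs and not flags
        if n_cpgs < min_cpgs:
            flags.append("too_few_cpgs")
            logger.info("state %s has %d < %d CpGs; excluded", state, n_cpgs, min_cpgs)
        rows.append({"state": state, "n_cpgs": n_cpgs, "z_age": z_age,
                     "z_treat": z_treat, "eligible": eligible,
                     "flags": ";".join(flags)})
    summary_table = pd.DataFrame(rows)
    per_sample_df = pd.DataFrame(per_sample, index=sample_ids).T
    per_sample_df.index.name = "state"
    return StateSummary(per_sample=per_sample_df, table=summary_table)


def classify_state(z_age: float, z_treat: float, z_threshold: float) -> str:
    if z_age >= z_threshold and z_treat <= -z_threshold:
        return "gain_reversed"
    if z_age <= -z_threshold and z_treat >= z_threshold:
        return "loss_mitigated"
    if abs(z_age) >= z_threshold and abs(z_treat) >= z_threshold:
        return "concordant"
    return "neutral"


def state_reversal(summary: StateSummary,
                   z_threshold: float = 1.645) -> tuple[float, float, dict[str, str]]:
    """Correlate (z_age, z_treat) across eligible states and classify each.

    Returns ``(pearson_r, two_sided_p, {state: class})``. Requires at least 3
    eligible states.
    """
    elig = summary.eligible()
    if len(elig) < 3:
        raise ValueError(f"need >= 3 eligible states, got {len(elig)}")
    res = stats.pearsonr(elig["z_age"], elig["z_treat"])
    classes = {
        row.state: classify_state(row.z_age, row.z_treat, z_threshold)
        for row in summary.table.itertuples()
    }
    return float(res.statistic), float(res.pvalue), classes
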