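"""Per-CpG association scans, rescued/aggravated classification and overlap.

Each scan correlates beta values with a contrast variable and maps the
correlation t-test to a signed standard-normal statistic
``z = sign(r) * Phi^-1(1 - p/2)`` so that the null follows N(0, 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import P_FLOOR, p_from_t, t_from_r, z_from_p
from .meth_io import CpGAnnotation, MethylationMatrix, SampleSheet

logger = logging.getLogger(__name__)

CONTRASTS = ("age", "treatment")
LABELS = ("rejuvenated", "aggravated", "age_only", "treat_only", "null")


def _contrast_variable(sample_sheet: SampleSheet, contrast: str):
    if contrast == "age":
        ids = sample_sheet.ids_for_group("young") + sample_sheet.ids_for_group("old_control")
        ages = sample_sheet.ages(ids)
        # numeric age when informative, else the young/old indicator
        if len(np.unique(ages)) >= 3:
            x = ages
        else:
            groups = sample_sheet.frame.set_index("sample_id").loc[ids, "group"]
            x = (groups == "old_control").to_numpy(dtype=float)
    elif contrast == "treatment":
        ids = (sample_sheet.ids_for_group("old_control")
               + sample_sheet.ids_for_group("old_treated"))
        groups = sample_sheet.frame.set_index("sample_id").loc[ids, "group"]
        x = (groups == "old_treated").to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown contrast {contrast!r}; allowed: {list(CONTRASTS)}")
    return ids, np.asarray(x, dtype=float)


def ewas_scan(matrix: MethylationMatrix, sample_sheet: SampleSheet,
              contrast: str) -> pd.DataFrame:
    """Pearson-correlation scan of every CpG against a contrast variable.

    Returns a DataFrame with columns ``cpg_id, r, t, p, z, n``. Zero-variance
    CpGs get (r=0, p=1, z=0) and are logged.
    """
    ids, x = _contrast_variable(sample_sheet, contrast)
    n = len(ids)
    if n < 4:
        raise ValueError(f"contrast {contrast!r} has n={n} < 4 samples")
    sub = matrix.subset_samples(ids)
    B = sub.beta
    xc = x - x.mean()
    sx = np.sqrt((xc**2).sum())
    if sx == 0:
        raise ValueError("contrast variable is constant")
    Bc = B - B.mean(axis=1, keepdims=True)
    sb = np.sqrt((Bc**2).sum(axis=1))
    degenerate = sb == 0
    if degenerate.any():
        logger.info("%d zero-variance CpGs set to z=0, p=1", int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Bc @ xc) / (sb * sx)
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))
    t = t_from_r(r, n)
    p = np.where(np.isinf(t), P_FLOOR, p_from_t(np.where(np.isinf(t), 0.0, t), n - 2))
    p = np.where(degenerate, 1.0, p)
    z = z_from_p(p, np.sign(r))
    return pd.DataFrame({"cpg_id": sub.cpg_ids, "r": r, "t": t, "p": p, "z": z, "n": n})


def classify_cpgs(z_age, z_treat, alpha: float = 0.01) -> np.ndarray:
    """Label CpGs by joint significance and sign pattern of the two scans.

    ``rejuvenated``: both |z| exceed the threshold with opposite signs;
    ``aggravated``: both exceed with equal signs; ``age_only``/``treat_only``:
    exactly one exceeds; ``null`` otherwise.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    za = np.asarray(z_age, dtype=float)
    zt = np.asarray(z_treat, dtype=float)
    zstar = stats.norm.isf(alpha / 2.0)
    sig_a = np.abs(za) >= zstar
    sig_t = np.abs(zt) >= zstar
    both = sig_a & sig_t
    opposite = za * zt < 0
    out = np.full(za.shape, "null", dtype=object)
    out[sig_a & ~sig_t] = "age_only"
    out[~sig_a & sig_t] = "treat_only"
    out[both & opposite] = "rejuvenated"
    out[both & ~opposite] = "aggravated"
    return out


def build_ewas_table(age_scan: pd.DataFrame, treat_scan: pd.DataFrame,
                     alpha: float = 0.01, adjust: bool = False) -> pd.DataFrame:
    """Join the two scans per CpG and attach the classification label.

    ``adjust=True`` adds Benjamini-Hochberg columns (``q_age``, ``q_treat``);
    headline classification always uses nominal p-values.
    """
    a = age_scan.set_index("cpg_id")[["r", "z", "p"]].add_suffix("_age")
    t = treat_scan.set_index("cpg_id")[["r", "z", "p"]].add_suffix("_treat")
    table = a.join(t, how="inner").reset_index()
    table["label"] = classify_cpgs(table["z_age"], table["z_treat"], alpha)
    if adjust:
        from statsmodels.stats.multitest import multipletests
        for c in ("age", "treat"):
            table[f"q_{c}"] = multipletests(table[f"p_{c}"], method="fdr_bh")[1]
    return table


def overlap_summary(labels) -> dict[str, int]:
    """Venn-style counts from the classification labels."""
    counts = pd.Series(labels, dtype=object).value_counts()
    n_rej = int(counts.get("rejuvenated", 0))
    n_agg = int(counts.get("aggravated", 0))
    return {
        "n_age_significant": n_rej + n_agg + int(counts.get("age_only", 0)),
        "n_treat_significant": n_rej + n_agg + int(counts.get("treat_only", 0)),
        "n_overlap": n_rej + n_agg,
        "n_rejuvenated": n_rej,
        "n_aggravated": n_agg,
    }


def reversal_correlation(z_age, z_treat, subset: str = "all",
                         alpha: float = 0.01) -> tuple[float, float]:
    """Pearson correlation between the age and treatment Z vectors.

    ``subset='significant_either'`` restricts to CpGs significant in at least
    one scan at ``alpha``. Returns ``(r, two_sided_p)``.
    """
    za = np.asarray(z_age, dtype=float)
    zt = np.asarray(z_treat, dtype=float)
    if subset == "significant_either":
        zstar = stats.norm.isf(alpha / 2.0)
        mask = (np.abs(za) >= zstar) | (np.abs(zt) >= zstar)
        za, zt = za[mask], zt[mask]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'significant_either'")
    if za.size < 3:
        raise ValueError(f"need at least 3 CpGs for a correlation, got {za.size}")
    res = stats.pearsonr(za, zt)
    return float(res.statistic), float(res.pvalue)


def top_hits(scan: pd.DataFrame, annotation: CpGAnnotation, k: int = 15) -> pd.DataFrame:
    """Top-k CpGs of a scan, annotated with nearest gene and direction.

    Ordered by ascending p, ties broken by (chrom, start); ``direction`` is
    'gain' for z > 0 and 'loss' otherwise. k beyond the table size returns
    the whole table.
    """
    ann = annotation.indexed()
    merged = scan.join(ann[["chrom", "start", "nearest_gene"]], on="cpg_id")
    merged = merged.sort_values(["p", "chrom", "start"], kind="mergesort")
    merged["direction"] = np.where(merged["z"] > 0, "gain", "loss")
    cols = ["cpg_id", "chrom", "start", "nearest_gene", "p", "z", "direction"]
    return merged.head(k)[cols].reset_index(drop=True)
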