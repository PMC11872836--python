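"""Context enrichment of EWAS hits: TSS position, island status, chromatin state.

The background set is always the CpGs that entered the scan, not the whole
annotation, so enrichment conditions on what was actually tested.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import welch_t

#: Default TSS-distance bin edges in bp; bins are half-open intervals (lo, hi].
DEFAULT_TSS_EDGES = (-math.inf, -50_000, -5_000, -1_000, 0, 1_000, 5_000, 50_000, math.inf)

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    """Star string at the 0.05 / 0.01 / 0.001 / 0.0001 thresholds."""
    for threshold, mark in STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, two_sided_p)`` with the sample odds ratio
    ``(a*d)/(b*c)`` (``inf`` when b*c = 0 with a*d > 0); p sums all tables
    with the same margins whose probability is <= the observed one.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero 2x2 table")
    a, b, c, d = (int(x) for x in cells)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return odds, min(p, 1.0)


def hypergeom_enrichment(k: int, K: int, n: int, N: int, tail: str = "upper") -> float:
    """Hypergeometric tail probability for k successes in n draws.

    Upper tail ``P[X >= k]`` for enrichment; ``tail='lower'`` gives the
    depletion tail ``P[X <= k]``. X ~ Hypergeom(N population, K marked,
    n drawn).
    """
    if not (0 <= k <= min(K, n)) or n > N or K > N:
        raise ValueError(f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    if tail == "upper":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if tail == "lower":
        return float(stats.hypergeom.cdf(k, N, K, n))
    raise ValueError("tail must be 'upper' or 'lower'")


def _bin_label(lo: float, hi: float) -> str:
    def fmt(x):
        if math.isinf(x):
            return "-inf" if x < 0 else "inf"
        return f"{x / 1000:g}kb"
    return f"({fmt(lo)}, {fmt(hi)}]"


def tss_position_enrichment(hits, annotation, edges=DEFAULT_TSS_EDGES,
                            direction: str | None = None) -> pd.DataFrame:
    """Per-TSS-bin odds ratios of hit membership with Fisher exact p-values.

    ``hits`` is an iterable of CpG ids; ``annotation`` covers the scanned
    background. Each bin yields the 2x2 of (hit vs non-hit) x (in-bin vs
    out-of-bin).
    """
    ann = annotation.frame if hasattr(annotation, "frame") else annotation
    hit_set = set(map(str, hits))
    unknown = hit_set - set(ann["cpg_id"])
    if unknown:
        raise ValueError(f"{len(unknown)} hits not in background annotation")
    is_hit = ann["cpg_id"].isin(hit_set).to_numpy()
    dist = ann["tss_distance"].to_numpy(dtype=float)
    n_hits, n_bg = int(is_hit.sum()), len(ann)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (dist > lo) & (dist <= hi)
        a = int((is_hit & in_bin).sum())
        b = n_hits - a
        c = int((~is_hit & in_bin).sum())
        d = (n_bg - n_hits) - c
        odds, p = fisher_2x2(a, b, c, d)
        rows.append({
            "bin": _bin_label(lo, hi), "lo": lo, "hi": hi,
            "n_hits_in_bin": a, "n_background_in_bin": a + c,
            "odds_ratio": odds, "p": p, "stars": significance_stars(p),
            "direction": direction or "all",
        })
    return pd.DataFrame(rows)


def island_status_comparison(z_values, island_flags) -> tuple[float, float, float]:
    """Welch comparison of EWAS Z between island and non-island CpGs.

    Returns ``(mean_difference, t, two_sided_p)`` with the difference taken
    as island minus non-island.
    """
    z = np.asarray(z_values, dtype=float)
    flags = np.asarray(island_flags, dtype=bool)
    if z.shape != flags.shape:
        raise ValueError("z_values and island_flags must align")
    t, _, p = welch_t(z[flags], z[~flags])
    diff = float(z[flags].mean() - z[~flags].mean())
    return diff, t, p


def state_enrichment(hits, annotation, direction: str | None = None) -> pd.DataFrame:
    """Per-chromatin-state fold enrichment of hits with hypergeometric p.

    Fold = (k/n) / (K/N); enrichment uses the upper tail, depletion
    (fold < 1) the lower tail.
    """
    ann = annotation.frame if hasattr(annotation, "frame") else annotation
    ann = ann.reset_index(drop=True)
    hit_set = set(map(str, hits))
    unknown = hit_set - set(ann["cpg_id"])
    if unknown:
        raise ValueError(f"{len(unknown)} hits not in background annotation")
    N = len(ann)
    n = len(hit_set)
    is_hit = ann["cpg_id"].isin(hit_set).to_numpy()
    rows = []
    for state, sub in ann.groupby("chromatin_state", sort=True):
        K = len(sub)
        k = int(is_hit[sub.index].sum())
        fold = (k / n) / (K / N) if n > 0 else math.nan
        tail = "upper" if (n == 0 or fold >= 1.0) else "lower"
        p = hypergeom_enrichment(k, K, n, N, tail=tail) if n > 0 else 1.0
        rows.append({"state": state, "n_hits_in_state": k, "n_state_cpgs": K,
                     "fold": fold, "p": p, "tail": tail,
                     "stars": significance_stars(p), "direction": direction or "all"})
    return pd.DataFrame(rows)
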