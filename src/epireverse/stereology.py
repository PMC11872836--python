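"""Optical-dissector total cell-count estimation from sampled sections."""

from __future__ import annotations

import pandas as pd


def estimate_total_count(rq_sum: float, ssf: float, asf: float, tsf: float) -> float:
    """Estimate total cell number: ``N = RQ_sum / (ssf * asf * tsf)``.

    ``rq_sum`` is the raw count over sampled dissectors; ``ssf``/``asf``/``tsf``
    are the section, area and thickness sampling fractions, each in (0, 1].
    The estimate is returned unrounded.
    """
    if rq_sum < 0:
        raise ValueError("rq_sum must be non-negative")
    for name, frac in (("ssf", ssf), ("asf", asf), ("tsf", tsf)):
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {frac}")
    return rq_sum / (ssf * asf * tsf)


def batch_estimate(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the estimator to a table with columns rq_sum, ssf, asf, tsf."""
    required = ("rq_sum", "ssf", "asf", "tsf")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = table.copy()
    out["estimated_total"] = [
        estimate_total_count(r.rq_sum, r.ssf, r.asf, r.tsf)
        for r in table.itertuples()
    ]
    return out
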