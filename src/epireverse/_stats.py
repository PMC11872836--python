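"""Shared small-sample statistics used by several analysis stages."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

#: Cap for standard-normal-scale statistics; keeps quantiles finite when p underflows.
Z_CAP = 40.0

#: Smallest representable positive p-value; p is reported in (0, 1].
P_FLOOR = np.finfo(float).tiny


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch (unequal-variance) two-sample t-test.

    Returns ``(t, df, two_sided_p)`` where ``t`` is computed as
    ``(mean(x) - mean(y)) / se``. Raises :class:`ValueError` if both groups
    have zero variance (the statistic is undefined, not NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both groups have zero variance; t statistic undefined")
    sx2 = vx / x.size
    sy2 = vy / y.size
    se = math.sqrt(sx2 + sy2)
    t = (x.mean() - y.mean()) / se
    df = (sx2 + sy2) ** 2 / (sx2**2 / (x.size - 1) + sy2**2 / (y.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(max(p, P_FLOOR), 1.0))


def z_from_p(p, sign):
    """Map a two-sided p-value and a sign to a signed standard-normal statistic.

    ``z = sign * Phi^-1(1 - p/2)``, capped at ``|z| <= Z_CAP``. Vectorized.
    """
    p = np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)
    z = np.sign(sign) * stats.norm.isf(p / 2.0)
    return np.clip(z, -Z_CAP, Z_CAP)


def t_from_r(r, n):
    """t statistic for a Pearson correlation ``r`` on ``n`` pairs."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    denom = np.sqrt(np.maximum(1.0 - r * r, 0.0))
    with np.errstate(divide="ignore"):
        return r * np.sqrt(n - 2) / denom


def p_from_t(t, df):
    """Two-sided p-value for a t statistic, floored to stay in (0, 1]."""
    p = 2.0 * stats.t.sf(np.abs(np.asarray(t, dtype=float)), df)
    return np.clip(p, P_FLOOR, 1.0)
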