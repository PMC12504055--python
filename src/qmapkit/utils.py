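"""Small shared helpers: report rounding and sample statistics."""

from __future__ import annotations

import numpy as np


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention of the study tables).

    numpy's ``round`` rounds half to even, which disagrees with how the
    benchmarking tables print 1-decimal percentages (e.g. 0.25 -> 0.3,
    -0.25 -> -0.3). Works on scalars and arrays.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def sample_sd(values) -> float:
    """Sample (n-1 denominator) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1))


def cv_percent(values) -> float:
    """Coefficient of variation, percent: sample SD / mean * 100.

    Returns NaN for fewer than two values (undefined sentinel).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    mean = float(np.mean(values))
    if mean == 0.0:
        return float("nan")
    return sample_sd(values) / mean * 100.0
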