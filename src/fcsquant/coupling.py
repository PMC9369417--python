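"""Rank normalisation of whole-cell intensity distributions onto FCS scales.

Whole-cell integrated intensities live on an arbitrary detector scale; to
compare them with FCS molecule numbers they are mapped onto the FCS
distribution by rank: each intensity is replaced by the FCS empirical
quantile at its own rank.  Quantiles use Hazen plotting positions
((k - 0.5)/n) with linear interpolation, so mapping a sample onto itself is
the identity on order statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["rank_normalize", "qq_pairs"]


def rank_normalize(sample, reference) -> np.ndarray:
    """Map ``sample`` values onto the scale of ``reference`` by rank.

    Output preserves the sample's ordering (ties share a value via mid-ranks);
    its order statistics are interpolated quantiles of the reference.
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(sample) < 2 or len(reference) < 2:
        raise ValueError("sample and reference must each contain >= 2 values")
    ranks = rankdata(sample, method="average")
    probs = (ranks - 0.5) / len(sample)
    return np.quantile(reference, probs, method="hazen")


def qq_pairs(a, b, n_quantiles: int = 99) -> np.ndarray:
    """Paired interpolated quantiles of two samples at 1%..99%.

    Returns an (n_quantiles, 2) array of (quantile of a, quantile of b),
    suitable for a Q-Q plot or a straight-line diagnostic fit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples must contain >= 2 values")
    if n_quantiles < 1:
        raise ValueError("n_quantiles must be >= 1")
    probs = np.linspace(0.01, 0.99, n_quantiles)
    qa = np.quantile(a, probs, method="hazen")
    qb = np.quantile(b, probs, method="hazen")
    return np.column_stack([qa, qb])
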