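"""Photon-trace autocorrelation.

Turns binned photon-count traces into normalized fluctuation autocorrelation
curves, either by brute force at every integer-bin lag (the reference
implementation) or with a multi-tau scheme on a quasi-logarithmic lag grid.

Both correlators use *symmetric* normalisation: for lag ``k`` the raw product
moment is divided by the product of the means of the two overlapping trace
segments, which suppresses bias from slow drifts.  Curves store the
fluctuation correlation ``g`` with a baseline of 0; the display convention
``1 + g`` is left to reporting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "PhotonTrace",
    "CorrelationCurve",
    "trim_trace",
    "autocorrelate_direct",
    "autocorrelate_multitau",
    "average_curves",
]


@dataclass
class PhotonTrace:
    """Binned photon counts for one repetition of one cell.

    Parameters
    ----------
    counts : ndarray of int
        Non-negative photon counts per time bin.
    bin_width : float
        Bin width in seconds.
    """

    counts: np.ndarray
    bin_width: float
    repetition_id: int = 0
    cell_id: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.counts) * self.bin_width

    @property
    def mean_rate_khz(self) -> float:
        """Mean count rate in kHz."""
        return float(self.counts.mean()) / self.bin_width / 1e3


@dataclass
class CorrelationCurve:
    """Fluctuation autocorrelation curve (baseline-0 convention)."""

    lags: np.ndarray
    g: np.ndarray
    mean_rate_khz: float = 0.0
    sigma: Optional[np.ndarray] = None
    n_effective: Optional[np.ndarray] = None
    flags: set = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must have identical shape")
        if len(self.lags) and (np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be positive and strictly increasing")
        if self.mean_rate_khz < 0:
            raise ValueError("mean_rate_khz must be non-negative")

    def __len__(self) -> int:
        return len(self.lags)


def trim_trace(trace: PhotonTrace, skip: float = 0.5) -> PhotonTrace:
    """Drop the first ``skip`` seconds of a trace.

    The opening stretch of a recording typically contains uncorrelated
    background while the detector settles, so it is removed before
    correlation.
    """
    if skip < 0:
        raise ValueError("skip must be non-negative")
    if skip >= trace.duration:
        raise ValueError(
            f"skip ({skip} s) must be shorter than the trace ({trace.duration} s)"
        )
    n_skip = int(round(skip / trace.bin_width))
    return replace(trace, counts=trace.counts[n_skip:])


def _g_at_lag(signal: np.ndarray, k: int) -> tuple[float, int]:
    """Symmetrically normalised fluctuation correlation at integer lag k."""
    n = len(signal)
    a = signal[: n - k]
    b = signal[k:]
    ma = a.mean()
    mb = b.mean()
    if ma <= 0 or mb <= 0:
        return 0.0, n - k
    return float((a * b).mean() / (ma * mb) - 1.0), n - k


def autocorrelate_direct(trace: PhotonTrace, max_lag: Optional[float] = None) -> CorrelationCurve:
    """Brute-force autocorrelation at every integer-bin lag up to ``max_lag``.

    Serves as the exact reference for :func:`autocorrelate_multitau`.  An
    all-zero trace has an undefined correlation; it is returned as g = 0 with
    the ``"undefined_mean"`` flag set.
    """
    counts = trace.counts.astype(float)
    if len(counts) < 2:
        raise ValueError("trace must contain at least 2 bins")
    if max_lag is None:
        max_lag = trace.duration / 4
    if max_lag >= trace.duration / 2:
        raise ValueError("max_lag must be below half the trace duration")
    k_max = max(1, int(max_lag / trace.bin_width))

    flags: set = set()
    lags = np.arange(1, k_max + 1) * trace.bin_width
    if counts.mean() == 0:
        flags.add("undefined_mean")
        g = np.zeros(k_max)
        n_eff = len(counts) - np.arange(1, k_max + 1)
    else:
        g = np.empty(k_max)
        n_eff = np.empty(k_max, dtype=int)
        for i, k in enumerate(range(1, k_max + 1)):
            g[i], n_eff[i] = _g_at_lag(counts, k)
    return CorrelationCurve(
        lags=lags,
        g=g,
        mean_rate_khz=trace.mean_rate_khz,
        n_effective=n_eff,
        flags=flags,
        meta={"method": "direct", "cell_id": trace.cell_id, "group": trace.group,
              "repetition_id": trace.repetition_id},
    )


def autocorrelate_multitau(
    trace: PhotonTrace, m: int = 16, max_lag: Optional[float] = None
) -> CorrelationCurve:
    """Multi-tau autocorrelation on a quasi-logarithmic lag grid.

    Stage 0 evaluates lags ``1..2m`` bins at native resolution — these are
    numerically identical to :func:`autocorrelate_direct`.  Each subsequent
    stage halves the time resolution by pairwise binning and evaluates lags
    ``m+1..2m`` at the coarsened resolution.
    """
    counts = trace.counts.astype(float)
    if len(counts) < 2 * m:
        raise ValueError(f"trace must contain at least {2 * m} bins")
    if max_lag is None:
        max_lag = trace.duration / 4

    flags: set = set()
    if counts.mean() == 0:
        flags.add("undefined_mean")

    lags: list[float] = []
    gs: list[float] = []
    n_eff: list[int] = []
    signal = counts
    width = trace.bin_width

    def _emit(k: int) -> None:
        lag = k * width
        if lag > max_lag or k >= len(signal):
            return
        if "undefined_mean" in flags:
            g, n = 0.0, len(signal) - k
        else:
            g, n = _g_at_lag(signal, k)
        lags.append(lag)
        gs.append(g)
        n_eff.append(n)

    for k in range(1, 2 * m + 1):
        _emit(k)
    while len(signal) // 2 >= 2 * m:
        n_pairs = len(signal) // 2
        signal = signal[: 2 * n_pairs].reshape(n_pairs, 2).sum(axis=1)
        width *= 2
        if (m + 1) * width > max_lag:
            break
        for k in range(m + 1, 2 * m + 1):
            _emit(k)

    return CorrelationCurve(
        lags=np.asarray(lags),
        g=np.asarray(gs),
        mean_rate_khz=trace.mean_rate_khz,
        n_effective=np.asarray(n_eff),
        flags=flags,
        meta={"method": "multitau", "m": m, "cell_id": trace.cell_id,
              "group": trace.group, "repetition_id": trace.repetition_id},
    )


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of curves sharing one lag grid."""
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if len(c) != len(ref) or not np.allclose(c.lags, ref.lags):
            raise ValueError("curves must share an identical lag grid")
    g = np.mean([c.g for c in curves], axis=0)
    rate = float(np.mean([c.mean_rate_khz for c in curves]))
    sigma = None
    if all(c.sigma is not None for c in curves):
        sigma = np.sqrt(np.mean([np.square(c.sigma) for c in curves], axis=0) / len(curves))
    flags = set().union(*(c.flags for c in curves))
    return CorrelationCurve(
        lags=ref.lags.copy(), g=g, mean_rate_khz=rate, sigma=sigma,
        flags=flags, meta={"method": "average", "n_curves": len(curves)},
    )
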