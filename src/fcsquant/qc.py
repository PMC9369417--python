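"""Fit QC filters, per-cell averaging and derived biological quantities.

Exclusion rules applied to repetition-level fits, in priority order:

1. failed / signal-free fits (``fit_failed``, ``no_correlation``, ...);
2. free-structural-parameter prescreen estimate outside [0.1, 15];
3. the chi-square rule — as printed in the source protocol, fits with
   chi2 *below* 1e-4 are excluded.  Because the conventional rule is the
   opposite (exclude poor fits, i.e. *large* chi2), the direction is
   configurable via ``chi2_rule``.

Surviving repetitions are averaged parameter-wise into one measurement per
cell, requiring a minimum of 5 valid repetitions under the 10 x 10 s
acquisition scheme or 3 under the 5 x 5 s scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_fit import FitResult
from .synthetic import OpticsSpec

__all__ = [
    "CellMeasurement",
    "PopulationSample",
    "apply_filters",
    "summarize_cell",
    "diffusion_constant",
    "per_cell_copies",
    "median_ci",
    "MIN_VALID_REPS",
]

MIN_VALID_REPS = {"10x10s": 5, "5x5s": 3}

DEFAULT_CHI2_THRESHOLD = 1e-4
DEFAULT_S_BOUNDS = (0.1, 15.0)


@dataclass
class CellMeasurement:
    """Repetition-averaged quantities for one cell."""

    cell_id: str
    group: str = ""
    n_valid_reps: int = 0
    n_molecules: float = math.nan
    cpm_khz: float = math.nan
    amplitude: float = math.nan
    d_fast_um2_s: float = math.nan
    d_slow_um2_s: float = math.nan
    frac_slow: float = math.nan
    per_cell_copies: float = math.nan
    excluded: bool = False
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "group": self.group,
            "n_valid_reps": self.n_valid_reps,
            "n_molecules": self.n_molecules,
            "cpm_khz": self.cpm_khz,
            "amplitude": self.amplitude,
            "d_fast_um2_s": self.d_fast_um2_s,
            "d_slow_um2_s": self.d_slow_um2_s,
            "frac_slow": self.frac_slow,
            "per_cell_copies": self.per_cell_copies,
            "excluded": self.excluded,
            "reason": self.reason,
        }


@dataclass
class PopulationSample:
    """All cell measurements for one strain x condition group."""

    strain: str
    condition: str
    measurements: list[CellMeasurement] = field(default_factory=list)

    @property
    def included(self) -> list[CellMeasurement]:
        return [m for m in self.measurements if not m.excluded]

    @property
    def n(self) -> int:
        return len(self.included)

    def values(self, fieldname: str) -> np.ndarray:
        return np.asarray([getattr(m, fieldname) for m in self.included], dtype=float)

    def summary(self, fieldname: str = "n_molecules", seed=None) -> dict:
        vals = self.values(fieldname)
        med, lo, hi = median_ci(vals, seed=seed)
        return {
            "strain": self.strain,
            "condition": self.condition,
            "field": fieldname,
            "median": med,
            "ci_low": lo,
            "ci_high": hi,
            "n": self.n,
            "n_excluded": len(self.measurements) - self.n,
        }


_FAILURE_FLAGS = ("fit_failed", "no_correlation", "undefined_mean", "too_few_lags")


def apply_filters(
    fits: Sequence[FitResult],
    chi2_threshold: float = DEFAULT_CHI2_THRESHOLD,
    s_bounds: tuple[float, float] = DEFAULT_S_BOUNDS,
    chi2_rule: str = "exclude_below",
) -> tuple[list[FitResult], list[tuple[FitResult, str]]]:
    """Split fits into (kept, discarded-with-reason).

    Every discarded fit carries exactly one primary reason; kept + discarded
    always partitions the input.
    """
    if chi2_rule not in ("exclude_below", "exclude_above"):
        raise ValueError("chi2_rule must be 'exclude_below' or 'exclude_above'")
    kept: list[FitResult] = []
    discarded: list[tuple[FitResult, str]] = []
    lo, hi = s_bounds
    for fit in fits:
        failure = next((f for f in _FAILURE_FLAGS if f in fit.qc_flags), None)
        if failure is not None:
            discarded.append((fit, failure))
            continue
        s_est = fit.free_s_estimate
        if "structural_parameter_out_of_range" in fit.qc_flags or (
            s_est is not None and not lo <= s_est <= hi
        ):
            discarded.append((fit, "structural_parameter_out_of_range"))
            continue
        bad_chi2 = (fit.chi2 < chi2_threshold) if chi2_rule == "exclude_below" \
            else (fit.chi2 > chi2_threshold)
        if bad_chi2 or not math.isfinite(fit.chi2):
            discarded.append((fit, "chi2_rule"))
            continue
        kept.append(fit)
    return kept, discarded


def diffusion_constant(tau_us: float, w0_um: float = 0.22) -> float:
    """Diffusion coefficient D = w0^2 / (4 tau) in um^2/s, tau in microseconds."""
    if tau_us <= 0 or w0_um <= 0:
        raise ValueError("tau and w0 must be positive")
    return w0_um**2 / (4.0 * tau_us * 1e-6)


def per_cell_copies(
    n_cv: float, confocal_volume_fl: float = 0.57, cell_volume_fl: float = 82.0
) -> float:
    """Extrapolate molecules per confocal volume to copies per cell.

    Assumes a homogeneous distribution: copies = N_cv * V_cell / V_confocal.
    """
    if n_cv < 0:
        raise ValueError("molecule number must be non-negative")
    if confocal_volume_fl <= 0 or cell_volume_fl <= 0:
        raise ValueError("volumes must be positive")
    return n_cv * cell_volume_fl / confocal_volume_fl


def summarize_cell(
    fits: Sequence[FitResult],
    scheme: str = "10x10s",
    optics: Optional[OpticsSpec] = None,
) -> CellMeasurement:
    """Average valid repetition fits into one per-cell measurement.

    ``fits`` must already have passed :func:`apply_filters` and share one
    ``cell_id``.  Diffusion constants are computed per repetition and then
    averaged.  Cells with fewer valid repetitions than the scheme minimum
    are flagged ``insufficient_repetitions``.
    """
    if scheme not in MIN_VALID_REPS:
        raise ValueError(f"scheme must be one of {sorted(MIN_VALID_REPS)}")
    if not fits:
        raise ValueError("no fits supplied")
    cell_ids = {f.cell_id for f in fits}
    if len(cell_ids) != 1:
        raise ValueError(f"fits mix cell ids: {sorted(cell_ids)}")
    optics = optics or OpticsSpec()

    cell_id = fits[0].cell_id
    group = fits[0].group
    n_valid = len(fits)
    if n_valid < MIN_VALID_REPS[scheme]:
        return CellMeasurement(
            cell_id=cell_id, group=group, n_valid_reps=n_valid,
            excluded=True, reason="insufficient_repetitions",
        )

    w0 = optics.w0_um
    d_fast = [diffusion_constant(f.tau_fast_s * 1e6, w0) for f in fits]
    d_slow = [diffusion_constant(f.tau_slow_s * 1e6, w0)
              for f in fits if f.tau_slow_s is not None]
    n_mean = float(np.mean([f.n_molecules for f in fits]))
    return CellMeasurement(
        cell_id=cell_id,
        group=group,
        n_valid_reps=n_valid,
        n_molecules=n_mean,
        cpm_khz=float(np.mean([f.cpm_khz for f in fits])),
        amplitude=float(np.mean([f.amplitude for f in fits])),
        d_fast_um2_s=float(np.mean(d_fast)),
        d_slow_um2_s=float(np.mean(d_slow)) if d_slow else math.nan,
        frac_slow=float(np.mean([f.frac_slow for f in fits])),
        per_cell_copies=per_cell_copies(n_mean, optics.confocal_volume_fl),
    )


def median_ci(
    values, level: float = 0.95, n_boot: int = 10_000, seed=None
) -> tuple[float, float, float]:
    """Sample median with a seeded percentile-bootstrap confidence interval."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("median_ci requires at least 3 values")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(np.median(values)), float(lo), float(hi)
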