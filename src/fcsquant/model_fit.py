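"""Closed-form confocal diffusion models and nonlinear least-squares fitting.

The fluctuation autocorrelation of molecules diffusing through a 3D Gaussian
observation volume with an optional fluorophore dark ("triplet") state is

    g(tau) = offset + (1/N) * [1 + (T/(1-T)) * exp(-tau/tau_T)]
             * sum_i f_i * (1 + tau/tau_i)^-1 * (1 + tau/(S^2 * tau_i))^-1/2

with N the mean molecule number in the observation volume, T the dark-state
fraction, tau_T its relaxation time, f_i / tau_i the fraction and diffusion
time of mobility component i, and S the axial-to-lateral aspect ratio of the
volume.

Fitting follows a two-stage protocol: a prescreen fit with S free (used only
to discard measurements whose S estimate falls outside a plausibility window)
followed by a refit with S fixed at 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .correlator import CorrelationCurve

__all__ = ["FitResult", "model_g", "fit_curve", "two_stage_fit"]

DEFAULT_STRUCTURAL_PARAMETER = 4.0
S_SCREEN_BOUNDS = (0.1, 15.0)

# parameter bounds used by the optimiser
_N_BOUNDS = (1e-3, 1e4)
_T_BOUNDS = (0.0, 0.8)
_TAU_T_BOUNDS_S = (1e-6, 1e-4)     # 1..100 us
_TAU_BOUNDS_S = (1e-6, 1.0)        # 1 us .. 1 s
_S_BOUNDS = (0.05, 50.0)
_OFFSET_BOUNDS = (-0.05, 0.05)


@dataclass
class FitResult:
    """Parameters of a (one- or two-component) diffusion + triplet fit."""

    n_molecules: float = math.nan
    triplet_fraction: float = 0.0
    tau_triplet_s: float = 20e-6
    frac_fast: float = 1.0
    tau_fast_s: float = math.nan
    tau_slow_s: Optional[float] = None
    structural_parameter: float = DEFAULT_STRUCTURAL_PARAMETER
    offset: float = 0.0
    chi2: float = math.nan
    cpm_khz: float = math.nan
    mean_rate_khz: float = 0.0
    components: int = 2
    qc_flags: set = field(default_factory=set)
    free_s_estimate: Optional[float] = None
    stage1: Optional["FitResult"] = None
    cell_id: str = ""
    group: str = ""
    repetition_id: int = 0

    @property
    def frac_slow(self) -> float:
        return 1.0 - self.frac_fast if self.components == 2 else 0.0

    @property
    def amplitude(self) -> float:
        """Model fluctuation amplitude g(0+)."""
        return (1.0 / self.n_molecules) / (1.0 - self.triplet_fraction) + self.offset

    @property
    def ok(self) -> bool:
        return not self.qc_flags

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "group": self.group,
            "repetition_id": self.repetition_id,
            "n_molecules": self.n_molecules,
            "triplet_fraction": self.triplet_fraction,
            "tau_triplet_s": self.tau_triplet_s,
            "frac_fast": self.frac_fast,
            "frac_slow": self.frac_slow,
            "tau_fast_s": self.tau_fast_s,
            "tau_slow_s": self.tau_slow_s,
            "structural_parameter": self.structural_parameter,
            "free_s_estimate": self.free_s_estimate,
            "offset": self.offset,
            "chi2": self.chi2,
            "cpm_khz": self.cpm_khz,
            "mean_rate_khz": self.mean_rate_khz,
            "amplitude": self.amplitude if self.n_molecules > 0 else math.nan,
            "components": self.components,
            "qc_flags": sorted(self.qc_flags),
        }


def model_g(
    lag,
    n_molecules: float,
    tau_fast_s: float,
    frac_fast: float = 1.0,
    tau_slow_s: Optional[float] = None,
    triplet_fraction: float = 0.0,
    tau_triplet_s: float = 20e-6,
    structural_parameter: float = DEFAULT_STRUCTURAL_PARAMETER,
    offset: float = 0.0,
):
    """Evaluate the diffusion + triplet autocorrelation model.

    ``lag`` may be a scalar or an array of lag times in seconds.  With
    ``tau_slow_s=None`` a single mobility component is used and ``frac_fast``
    is ignored.
    """
    lag = np.asarray(lag, dtype=float)
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if not 0.0 <= triplet_fraction < 1.0:
        raise ValueError("triplet_fraction must lie in [0, 1)")
    if tau_fast_s <= 0 or (tau_slow_s is not None and tau_slow_s <= 0):
        raise ValueError("diffusion times must be positive")
    if tau_triplet_s <= 0:
        raise ValueError("tau_triplet_s must be positive")

    s2 = structural_parameter**2

    def _component(tau_d: float) -> np.ndarray:
        return 1.0 / (1.0 + lag / tau_d) / np.sqrt(1.0 + lag / (s2 * tau_d))

    if tau_slow_s is None:
        diff = _component(tau_fast_s)
    else:
        diff = frac_fast * _component(tau_fast_s) + (1.0 - frac_fast) * _component(tau_slow_s)

    trip = 1.0
    if triplet_fraction > 0.0:
        trip = 1.0 + triplet_fraction / (1.0 - triplet_fraction) * np.exp(-lag / tau_triplet_s)

    return offset + trip * diff / n_molecules


def _flat_flags(curve: CorrelationCurve) -> set:
    """Detect curves carrying no usable correlation signal.

    The short-lag signal level is compared against ten times the standard
    error of the long-lag baseline (per-lag noise scatter does not itself
    disqualify a curve; only a signal indistinguishable from baseline
    uncertainty does).
    """
    flags = set(curve.flags)
    g = curve.g
    if len(g) < 10:
        flags.add("too_few_lags")
        return flags
    if np.max(np.abs(g)) < 1e-12:
        flags.add("no_correlation")
        return flags
    n_head = max(5, len(g) // 10)
    n_tail = max(5, len(g) // 8)
    signal = float(np.mean(g[:n_head]))
    if curve.sigma is not None:
        floor = float(np.mean(curve.sigma[-n_tail:])) / math.sqrt(n_tail)
    else:
        floor = float(np.std(g[-n_tail:])) / math.sqrt(n_tail)
    if signal < 10.0 * floor:
        flags.add("no_correlation")
    return flags


def _initial_guess(curve: CorrelationCurve, components: int) -> dict:
    """Deterministic data-driven starting values."""
    g = curve.g
    g0 = max(float(np.mean(g[: max(3, len(g) // 20)])), 1e-6)
    n0 = min(max(1.0 / g0, _N_BOUNDS[0] * 10), _N_BOUNDS[1] / 10)
    # lags where the curve decays to 75% / 25% of its initial value
    def _decay_lag(level: float, fallback: float) -> float:
        below = np.nonzero(g < level * g0)[0]
        if len(below) == 0:
            return fallback
        return float(curve.lags[below[0]])

    tau1 = _decay_lag(0.75, float(curve.lags[len(curve.lags) // 3]))
    tau2 = _decay_lag(0.25, float(curve.lags[2 * len(curve.lags) // 3]))
    tau1 = float(np.clip(tau1, _TAU_BOUNDS_S[0] * 2, _TAU_BOUNDS_S[1] / 2))
    tau2 = float(np.clip(tau2, tau1 * 2, _TAU_BOUNDS_S[1] / 2))
    return {
        "n_molecules": n0,
        "frac_fast": 0.5,
        "tau_fast_s": tau1,
        "tau_slow_s": tau2 if components == 2 else None,
        "triplet_fraction": 0.1,
        "tau_triplet_s": 20e-6,
        "structural_parameter": DEFAULT_STRUCTURAL_PARAMETER,
        "offset": 0.0,
    }


def _prefit_init(
    curve: CorrelationCurve, components: int, fix_s: Optional[float]
) -> Optional[dict]:
    """Diffusion-only pre-fit on lags beyond the triplet window.

    The triplet term and a very fast diffusion component are nearly
    degenerate on noisy curves; seeding the full fit from a triplet-free fit
    restricted to lags >= 15 x the maximum triplet time keeps the optimiser
    in the physical basin.
    """
    cutoff = 15.0 * _TAU_T_BOUNDS_S[1]
    mask = curve.lags >= cutoff
    if mask.sum() < 8 + 2 * components:
        return None
    sub = CorrelationCurve(
        lags=curve.lags[mask], g=curve.g[mask],
        sigma=None if curve.sigma is None else curve.sigma[mask],
        mean_rate_khz=curve.mean_rate_khz,
    )
    pre = fit_curve(sub, components=components,
                    fix_s=fix_s if fix_s is not None else DEFAULT_STRUCTURAL_PARAMETER,
                    with_triplet=False, _allow_prefit=False, _check_signal=False)
    if not pre.ok:
        return None
    return {
        "n_molecules": pre.n_molecules,
        "frac_fast": pre.frac_fast,
        "tau_fast_s": pre.tau_fast_s,
        "tau_slow_s": pre.tau_slow_s,
        "offset": pre.offset,
    }


def fit_curve(
    curve: CorrelationCurve,
    components: int = 2,
    fix_s: Optional[float] = None,
    with_triplet: bool = True,
    init: Optional[dict] = None,
    max_nfev: int = 2000,
    _allow_prefit: bool = True,
    _check_signal: bool = True,
) -> FitResult:
    """Weighted least-squares fit of the diffusion model to one curve.

    When the curve carries a per-lag noise scale (``curve.sigma``) the
    residuals are weighted by 1/sigma and ``chi2`` is the reduced chi-square;
    otherwise unit weights are used and ``chi2`` is the mean squared residual.
    Mobility components are relabelled after the fit so that
    ``tau_fast_s < tau_slow_s``.
    """
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")

    meta = curve.meta or {}
    base = FitResult(
        components=components,
        mean_rate_khz=curve.mean_rate_khz,
        cell_id=str(meta.get("cell_id", "")),
        group=str(meta.get("group", "")),
        repetition_id=int(meta.get("repetition_id", 0)),
    )

    flags = _flat_flags(curve) if _check_signal else set()
    if flags:
        base.qc_flags = flags
        return base

    guess = _initial_guess(curve, components)
    if init is None and with_triplet and _allow_prefit:
        init = _prefit_init(curve, components, fix_s)
    if init:
        guess.update({k: v for k, v in init.items() if v is not None})
    if fix_s is not None:
        guess["structural_parameter"] = fix_s

    # free-parameter layout: (name, init, lo, hi, log-scale?)
    layout: list[tuple[str, float, float, float, bool]] = [
        ("n_molecules", guess["n_molecules"], *_N_BOUNDS, True),
        ("tau_fast_s", guess["tau_fast_s"], *_TAU_BOUNDS_S, True),
    ]
    if components == 2:
        layout += [
            ("frac_fast", guess["frac_fast"], 0.0, 1.0, False),
            ("tau_slow_s", guess["tau_slow_s"], *_TAU_BOUNDS_S, True),
        ]
    if with_triplet:
        layout += [
            ("triplet_fraction", min(guess["triplet_fraction"], _T_BOUNDS[1]), *_T_BOUNDS, False),
            ("tau_triplet_s", guess["tau_triplet_s"], *_TAU_T_BOUNDS_S, True),
        ]
    if fix_s is None:
        layout.append(("structural_parameter", guess["structural_parameter"], *_S_BOUNDS, True))
    layout.append(("offset", guess["offset"], *_OFFSET_BOUNDS, False))

    names = [row[0] for row in layout]
    x0, lo, hi = [], [], []
    for _, v, a, b, is_log in layout:
        if is_log:
            v = math.log10(min(max(v, a), b))
            a, b = math.log10(a), math.log10(b)
        x0.append(min(max(v, a), b))
        lo.append(a)
        hi.append(b)
    log_mask = np.array([row[4] for row in layout])

    lags = curve.lags
    target = curve.g
    weights = 1.0 / curve.sigma if curve.sigma is not None else np.ones_like(target)

    fixed = {
        "triplet_fraction": 0.0 if not with_triplet else None,
        "structural_parameter": fix_s,
    }

    def _params(x: np.ndarray) -> dict:
        vals = np.where(log_mask, np.power(10.0, x), x)
        p = dict(zip(names, vals))
        if not with_triplet:
            p["triplet_fraction"] = 0.0
            p["tau_triplet_s"] = guess["tau_triplet_s"]
        if fix_s is not None:
            p["structural_parameter"] = fix_s
        if components == 1:
            p["frac_fast"] = 1.0
            p["tau_slow_s"] = None
        return p

    def _residuals(x: np.ndarray) -> np.ndarray:
        p = _params(x)
        return (model_g(lags, **p) - target) * weights

    # multi-start over S when it is free: the structural parameter's
    # likelihood surface is multi-modal and a single start can land in a
    # poor local minimum
    starts = [list(x0)]
    if fix_s is None:
        s_idx = names.index("structural_parameter")
        for s_alt in (0.3, 20.0):
            alt = list(x0)
            alt[s_idx] = math.log10(s_alt)
            starts.append(alt)

    sol = None
    for start in starts:
        try:
            cand = least_squares(
                _residuals, start, bounds=(lo, hi), method="trf",
                x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if cand.success and (sol is None or cand.cost < sol.cost):
            sol = cand
    if sol is None:
        base.qc_flags.add("fit_failed")
        return base

    p = _params(sol.x)
    dof = max(1, len(lags) - len(sol.x))
    chi2 = float(2.0 * sol.cost / dof)

    result = FitResult(
        n_molecules=float(p["n_molecules"]),
        triplet_fraction=float(p["triplet_fraction"]),
        tau_triplet_s=float(p.get("tau_triplet_s", guess["tau_triplet_s"])),
        frac_fast=float(p["frac_fast"]),
        tau_fast_s=float(p["tau_fast_s"]),
        tau_slow_s=None if p["tau_slow_s"] is None else float(p["tau_slow_s"]),
        structural_parameter=float(p["structural_parameter"]),
        offset=float(p["offset"]),
        chi2=chi2,
        mean_rate_khz=curve.mean_rate_khz,
        components=components,
        cell_id=base.cell_id,
        group=base.group,
        repetition_id=base.repetition_id,
    )
    # relabel so the fast component carries the shorter diffusion time
    if result.tau_slow_s is not None and result.tau_fast_s > result.tau_slow_s:
        result.tau_fast_s, result.tau_slow_s = result.tau_slow_s, result.tau_fast_s
        result.frac_fast = 1.0 - result.frac_fast
    if result.n_molecules > 0:
        result.cpm_khz = result.mean_rate_khz / result.n_molecules
    return result


def two_stage_fit(
    curve: CorrelationCurve,
    components: int = 2,
    with_triplet: bool = True,
    fix_s: float = DEFAULT_STRUCTURAL_PARAMETER,
    s_screen_bounds: tuple[float, float] = S_SCREEN_BOUNDS,
) -> FitResult:
    """Free-S prescreen followed by a fixed-S refit.

    Stage 1 fits with the structural parameter free and records the estimate;
    values outside ``s_screen_bounds`` mark the measurement
    ``structural_parameter_out_of_range`` (it is still refit, and excluded
    downstream).  Stage 2 refits with S fixed, seeded from the stage-1
    solution when available.
    """
    stage1 = fit_curve(curve, components=components, fix_s=None, with_triplet=with_triplet)
    init = None
    if stage1.ok:
        init = {
            "n_molecules": stage1.n_molecules,
            "frac_fast": stage1.frac_fast,
            "tau_fast_s": stage1.tau_fast_s,
            "tau_slow_s": stage1.tau_slow_s,
            "triplet_fraction": stage1.triplet_fraction,
            "tau_triplet_s": stage1.tau_triplet_s,
            "offset": stage1.offset,
        }
    result = fit_curve(curve, components=components, fix_s=fix_s,
                       with_triplet=with_triplet, init=init)
    result.stage1 = stage1
    result.free_s_estimate = stage1.structural_parameter if stage1.ok else None
    if stage1.ok:
        lo, hi = s_screen_bounds
        if not lo <= stage1.structural_parameter <= hi:
            result.qc_flags.add("structural_parameter_out_of_range")
    else:
        result.qc_flags |= stage1.qc_flags
    return result
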