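"""Synthetic fluorescence-fluctuation data.

Provides everything the downstream pipeline needs to be exercised without a
microscope: Brownian-dynamics photon traces (molecules diffusing through a 3D
Gaussian detection volume with triplet blinking and Poisson counting),
analytic correlation curves with controlled noise, and whole study designs
(per-cell parameter draws and integrated-intensity tables for several
strain x condition groups).

Every synthetic record keeps its generating parameters ("ground truth") in
its metadata so recovery can be quantified downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .correlator import CorrelationCurve, PhotonTrace
from .model_fit import model_g

__all__ = [
    "SpeciesSpec",
    "OpticsSpec",
    "TripletSpec",
    "SimulationConfig",
    "GroupSpec",
    "StudyDesign",
    "CellRecord",
    "make_lag_grid",
    "effective_volume_um3",
    "simulate_trace",
    "generate_curve",
    "generate_population",
    "generate_intensity_table",
]

DEFAULT_W0_UM = 0.22
DEFAULT_STRUCTURAL_PARAMETER = 4.0
DEFAULT_CONFOCAL_VOLUME_FL = 0.57

# MDF volume ratio: integral of MDF^1 over the integral defining the
# effective volume; the mean count rate of a uniform molecule field is
# brightness * occupancy * this factor.
MDF_RATE_FACTOR = 2.0 ** -1.5


@dataclass
class SpeciesSpec:
    """One diffusing species: mobility, abundance share and brightness.

    ``brightness_khz`` is the per-molecule detected count rate at the focus
    centre (the fitted counts-per-molecule of a uniform field is a factor
    2^-3/2 lower, see :data:`MDF_RATE_FACTOR`).
    """

    diffusion_um2_s: float
    fraction: float = 1.0
    brightness_khz: float = 10.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.diffusion_um2_s) or self.diffusion_um2_s < 0:
            raise ValueError("diffusion coefficient must be finite and non-negative")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.brightness_khz < 0:
            raise ValueError("brightness must be non-negative")


@dataclass
class OpticsSpec:
    """Confocal observation-volume geometry."""

    w0_um: float = DEFAULT_W0_UM
    structural_parameter: float = DEFAULT_STRUCTURAL_PARAMETER
    confocal_volume_fl: float = DEFAULT_CONFOCAL_VOLUME_FL

    def __post_init__(self) -> None:
        if self.w0_um <= 0:
            raise ValueError("w0 must be positive")
        if self.structural_parameter < 1:
            raise ValueError("structural parameter must be >= 1")
        if self.confocal_volume_fl <= 0:
            raise ValueError("confocal volume must be positive")


@dataclass
class TripletSpec:
    """Reversible dark-state blinking: equilibrium dark fraction and relaxation time."""

    dark_fraction: float = 0.15
    relaxation_time_s: float = 20e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.dark_fraction < 1.0:
            raise ValueError("dark fraction must lie in [0, 1)")
        if self.relaxation_time_s <= 0:
            raise ValueError("relaxation time must be positive")

    @property
    def rate_to_dark(self) -> float:
        return self.dark_fraction / self.relaxation_time_s

    @property
    def rate_to_bright(self) -> float:
        return (1.0 - self.dark_fraction) / self.relaxation_time_s


@dataclass
class SimulationConfig:
    """Brownian-dynamics trace simulation parameters.

    The default 2 us bin width coarsens the hardware's native binning to a
    desk-scale cost while still resolving triplet relaxation (>= 10 us) and
    all diffusion times of interest.
    """

    species: Sequence[SpeciesSpec] = field(default_factory=lambda: [SpeciesSpec(10.0)])
    optics: OpticsSpec = field(default_factory=OpticsSpec)
    triplet: Optional[TripletSpec] = None
    mean_molecules_in_cv: float = 10.0
    bin_width_s: float = 2e-6
    duration_s: float = 10.0
    repetitions: int = 10
    background_khz: float = 0.0
    box_xy_um: Optional[float] = None
    box_z_um: Optional[float] = None
    timestep_s: Optional[float] = None
    seed: Optional[int] = None
    initial_positions: Optional[np.ndarray] = None  # calibration hook

    def __post_init__(self) -> None:
        frac_sum = sum(s.fraction for s in self.species)
        if abs(frac_sum - 1.0) > 1e-9:
            raise ValueError("species fractions must sum to 1")
        if self.mean_molecules_in_cv <= 0:
            raise ValueError("mean_molecules_in_cv must be positive")
        w0, s = self.optics.w0_um, self.optics.structural_parameter
        if self.box_xy_um is None:
            self.box_xy_um = 6.0 * w0
        if self.box_z_um is None:
            self.box_z_um = 6.0 * s * w0
        if self.box_xy_um < 6.0 * w0 - 1e-12 or self.box_z_um < 6.0 * s * w0 - 1e-12:
            raise ValueError("box must span at least 6 beam waists per axis")
        if self.timestep_s is None:
            self.timestep_s = self.bin_width_s
        if self.timestep_s > self.bin_width_s + 1e-15:
            raise ValueError("timestep must not exceed the bin width")
        steps = self.bin_width_s / self.timestep_s
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("bin width must be an integer multiple of the timestep")
        n_bins = self.duration_s / self.bin_width_s
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("duration must be an integer number of bins")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def effective_volume_um3(optics: OpticsSpec) -> float:
    """Effective (correlation) volume pi^3/2 * S * w0^3 in um^3 (= fl)."""
    return math.pi**1.5 * optics.structural_parameter * optics.w0_um**3


def _occupancy_radius_um(optics: OpticsSpec) -> float:
    """Lateral semi-axis of the ellipsoid whose volume equals the effective volume."""
    return optics.w0_um * (3.0 * math.sqrt(math.pi) / 4.0) ** (1.0 / 3.0)


def simulate_trace(
    config: SimulationConfig,
    seed: Optional[int] = None,
    record_occupancy: bool = False,
) -> list[PhotonTrace]:
    """Simulate one Brownian-dynamics measurement (one trace per repetition).

    Molecules random-walk in a periodic box sized so the expected occupancy
    of the effective volume equals ``mean_molecules_in_cv``; per-step
    detected intensity follows the Gaussian molecular detection function
    ``exp(-2(x^2+y^2)/w0^2 - 2 z^2/(S w0)^2)``; bin counts are Poisson.

    With ``record_occupancy=True`` each trace's ``meta`` carries the
    time-averaged molecule count inside an ellipsoid of effective-volume
    size plus its between-block standard error — the direct occupancy oracle.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    optics = config.optics
    w0 = optics.w0_um
    s_par = optics.structural_parameter
    lx = ly = config.box_xy_um
    lz = config.box_z_um
    v_box = lx * ly * lz
    v_eff = effective_volume_um3(optics)

    # molecule counts per species, matching the requested occupancy in expectation
    n_by_species = [
        max(0, int(round(config.mean_molecules_in_cv * sp.fraction * v_box / v_eff)))
        for sp in config.species
    ]
    n_mol = sum(n_by_species)
    if n_mol == 0:
        raise ValueError("simulation contains no molecules; increase occupancy")

    dt = config.timestep_s
    steps_per_bin = int(round(config.bin_width_s / dt))
    n_bins = int(round(config.duration_s / config.bin_width_s))
    n_steps = n_bins * steps_per_bin

    # per-molecule arrays
    q = np.concatenate([
        np.full(n, sp.brightness_khz * 1e3) for n, sp in zip(n_by_species, config.species)
    ])
    step_sigma = np.concatenate([
        np.full(n, math.sqrt(2.0 * sp.diffusion_um2_s * dt))
        for n, sp in zip(n_by_species, config.species)
    ])
    box = np.array([lx, ly, lz])
    bg_per_step = config.background_khz * 1e3 * dt

    trip = config.triplet
    r_occ = _occupancy_radius_um(optics)
    inv_ax = np.array([1.0 / r_occ, 1.0 / r_occ, 1.0 / (s_par * r_occ)])

    chunk = max(1, int(4_000_000 / max(n_mol, 1)))
    chunk = min(chunk, n_steps)
    step_sigma32 = step_sigma.astype(np.float32)
    q32 = q.astype(np.float32)
    box32 = box.astype(np.float32)
    inv_ax32 = inv_ax.astype(np.float32)

    traces: list[PhotonTrace] = []
    truth = {
        "species": [
            {"diffusion_um2_s": sp.diffusion_um2_s, "fraction": sp.fraction,
             "brightness_khz": sp.brightness_khz}
            for sp in config.species
        ],
        "mean_molecules_in_cv": config.mean_molecules_in_cv,
        "n_simulated_molecules": n_mol,
        "w0_um": w0,
        "structural_parameter": s_par,
        "triplet": None if trip is None else {
            "dark_fraction": trip.dark_fraction,
            "relaxation_time_s": trip.relaxation_time_s,
        },
    }

    p_to_dark = p_to_bright = 0.0
    if trip is not None:
        p_to_dark = trip.rate_to_dark * dt
        p_to_bright = trip.rate_to_bright * dt
        if p_to_dark > 1.0 or p_to_bright > 1.0:
            raise ValueError("timestep too coarse for the triplet rates")

    def _markov_timeline(state: np.ndarray, remaining: np.ndarray,
                         n_c: int) -> np.ndarray:
        """Evolve per-molecule two-state timelines for n_c steps.

        Dwell times are geometric with the per-step leave probability, which
        reproduces the discrete-time Markov chain exactly; ``state`` and
        ``remaining`` (steps left in the current dwell) are updated in place.
        """
        out = np.empty((n_c, n_mol), dtype=bool)
        for j in range(n_mol):
            t = 0
            s = state[j]
            rem = remaining[j]
            while t < n_c:
                take = min(int(rem), n_c - t)
                out[t: t + take, j] = s
                t += take
                rem -= take
                if rem == 0:
                    s = not s
                    p_leave = p_to_dark if s else p_to_bright
                    rem = rng.geometric(p_leave)
            state[j] = s
            remaining[j] = rem
        return out

    for rep in range(config.repetitions):
        pos = rng.uniform(-box / 2, box / 2, size=(n_mol, 3))
        if config.initial_positions is not None:
            fixed = np.asarray(config.initial_positions, dtype=float)
            pos[: len(fixed)] = fixed
        if trip is not None:
            state = rng.random(n_mol) >= trip.dark_fraction
            remaining = np.where(
                state,
                rng.geometric(p_to_dark, n_mol),
                rng.geometric(p_to_bright, n_mol),
            ).astype(np.int64)

        expected = np.empty(n_steps)
        occ_sums: list[float] = []
        done = 0
        while done < n_steps:
            n_c = min(chunk, n_steps - done)
            # single precision is ample: positions are O(1) um and the MDF
            # needs ~4 significant digits
            disp = rng.standard_normal((n_c, n_mol, 3), dtype=np.float32)
            disp *= step_sigma32[None, :, None]
            np.cumsum(disp, axis=0, out=disp)
            traj = disp
            traj += pos[None, :, :].astype(np.float32)
            # periodic wrap (wrap-once equals wrap-per-step modulo the box)
            tmp = traj / box32
            np.round(tmp, out=tmp)
            tmp *= box32
            traj -= tmp
            pos = traj[-1].astype(float)
            arg = traj[:, :, 0] ** 2
            arg += traj[:, :, 1] ** 2
            arg *= np.float32(-2.0 / w0**2)
            arg += traj[:, :, 2] ** 2 * np.float32(-2.0 / (s_par * w0) ** 2)
            mdf = np.exp(arg)
            if trip is not None:
                mdf *= _markov_timeline(state, remaining, n_c)
            lam = mdf @ q32
            expected[done: done + n_c] = lam.astype(float) * dt + bg_per_step
            if record_occupancy:
                sub = traj[::4] * inv_ax32[None, None, :]
                inside = np.sum(sub**2, axis=2) <= 1.0
                occ_sums.append(float(inside.sum(axis=1).mean()))
            done += n_c

        counts = rng.poisson(expected.reshape(n_bins, steps_per_bin).sum(axis=1))
        meta = {"ground_truth": truth, "seed": seed if seed is not None else config.seed}
        if record_occupancy:
            occ = np.asarray(occ_sums)
            meta["occupancy_mean"] = float(occ.mean())
            meta["occupancy_se"] = float(occ.std(ddof=1) / math.sqrt(len(occ))) if len(occ) > 1 else math.nan
        traces.append(PhotonTrace(
            counts=counts, bin_width=config.bin_width_s,
            repetition_id=rep, meta=meta,
        ))
    return traces


def make_lag_grid(min_s: float = 1e-6, max_s: float = 2.0, n: int = 120) -> np.ndarray:
    """Logarithmically spaced lag grid in seconds."""
    if min_s <= 0 or max_s <= min_s or n < 2:
        raise ValueError("invalid lag grid specification")
    return np.geomspace(min_s, max_s, n)


def generate_curve(
    params: dict,
    lags: np.ndarray,
    noise_scale: float = 0.0,
    seed=None,
    mean_rate_khz: float = 0.0,
    noise_model: str = "display",
) -> CorrelationCurve:
    """Closed-form model curve plus heteroscedastic Gaussian noise.

    Two noise models are available.  ``"display"`` (default) draws zero-mean
    Gaussian noise with standard deviation ``noise_scale * (1 + g_model)`` —
    i.e. scaled to the display-convention curve ``1 + g``, so it is nearly
    uniform in absolute terms.  ``"proportional"`` scales the noise to the
    correlation signal itself, ``noise_scale * g_model`` — "1% multiplicative
    noise" in the proportional model leaves every lag with a signal-to-noise
    ratio of 100.  The per-lag scale is stored on the curve so fits can
    weight residuals.  ``params`` are keyword arguments of
    :func:`fcsquant.model_fit.model_g`.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    if noise_model not in ("display", "proportional"):
        raise ValueError("noise_model must be 'display' or 'proportional'")
    lags = np.asarray(lags, dtype=float)
    g_model = model_g(lags, **params)
    meta = {"ground_truth": dict(params), "noise_scale": noise_scale,
            "noise_model": noise_model}
    if noise_scale == 0:
        return CorrelationCurve(lags=lags, g=g_model, mean_rate_khz=mean_rate_khz, meta=meta)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_model == "display":
        sigma = noise_scale * (1.0 + g_model)
    else:
        sigma = noise_scale * np.abs(g_model)
        sigma = np.maximum(sigma, 1e-12)
    g = g_model + rng.standard_normal(len(lags)) * sigma
    return CorrelationCurve(
        lags=lags, g=g, mean_rate_khz=mean_rate_khz, sigma=sigma, meta=meta,
    )


@dataclass
class GroupSpec:
    """Per-group (strain x condition) population parameters.

    Medians are the population medians of the per-cell log-normal draws;
    ``cv``-style dispersions are relative (0 = every cell at the median).
    ``frac_slow_scale`` is the logit-space spread of the slow fraction.
    """

    strain: str
    condition: str
    n_cells: int
    n_molecules_median: float
    cpm_khz_median: float = 10.0
    frac_slow_median: float = 0.4
    d_fast_median_um2_s: float = 12.25
    d_slow_median_um2_s: float = 0.15
    n_molecules_cv: float = 0.2
    cpm_cv: float = 0.1
    frac_slow_scale: float = 0.2
    d_cv: float = 0.1
    repetitions: int = 5
    intensity_median: float = 5e5
    intensity_cv: float = 0.25
    positive_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("n_molecules_median", "cpm_khz_median", "d_fast_median_um2_s",
                     "d_slow_median_um2_s", "intensity_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_molecules_cv", "cpm_cv", "frac_slow_scale", "d_cv", "intensity_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.frac_slow_median < 1.0:
            raise ValueError("frac_slow_median must lie in (0, 1)")

    @property
    def label(self) -> str:
        return f"{self.strain}|{self.condition}"


@dataclass
class StudyDesign:
    """A set of population groups sharing optics, noise and lag grid."""

    groups: Sequence[GroupSpec]
    optics: OpticsSpec = field(default_factory=OpticsSpec)
    triplet: Optional[TripletSpec] = field(default_factory=TripletSpec)
    noise_scale: float = 0.01
    noise_model: str = "proportional"
    lag_min_s: float = 1e-6
    lag_max_s: float = 2.0
    n_lags: int = 120

    def lag_grid(self) -> np.ndarray:
        return make_lag_grid(self.lag_min_s, self.lag_max_s, self.n_lags)


@dataclass
class CellRecord:
    """Ground truth and synthetic curves for one cell."""

    cell_id: str
    strain: str
    condition: str
    truth: dict
    curves: list[CorrelationCurve]

    @property
    def group(self) -> str:
        return f"{self.strain}|{self.condition}"


def _lognormal(rng: np.random.Generator, median: float, cv: float, size=None):
    """Log-normal draw parameterised by its median and coefficient of variation."""
    if cv == 0:
        return np.full(size, median) if size is not None else median
    sigma = math.sqrt(math.log1p(cv**2))
    return median * np.exp(rng.normal(0.0, sigma, size))


def _logitnormal(rng: np.random.Generator, median: float, scale: float, size=None):
    if scale == 0:
        return np.full(size, median) if size is not None else median
    return expit(rng.normal(logit(median), scale, size))


def generate_population(design: StudyDesign, seed=None) -> list[CellRecord]:
    """Draw per-cell ground-truth parameters and synthesise noisy curves.

    Positive quantities (N, CPM, diffusion coefficients) are log-normal with
    the requested group median; the slow fraction is logit-normal.  Each cell
    receives ``repetitions`` independently noisy curves on the design's lag
    grid, with mean count rate CPM x N.
    """
    rng = np.random.default_rng(seed)
    lags = design.lag_grid()
    w0 = design.optics.w0_um
    s_par = design.optics.structural_parameter
    trip = design.triplet

    records: list[CellRecord] = []
    for group in design.groups:
        for i in range(group.n_cells):
            n_mol = float(_lognormal(rng, group.n_molecules_median, group.n_molecules_cv))
            cpm = float(_lognormal(rng, group.cpm_khz_median, group.cpm_cv))
            frac_slow = float(_logitnormal(rng, group.frac_slow_median, group.frac_slow_scale))
            d_fast = float(_lognormal(rng, group.d_fast_median_um2_s, group.d_cv))
            d_slow = float(_lognormal(rng, group.d_slow_median_um2_s, group.d_cv))
            tau_fast = w0**2 / (4.0 * d_fast)
            tau_slow = w0**2 / (4.0 * d_slow)
            params = {
                "n_molecules": n_mol,
                "frac_fast": 1.0 - frac_slow,
                "tau_fast_s": tau_fast,
                "tau_slow_s": tau_slow,
                "triplet_fraction": 0.0 if trip is None else trip.dark_fraction,
                "tau_triplet_s": 20e-6 if trip is None else trip.relaxation_time_s,
                "structural_parameter": s_par,
                "offset": 0.0,
            }
            mean_rate = cpm * n_mol
            cell_id = f"{group.strain}-{group.condition}-{i:04d}"
            curves = []
            for rep in range(group.repetitions):
                curve = generate_curve(params, lags, design.noise_scale, rng,
                                       mean_rate, noise_model=design.noise_model)
                curve.meta.update({"cell_id": cell_id, "group": group.label,
                                   "repetition_id": rep})
                curves.append(curve)
            truth = dict(params)
            truth.update({
                "cpm_khz": cpm, "mean_rate_khz": mean_rate, "frac_slow": frac_slow,
                "d_fast_um2_s": d_fast, "d_slow_um2_s": d_slow,
            })
            records.append(CellRecord(
                cell_id=cell_id, strain=group.strain, condition=group.condition,
                truth=truth, curves=curves,
            ))
    return records


def generate_intensity_table(design: StudyDesign, seed=None) -> pd.DataFrame:
    """Per-cell integrated whole-cell intensities (log-normal per group)."""
    rng = np.random.default_rng(seed)
    rows = []
    for group in design.groups:
        intensities = _lognormal(rng, group.intensity_median, group.intensity_cv,
                                 size=group.n_cells)
        positive = rng.random(group.n_cells) < group.positive_fraction
        for i in range(group.n_cells):
            rows.append({
                "cell_id": f"{group.strain}-{group.condition}-img-{i:04d}",
                "strain": group.strain,
                "condition": group.condition,
                "group": group.label,
                "integrated_intensity": float(intensities[i]),
                "localisation_class": "positive" if positive[i] else "negative",
            })
    return pd.DataFrame(rows)
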