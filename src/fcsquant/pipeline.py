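"""End-to-end orchestration: simulate -> (correlate) -> fit -> quantify -> compare.

A run is described by a plain mapping (usually loaded from YAML), executed
deterministically from a single seed, and leaves a directory of per-stage
artefacts plus a manifest tying every output to the configuration hash and
seed.

Two execution paths exist: the default "curve" path synthesises analytic
correlation curves with noise (seconds of runtime), while the "trace" path
runs the Brownian-dynamics photon simulation and the multi-tau correlator
(minutes; used for physics validation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .correlator import autocorrelate_multitau, trim_trace
from .io import fits_to_dataframe, measurements_to_dataframe, write_json
from .model_fit import fit_curve, two_stage_fit
from .qc import (PopulationSample, apply_filters, summarize_cell)
from .synthetic import (GroupSpec, OpticsSpec, SimulationConfig, SpeciesSpec,
                        StudyDesign, TripletSpec, generate_intensity_table,
                        generate_population, simulate_trace)
from .stats import mann_whitney

__all__ = ["RunConfig", "run_experiment", "design_from_config"]

_SCHEME_REPS = {"10x10s": 10, "5x5s": 5}


@dataclass
class RunConfig:
    """Validated run configuration (see ``design_from_config`` for the schema)."""

    design: StudyDesign
    seed: int = 0
    scheme: str = "5x5s"
    mode: str = "curve"
    two_stage: bool = True
    with_triplet: bool = True
    fix_s: float = 4.0
    chi2_threshold: float = 1e-4
    s_bounds: tuple[float, float] = (0.1, 15.0)
    chi2_rule: str = "exclude_below"
    comparisons: list[dict] = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEME_REPS:
            raise ValueError(f"scheme must be one of {sorted(_SCHEME_REPS)}")
        if self.mode not in ("curve", "trace"):
            raise ValueError("mode must be 'curve' or 'trace'")


def design_from_config(cfg: dict) -> RunConfig:
    """Build a RunConfig from a plain mapping.

    Expected keys: ``groups`` (list of GroupSpec fields), optional
    ``optics``, ``triplet`` (or null), ``noise_scale``, ``lag_grid``
    ({min_s,max_s,n}), ``seed``, ``scheme``, ``mode``, ``fit``
    ({two_stage,with_triplet,fix_s}), ``filters``
    ({chi2_threshold,s_bounds,chi2_rule}), ``comparisons``
    (list of {field, a, b} with group labels "strain|condition").
    """
    optics = OpticsSpec(**cfg.get("optics", {}))
    trip_cfg = cfg.get("triplet", "default")
    if trip_cfg is None:
        triplet = None
    elif trip_cfg == "default":
        triplet = TripletSpec()
    else:
        triplet = TripletSpec(**trip_cfg)
    lag = cfg.get("lag_grid", {})
    groups = [GroupSpec(**g) for g in cfg["groups"]]
    design = StudyDesign(
        groups=groups, optics=optics, triplet=triplet,
        noise_scale=float(cfg.get("noise_scale", 0.01)),
        noise_model=str(cfg.get("noise_model", "proportional")),
        lag_min_s=float(lag.get("min_s", 1e-6)),
        lag_max_s=float(lag.get("max_s", 2.0)),
        n_lags=int(lag.get("n", 120)),
    )
    fit_cfg = cfg.get("fit", {})
    filt = cfg.get("filters", {})
    return RunConfig(
        design=design,
        seed=int(cfg.get("seed", 0)),
        scheme=str(cfg.get("scheme", "5x5s")),
        mode=str(cfg.get("mode", "curve")),
        two_stage=bool(fit_cfg.get("two_stage", True)),
        with_triplet=bool(fit_cfg.get("with_triplet", True)),
        fix_s=float(fit_cfg.get("fix_s", 4.0)),
        chi2_threshold=float(filt.get("chi2_threshold", 1e-4)),
        s_bounds=tuple(filt.get("s_bounds", (0.1, 15.0))),
        chi2_rule=str(filt.get("chi2_rule", "exclude_below")),
        comparisons=list(cfg.get("comparisons", [])),
        raw=cfg,
    )


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _curves_for_cell(record, config: RunConfig, rng: np.random.Generator):
    """Trace-path: simulate photon traces for one cell and correlate them."""
    truth = record.truth
    d_fast = truth["d_fast_um2_s"]
    d_slow = truth["d_slow_um2_s"]
    frac_slow = truth["frac_slow"]
    # per-molecule peak brightness backs out from the target CPM
    q = truth["cpm_khz"] * 2.0**1.5
    sim = SimulationConfig(
        species=[
            SpeciesSpec(d_fast, 1.0 - frac_slow, q),
            SpeciesSpec(d_slow, frac_slow, q),
        ],
        optics=config.design.optics,
        triplet=config.design.triplet,
        mean_molecules_in_cv=truth["n_molecules"],
        bin_width_s=float(config.raw.get("trace", {}).get("bin_width_s", 1e-5)),
        duration_s=float(config.raw.get("trace", {}).get("duration_s", 1.0)),
        repetitions=len(record.curves),
    )
    traces = simulate_trace(sim, seed=int(rng.integers(2**31)))
    curves = []
    for trace in traces:
        trace.cell_id = record.cell_id
        trace.group = record.group
        skip = float(config.raw.get("trace", {}).get("skip_s", 0.0))
        if skip > 0:
            trace = trim_trace(trace, skip)
        curves.append(autocorrelate_multitau(trace))
    return curves


def run_experiment(config: RunConfig, out_dir: Path | str) -> dict:
    """Execute a full run and write the report bundle.

    Returns the manifest dict.  Identical config + seed give identical
    numeric outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    rng = np.random.default_rng(config.seed)

    counts = {}
    records = generate_population(design, seed=config.seed)
    counts["cells_generated"] = len(records)

    # fit every repetition curve
    all_fits = []
    for record in records:
        curves = record.curves if config.mode == "curve" else \
            _curves_for_cell(record, config, rng)
        for curve in curves:
            curve.meta.setdefault("cell_id", record.cell_id)
            curve.meta.setdefault("group", record.group)
            if config.two_stage:
                fit = two_stage_fit(curve, with_triplet=config.with_triplet,
                                    fix_s=config.fix_s,
                                    s_screen_bounds=config.s_bounds)
            else:
                fit = fit_curve(curve, fix_s=config.fix_s,
                                with_triplet=config.with_triplet)
            all_fits.append(fit)
    counts["fits"] = len(all_fits)
    fits_to_dataframe(all_fits).to_csv(out / "fits.csv", index=False)

    kept, discarded = apply_filters(
        all_fits, chi2_threshold=config.chi2_threshold,
        s_bounds=config.s_bounds, chi2_rule=config.chi2_rule,
    )
    counts["fits_kept"] = len(kept)
    counts["fits_discarded"] = len(discarded)
    exclusion_tally: dict[str, int] = {}
    for _, reason in discarded:
        exclusion_tally[reason] = exclusion_tally.get(reason, 0) + 1

    # per-cell summaries
    by_cell: dict[str, list] = {}
    for fit in kept:
        by_cell.setdefault(fit.cell_id, []).append(fit)
    samples: dict[str, PopulationSample] = {
        g.label: PopulationSample(strain=g.strain, condition=g.condition)
        for g in design.groups
    }
    truth_by_cell = {r.cell_id: r for r in records}
    rows = []
    for record in records:
        fits = by_cell.get(record.cell_id, [])
        if fits:
            meas = summarize_cell(fits, scheme=config.scheme, optics=design.optics)
        else:
            from .qc import CellMeasurement
            meas = CellMeasurement(cell_id=record.cell_id, group=record.group,
                                   excluded=True, reason="insufficient_repetitions")
        meas.group = record.group
        samples[record.group].measurements.append(meas)
        row = meas.to_dict()
        row.update({
            "truth_n_molecules": record.truth["n_molecules"],
            "truth_cpm_khz": record.truth["cpm_khz"],
            "truth_frac_slow": record.truth["frac_slow"],
            "truth_d_fast_um2_s": record.truth["d_fast_um2_s"],
            "truth_d_slow_um2_s": record.truth["d_slow_um2_s"],
        })
        rows.append(row)
    cells_df = pd.DataFrame(rows)
    cells_df.to_csv(out / "cells.csv", index=False)
    counts["cells_included"] = int((~cells_df["excluded"]).sum())

    # group summaries (seeded bootstrap CIs)
    summaries = []
    for label, sample in samples.items():
        if sample.n >= 3:
            for fieldname in ("n_molecules", "cpm_khz", "d_fast_um2_s",
                              "d_slow_um2_s", "frac_slow", "per_cell_copies"):
                s = sample.summary(fieldname, seed=np.random.default_rng(config.seed))
                s["exclusion_tally"] = exclusion_tally
                summaries.append(s)
    write_json(summaries, out / "group_summaries.json")

    # truth-vs-recovered table
    recovery = []
    for label, sample in samples.items():
        if sample.n == 0:
            continue
        inc = sample.included
        truth_n = np.median([truth_by_cell[m.cell_id].truth["n_molecules"] for m in inc])
        fit_n = float(np.median([m.n_molecules for m in inc]))
        recovery.append({
            "group": label,
            "truth_median_n": float(truth_n),
            "recovered_median_n": fit_n,
            "relative_error": fit_n / truth_n - 1.0,
            "n": sample.n,
        })
    pd.DataFrame(recovery).to_csv(out / "recovery.csv", index=False)

    # statistical comparisons
    reports = []
    for comp in config.comparisons:
        fieldname = comp.get("field", "n_molecules")
        a = samples[comp["a"]].values(fieldname)
        b = samples[comp["b"]].values(fieldname)
        rep = mann_whitney(a, b).to_dict()
        rep.update({"field": fieldname, "a": comp["a"], "b": comp["b"]})
        reports.append(rep)
    write_json(reports, out / "comparisons.json")

    intensity = generate_intensity_table(design, seed=config.seed)
    intensity.to_csv(out / "intensity.csv", index=False)

    manifest = {
        "config_hash": _config_hash(config.raw),
        "seed": config.seed,
        "mode": config.mode,
        "scheme": config.scheme,
        "versions": {
            "fcsquant": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": counts,
        "exclusion_tally": exclusion_tally,
        "artefacts": ["fits.csv", "cells.csv", "group_summaries.json",
                      "recovery.csv", "comparisons.json", "intensity.csv"],
    }
    write_json(manifest, out / "manifest.json")
    return manifest
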