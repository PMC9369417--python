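"""Plain-text I/O: CSV tables with JSON sidecar metadata.

Traces are stored as ``<prefix>.csv`` (bin_index, counts) plus
``<prefix>.json``; curves as (lag_s, g[, sigma]) plus sidecar carrying the
mean count rate and provenance.  Fits and measurements are flat JSON records
and CSV summaries.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .correlator import CorrelationCurve, PhotonTrace
from .model_fit import FitResult
from .qc import CellMeasurement

__all__ = [
    "write_trace", "read_trace", "write_curve", "read_curve",
    "write_fits", "read_fits", "measurements_to_dataframe",
    "write_json",
]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, set):
            return sorted(obj)
        return super().default(obj)


def write_json(payload, path: Path | str) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")


def write_trace(trace: PhotonTrace, prefix: Path | str) -> None:
    prefix = Path(prefix)
    df = pd.DataFrame({"bin_index": np.arange(len(trace.counts)),
                       "counts": trace.counts})
    df.to_csv(prefix.with_suffix(".csv"), index=False)
    write_json({
        "bin_width_s": trace.bin_width,
        "duration_s": trace.duration,
        "repetition": trace.repetition_id,
        "cell_id": trace.cell_id,
        "group": trace.group,
        **trace.meta,
    }, prefix.with_suffix(".json"))


def read_trace(prefix: Path | str) -> PhotonTrace:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return PhotonTrace(
        counts=df["counts"].to_numpy(),
        bin_width=meta.pop("bin_width_s"),
        repetition_id=int(meta.pop("repetition", 0)),
        cell_id=str(meta.pop("cell_id", "")),
        group=str(meta.pop("group", "")),
        meta=meta,
    )


def write_curve(curve: CorrelationCurve, prefix: Path | str) -> None:
    prefix = Path(prefix)
    cols = {"lag_s": curve.lags, "g": curve.g}
    if curve.sigma is not None:
        cols["sigma"] = curve.sigma
    pd.DataFrame(cols).to_csv(prefix.with_suffix(".csv"), index=False)
    write_json({
        "mean_rate_khz": curve.mean_rate_khz,
        "flags": sorted(curve.flags),
        **curve.meta,
    }, prefix.with_suffix(".json"))


def read_curve(prefix: Path | str) -> CorrelationCurve:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return CorrelationCurve(
        lags=df["lag_s"].to_numpy(),
        g=df["g"].to_numpy(),
        sigma=df["sigma"].to_numpy() if "sigma" in df else None,
        mean_rate_khz=float(meta.pop("mean_rate_khz", 0.0)),
        flags=set(meta.pop("flags", [])),
        meta=meta,
    )


def write_fits(fits: Sequence[FitResult], path: Path | str) -> None:
    """One JSON record per fit (list form)."""
    write_json([f.to_dict() for f in fits], path)


def read_fits(path: Path | str) -> list[FitResult]:
    records = json.loads(Path(path).read_text())
    fits = []
    for rec in records:
        fits.append(FitResult(
            n_molecules=rec["n_molecules"],
            triplet_fraction=rec["triplet_fraction"],
            tau_triplet_s=rec["tau_triplet_s"],
            frac_fast=rec["frac_fast"],
            tau_fast_s=rec["tau_fast_s"],
            tau_slow_s=rec["tau_slow_s"],
            structural_parameter=rec["structural_parameter"],
            offset=rec["offset"],
            chi2=rec["chi2"],
            cpm_khz=rec["cpm_khz"],
            mean_rate_khz=rec["mean_rate_khz"],
            components=rec["components"],
            qc_flags=set(rec.get("qc_flags", [])),
            free_s_estimate=rec.get("free_s_estimate"),
            cell_id=rec.get("cell_id", ""),
            group=rec.get("group", ""),
            repetition_id=rec.get("repetition_id", 0),
        ))
    return fits


def fits_to_dataframe(fits: Sequence[FitResult]) -> pd.DataFrame:
    rows = [f.to_dict() for f in fits]
    for row in rows:
        row["qc_flags"] = ";".join(row["qc_flags"])
    return pd.DataFrame(rows)


def measurements_to_dataframe(measurements: Sequence[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.to_dict() for m in measurements])
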