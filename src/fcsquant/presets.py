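"""Calibration presets for the bundled demonstration study.

Group medians mirror a yeast mitochondrial-fission study design: two
GFP-tagged proteins (Fis1p, Mdv1p) in homozygote / heterozygote / hemizygote
diploids, grown on glucose (fermentative) or glycerol (respiratory).  These
values parameterise the synthetic-data generator; they are inputs, not
measurements.
"""

from __future__ import annotations

from .synthetic import GroupSpec, OpticsSpec, StudyDesign, TripletSpec

__all__ = [
    "OPTICS", "TRIPLET", "GROUP_MEDIANS", "MOBILITY",
    "demo_group", "demo_study",
]

OPTICS = OpticsSpec(w0_um=0.22, structural_parameter=4.0, confocal_volume_fl=0.57)
TRIPLET = TripletSpec(dark_fraction=0.15, relaxation_time_s=20e-6)

CELL_VOLUME_FL = 82.0

# median molecules per confocal volume and study sample sizes, by
# (strain, condition); cpm is the per-molecule brightness in kHz
GROUP_MEDIANS: dict[tuple[str, str], dict] = {
    ("FIS1-GFP/GFP", "glucose"): {"n_molecules": 25.19, "cpm_khz": 20.0, "n_cells": 63},
    ("FIS1-GFP/+", "glucose"): {"n_molecules": 20.85, "cpm_khz": 5.0, "n_cells": 107},
    ("FIS1-GFP/-", "glucose"): {"n_molecules": 23.85, "cpm_khz": 5.0, "n_cells": 145},
    ("FIS1-GFP/+", "glycerol"): {"n_molecules": 20.02, "cpm_khz": 5.0, "n_cells": 103},
    ("FIS1-GFP/-", "glycerol"): {"n_molecules": 22.98, "cpm_khz": 5.0, "n_cells": 158},
    ("MDV1-GFP/GFP", "glucose"): {"n_molecules": 22.29, "cpm_khz": 10.0, "n_cells": 124},
    ("MDV1-GFP/+", "glucose"): {"n_molecules": 19.93, "cpm_khz": 5.0, "n_cells": 108},
    ("MDV1-GFP/-", "glucose"): {"n_molecules": 20.19, "cpm_khz": 5.0, "n_cells": 81},
}

# two-component mobility: fast diffusion coefficient, slow coefficient and
# slow-moving fraction by (strain, condition).  Coefficients not reported
# for a given group fall back to the in-regime defaults (fast ~9-12,
# slow 0.1-0.2 um^2/s).
MOBILITY: dict[tuple[str, str], dict] = {
    ("FIS1-GFP/+", "glucose"): {"d_fast": 12.25, "d_slow": 0.15, "frac_slow": 1 - 0.596},
    ("FIS1-GFP/-", "glucose"): {"d_fast": 9.48, "d_slow": 0.15, "frac_slow": 1 - 0.612},
    ("MDV1-GFP/+", "glucose"): {"d_fast": 9.56, "d_slow": 0.15, "frac_slow": 1 - 0.511},
    ("MDV1-GFP/-", "glucose"): {"d_fast": 10.46, "d_slow": 0.15, "frac_slow": 1 - 0.516},
    ("FIS1-GFP/+", "glycerol"): {"d_fast": 11.11, "d_slow": 0.15, "frac_slow": 1 - 0.585},
    ("FIS1-GFP/-", "glycerol"): {"d_fast": 11.09, "d_slow": 0.15, "frac_slow": 1 - 0.62},
    ("MDV1-GFP/+", "glycerol"): {"d_fast": 9.56, "d_slow": 0.15, "frac_slow": 0.555},
    ("MDV1-GFP/-", "glycerol"): {"d_fast": 10.46, "d_slow": 0.18, "frac_slow": 0.584},
}


def demo_group(
    strain: str,
    condition: str = "glucose",
    n_cells: int | None = None,
    repetitions: int = 5,
    cv: float = 0.2,
) -> GroupSpec:
    """A GroupSpec preset for one strain x condition of the demo study."""
    key = (strain, condition)
    if key not in GROUP_MEDIANS:
        raise KeyError(f"no preset for {key}")
    med = GROUP_MEDIANS[key]
    mob = MOBILITY.get(key, {"d_fast": 10.0, "d_slow": 0.15, "frac_slow": 0.45})
    return GroupSpec(
        strain=strain,
        condition=condition,
        n_cells=n_cells if n_cells is not None else med["n_cells"],
        n_molecules_median=med["n_molecules"],
        cpm_khz_median=med["cpm_khz"],
        frac_slow_median=mob["frac_slow"],
        d_fast_median_um2_s=mob["d_fast"],
        d_slow_median_um2_s=mob["d_slow"],
        n_molecules_cv=cv,
        repetitions=repetitions,
    )


def demo_study(
    keys: list[tuple[str, str]] | None = None,
    n_cells: int | None = None,
    repetitions: int = 5,
    cv: float = 0.2,
    **design_kwargs,
) -> StudyDesign:
    """Assemble a StudyDesign from preset groups (all groups by default)."""
    keys = keys if keys is not None else list(GROUP_MEDIANS)
    groups = [demo_group(s, c, n_cells=n_cells, repetitions=repetitions, cv=cv)
              for s, c in keys]
    return StudyDesign(groups=groups, optics=OPTICS, triplet=TRIPLET, **design_kwargs)
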