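"""Two-group synthetic cohorts of beaded axons for end-to-end testing.

Emulates the contrast between a control ("sham-like") and an injured
("TBI-like") axon population by shifting the bead-generator parameter ranges:
injury corresponds to more and more prominent beads (smaller mean bead
spacing, larger bead amplitude).  Per-axon parameters are drawn uniformly
from each group's ranges; every draw is recorded in the manifest, so a recipe
plus its master seed reproduces the cohort exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import spectral, theory
from .geometry import relative_profile, tortuosity, volume_weights, write_profile_table
from .synthesize import BeadModelParams, generate_bead_profile

__all__ = ["GroupRanges", "CohortRecipe", "generate_cohort", "cohort_parameter_table",
           "write_cohort"]


@dataclass
class GroupRanges:
    """Uniform per-axon parameter ranges of one group (lo, hi), units um/um^2."""

    bead_amplitude: tuple = (0.1, 2.5)
    bead_width: tuple = (3.0, 7.0)
    mean_spacing: tuple = (3.0, 7.0)
    sd_spacing_factor: tuple = (0.8, 1.2)     # sigma_a / abar
    base_area: float = math.pi * 0.25

    def __post_init__(self) -> None:
        for name in ("bead_amplitude", "bead_width", "mean_spacing", "sd_spacing_factor"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


@dataclass
class CohortRecipe:
    control: GroupRanges = field(default_factory=GroupRanges)
    injured: GroupRanges = field(default_factory=GroupRanges)
    n_axons: int = 20
    length: float = 300.0
    dl: float = 0.1
    seed: int = 0
    labels: tuple = ("sham", "tbi")

    def __post_init__(self) -> None:
        if self.n_axons < 1:
            raise ValueError("need at least one axon per group")


def _draw_params(rng: np.random.Generator, ranges: GroupRanges, recipe: CohortRecipe,
                 seed: int) -> BeadModelParams:
    abar = rng.uniform(*ranges.mean_spacing)
    return BeadModelParams(
        base_area=ranges.base_area,
        bead_amplitude=rng.uniform(*ranges.bead_amplitude),
        bead_width=rng.uniform(*ranges.bead_width),
        mean_spacing=abar,
        sd_spacing=abar * rng.uniform(*ranges.sd_spacing_factor),
        length=recipe.length,
        dl=recipe.dl,
        seed=seed,
    )


def generate_cohort(recipe: CohortRecipe):
    """Generate the labeled profiles; returns (list of (profile, label), manifest)."""
    rng = np.random.default_rng(recipe.seed)
    out = []
    manifest = {"seed": recipe.seed, "n_axons": recipe.n_axons, "draws": []}
    for label, ranges in zip(recipe.labels, (recipe.control, recipe.injured)):
        for i in range(recipe.n_axons):
            sub = int(rng.integers(0, 2**31 - 1))
            params = _draw_params(rng, ranges, recipe, sub)
            profile = generate_bead_profile(params)
            profile.axon_id = f"{label}-{i:03d}"
            out.append((profile, label))
            manifest["draws"].append({"axon_id": profile.axon_id, "group": label,
                                      **params.manifest()})
    return out, manifest


def cohort_parameter_table(
    profiles_labels,
    D0: float = theory.DEFAULT_D0,
) -> pd.DataFrame:
    """Run the forward pipeline on labeled profiles and build a cohort table.

    Per axon: tortuosity and PSD-plateau Gamma_0 from the profile, then the
    predicted (D_inf, c_D) through the closed-form maps, volume weights
    normalized per group, and xi = 1 (straight synthetic tubes).
    """
    rows = []
    profiles = [p for p, _ in profiles_labels]
    weights = volume_weights(profiles)
    for (profile, label), w in zip(profiles_labels, weights):
        rel = relative_profile(profile)
        tort = tortuosity(rel)
        est = spectral.plateau(spectral.psd(rel.eta, rel.dl))
        dinf = theory.predict_dinf(rel, D0=D0)
        cd = theory.predict_cd(est.gamma0, dinf)
        rows.append({
            "axon_id": profile.axon_id, "group": label, "tortuosity": tort,
            "gamma0_um": est.gamma0, "Dinf": dinf, "cD": cd,
            "weight": w, "xi": 1.0,
        })
    return pd.DataFrame(rows)


def write_cohort(profiles_labels, manifest: dict, out_dir) -> None:
    """Write one profile TSV per axon plus the cohort manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for profile, _ in profiles_labels:
        write_profile_table(profile, out / f"{profile.axon_id}.tsv")
    with open(out / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
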