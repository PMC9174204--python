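"""Synthetic ONH cohort generator.

Emulates the cross-sectional study design the stage analysis assumes:
four groups (healthy controls C, preperimetric PG, early EG and
moderate-advanced MAG glaucoma), two eyes per participant sharing a
participant-level random intercept, stage-dependent multiplicative
thinning of the parameter families, per-stage covariate distributions,
and visual-field mean deviation (VF MD) coupled linearly to structural
loss.

Each eye is realised as a :class:`~onhmorph.phantom.PhantomParams`
whose angular profiles carry the stage effect plus participant and eye
noise; the tabulated parameter values are the analytic morphometry of
that anatomy, so the cohort table and any surface realisation are
mutually consistent.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import PARAMETER_COLUMNS
from .phantom import PhantomParams, SurfaceSet, analytic_truth, generate_surfaces
from .regions import REGIONS

STAGES = ("C", "PG", "EG", "MAG")

#: Parameter families that take independent stage effects and noise.
#: mrw/mra derive from the rim (bnfl) geometry; prelamina volume from plt.
NOISE_FAMILIES = ("bnfl", "pnfl", "plt")

#: Per-stage covariate distributions (mean, SD), matching the demographic
#: structure of a POAG cohort with age-matched controls.
DEFAULT_COVARIATES: dict[str, dict[str, tuple[float, float]]] = {
    "age_years": {"C": (67.27, 5.06), "PG": (67.58, 9.09),
                  "EG": (71.16, 7.80), "MAG": (72.61, 7.76)},
    "ms_d":      {"C": (1.10, 1.65), "PG": (-0.13, 2.85),
                  "EG": (0.20, 2.52), "MAG": (0.07, 2.26)},
    "iop_mmhg":  {"C": (14.98, 3.31), "PG": (13.39, 2.12),
                  "EG": (13.36, 2.36), "MAG": (12.13, 2.59)},
    "ael_mm":    {"C": (23.69, 0.94), "PG": (23.94, 1.72),
                  "EG": (23.90, 1.34), "MAG": (24.06, 1.35)},
    "cct_um":    {"C": (560.60, 41.29), "PG": (529.48, 31.14),
                  "EG": (534.14, 44.28), "MAG": (526.09, 32.60)},
    "acd_mm":    {"C": (2.84, 0.60), "PG": (2.93, 0.68),
                  "EG": (3.14, 0.89), "MAG": (3.16, 0.87)},
}

#: Fractional thinning per stage and family (0 = control anatomy).
#: Prelamina compresses early; the rim and NFL thin progressively.
DEFAULT_STAGE_EFFECTS: dict[str, dict[str, float]] = {
    "C":   {"bnfl": 0.00, "pnfl": 0.00, "plt": 0.00},
    "PG":  {"bnfl": 0.06, "pnfl": 0.06, "plt": 0.15},
    "EG":  {"bnfl": 0.18, "pnfl": 0.15, "plt": 0.20},
    "MAG": {"bnfl": 0.45, "pnfl": 0.35, "plt": 0.30},
}


class CohortSpecError(ValueError):
    """Raised for invalid cohort specifications."""


@dataclass
class CohortSpec:
    """Statistical structure of a synthetic cohort.

    ``inter_eye_sd`` is the SD (mm) of the participant-level random
    intercept shared by both eyes; ``residual_sd`` the per-eye residual
    SD (mm).  ``vfmd_coupling`` is the VF MD loss in dB per mm of mean
    border-NFL deficit relative to the control baseline;
    ``covariate_effects`` optionally injects linear covariate effects
    (family -> covariate -> slope in mm per covariate unit, covariates
    centred at their control means).
    """

    n_per_stage: dict[str, int] = field(
        default_factory=lambda: {"C": 26, "PG": 16, "EG": 31, "MAG": 12})
    stage_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_STAGE_EFFECTS))
    base_params: PhantomParams = field(default_factory=PhantomParams)
    inter_eye_sd: float = 0.020
    residual_sd: float = 0.015
    covariates: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_COVARIATES))
    eye_jitter_fraction: float = 0.2  # within-participant SD as fraction of population SD
    vfmd_baseline_db: float = -0.4
    vfmd_coupling_db_per_mm: float = 55.0
    vfmd_noise_sd_db: float = 1.2
    missing_eye_prob: float = 0.0
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for st, n in self.n_per_stage.items():
            if st not in STAGES:
                raise CohortSpecError(f"unknown stage {st!r}")
            if n < 0:
                raise CohortSpecError("participant counts must be >= 0")
        if self.inter_eye_sd < 0 or self.residual_sd < 0 or self.vfmd_noise_sd_db < 0:
            raise CohortSpecError("SDs must be >= 0")
        if not 0.0 <= self.missing_eye_prob < 1.0:
            raise CohortSpecError("missing_eye_prob must be in [0, 1)")
        for st, fams in self.stage_effects.items():
            for fam, e in fams.items():
                if fam not in NOISE_FAMILIES:
                    raise CohortSpecError(f"unknown parameter family {fam!r}")
                if not 0.0 <= e < 1.0:
                    raise CohortSpecError("stage effects must be in [0, 1)")


def _shifted_profile(profile: dict[str, float], factor: float, shift: float,
                     floor: float = 0.02) -> dict[str, float]:
    return {r: max(profile[r] * factor + shift, floor) for r in REGIONS}


def _eye_params(spec: CohortSpec, stage: str,
                shifts: dict[str, float]) -> PhantomParams:
    """Phantom anatomy for one eye given stage and additive shifts (mm)."""
    base = spec.base_params
    eff = spec.stage_effects.get(stage, {})
    f_bnfl = 1.0 - eff.get("bnfl", 0.0)
    f_pnfl = 1.0 - eff.get("pnfl", 0.0)
    f_plt = 1.0 - eff.get("plt", 0.0)
    tc = base.prelamina_center_thickness * f_plt + shifts["plt"]
    tc = max(tc, 0.02)
    return replace(
        base,
        rim_height_profile=_shifted_profile(base.rim_height_profile, f_bnfl, shifts["bnfl"], 0.0),
        pnfl_profile=_shifted_profile(base.pnfl_profile, f_pnfl, shifts["pnfl"], 0.0),
        prelamina_thickness_profile=_shifted_profile(
            base.prelamina_thickness_profile, f_plt, shifts["plt"]),
        lc_depth=base.cup_depth + tc,
        prelamina_center_thickness=None,
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None,
                    with_surfaces: bool = False,
                    max_surfaces: int | None = None
                    ) -> tuple[pd.DataFrame, list[SurfaceSet]]:
    """Generate a cohort table (one row per eye) and optional surfaces.

    The table carries participant id, eye, stage, covariates, VF MD, all
    parameter columns (the analytic morphometry of each eye's anatomy,
    which embeds the participant/eye noise), and ``*_true`` columns with
    the noise-free stage-level family means.  Output is a deterministic
    function of (spec, seed).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    control_truth = analytic_truth(_eye_params(spec, "C",
                                               {f: 0.0 for f in NOISE_FAMILIES}))
    stage_truths = {
        st: analytic_truth(_eye_params(spec, st, {f: 0.0 for f in NOISE_FAMILIES}))
        for st in STAGES if spec.n_per_stage.get(st, 0) > 0
    }

    cov_names = list(spec.covariates)
    c_means = {c: spec.covariates[c]["C"][0] for c in cov_names}

    rows: list[dict] = []
    surfaces: list[SurfaceSet] = []
    eye_specs: list[tuple[PhantomParams, int]] = []
    pid = 0
    for stage in STAGES:
        n = spec.n_per_stage.get(stage, 0)
        for _ in range(n):
            pid += 1
            participant = f"P{pid:04d}"
            cov_participant = {
                c: rng.normal(*spec.covariates[c][stage]) for c in cov_names}
            b = {f: rng.normal(0.0, spec.inter_eye_sd) for f in NOISE_FAMILIES}
            eyes = ["OD", "OS"]
            drop_second = rng.random() < spec.missing_eye_prob
            for eye in eyes:
                eps = {f: rng.normal(0.0, spec.residual_sd) for f in NOISE_FAMILIES}
                cov_eye = {}
                for c in cov_names:
                    if c == "age_years":
                        cov_eye[c] = cov_participant[c]
                    else:
                        sd = spec.covariates[c][stage][1] * spec.eye_jitter_fraction
                        cov_eye[c] = rng.normal(cov_participant[c], sd)
                md_noise = rng.normal(0.0, spec.vfmd_noise_sd_db)
                if eye == "OS" and drop_second:
                    continue
                shifts = {}
                for f in NOISE_FAMILIES:
                    s = b[f] + eps[f]
                    for c, slope in spec.covariate_effects.get(f, {}).items():
                        s += slope * (cov_eye[c] - c_means[c])
                    shifts[f] = s
                params = _eye_params(spec, stage, shifts)
                truth = analytic_truth(params)
                deficit = control_truth.bnfl_mean - truth.bnfl_mean
                vfmd = (spec.vfmd_baseline_db
                        - spec.vfmd_coupling_db_per_mm * deficit + md_noise)
                row = {"participant_id": participant, "eye": eye, "stage": stage,
                       **{c: cov_eye[c] for c in cov_names}, "vfmd_db": vfmd}
                row.update(truth.to_series().to_dict())
                st_truth = stage_truths[stage]
                row.update({
                    "bnfl_mean_true": st_truth.bnfl_mean,
                    "pnfl_mean_true": st_truth.pnfl_mean,
                    "mrw_mean_true": st_truth.mrw_mean,
                    "mra_mean_true": st_truth.mra_mean,
                    "plt_centre_true": st_truth.plt["centre"],
                    "plv_true": st_truth.plv,
                })
                rows.append(row)
                # surface seed always drawn: the table is then invariant to
                # whether surfaces are materialised
                surf_seed = int(rng.integers(0, 2 ** 31 - 1))
                eye_specs.append((params, surf_seed))
                if with_surfaces and (max_surfaces is None
                                      or len(surfaces) < max_surfaces):
                    surfaces.append(generate_surfaces(params, seed=surf_seed))

    cols = (["participant_id", "eye", "stage"] + cov_names + ["vfmd_db"]
            + list(PARAMETER_COLUMNS)
            + ["bnfl_mean_true", "pnfl_mean_true", "mrw_mean_true",
               "mra_mean_true", "plt_centre_true", "plv_true"])
    df = pd.DataFrame(rows, columns=cols)
    # per-eye generating anatomy and surface seed, for streaming realisation
    df.attrs["eye_specs"] = eye_specs
    return df, surfaces
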