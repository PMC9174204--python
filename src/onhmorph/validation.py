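"""Oracle, invariant and statistical-recovery checks.

These routines regenerate randomized phantoms/cohorts from scratch and
quantify how well the measurement pipeline reproduces analytic ground
truth and how well the stage analysis recovers injected effects.  They
back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np

from .cohort import CohortSpec, generate_cohort
from .morphometry import extract_radial_sections, fit_bmo_frame, measure_eye, mrw
from .phantom import PhantomParams, analytic_truth, generate_surfaces, rolled_params
from .regions import REGIONS, region_angle, trig_interp_profile
from .stats import StageModel

LENGTH_FAMILIES = ("bnfl", "pnfl", "mrw", "plt")


def random_phantom(rng: np.random.Generator, grid_spacing: float = 0.010,
                   tilt: bool = True, noise_sd: float = 0.0) -> PhantomParams:
    """Randomized smooth ONH phantom within physiological ranges."""
    def profile(lo: float, hi: float) -> dict[str, float]:
        return {r: float(rng.uniform(lo, hi)) for r in REGIONS}

    cup = float(rng.uniform(0.05, 0.30))
    tc = float(rng.uniform(0.25, 0.45))
    return PhantomParams(
        bmo_radius=float(rng.uniform(0.7, 1.1)),
        bmo_plane_tilt=float(rng.uniform(-3.0, 3.0)) if tilt else 0.0,
        rim_height_profile=profile(0.20, 0.40),
        pnfl_profile=profile(0.08, 0.16),
        cup_depth=cup,
        lc_depth=cup + tc,
        prelamina_thickness_profile=profile(0.25, 0.45),
        rim_slope=float(rng.uniform(-0.05, 0.30)),
        surface_noise_sd=noise_sd,
        grid_spacing=grid_spacing,
    )


def geometric_oracle_errors(n_phantoms: int = 20, grid_spacing: float = 0.005,
                            seed: int = 0) -> dict[str, float]:
    """Max |measured - analytic truth| over randomized noise-free phantoms.

    Returns per-family maximum absolute errors in mm and the maximum
    relative prelamina-volume error (fraction).
    """
    rng = np.random.default_rng(seed)
    worst = {f: 0.0 for f in LENGTH_FAMILIES}
    worst["mra_rel"] = 0.0
    worst["plv_rel"] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_phantoms):
            p = random_phantom(rng, grid_spacing=grid_spacing)
            truth = analytic_truth(p)
            meas = measure_eye(generate_surfaces(p, seed=seed + 1000 + i))
            for fam in LENGTH_FAMILIES:
                tv, mv = getattr(truth, fam), getattr(meas, fam)
                worst[fam] = max(worst[fam],
                                 max(abs(mv[k] - tv[k]) for k in tv))
            worst["mra_rel"] = max(worst["mra_rel"], max(
                abs(meas.mra[k] - truth.mra[k]) / truth.mra[k] for k in REGIONS))
            worst["plv_rel"] = max(worst["plv_rel"],
                                   abs(meas.plv - truth.plv) / truth.plv)
    worst["grid_spacing_mm"] = grid_spacing
    worst["n_phantoms"] = n_phantoms
    return worst


def mrw_bruteforce_deviation(n_profiles: int = 50, seed: int = 0,
                             dense_spacing: float = 1e-4) -> dict[str, float]:
    """Section-plane MRW vs dense-sampled minimum over the same ILM curve.

    The oracle evaluates the measured half-meridian's ILM interpolant on
    a 0.1 um lattice and takes the discrete minimum distance; the
    refined search must agree to well under that lattice spacing.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_profiles):
            p = random_phantom(rng, grid_spacing=0.010, tilt=False)
            ss = generate_surfaces(p, seed=seed + 2000 + i)
            frame = fit_bmo_frame(ss.bmo_terminations, eye=ss.eye)
            sections = extract_radial_sections(ss, frame)
            region = REGIONS[i % 8]
            hm = next(sec.halves[region] for sec in sections
                      if region in sec.halves)
            w = mrw(hm)
            sp = hm.spline("ilm")
            rr = hm.r[np.isfinite(hm.curves["ilm"])]
            r_dense = np.arange(rr[0], rr[-1], dense_spacing)
            z_dense = sp(r_dense)
            d = np.sqrt((r_dense - hm.term_r) ** 2 + (z_dense - hm.term_depth) ** 2)
            worst = max(worst, abs(w - float(np.min(d))))
    return {"max_deviation_mm": worst, "n_profiles": n_profiles}


def mra_ring_check() -> dict[str, float]:
    """Axisymmetric rim-area ring against the frustum closed form.

    A flat rim of height 0.25 mm on a 0.8 mm opening sweeps a full ring
    of area 2 pi * 0.8 * 0.25; the regional quadrature at 0.5-degree
    steps must agree with the measured 8-region total within 1%.
    """
    p = PhantomParams(bmo_radius=0.8,
                      rim_height_profile={r: 0.25 for r in REGIONS},
                      cup_depth=0.1, lc_depth=0.45, grid_spacing=0.008)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        meas = measure_eye(generate_surfaces(p, seed=0))
    total = 8.0 * meas.mra_mean
    closed_form = 2.0 * math.pi * 0.8 * 0.25

    # fine-angle quadrature of the swept frustum from generating functions
    theta = np.deg2rad(np.arange(0.0, 360.0, 0.5))
    h = trig_interp_profile(p.rim_height_profile, theta)
    w = h / math.sqrt(1.0 + p.rim_slope ** 2)
    d_mid = p.bmo_radius + 0.0 * theta  # flat rim: foot at the opening edge
    quad = float(np.trapezoid(np.append(d_mid * w, d_mid[0] * w[0]),
                              dx=np.deg2rad(0.5)))
    return {"total_mm2": total, "closed_form_mm2": closed_form,
            "quadrature_mm2": quad,
            "rel_err_vs_closed_form": abs(total - closed_form) / closed_form,
            "rel_err_vs_quadrature": abs(total - quad) / quad}


def invariant_suite(n_phantoms: int = 1000, seed: int = 0,
                    n_rotation_checks: int = 12) -> dict[str, float]:
    """Structural invariants over randomized (including noisy) phantoms.

    Checks, per phantom: mrw <= border NFL in every region; prelamina
    volume >= 0; and, on a subset, that rotating the anatomy by 45
    degrees permutes the regional outputs accordingly.
    """
    rng = np.random.default_rng(seed)
    violations_mrw = 0
    violations_vol = 0
    rotation_dev = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_phantoms):
            noise = float(rng.uniform(0.0, 0.015)) if i % 2 else 0.0
            p = random_phantom(rng, grid_spacing=0.020,
                               tilt=bool(i % 4 == 1), noise_sd=noise)
            meas = measure_eye(generate_surfaces(p, seed=seed + 3000 + i),
                               volume_n_r=80, volume_n_theta=96)
            for k in REGIONS:
                if meas.mrw[k] > meas.bnfl[k] + 1e-9:
                    violations_mrw += 1
            if meas.plv < 0:
                violations_vol += 1
            if i < n_rotation_checks and noise == 0.0:
                rolled = rolled_params(p, k=1)
                meas_r = measure_eye(generate_surfaces(rolled, seed=seed + 3000 + i),
                                     volume_n_r=80, volume_n_theta=96)
                # rotating the anatomy one sector anticlockwise moves the
                # value measured at angle k*45 to angle (k+1)*45
                for fam in ("bnfl", "pnfl", "mrw"):
                    mv, rv = getattr(meas, fam), getattr(meas_r, fam)
                    for reg in REGIONS:
                        th = region_angle(reg) + math.pi / 4.0
                        reg2 = next(r2 for r2 in REGIONS
                                    if math.isclose(region_angle(r2) % (2 * math.pi),
                                                    th % (2 * math.pi), abs_tol=1e-9))
                        rotation_dev = max(rotation_dev, abs(rv[reg2] - mv[reg]))
    return {"mrw_le_bnfl_violations": violations_mrw,
            "negative_volume_count": violations_vol,
            "rotation_relabel_max_dev_mm": rotation_dev,
            "n_phantoms": n_phantoms}


# ---------------------------------------------------------------------------
# statistical recovery
# ---------------------------------------------------------------------------

_NULL_EFFECTS = {s: {f: 0.0 for f in ("bnfl", "pnfl", "plt")}
                 for s in ("C", "PG", "EG", "MAG")}


def _balanced_spec(**kwargs) -> CohortSpec:
    base = dict(n_per_stage={"C": 15, "PG": 15, "EG": 15, "MAG": 15},
                inter_eye_sd=0.020, residual_sd=0.015)
    base.update(kwargs)
    return CohortSpec(**base)


def null_tukey_rates(n_reps: int = 500, seed: int = 0,
                     check_covariate: str = "cct_um") -> dict[str, float]:
    """Type-I behaviour under a stage-null generator with inter-eye correlation.

    Returns the familywise (any of 6 Tukey contrasts) rejection rate,
    the Tukey-adjusted and unadjusted C-vs-PG rates, and the stepwise
    retention rate of a zero-effect covariate (shared replicates).
    """
    rng = np.random.default_rng(seed)
    fam = cpg_adj = cpg_unadj = retained = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            spec = _balanced_spec(stage_effects=_NULL_EFFECTS)
            df, _ = generate_cohort(spec, seed=int(rng.integers(2 ** 31)))
            res = StageModel(df, "bnfl_mean", candidates=()).fit(stepwise=False)
            fam += bool((res.pairwise["p_tukey"] < 0.05).any())
            row = res.pairwise.loc[res.pairwise["contrast"] == "C - PG"].iloc[0]
            cpg_adj += bool(row["p_tukey"] < 0.05)
            cpg_unadj += bool(row["p_unadj"] < 0.05)
            res2 = StageModel(df, "bnfl_mean",
                              candidates=(check_covariate,)).fit(stepwise=True)
            retained += check_covariate in res2.retained_fixed
    return {"familywise_rate": fam / n_reps,
            "c_vs_pg_adjusted_rate": cpg_adj / n_reps,
            "c_vs_pg_unadjusted_rate": cpg_unadj / n_reps,
            "null_covariate_retention_rate": retained / n_reps,
            "n_reps": n_reps}


def eg_effect_recovery(n_reps: int = 300, seed: int = 0,
                       thinning: float = 0.15) -> dict[str, float]:
    """Bias and power for an injected border-NFL thinning in the EG group."""
    effects = {s: {f: 0.0 for f in ("bnfl", "pnfl", "plt")}
               for s in ("C", "PG", "EG", "MAG")}
    effects["EG"]["bnfl"] = thinning
    base_truth = analytic_truth(PhantomParams())
    true_diff = thinning * base_truth.bnfl_mean
    rng = np.random.default_rng(seed)
    ests, rejects = [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            spec = _balanced_spec(stage_effects=effects)
            df, _ = generate_cohort(spec, seed=int(rng.integers(2 ** 31)))
            res = StageModel(df, "bnfl_mean", candidates=()).fit(stepwise=False)
            row = res.pairwise.loc[res.pairwise["contrast"] == "C - EG"].iloc[0]
            ests.append(float(row["estimate"]))
            rejects += bool(row["p_tukey"] < 0.05)
    mean_est = float(np.mean(ests))
    return {"true_diff_mm": true_diff, "mean_estimate_mm": mean_est,
            "bias_fraction": (mean_est - true_diff) / true_diff,
            "power": rejects / n_reps, "n_reps": n_reps,
            "eyes_per_group": 30}


def covariate_power(n_reps: int = 200, seed: int = 0,
                    covariate: str = "cct_um") -> dict[str, float]:
    """Stepwise retention rate for a standardized-slope-1 covariate."""
    response_sd = math.hypot(0.020, 0.015)
    cov_sd = 40.0  # pooled central corneal thickness SD, um
    slope = response_sd / cov_sd
    rng = np.random.default_rng(seed)
    retained = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            spec = _balanced_spec(stage_effects=_NULL_EFFECTS,
                                  covariate_effects={"bnfl": {covariate: slope}})
            df, _ = generate_cohort(spec, seed=int(rng.integers(2 ** 31)))
            res = StageModel(df, "bnfl_mean", candidates=(covariate,)).fit()
            retained += covariate in res.retained_fixed
    return {"retention_rate": retained / n_reps, "n_reps": n_reps,
            "standardized_slope": 1.0}


def determinism_check(tmpdir, seed: int = 0) -> dict[str, float]:
    """Same config + seed twice must yield byte-identical manifest hashes."""
    import json
    from pathlib import Path

    from .io import PipelineConfig
    from .pipeline import run_pipeline

    tmpdir = Path(tmpdir)
    cfg = PipelineConfig(seed=seed)
    cfg.cohort = _balanced_spec(n_per_stage={"C": 3, "PG": 3, "EG": 3, "MAG": 3},
                                base_params=PhantomParams(grid_spacing=0.02))
    manifests = []
    for run_id in ("a", "b"):
        out = tmpdir / f"run_{run_id}"
        res = run_pipeline(cfg, outdir=out)
        manifests.append(json.loads(Path(res["manifest"]).read_text()))
    return {"identical": float(manifests[0] == manifests[1]),
            "n_files": len(manifests[0])}


def quick_selftest() -> list[str]:
    """Small, fast subset of the oracle checks for the CLI selftest verb."""
    failures = []
    g = geometric_oracle_errors(n_phantoms=3, grid_spacing=0.010, seed=0)
    for fam in LENGTH_FAMILIES:
        if g[fam] > 2 * 0.010:
            failures.append(f"{fam} error {g[fam]:.2e} mm exceeds 2x grid spacing")
    if g["plv_rel"] > 0.01:
        failures.append(f"prelamina volume error {g['plv_rel']:.2%} exceeds 1%")
    ring = mra_ring_check()
    if ring["rel_err_vs_closed_form"] > 0.01:
        failures.append("MRA ring deviates >1% from the frustum closed form")
    inv = invariant_suite(n_phantoms=20, seed=0, n_rotation_checks=2)
    if inv["mrw_le_bnfl_violations"] or inv["negative_volume_count"]:
        failures.append("structural invariant violated")
    return failures
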