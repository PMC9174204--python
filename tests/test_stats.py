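"""Mixed-effects stage analysis: recovery, contrasts, correlations, screens."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from onhmorph.cohort import NOISE_FAMILIES, STAGES, CohortSpec, generate_cohort
from onhmorph.stats import (DEFAULT_CANDIDATES, ModelSpec, StageModel,
                            analyze_cohort, contrasts_table, fit_lmm,
                            normality_screen, stepwise_select, structure_function)

NULL_EFFECTS = {s: {f: 0.0 for f in NOISE_FAMILIES} for s in STAGES}


def _cohort(seed=0, **kwargs):
    base = dict(n_per_stage={"C": 15, "PG": 15, "EG": 15, "MAG": 15})
    base.update(kwargs)
    df, _ = generate_cohort(CohortSpec(**base), seed=seed)
    return df


def test_variance_components_recovered():
    """sigma_b = 0.05, sigma_e = 0.01: estimates within 25% of truth (n=60)."""
    ests_b, ests_e = [], []
    for seed in range(5):
        df = _cohort(seed=seed, inter_eye_sd=0.05, residual_sd=0.01,
                     stage_effects=NULL_EFFECTS)
        res = StageModel(df, "bnfl_mean", candidates=()).fit(stepwise=False)
        ests_b.append(res.variance_components["participant"])
        ests_e.append(res.variance_components["residual"])
    assert np.mean(ests_b) == pytest.approx(0.05 ** 2, rel=0.25)
    assert np.mean(ests_e) == pytest.approx(0.01 ** 2, rel=0.25)


def test_zero_between_participant_variance_flags_singular():
    df = _cohort(seed=1, inter_eye_sd=0.0, residual_sd=0.015,
                 stage_effects=NULL_EFFECTS)
    res = StageModel(df, "bnfl_mean", candidates=()).fit(stepwise=False)
    assert res.variance_components["participant"] < 1e-5
    assert res.singular


def test_single_eye_cohort_still_fits_with_flag():
    df = _cohort(seed=2)
    df = df[df.eye == "OD"]
    with pytest.warns(UserWarning, match="one eye"):
        res = StageModel(df, "bnfl_mean", candidates=()).fit(stepwise=False)
    assert res.n_obs == df.shape[0]
    assert res.singular


def test_stepwise_without_candidates_is_identity():
    df = _cohort(seed=3)
    res = StageModel(df, "bnfl_mean", candidates=()).fit(stepwise=True)
    assert res.retained_fixed == []
    assert len(res.pairwise) == 6  # C(4,2) contrasts


def test_adjusted_p_never_below_unadjusted():
    for seed in (4, 5, 6):
        res = StageModel(_cohort(seed=seed), "bnfl_mean").fit()
        assert (res.pairwise["p_tukey"] >= res.pairwise["p_unadj"] - 1e-15).all()


def test_null_contrast_estimate_near_zero():
    """Stages constructed identical: C-PG contrast is noise around zero."""
    res = StageModel(_cohort(seed=7, stage_effects=NULL_EFFECTS), "bnfl_mean",
                     candidates=()).fit(stepwise=False)
    row = res.pairwise.loc[res.pairwise.contrast == "C - PG"].iloc[0]
    assert abs(row["estimate"]) < 4 * row["se"]


def test_injected_ordering_recovered_in_contrast_signs():
    """MAG < EG < PG < C thinning: all 6 contrast signs follow the ordering."""
    res = StageModel(_cohort(seed=8), "bnfl_mean", candidates=()).fit(stepwise=False)
    signs = dict(zip(res.pairwise["contrast"], np.sign(res.pairwise["estimate"])))
    assert all(v > 0 for v in signs.values())  # earlier stage minus later > 0


def test_results_invariant_to_row_order():
    df = _cohort(seed=9)
    res1 = StageModel(df, "bnfl_mean").fit()
    res2 = StageModel(df.sample(frac=1.0, random_state=0), "bnfl_mean").fit()
    pd.testing.assert_frame_equal(res1.emmeans, res2.emmeans, atol=1e-8)
    assert res1.retained_fixed == res2.retained_fixed


def test_structure_function_identity_and_sign():
    df = _cohort(seed=10)
    r, p = structure_function(df, "vfmd_db")
    assert r == pytest.approx(1.0)
    # positive coupling: thinner parameter accompanies more negative MD
    r2, p2 = structure_function(df, "bnfl_mean")
    assert r2 > 0.5 and p2 < 1e-6


def test_structure_function_null_noise_small_r(rng):
    hits = 0
    for _ in range(100):
        df = pd.DataFrame({"x": rng.normal(size=100), "vfmd_db": rng.normal(size=100)})
        r, _ = structure_function(df, "x")
        hits += abs(r) < 0.2
    assert hits >= 95


def test_structure_function_degenerate_inputs():
    df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "vfmd_db": [0.1, 0.2, 0.3]})
    with pytest.raises(ValueError, match="zero variance"):
        structure_function(df, "x")
    with pytest.raises(ValueError, match="3 complete"):
        structure_function(df.iloc[:2], "x")


def test_normality_screen_power_and_errors(rng):
    rejections = sum(normality_screen(rng.exponential(size=200)) < 0.05
                     for _ in range(50))
    assert rejections >= 49
    with pytest.raises(ValueError):
        normality_screen(np.ones(100))
    with pytest.raises(ValueError):
        normality_screen(np.arange(2))
    with pytest.raises(ValueError):
        normality_screen(rng.normal(size=6000))


def test_spec_surface_wrappers():
    df = _cohort(seed=11)
    spec = ModelSpec(response="bnfl_mean", candidate_fixed=("age_years",))
    full = fit_lmm(df, spec)
    assert "age_years" in full.coef_table.index
    reduced = stepwise_select(df, spec)
    assert set(reduced.retained_fixed) <= {"age_years"}
    analyses = analyze_cohort(df, ["bnfl_mean", "plv"], candidates=())
    flat = contrasts_table(analyses)
    assert set(flat["parameter"]) == {"bnfl_mean", "plv"}
    assert len(flat) == 12


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(response="x", alpha_retain=0.0)
    with pytest.raises(KeyError):
        StageModel(pd.DataFrame({"stage": [], "participant_id": []}), "missing")


def test_mixed_model_agrees_with_lme4_emmeans(tmp_path):
    """Independent oracle: lme4 REML fit and emmeans on the same cohort."""
    rscript = shutil.which("Rscript")
    assert rscript, "Rscript expected on PATH in this environment"
    df = _cohort(seed=12)
    csv = tmp_path / "cohort.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(f"""
suppressMessages({{library(lme4); library(emmeans); library(jsonlite)}})
d <- read.csv("{csv}")
d$stage <- factor(d$stage, levels=c("C","PG","EG","MAG"))
fit <- lmer(bnfl_mean ~ stage + age_years + (1|participant_id), data=d, REML=TRUE)
emm <- summary(emmeans(fit, "stage"))
vc <- as.data.frame(VarCorr(fit))
cat(toJSON(list(
  emmean=emm$emmean, se=emm$SE,
  sigma_b2=vc$vcov[1], sigma_e2=vc$vcov[2],
  contrast=as.data.frame(pairs(emmeans(fit, "stage")))$estimate
), digits=12))
""")
    out = subprocess.run([rscript, "--vanilla", str(script)],
                         capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    oracle = json.loads(out.stdout)

    res = StageModel(df, "bnfl_mean", candidates=("age_years",)).fit(stepwise=False)
    np.testing.assert_allclose(res.emmeans["emmean"], oracle["emmean"], atol=5e-5)
    np.testing.assert_allclose(res.emmeans["se"], oracle["se"], rtol=0.02)
    np.testing.assert_allclose(res.pairwise["estimate"],
                               np.array(oracle["contrast"]), atol=1e-4)
    assert res.variance_components["participant"] == pytest.approx(
        oracle["sigma_b2"][0], rel=0.05)
    assert res.variance_components["residual"] == pytest.approx(
        oracle["sigma_e2"][0], rel=0.05)


def test_summary_renders(capsys):
    res = StageModel(_cohort(seed=13), "bnfl_mean", candidates=("age_years",)).fit()
    text = res.summary()
    assert "Tukey-adjusted" in text and "Pearson" in text
    d = res.to_dict()
    json.dumps(d)  # JSON-serialisable
    assert d["response"] == "bnfl_mean"
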