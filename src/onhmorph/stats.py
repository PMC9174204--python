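"""Mixed-effects disease-stage analysis of ONH parameters.

For each parameter (e.g. mean border NFL) a linear mixed-effects model
with a participant random intercept accounts for the inter-eye
correlation of fellow eyes:

    y_ij = X_ij beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma^2)

Candidate fixed effects (age, stage, axial eye length, anterior chamber
depth, refractive error, central corneal thickness, intraocular
pressure) are reduced by backward stepwise deletion: repeatedly drop
the non-stage covariate with the largest p >= alpha, refit, until all
retained covariates have p < alpha.  Stage is the inference target and
is never dropped.  Stage groups are then compared through estimated
marginal means (model-adjusted means at covariate means) with
Tukey-adjusted (studentized-range) pairwise p-values.  Structure to
function association is the pooled-eyes Pearson correlation with
visual-field mean deviation; Shapiro-Wilk screens residual normality
(advisory, never gating).

Wald tests use containment-style denominator degrees of freedom
(participants minus fixed-effect rank), appropriate for the
participant-level covariates and stage factor used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

import statsmodels.formula.api as smf

DEFAULT_STAGE_ORDER = ("C", "PG", "EG", "MAG")
DEFAULT_CANDIDATES = ("age_years", "ael_mm", "acd_mm", "ms_d", "cct_um", "iop_mmhg")


class ModelFitError(RuntimeError):
    """Mixed-model fit failed to converge; carries optimizer diagnostics."""


@dataclass
class ModelSpec:
    """Response, candidate fixed effects and retention threshold."""

    response: str
    candidate_fixed: tuple[str, ...] = DEFAULT_CANDIDATES
    alpha_retain: float = 0.05
    stage_col: str = "stage"
    group_col: str = "participant_id"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_retain < 1.0:
            raise ValueError("alpha_retain must be in (0, 1)")


def _stage_term(spec: ModelSpec, order: tuple[str, ...]) -> str:
    levels = ", ".join(repr(s) for s in order)
    return f"C({spec.stage_col}, levels=[{levels}])"


def _fit_mixedlm(data: pd.DataFrame, spec: ModelSpec, covariates: list[str],
                 order: tuple[str, ...], reml: bool = True):
    rhs = " + ".join([_stage_term(spec, order)] + covariates) or "1"
    formula = f"{spec.response} ~ {rhs}"
    model = smf.mixedlm(formula, data, groups=data[spec.group_col])
    last_exc: Exception | None = None
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "nm"):
            try:
                res = (model.fit(reml=reml) if method is None
                       else model.fit(reml=reml, method=method))
            except Exception as exc:
                last_exc = exc
                continue
            if res.converged:
                return res
    if res is None:
        raise ModelFitError(
            f"mixed-model fit failed for {formula}: {last_exc}") from last_exc
    raise ModelFitError(
        f"mixed-model fit did not converge for {formula}; "
        f"final optimizer diagnostics: {getattr(res, 'mle_retvals', None)!r}")


def _containment_df(res, data: pd.DataFrame, group_col: str) -> float:
    n_groups = data[group_col].nunique()
    return max(float(n_groups - res.k_fe), 1.0)


def _fixed_effect_pvalues(res, df_denom: float) -> pd.Series:
    t = res.fe_params / res.bse_fe
    return pd.Series(2.0 * sps.t.sf(np.abs(t), df_denom), index=res.fe_params.index)


@dataclass
class StageResults:
    """Fitted stage analysis for one parameter.

    Attributes mirror what a reader of the analysis needs: the retained
    covariates, the coefficient table, estimated marginal means per
    stage, Tukey-adjusted pairwise contrasts, the pooled-eyes Pearson
    correlation with VF MD, and the Shapiro-Wilk residual normality p.
    """

    response: str
    retained_fixed: list[str]
    coef_table: pd.DataFrame
    emmeans: pd.DataFrame
    pairwise: pd.DataFrame
    pearson_r: float
    pearson_p: float
    shapiro_p: float
    singular: bool
    df_denom: float
    n_obs: int
    n_participants: int
    variance_components: dict[str, float] = field(default_factory=dict)
    _result: object = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"Stage analysis: {self.response}",
            "=" * 60,
            f"eyes: {self.n_obs}   participants: {self.n_participants}   "
            f"denominator df: {self.df_denom:.0f}",
            f"variance components: participant {self.variance_components.get('participant', float('nan')):.3e}, "
            f"residual {self.variance_components.get('residual', float('nan')):.3e}"
            + ("   [singular fit]" if self.singular else ""),
            f"retained covariates: {', '.join(self.retained_fixed) or '(none)'}",
            "",
            "Fixed effects",
            self.coef_table.to_string(float_format=lambda v: f"{v: .4g}"),
            "",
            "Estimated marginal means (at covariate means)",
            self.emmeans.to_string(index=False, float_format=lambda v: f"{v: .4g}"),
            "",
            "Tukey-adjusted pairwise stage contrasts",
            self.pairwise.to_string(index=False, float_format=lambda v: f"{v: .4g}"),
            "",
            f"Pearson r vs VF MD: {self.pearson_r:.3f} (p = {self.pearson_p:.3g})",
            f"Shapiro-Wilk residual normality p: {self.shapiro_p:.3g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "retained_fixed": list(self.retained_fixed),
            "coefficients": self.coef_table.reset_index()
                                .rename(columns={"index": "term"})
                                .to_dict(orient="records"),
            "emmeans": self.emmeans.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "pearson": {"r": self.pearson_r, "p": self.pearson_p},
            "shapiro_p": self.shapiro_p,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "variance_components": self.variance_components,
        }


class StageModel:
    """Mixed-effects stage model for one ONH parameter.

    Parameters
    ----------
    data : DataFrame
        One row per eye; must contain the response, stage, participant
        id and any candidate covariates.
    response : str
        Parameter column to model.
    candidates : sequence of str
        Candidate fixed-effect covariates subject to stepwise deletion.
    stage_order : sequence of str
        Stage levels in increasing-severity order; levels absent from
        the data are dropped.
    vfmd_col : str
        Column used for the structure-function Pearson correlation.
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
                 stage_col: str = "stage", group_col: str = "participant_id",
                 stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER,
                 vfmd_col: str = "vfmd_db", alpha_retain: float = 0.05):
        if response not in data.columns:
            raise KeyError(f"response column {response!r} not in data")
        candidates = tuple(c for c in candidates if c in data.columns)
        self.spec = ModelSpec(response=response, candidate_fixed=candidates,
                              alpha_retain=alpha_retain, stage_col=stage_col,
                              group_col=group_col)
        keep = [response, stage_col, group_col, *candidates]
        if vfmd_col in data.columns:
            keep.append(vfmd_col)
        self.data = data[list(dict.fromkeys(keep))].dropna(subset=[response]).copy()
        self.stage_order = tuple(s for s in stage_order
                                 if s in set(self.data[stage_col]))
        if len(self.stage_order) < 2:
            raise ValueError("need at least two stage groups with data")
        self.vfmd_col = vfmd_col
        n_two_eyed = (self.data.groupby(group_col)[response].count() >= 2).sum()
        if self.data[group_col].nunique() < 2:
            raise ValueError("need at least 2 participants")
        self.single_eye_only = n_two_eyed == 0

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kwargs) -> "StageModel":
        return cls(data, response, **kwargs)

    # -- fitting ---------------------------------------------------------

    def fit(self, stepwise: bool = True, reml: bool = True) -> StageResults:
        spec, data, order = self.spec, self.data, self.stage_order
        covariates = list(spec.candidate_fixed)
        res = _fit_mixedlm(data, spec, covariates, order, reml=reml)
        if stepwise:
            covariates, res = self._backward_delete(res, covariates)
        df_denom = _containment_df(res, data, spec.group_col)
        pvals = _fixed_effect_pvalues(res, df_denom)
        coef = pd.DataFrame({
            "estimate": res.fe_params,
            "se": res.bse_fe,
            "t": res.fe_params / res.bse_fe,
            "p": pvals,
        })
        sigma_b2 = float(np.asarray(res.cov_re).ravel()[0])
        sigma_e2 = float(res.scale)
        # random-intercept variance collapsed to (numerically) zero
        singular = sigma_b2 < 1e-4 * max(sigma_e2, 1e-300) or self.single_eye_only
        if self.single_eye_only:
            warnings.warn("one eye per participant: random-intercept variance "
                          "is not identified", stacklevel=2)

        emmeans = self._emmeans(res, covariates, df_denom)
        pairwise = self._tukey(emmeans, res, covariates, df_denom)
        pearson_r, pearson_p = self.structure_function()
        shapiro_p = normality_screen(np.asarray(res.resid))

        return StageResults(
            response=spec.response, retained_fixed=covariates,
            coef_table=coef, emmeans=emmeans, pairwise=pairwise,
            pearson_r=pearson_r, pearson_p=pearson_p, shapiro_p=shapiro_p,
            singular=bool(singular), df_denom=df_denom,
            n_obs=int(res.nobs), n_participants=int(data[spec.group_col].nunique()),
            variance_components={"participant": sigma_b2, "residual": sigma_e2},
            _result=res)

    def _backward_delete(self, res, covariates: list[str]):
        spec, data, order = self.spec, self.data, self.stage_order
        while covariates:
            df_denom = _containment_df(res, data, spec.group_col)
            pvals = _fixed_effect_pvalues(res, df_denom)
            cov_p = {c: float(pvals[c]) for c in covariates}
            worst = max(cov_p, key=cov_p.get)
            if cov_p[worst] < spec.alpha_retain:
                break
            covariates = [c for c in covariates if c != worst]
            res = _fit_mixedlm(data, spec, covariates, order)
        return covariates, res

    # -- inference on stages ---------------------------------------------

    def _design_rows(self, res, covariates: list[str]) -> pd.DataFrame:
        """One prediction row per stage, covariates at their sample means."""
        from patsy import build_design_matrices

        base = {c: [float(self.data[c].mean())] for c in covariates}
        rows = []
        for stage in self.stage_order:
            d = dict(base)
            d[self.spec.stage_col] = [stage]
            (X,) = build_design_matrices(
                [res.model.data.design_info], pd.DataFrame(d))
            rows.append(np.asarray(X)[0])
        return pd.DataFrame(rows, index=list(self.stage_order),
                            columns=res.fe_params.index)

    def _emmeans(self, res, covariates: list[str], df_denom: float) -> pd.DataFrame:
        X = self._design_rows(res, covariates)
        beta = res.fe_params.values
        cov = np.asarray(res.cov_params())[:len(beta), :len(beta)]
        est = X.values @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X.values, cov, X.values))
        tcrit = sps.t.ppf(0.975, df_denom)
        return pd.DataFrame({
            "stage": list(self.stage_order),
            "emmean": est, "se": se,
            "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
        })

    def _tukey(self, emmeans: pd.DataFrame, res, covariates: list[str],
               df_denom: float) -> pd.DataFrame:
        X = self._design_rows(res, covariates)
        beta = res.fe_params.values
        cov = np.asarray(res.cov_params())[:len(beta), :len(beta)]
        k = len(self.stage_order)
        rows = []
        for a, b in combinations(range(k), 2):
            c = X.values[a] - X.values[b]
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else np.nan
            p_unadj = float(2.0 * sps.t.sf(abs(t), df_denom))
            p_tukey = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_denom))
            rows.append({
                "contrast": f"{self.stage_order[a]} - {self.stage_order[b]}",
                "estimate": est, "se": se, "t": t,
                "p_unadj": p_unadj, "p_tukey": min(max(p_tukey, p_unadj), 1.0),
            })
        return pd.DataFrame(rows)

    # -- auxiliary analyses ----------------------------------------------

    def structure_function(self) -> tuple[float, float]:
        """Pooled-eyes Pearson correlation of the parameter with VF MD."""
        if self.vfmd_col not in self.data.columns:
            return float("nan"), float("nan")
        return structure_function(self.data, self.spec.response,
                                  vfmd_col=self.vfmd_col)


def normality_screen(residuals: np.ndarray) -> float:
    """Shapiro-Wilk normality p-value (advisory only).

    Requires 3 <= n <= 5000 and non-degenerate data.
    """
    x = np.asarray(residuals, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


# -- spec-surface convenience wrappers -------------------------------------

def fit_lmm(cohort: pd.DataFrame, spec: ModelSpec,
            stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER) -> StageResults:
    """REML mixed-model fit without stepwise deletion."""
    m = StageModel(cohort, spec.response, candidates=spec.candidate_fixed,
                   stage_col=spec.stage_col, group_col=spec.group_col,
                   stage_order=stage_order, alpha_retain=spec.alpha_retain)
    return m.fit(stepwise=False)


def stepwise_select(cohort: pd.DataFrame, spec: ModelSpec,
                    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER) -> StageResults:
    """Backward deletion of non-stage covariates; stage is never dropped."""
    m = StageModel(cohort, spec.response, candidates=spec.candidate_fixed,
                   stage_col=spec.stage_col, group_col=spec.group_col,
                   stage_order=stage_order, alpha_retain=spec.alpha_retain)
    return m.fit(stepwise=True)


def tukey_stage_contrasts(results: StageResults) -> pd.DataFrame:
    """Tukey-adjusted pairwise stage contrast table of a fitted analysis."""
    return results.pairwise


def structure_function(cohort: pd.DataFrame, parameter: str,
                       vfmd_col: str = "vfmd_db") -> tuple[float, float]:
    """Pooled-eyes Pearson correlation (r, p) of a parameter with VF MD."""
    x = np.asarray(cohort[parameter], dtype=float)
    y = np.asarray(cohort[vfmd_col], dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs for Pearson r")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def analyze_cohort(cohort: pd.DataFrame, responses: list[str],
                   **model_kwargs) -> dict[str, StageResults]:
    """Run the full per-parameter stage analysis for several responses."""
    return {resp: StageModel(cohort, resp, **model_kwargs).fit()
            for resp in responses}


def contrasts_table(analyses: dict[str, StageResults]) -> pd.DataFrame:
    """Flat table of all pairwise contrasts across analysed parameters."""
    frames = []
    for resp, res in analyses.items():
        t = res.pairwise.copy()
        t.insert(0, "parameter", resp)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
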