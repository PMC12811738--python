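"""Covariate-structured linear mixed models for the seven cardiovascular outcomes.

Each outcome (HR, ln LF-HRV, ln HF-HRV, PTTv, MAP, ln LF-BPV, ln HF-BPV)
is modelled with task, sex and their interaction as fixed effects, an
outcome-specific covariate set entered as main effects, and a random
intercept per subject (REML).  The covariate structure isolates each
index: the HR model controls for PWV (vascular drive) and RSA
(respiratory drive); each band-power model controls for RSA and the
opposite band; PTTv controls for HR; MAP controls for PWV and HR (an
alternate HR + PTTv set is selectable).

Pairwise task contrasts are computed regardless of omnibus significance
(uncorrected p, by design: the interest is in graded dose-response
patterns), as marginal means averaged equally over the sexes; sex x task
contrasts are differences-in-change (male change minus female change).
F tests use residual denominator degrees of freedom (n_obs minus fixed
effect rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .influence import DEFAULT_RULES, flag_influential, influence_measures
from .protocol import BASELINE, LONG, SHORT, TASK_LABELS

OUTCOMES = ["hr", "ln_lf_hrv", "ln_hf_hrv", "pttv", "map", "ln_lf_bpv", "ln_hf_bpv"]

MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "hr": ("pwv", "rsa"),
    "ln_lf_hrv": ("rsa", "ln_hf_hrv"),
    "ln_hf_hrv": ("rsa", "ln_lf_hrv"),
    "pttv": ("hr",),
    "map": ("pwv", "hr"),
    "ln_lf_bpv": ("rsa", "ln_hf_bpv"),
    "ln_hf_bpv": ("rsa", "ln_lf_bpv"),
}

# the sources of the paper trail disagree on the MAP covariates; both sets
# are selectable and neither is asserted as the canonical one
MAP_COVARIATE_VARIANTS = {"pwv_hr": ("pwv", "hr"), "hr_pttv": ("hr", "pttv")}

TASK_PAIRS = [(BASELINE, LONG), (BASELINE, SHORT), (LONG, SHORT)]
_SHORT_LABEL = {BASELINE: "BL", LONG: "long", SHORT: "short"}


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    covariates: tuple[str, ...]
    reference_task: str = BASELINE

    @classmethod
    def for_outcome(cls, outcome: str, map_covariates: str = "pwv_hr") -> "ModelSpec":
        if outcome == "map":
            covs = MAP_COVARIATE_VARIANTS[map_covariates]
        else:
            covs = MODEL_COVARIATES[outcome]
        return cls(outcome=outcome, covariates=covs)

    @property
    def formula(self) -> str:
        rhs = f"C(task, Treatment('{self.reference_task}')) * C(sex)"
        for c in self.covariates:
            rhs += f" + {c}"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    t: float
    p: float
    df: float


@dataclass
class ModelFit:
    spec: ModelSpec
    result: object  # statsmodels MixedLMResults
    data: pd.DataFrame
    f_tests: dict
    n_obs: int
    n_subjects: int
    df_resid: float

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def cov_fe(self) -> np.ndarray:
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]

    @property
    def variance_ratio(self) -> float:
        """Random-intercept to residual variance ratio (gamma)."""
        tau2 = float(np.asarray(self.result.cov_re)[0, 0])
        return max(tau2 / float(self.result.scale), 0.0)


def build_long_table(summary_rows: pd.DataFrame) -> pd.DataFrame:
    """Validate and order the subject x task long table for modelling."""
    if summary_rows is None or len(summary_rows) == 0:
        raise ValueError("empty summary table")
    table = summary_rows.copy()
    required = {"subject", "sex", "task"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    bad = set(table["task"].unique()) - set(TASK_LABELS)
    if bad:
        raise ValueError(f"unknown task labels: {sorted(bad)}")
    table["task"] = pd.Categorical(table["task"], categories=TASK_LABELS, ordered=True)
    n_tasks = table.groupby("subject", observed=True)["task"].count()
    empty = n_tasks[n_tasks == 0].index
    if len(empty):
        warnings.warn(f"dropping {len(empty)} subject(s) with no task rows")
        table = table[~table["subject"].isin(empty)]
    return table.sort_values(["subject", "task"], ignore_index=True)


def _design(fit_data: pd.DataFrame, spec: ModelSpec):
    import patsy

    return patsy.dmatrices(spec.formula, fit_data, return_type="dataframe")


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML random-intercept fit of one outcome with its covariate set.

    Raises on rank-deficient designs (including a covariate identical to
    the outcome).  Singular fits (zero between-subject variance) are
    handled by statsmodels' boundary estimate and reported with a warning.
    """
    cols = ["subject", "sex", "task", spec.outcome, *spec.covariates]
    data = table.dropna(subset=[spec.outcome, *spec.covariates])[cols].copy()
    n_dropped = len(table) - len(data)
    if n_dropped:
        warnings.warn(f"{spec.outcome}: dropped {n_dropped} row(s) with missing values")
    for c in spec.covariates:
        if np.allclose(data[c].to_numpy(float), data[spec.outcome].to_numpy(float)):
            raise ValueError(f"covariate {c!r} is identical to outcome {spec.outcome!r}")
    counts = data.groupby("subject", observed=True).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 subjects with at least 2 tasks each")

    y_df, X_df = _design(data, spec)
    X = X_df.to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effects design")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            spec.formula, data=data, groups=data["subject"].to_numpy()
        )
        result = model.fit(reml=True)
    tau2 = float(np.asarray(result.cov_re)[0, 0])
    if tau2 < 1e-10 * float(result.scale):
        warnings.warn(
            f"{spec.outcome}: between-subject variance estimated at the zero "
            "boundary; random intercept is effectively absent"
        )

    n_obs = len(data)
    p = X.shape[1]
    df_resid = float(n_obs - p)
    fit = ModelFit(
        spec=spec,
        result=result,
        data=data,
        f_tests={},
        n_obs=n_obs,
        n_subjects=data["subject"].nunique(),
        df_resid=df_resid,
    )
    fit.f_tests = {term: _wald_f(fit, term) for term in ("task", "sex", "task:sex")}
    return fit


def _term_indices(fit: ModelFit, term: str) -> list[int]:
    names = list(fit.fe_params.index)
    out = []
    for i, name in enumerate(names):
        has_task = "C(task" in name
        has_sex = "C(sex" in name
        inter = ":" in name
        if term == "task" and has_task and not inter:
            out.append(i)
        elif term == "sex" and has_sex and not inter:
            out.append(i)
        elif term == "task:sex" and has_task and has_sex and inter:
            out.append(i)
    if not out:
        raise KeyError(f"no fixed-effect terms for {term!r}")
    return out


def _wald_f(fit: ModelFit, term: str) -> dict:
    idx = _term_indices(fit, term)
    beta = fit.fe_params.to_numpy()[idx]
    V = fit.cov_fe[np.ix_(idx, idx)]
    q = len(idx)
    F = float(beta @ np.linalg.solve(V, beta)) / q
    p = float(stats.f.sf(F, q, fit.df_resid))
    return {"F": F, "df_num": q, "df_den": fit.df_resid, "p": p}


def _mean_design_row(fit: ModelFit, task: str, sex: str) -> np.ndarray:
    """Design row for a (task, sex) cell with covariates at their sample means."""
    import patsy

    ref = {c: [fit.data[c].mean()] for c in fit.spec.covariates}
    new = pd.DataFrame({"task": [task], "sex": [sex], **ref})
    design_info = fit.result.model.data.design_info
    (row,) = patsy.build_design_matrices([design_info], new)
    return np.asarray(row, float)[0]


def _contrast(fit: ModelFit, L: np.ndarray, label: str) -> ContrastResult:
    beta = fit.fe_params.to_numpy()
    est = float(L @ beta)
    se = float(np.sqrt(L @ fit.cov_fe @ L))
    t = est / se if se > 0 else np.nan
    p = float(2.0 * stats.t.sf(abs(t), fit.df_resid)) if np.isfinite(t) else np.nan
    return ContrastResult(label, est, se, t, p, fit.df_resid)


def task_contrasts(fit: ModelFit) -> list[ContrastResult]:
    """Pairwise task contrasts on marginal means (equal weight per sex).

    Estimates are ``later task minus earlier task``; by construction
    (BL vs short) - (BL vs long) equals (long vs short).
    """
    rows = {
        (task, sex): _mean_design_row(fit, task, sex)
        for task in TASK_LABELS
        for sex in ("F", "M")
    }
    out = []
    for a, b in TASK_PAIRS:
        L = 0.5 * (rows[(b, "F")] + rows[(b, "M")]) - 0.5 * (rows[(a, "F")] + rows[(a, "M")])
        out.append(_contrast(fit, L, f"{_SHORT_LABEL[a]}_vs_{_SHORT_LABEL[b]}"))
    return out


def sex_task_contrasts(fit: ModelFit) -> list[ContrastResult]:
    """Difference-in-change contrasts: male task change minus female task change."""
    sexes = set(fit.data["sex"].unique())
    if sexes != {"F", "M"}:
        raise ValueError(f"both sexes required for interaction contrasts, got {sorted(sexes)}")
    rows = {
        (task, sex): _mean_design_row(fit, task, sex)
        for task in TASK_LABELS
        for sex in ("F", "M")
    }
    out = []
    for a, b in TASK_PAIRS:
        L = (rows[(b, "M")] - rows[(a, "M")]) - (rows[(b, "F")] - rows[(a, "F")])
        out.append(
            _contrast(fit, L, f"sex_diff_{_SHORT_LABEL[a]}_to_{_SHORT_LABEL[b]}")
        )
    return out


@dataclass
class InfluenceReport:
    diagnostics: pd.DataFrame  # per modelled observation, indexed like fit.data
    flags: pd.Series
    rules: dict
    n_removed: int


def influence_screen(
    fit: ModelFit, rules: dict | None = None
) -> tuple[InfluenceReport, ModelFit]:
    """Single-pass influence screen and refit.

    Computes Cook's D, RLD and externally studentized residuals per
    observation (variance components fixed at the full-data estimates),
    removes rows breaking any rule, and refits once.
    """
    y_df, X_df = _design(fit.data, fit.spec)
    diag = influence_measures(
        X_df.to_numpy(float),
        y_df.to_numpy(float).ravel(),
        groups=fit.data["subject"].to_numpy(),
        gamma=fit.variance_ratio,
    )
    diag.index = fit.data.index
    flags = flag_influential(diag, rules)
    report = InfluenceReport(diag, flags, rules or dict(DEFAULT_RULES), int(flags.sum()))
    if flags.any():
        refit = fit_mixed_model(fit.data[~flags.to_numpy()], fit.spec)
    else:
        refit = fit
    return report, refit


def _direction(c: ContrastResult, alpha: float) -> str:
    if c.p < alpha:
        return "<" if c.estimate > 0 else ">"
    return "="


@dataclass
class OutcomeDissection:
    fit: ModelFit
    influence: InfluenceReport
    refit: ModelFit
    contrasts: list[ContrastResult]
    sex_contrasts: list[ContrastResult]


def dissect_all_outcomes(
    long_table: pd.DataFrame,
    map_covariates: str = "pwv_hr",
    alpha: float = 0.05,
    screen_influence: bool = True,
) -> tuple[dict[str, OutcomeDissection], pd.DataFrame]:
    """Fit all seven outcome models; returns per-outcome results and a
    direction summary (one row per outcome: 'BL < long < short' style labels).
    """
    table = build_long_table(long_table)
    results: dict[str, OutcomeDissection] = {}
    rows = []
    for outcome in OUTCOMES:
        if outcome not in table.columns or table[outcome].notna().sum() == 0:
            warnings.warn(f"outcome {outcome!r} missing from table: model skipped")
            continue
        spec = ModelSpec.for_outcome(outcome, map_covariates)
        fit = fit_mixed_model(table, spec)
        if screen_influence:
            report, refit = influence_screen(fit)
        else:
            report, refit = (
                InfluenceReport(pd.DataFrame(), pd.Series(dtype=bool), dict(DEFAULT_RULES), 0),
                fit,
            )
        contrasts = task_contrasts(refit)
        sex_c = sex_task_contrasts(refit)
        results[outcome] = OutcomeDissection(fit, report, refit, contrasts, sex_c)
        by_label = {c.label: c for c in contrasts}
        d1 = _direction(by_label["BL_vs_long"], alpha)
        d2 = _direction(by_label["long_vs_short"], alpha)
        sex_f = refit.f_tests["sex"]
        inter_f = refit.f_tests["task:sex"]
        rows.append(
            {
                "outcome": outcome,
                "task_pattern": f"BL {d1} long {d2} short",
                "task_F": refit.f_tests["task"]["F"],
                "task_p": refit.f_tests["task"]["p"],
                "sex_F": sex_f["F"],
                "sex_p": sex_f["p"],
                "interaction_F": inter_f["F"],
                "interaction_p": inter_f["p"],
                "n_removed": report.n_removed,
            }
        )
    return results, pd.DataFrame(rows)
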