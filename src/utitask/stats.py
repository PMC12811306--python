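"""Inferential harness: validity correlations, two-group contrasts,
trial-level mixed models with crossed random intercepts, simple-slope
contrasts, incremental validity, and Fisher-z power analysis.

Scalar statistics (Pearson r, Welch t, Cohen's d, F-change) are
implemented directly from their textbook formulas so they can be
cross-checked against independent library evaluations.  Mixed models
are estimated with statsmodels: linear models by REML with variance
components encoding the crossed participant and stimulus intercepts,
and the logistic classification model by variational Bayes.  Mixed-model
coefficient p-values use the normal approximation on estimate/SE (a df
method is deliberately not imposed); this is configurable by
post-processing the returned coefficient table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ModelError


# ---------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------

def pearson_r(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with the two-sided t-based p-value,
    t = r * sqrt((n-2) / (1-r^2)).  Pairs with any NaN are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs at least 3 complete pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def welch_t(group_a, group_b) -> dict:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("t undefined: both groups have zero variance")
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df=df)
    return {"t": float(t), "df": float(df), "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "sd_a": float(a.std(ddof=1)), "sd_b": float(b.std(ddof=1)),
            "n_a": na, "n_b": nb}


def cohens_d_ci(group_a, group_b, level: float = 0.95
                ) -> tuple[float, float, float]:
    """Pooled-SD standardised mean difference with the
    normal-approximation confidence interval,
    SE = sqrt((na+nb)/(na*nb) + d^2 / (2(na+nb)))."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                       / (na + nb - 2))
    if pooled == 0:
        raise ValueError("d undefined: zero pooled variance")
    d = (a.mean() - b.mean()) / pooled
    se = math.sqrt((na + nb) / (na * nb) + d * d / (2 * (na + nb)))
    z = sps.norm.ppf(0.5 + level / 2)
    return float(d), float(d - z * se), float(d + z * se)


def power_n_for_r(r: float, alpha: float = 0.05, power: float = 0.90,
                  tails: int = 2) -> int:
    """Minimum sample size to detect a correlation ``r`` via the Fisher
    z approximation: n = ceil(((z_{1-alpha/tails} + z_{power}) /
    atanh(|r|))^2 + 3)."""
    if not (0 < abs(r) < 1):
        raise ValueError("r must satisfy 0 < |r| < 1")
    if not (0 < alpha < 1 and alpha < power < 1):
        raise ValueError("require 0 < alpha < power < 1")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    za = sps.norm.ppf(1 - alpha / tails)
    zp = sps.norm.ppf(power)
    return int(math.ceil(((za + zp) / math.atanh(abs(r))) ** 2 + 3))


# ---------------------------------------------------------------------
# Trial-level mixed models
# ---------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Fixed and random structure for the trial-level models.

    The fixed part is the full factorial of food type (indicator
    ``food_healthy``), classification (indicator ``cls_not_tasty``) and
    the standardised explicit score ``uti_z``, plus demographic
    covariates; random intercepts are crossed over participants and
    stimuli.
    """

    outcome: str = "rt_ms"
    family: str = "gaussian"          # or "binomial"
    covariates: tuple[str, ...] = ("age", "gender", "education")

    def fixed_formula(self, data: pd.DataFrame) -> str:
        terms = ["food_healthy * cls_not_tasty * uti_z"]
        for cov in self.covariates:
            if cov not in data.columns:
                continue
            if data[cov].dtype.kind in "if":
                terms.append(cov)
            else:
                ref = data[cov].mode().iloc[0]
                terms.append(f"C({cov}, Treatment('{ref}'))")
        return f"{self.outcome} ~ " + " + ".join(terms)


@dataclass
class ModelFit:
    """Portable summary of a fitted (mixed) model."""

    coef: pd.DataFrame                # estimate, se, stat, p per term
    cov_params: pd.DataFrame | None
    variance_components: dict[str, float]
    n_obs: int
    converged: bool
    family: str = "gaussian"
    notes: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.coef.loc[term]


def standardize_uti(data: pd.DataFrame,
                    score_col: str = "uti_explicit") -> pd.Series:
    """z-score the explicit UTI score over the participants present in
    the analysis data (so coefficients read "per 1 SD UTI")."""
    per_p = data.drop_duplicates("participant_id")[
        ["participant_id", score_col]]
    mu = per_p[score_col].mean()
    sd = per_p[score_col].std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ModelError("explicit score has zero variance; uti_z undefined")
    return (data[score_col] - mu) / sd


def prepare_trial_data(metrics_flagged: pd.DataFrame, trials: pd.DataFrame,
                       participants: pd.DataFrame,
                       outcome: str = "rt_ms") -> pd.DataFrame:
    """Merge metrics, trial design and participant covariates into a
    trial-level analysis frame with the model's coded predictors,
    dropping degenerate/excluded trials for the chosen outcome."""
    df = metrics_flagged.merge(
        trials, on=["participant_id", "trial_id"], validate="1:1")
    part = participants.copy()
    part["uti_explicit"] = part[
        ["uti_item_1", "uti_item_2", "uti_item_3"]].mean(axis=1)
    df = df.merge(part[["participant_id", "uti_explicit", "age", "gender",
                        "education", "condition"]], on="participant_id")
    keep = ~df["degenerate"]
    if outcome == "rt_ms" and "excluded_rt" in df:
        keep &= ~df["excluded_rt"]
    if outcome in ("mad_px", "mad_unit") and "excluded_mad" in df:
        keep &= ~df["excluded_mad"]
    df = df[keep].copy()
    df["food_healthy"] = (df["food_type"] == "healthy").astype(float)
    df["cls_not_tasty"] = (df["classification"] == "not_tasty").astype(float)
    df["tasty"] = 1.0 - df["cls_not_tasty"]
    df["condition_hedonic"] = (df["condition"] == "hedonic").astype(float)
    df["uti_z"] = standardize_uti(df)
    df["_all"] = 1
    return df


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """REML linear mixed model with crossed random intercepts for
    participant and stimulus (variance-component encoding).

    Non-convergence is reported via ``converged=False`` — there is no
    silent fallback.  Coefficient p-values are normal-approximation
    z-tests on estimate/SE.
    """
    data = data.copy()
    if "_all" not in data:
        data["_all"] = 1
    y = data[spec.outcome]
    if y.nunique() == 1:
        coef = pd.DataFrame({"estimate": [float(y.iloc[0])], "se": [0.0],
                             "stat": [np.nan], "p": [np.nan]},
                            index=["Intercept"])
        return ModelFit(coef, None, {"participant": 0.0, "stimulus": 0.0},
                        len(data), True, notes=["constant outcome"])
    vc = {"participant": "0 + C(participant_id)",
          "stimulus": "0 + C(stimulus_id)"}
    model = smf.mixedlm(spec.fixed_formula(data), data, groups="_all",
                        re_formula="0", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs")
        except Exception as e:          # noqa: BLE001 - surfaced as flag
            raise ModelError(f"mixed model estimation failed: {e}") from e
    k_fe = model.k_fe
    fe_names = model.exog_names
    coef = pd.DataFrame({
        "estimate": res.params[:k_fe].to_numpy(),
        "se": res.bse[:k_fe].to_numpy(),
    }, index=fe_names)
    coef["stat"] = coef["estimate"] / coef["se"]
    coef["p"] = 2 * sps.norm.sf(np.abs(coef["stat"]))
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k_fe, :k_fe],
                       index=fe_names, columns=fe_names)
    vcomp = {name: float(v) for name, v in
             zip(model.exog_vc.names, res.vcomp)}
    vcomp["residual"] = float(res.scale)
    return ModelFit(coef, cov, vcomp, int(res.nobs),
                    bool(res.converged), family="gaussian")


def fit_glmm_choice(data: pd.DataFrame,
                    formula: str | None = None) -> ModelFit:
    """Logistic mixed model for the tasty/not-tasty classification with
    crossed random intercepts (participant, stimulus), estimated by
    variational Bayes.

    Default fixed structure follows the goal-manipulation analysis:
    condition, food type, their interaction, plus demographic
    covariates.  A constant outcome (e.g., every response "tasty") is
    degenerate and raises :class:`ModelError`.
    """
    data = data.copy()
    if data["tasty"].nunique() == 1:
        raise ModelError("classification outcome is constant; logistic "
                         "model is degenerate")
    if formula is None:
        cov_terms = []
        for cov in ("age", "gender", "education"):
            if cov in data.columns:
                if data[cov].dtype.kind in "if":
                    cov_terms.append(cov)
                else:
                    ref = data[cov].mode().iloc[0]
                    cov_terms.append(f"C({cov}, Treatment('{ref}'))")
        formula = ("tasty ~ condition_hedonic * food_healthy + "
                   + " + ".join(cov_terms))
    vc = {"participant": "0 + C(participant_id)",
          "stimulus": "0 + C(stimulus_id)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.BinomialBayesMixedGLM.from_formula(formula, vc, data)
        try:
            res = model.fit_vb()
        except Exception as e:          # noqa: BLE001
            raise ModelError(f"logistic mixed model failed: {e}") from e
    fe_names = list(getattr(model, "fep_names", None) or model.exog_names)
    coef = pd.DataFrame({
        "estimate": np.asarray(res.fe_mean),
        "se": np.asarray(res.fe_sd),
    }, index=fe_names)
    coef["stat"] = coef["estimate"] / coef["se"]
    coef["p"] = 2 * sps.norm.sf(np.abs(coef["stat"]))
    vcomp = {name: float(np.exp(2 * m)) for name, m in
             zip(model.vcp_names, res.vcp_mean)}
    return ModelFit(coef, None, vcomp, len(data), True, family="binomial")


# ---------------------------------------------------------------------
# Simple slopes
# ---------------------------------------------------------------------

def _find_term(names, parts: set[str]) -> str | None:
    for name in names:
        if set(name.split(":")) == parts:
            return name
    return None


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    z: float
    p: float


def simple_slopes(fit: ModelFit,
                  classifications: tuple[str, ...] = ("tasty", "not_tasty")
                  ) -> list[ContrastResult]:
    """Healthy-minus-unhealthy difference in the UTI slope within each
    classification cell.

    With indicator coding (``food_healthy``, ``cls_not_tasty``) the UTI
    slope in cell (f, c) is  b_uti + f*b_uti:food + c*b_uti:cls +
    f*c*b_uti:food:cls, so the healthy-unhealthy slope difference at
    classification c is  b_uti:food + c*b_uti:food:cls.  The SE comes
    from the corresponding linear combination of the coefficient
    covariance.
    """
    if fit.cov_params is None:
        raise ValueError("fit carries no coefficient covariance")
    names = list(fit.coef.index)
    two_way = _find_term(names, {"food_healthy", "uti_z"})
    three_way = _find_term(names, {"food_healthy", "cls_not_tasty", "uti_z"})
    if two_way is None:
        raise ValueError("model lacks the uti_z x food_healthy interaction")
    results = []
    for cls in classifications:
        c = 1.0 if cls == "not_tasty" else 0.0
        L = pd.Series(0.0, index=names)
        L[two_way] = 1.0
        if three_way is not None:
            L[three_way] = c
        est = float(L @ fit.coef["estimate"])
        var = float(L @ fit.cov_params.to_numpy() @ L)
        se = math.sqrt(var)
        z = est / se if se > 0 else np.nan
        p = 2 * sps.norm.sf(abs(z)) if se > 0 else np.nan
        results.append(ContrastResult(
            label=f"healthy-unhealthy UTI slope | {cls}",
            estimate=est, se=se, z=float(z), p=float(p)))
    return results


# ---------------------------------------------------------------------
# Incremental validity
# ---------------------------------------------------------------------

def incremental_validity(indices: pd.DataFrame, added: str,
                         outcome: str = "dqs",
                         base: tuple[str, ...] = ("uti_explicit",),
                         covariates: tuple[str, ...] = ("age", "gender",
                                                        "education")) -> dict:
    """Nested OLS comparison: does ``added`` (a behavioural index)
    explain outcome variance beyond the explicit score and covariates?

    Returns the F-change ((RSS_r - RSS_f)/1) / (RSS_f/df_f), its
    degrees of freedom, p-value, the full-model coefficient table, and
    a ``singular`` flag when the added column is collinear with the
    base model.
    """
    cols = [outcome, added, *base]
    data = indices.copy()
    cov_terms = []
    for cov in covariates:
        if cov not in data.columns:
            continue
        cols.append(cov)
        if data[cov].dtype.kind in "if":
            cov_terms.append(cov)
        else:
            ref = data[cov].mode().iloc[0]
            cov_terms.append(f"C({cov}, Treatment('{ref}'))")
    data = data.dropna(subset=[c for c in cols if c in data.columns])
    rhs = " + ".join([*base, *cov_terms])
    reduced = smf.ols(f"{outcome} ~ {rhs}", data).fit()
    full = smf.ols(f"{outcome} ~ {rhs} + {added}", data).fit()
    singular = full.df_model <= reduced.df_model or np.isnan(
        full.params.get(added, np.nan))
    if singular:
        return {"f_change": np.nan, "df": (np.nan, np.nan), "p": np.nan,
                "coef": full.params.to_frame("estimate"),
                "singular": True}
    df_f = full.df_resid
    f_change = ((reduced.ssr - full.ssr) / 1.0) / (full.ssr / df_f)
    p = sps.f.sf(f_change, 1, df_f)
    coef = pd.DataFrame({"estimate": full.params, "se": full.bse,
                         "stat": full.tvalues, "p": full.pvalues})
    return {"f_change": float(f_change), "df": (1, float(df_f)),
            "p": float(p), "coef": coef, "singular": False}
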