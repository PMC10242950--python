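"""Statistical models for the scored task data.

Two mixed models carry the analysis:

* **Adjustment model** — round-level weight of advice s regressed on group
  (TD reference) with a participant random intercept, restricted maximum
  likelihood.  Group effects test whether *how much* people move towards
  the advice differs.
* **Strategy model** — a random-intercept logistic model of the decision
  to use an all-or-nothing strategy (stay/copy, coded 1) versus a
  compromise (coded 0), ML with adaptive Gauss-Hermite quadrature.
  Exploratory codings contrast stay (or copy) against the other two
  strategies.  Group effects are summarized by a likelihood-ratio chi2 and
  Tukey-adjusted pairwise contrasts.

Both report the intraclass correlation tau00/(tau00 + sigma2) — with
sigma2 = pi^2/3 on the latent logit scale — and Nakagawa's marginal /
conditional R2, i.e. the variance share of the fixed effects alone and of
fixed plus random effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ._glmm import fit_logistic_random_intercept
from .core_model import GROUPS, CohortDataset
from .scoring import ParticipantSummary

#: Residual variance of a logistic model on the latent scale.
LOGIT_SIGMA2 = math.pi**2 / 3.0

CODINGS = ("aon_vs_comp", "stay_vs_rest", "copy_vs_rest")


@dataclass(frozen=True)
class FixedEffect:
    term: str
    estimate: float          # link scale
    se: float
    ci_low: float
    ci_high: float
    p: float
    odds_ratio: Optional[float] = None
    or_ci_low: Optional[float] = None
    or_ci_high: Optional[float] = None


@dataclass(frozen=True)
class Contrast:
    pair: tuple              # (group_a, group_b); estimate is a - b
    estimate: float
    se: float
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class ModelFit:
    model_id: str
    fixed_effects: list
    sigma2: float
    tau00: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    n_participants: int
    n_observations: int
    loglik: Optional[float] = None
    lr_group_chi2: Optional[float] = None
    lr_group_df: Optional[int] = None
    lr_group_p: Optional[float] = None
    contrasts: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def fixed_effect(self, term: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.term == term:
                return fe
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        """Tidy term-level table (one row per fixed effect)."""
        return pd.DataFrame(
            [
                {
                    "model": self.model_id, "term": fe.term,
                    "estimate": fe.estimate, "se": fe.se,
                    "ci_low": fe.ci_low, "ci_high": fe.ci_high, "p": fe.p,
                    "odds_ratio": np.nan if fe.odds_ratio is None else fe.odds_ratio,
                    "or_ci_low": np.nan if fe.or_ci_low is None else fe.or_ci_low,
                    "or_ci_high": np.nan if fe.or_ci_high is None else fe.or_ci_high,
                }
                for fe in self.fixed_effects
            ]
        )


# ---------------------------------------------------------------------------
# Variance-component arithmetic
# ---------------------------------------------------------------------------

def icc_from_components(tau00: float, sigma2: float) -> float:
    """Intraclass correlation tau00 / (tau00 + sigma2)."""
    if tau00 < 0 or sigma2 < 0:
        raise ValueError("variance components must be nonnegative")
    if tau00 + sigma2 == 0:
        raise ValueError("ICC undefined: both variance components are zero")
    return tau00 / (tau00 + sigma2)


def nakagawa_r2(fixed_effect_variance: float, tau00: float, sigma2: float) -> tuple:
    """(marginal, conditional) variance-explained of a mixed model.

    marginal = Vf / (Vf + tau00 + sigma2); conditional adds tau00 to the
    numerator.  Vf is the variance of the fixed-effect linear predictor
    over the estimation sample.
    """
    if min(fixed_effect_variance, tau00, sigma2) < 0:
        raise ValueError("all variance components must be nonnegative")
    total = fixed_effect_variance + tau00 + sigma2
    if total == 0:
        raise ValueError("R2 undefined: zero total variance")
    return fixed_effect_variance / total, (fixed_effect_variance + tau00) / total


def conditional_r2_from_marginal(r2_marginal: float, tau00: float, sigma2: float) -> float:
    """Invert the marginal-R2 formula for Vf, then return the conditional R2."""
    if not 0 <= r2_marginal < 1:
        raise ValueError("marginal R2 must be in [0, 1)")
    vf = r2_marginal * (tau00 + sigma2) / (1.0 - r2_marginal)
    return nakagawa_r2(vf, tau00, sigma2)[1]


# ---------------------------------------------------------------------------
# Design-matrix plumbing
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, covariates: Sequence[str]) -> tuple:
    """Intercept + treatment-coded group (TD reference) + centered covariates."""
    groups_present = [g for g in GROUPS if (df["group"] == g).any()]
    if groups_present[0] != "TD" and "TD" in groups_present:
        groups_present.remove("TD")
        groups_present.insert(0, "TD")
    ref, others = groups_present[0], groups_present[1:]
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for g in others:
        cols.append((df["group"] == g).to_numpy(dtype=float))
        names.append(f"group[{g}]")
    for cov in covariates:
        if cov not in df.columns or df[cov].isna().any():
            raise ValueError(f"covariate {cov!r} missing for some participants")
        x = df[cov].to_numpy(dtype=float)
        cols.append(x - x.mean())
        names.append(cov)
    return np.column_stack(cols), names, ref, others


def _valid_rounds_frame(cohort: CohortDataset) -> pd.DataFrame:
    df = cohort.to_frame()
    if df.empty or df["label"].isna().any():
        raise ValueError("cohort must be scored (run score_cohort) before fitting")
    return df[df["is_valid"]].reset_index(drop=True)


def _wald_effects(names, params, bse, odds: bool) -> list:
    z975 = stats.norm.ppf(0.975)
    out = []
    for name, b, se in zip(names, params, bse):
        lo, hi = b - z975 * se, b + z975 * se
        p = 2.0 * stats.norm.sf(abs(b) / se) if se > 0 else float("nan")
        out.append(
            FixedEffect(
                term=name, estimate=float(b), se=float(se),
                ci_low=float(lo), ci_high=float(hi), p=float(p),
                odds_ratio=float(np.exp(b)) if odds else None,
                or_ci_low=float(np.exp(lo)) if odds else None,
                or_ci_high=float(np.exp(hi)) if odds else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model 1: linear mixed model of the adjustment weight
# ---------------------------------------------------------------------------

def fit_adjustment_model(
    cohort: CohortDataset,
    covariates: Sequence[str] = (),
) -> ModelFit:
    """Round-level s on group with a participant random intercept (REML).

    The intercept is the TD mean adjustment; group terms are differences
    from TD.  A near-zero random-intercept variance is reported with a
    singular-fit warning rather than an error.
    """
    import statsmodels.api as sm

    df = _valid_rounds_frame(cohort)
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups to fit the adjustment model")
    X, names, _, _ = _design(df, covariates)
    y = df["s"].to_numpy(dtype=float)
    ids = df["participant_id"].to_numpy()

    notes = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=ids)
        res = model.fit(reml=True)
    tau00 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    if tau00 < 1e-8:
        notes.append("singular fit: random-intercept variance is ~0")

    effects = _wald_effects(names, np.asarray(res.fe_params), np.asarray(res.bse_fe),
                            odds=False)
    vf = float(np.var(X @ np.asarray(res.fe_params)))
    r2m, r2c = nakagawa_r2(vf, tau00, sigma2)

    fit = ModelFit(
        model_id="adjustment",
        fixed_effects=effects,
        sigma2=sigma2,
        tau00=tau00,
        icc=icc_from_components(tau00, sigma2) if tau00 + sigma2 > 0 else float("nan"),
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_participants=int(df["participant_id"].nunique()),
        n_observations=len(df),
        loglik=float(res.llf),
        warnings=notes,
    )
    fit.contrasts = _maybe_tukey(fit, names, np.asarray(res.fe_params),
                                 np.asarray(res.cov_params())[: len(names), : len(names)],
                                 df)
    return fit


# ---------------------------------------------------------------------------
# Model 2 and exploratory codings: random-intercept logistic models
# ---------------------------------------------------------------------------

def _outcome(df: pd.DataFrame, coding: str) -> np.ndarray:
    if coding == "aon_vs_comp":
        return (df["label"] != "compromise").to_numpy(dtype=float)
    if coding == "stay_vs_rest":
        return (df["label"] == "stay").to_numpy(dtype=float)
    if coding == "copy_vs_rest":
        return (df["label"] == "copy").to_numpy(dtype=float)
    raise ValueError(f"unknown coding {coding!r}; expected one of {CODINGS}")


def fit_strategy_model(
    cohort: CohortDataset,
    coding: str = "aon_vs_comp",
    covariates: Sequence[str] = (),
    n_quad: int = 21,
) -> ModelFit:
    """Random-intercept logistic model of strategy choice.

    ``aon_vs_comp`` codes stay/copy as 1 and compromise as 0 (the primary
    model); the exploratory codings contrast one strategy against the other
    two.  Reports subject-specific (conditional) odds ratios, the latent
    ICC with sigma2 = pi^2/3, Nakagawa R2, and a likelihood-ratio chi2 for
    dropping the group terms.
    """
    df = _valid_rounds_frame(cohort)
    y = _outcome(df, coding)
    X, names, _, _ = _design(df, covariates)
    ids = df["participant_id"].to_numpy()

    res = fit_logistic_random_intercept(X, y, ids, n_quad=n_quad)
    effects = _wald_effects(names, res.params, res.bse, odds=True)
    vf = float(np.var(X @ res.params))
    r2m, r2c = nakagawa_r2(vf, res.tau00, LOGIT_SIGMA2)

    fit = ModelFit(
        model_id=coding,
        fixed_effects=effects,
        sigma2=LOGIT_SIGMA2,
        tau00=res.tau00,
        icc=icc_from_components(res.tau00, LOGIT_SIGMA2),
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_participants=res.n_clusters,
        n_observations=res.n_obs,
        loglik=res.loglik,
        warnings=list(res.warnings),
    )

    # Likelihood-ratio test for the group factor (vs covariates-only null).
    group_terms = [n for n in names if n.startswith("group[")]
    if group_terms and not res.penalized:
        keep = [i for i, n in enumerate(names) if not n.startswith("group[")]
        res0 = fit_logistic_random_intercept(X[:, keep], y, ids, n_quad=n_quad)
        chi2 = max(0.0, 2.0 * (res.loglik - res0.loglik))
        fit.lr_group_chi2 = chi2
        fit.lr_group_df = len(group_terms)
        fit.lr_group_p = float(stats.chi2.sf(chi2, len(group_terms)))

    fit.contrasts = _maybe_tukey(fit, names, res.params, res.cov_params, df)
    return fit


# ---------------------------------------------------------------------------
# Tukey contrasts
# ---------------------------------------------------------------------------

def tukey_contrasts(
    group_names: Sequence[str],
    params: np.ndarray,
    cov: np.ndarray,
    term_names: Sequence[str],
) -> list:
    """All pairwise group contrasts, single-step (multivariate-t-free) Tukey.

    Each contrast is a linear combination of the treatment-coded fixed
    effects; the adjusted p-value of contrast k is
    1 - P(max_j |Z_j| <= |z_k|) under the joint normal of all contrast
    z-statistics, which is monotone in |z| and never below the unadjusted
    Wald p.  With two groups this reduces to the unadjusted test.
    """
    idx = {g: term_names.index(f"group[{g}]") for g in group_names[1:]}
    pairs, L = [], []
    for i in range(len(group_names)):
        for j in range(i + 1, len(group_names)):
            a, b = group_names[i], group_names[j]
            v = np.zeros(len(term_names))
            if a in idx:
                v[idx[a]] += 1.0
            if b in idx:
                v[idx[b]] -= 1.0
            pairs.append((a, b))
            L.append(v)
    L = np.asarray(L)
    est = L @ params
    V = L @ cov @ L.T
    se = np.sqrt(np.diag(V))
    z = est / se
    corr = V / np.outer(se, se)
    # Guard tiny asymmetries before handing the matrix to MVN.
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)

    out = []
    mvn = stats.multivariate_normal(mean=np.zeros(len(pairs)), cov=corr,
                                    allow_singular=True)
    for k, (pair, e, s_, zk) in enumerate(zip(pairs, est, se, z)):
        p_un = 2.0 * stats.norm.sf(abs(zk))
        if len(pairs) == 1:
            p_adj = p_un
        else:
            lim = abs(zk) * np.ones(len(pairs))
            inside = float(mvn.cdf(lim, lower_limit=-lim))
            p_adj = min(1.0, max(p_un, 1.0 - inside))
        out.append(
            Contrast(pair=pair, estimate=float(e), se=float(s_), z=float(zk),
                     p_unadjusted=float(p_un), p_adjusted=float(p_adj))
        )
    return out


def _maybe_tukey(fit: ModelFit, names, params, cov, df) -> list:
    groups_present = [g for g in GROUPS if (df["group"] == g).any()]
    if len(groups_present) < 2:
        return []
    return tukey_contrasts(groups_present, np.asarray(params), np.asarray(cov), names)


# ---------------------------------------------------------------------------
# Parameter recovery for the strategy model
# ---------------------------------------------------------------------------

def simulate_strategy_outcomes(
    group_sizes: dict,
    log_odds: dict,
    tau00: float,
    rng: np.random.Generator,
    n_rounds: int = 5,
) -> pd.DataFrame:
    """Binary outcomes straight from the logistic-normal generative model.

    ``log_odds`` maps "(Intercept)" and "group[G]" terms to conditional
    (subject-specific) log-odds of an all-or-nothing response.
    """
    rows = []
    pid = 0
    for g, n in group_sizes.items():
        eta_fixed = log_odds["(Intercept)"] + log_odds.get(f"group[{g}]", 0.0)
        for _ in range(n):
            pid += 1
            u = rng.normal(0.0, math.sqrt(tau00))
            p = special.expit(eta_fixed + u)
            y = rng.random(n_rounds) < p
            for j, yj in enumerate(y, start=1):
                rows.append((f"P{pid:05d}", g, j, int(yj)))
    return pd.DataFrame(rows, columns=["participant_id", "group", "round", "y"])


def fit_strategy_outcomes(df: pd.DataFrame, n_quad: int = 21):
    """Fit the random-intercept logistic model to a plain outcome table."""
    X, names, _, _ = _design(df, ())
    res = fit_logistic_random_intercept(
        X, df["y"].to_numpy(dtype=float), df["participant_id"].to_numpy(), n_quad=n_quad
    )
    return {**{n: float(b) for n, b in zip(names, res.params)}, "tau00": res.tau00}


def parameter_recovery(
    group_sizes: dict,
    log_odds: dict,
    tau00: float,
    n_replicates: int,
    seed: int,
    n_rounds: int = 5,
) -> pd.DataFrame:
    """Replicate simulation/refit experiment for the strategy model.

    Returns one row per replicate with the fitted log-odds and tau00;
    medians over replicates estimate the recovery bias.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        df = simulate_strategy_outcomes(group_sizes, log_odds, tau00, rng,
                                        n_rounds=n_rounds)
        est = fit_strategy_outcomes(df)
        est["replicate"] = rep
        rows.append(est)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Accuracy ANOVA
# ---------------------------------------------------------------------------

def anova_accuracy(summaries: Sequence[ParticipantSummary]) -> dict:
    """One-way ANOVA of the first-estimate accuracy ratio across groups."""
    by_group: dict[str, list[float]] = {}
    for s in summaries:
        by_group.setdefault(s.group, []).append(s.accuracy_ratio)
    samples = [np.asarray(v, dtype=float) for v in by_group.values()]
    if len(samples) < 2 or any(len(v) < 2 for v in samples):
        raise ValueError("need >= 2 groups with >= 2 participants each")
    allv = np.concatenate(samples)
    if np.ptp(allv) == 0:
        raise ValueError("accuracy is constant; F undefined")
    grand = allv.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in samples)
    ss_total = float(np.sum((allv - grand) ** 2))
    df1 = len(samples) - 1
    df2 = len(allv) - len(samples)
    f_stat, p = stats.f_oneway(*samples)
    return {
        "F": float(f_stat), "df1": df1, "df2": df2, "p": float(p),
        "eta_squared": ss_between / ss_total,
    }
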