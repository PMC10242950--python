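"""Mixed models, variance components, contrasts, and the accuracy ANOVA."""

import dataclasses
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beastlab._glmm import _cluster_loglik, fit_logistic_random_intercept
from beastlab.core_model import CohortDataset, ParticipantRecord
from beastlab.inference import (
    LOGIT_SIGMA2,
    anova_accuracy,
    conditional_r2_from_marginal,
    fit_adjustment_model,
    fit_strategy_model,
    icc_from_components,
    nakagawa_r2,
    parameter_recovery,
    simulate_strategy_outcomes,
)
from beastlab.scoring import filter_participants, score_cohort, summarize_cohort
from beastlab.synthetic_cohort import SimulationConfig, simulate_cohort

from conftest import make_participant


# ---------------------------------------------------------------------------
# Variance-component arithmetic
# ---------------------------------------------------------------------------

def test_icc_closed_forms():
    assert icc_from_components(3.96, 3.29) == pytest.approx(0.546, abs=5e-4)
    assert round(icc_from_components(3.96, 3.29), 2) == 0.55
    assert icc_from_components(0.0, 1.0) == 0.0
    assert icc_from_components(1.0, 1e-12) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        icc_from_components(0.0, 0.0)


def test_nakagawa_r2_closed_forms():
    m, c = nakagawa_r2(0.0, 3.96, 3.29)
    assert m == 0.0 and c == pytest.approx(icc_from_components(3.96, 3.29))
    assert conditional_r2_from_marginal(0.068, 3.96, 3.29) == \
        pytest.approx(0.577, abs=0.005)
    rng = np.random.default_rng(0)
    for _ in range(200):
        vf, t, s = rng.uniform(0, 5, 3)
        m, c = nakagawa_r2(vf, t, s + 1e-6)
        assert 0.0 <= m <= c <= 1.0


# ---------------------------------------------------------------------------
# GLMM engine
# ---------------------------------------------------------------------------

def test_glmm_loglik_nests_ordinary_logistic():
    """At vanishing tau00 the quadrature reproduces the GLM log-likelihood."""
    rng = np.random.default_rng(4)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([-0.5, 1.0])
    y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
    ids = np.arange(n) // 5
    _, first, counts = np.unique(ids, return_index=True, return_counts=True)
    gh_x, gh_w = np.polynomial.hermite.hermgauss(21)
    theta = np.concatenate([beta, [np.log(1e-6)]])
    ll_mixed = _cluster_loglik(theta, X, y, np.sort(first), counts, gh_x, gh_w)
    eta = X @ beta
    ll_glm = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    assert ll_mixed == pytest.approx(ll_glm, abs=1e-6 * n)


def test_glmm_matches_lme4_reference():
    """Cross-check the AGQ fitter against lme4::glmer (nAGQ = 25)."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the lme4 cross-check")
    rng = np.random.default_rng(5)
    df = simulate_strategy_outcomes(
        {"TD": 45, "CP_LCU": 31, "CP_HCU": 32},
        {"(Intercept)": math.log(0.42), "group[CP_LCU]": math.log(5.78),
         "group[CP_HCU]": math.log(2.20)},
        tau00=3.96, rng=rng,
    )
    X = np.column_stack([
        np.ones(len(df)),
        (df.group == "CP_LCU").to_numpy(float),
        (df.group == "CP_HCU").to_numpy(float),
    ])
    fit = fit_logistic_random_intercept(X, df.y.to_numpy(float),
                                        df.participant_id.to_numpy())

    import tempfile, os
    with tempfile.TemporaryDirectory() as td:
        csv = os.path.join(td, "d.csv")
        out = os.path.join(td, "out.csv")
        df.to_csv(csv, index=False)
        rcode = f"""
        d <- read.csv("{csv}")
        d$group <- relevel(factor(d$group), "TD")
        suppressMessages(library(lme4))
        m <- glmer(y ~ group + (1 | participant_id), data = d,
                   family = binomial, nAGQ = 25)
        co <- summary(m)$coefficients
        write.csv(data.frame(term = rownames(co), est = co[, 1], se = co[, 2],
                             tau = as.numeric(VarCorr(m)$participant_id),
                             ll = as.numeric(logLik(m))),
                  "{out}", row.names = FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(out)

    ref_map = dict(zip(ref.term, ref.est))
    se_map = dict(zip(ref.term, ref.se))
    ours = dict(zip(["(Intercept)", "groupCP_LCU", "groupCP_HCU"], fit.params))
    ours_se = dict(zip(["(Intercept)", "groupCP_LCU", "groupCP_HCU"], fit.bse))
    for term in ours:
        assert ours[term] == pytest.approx(ref_map[term], abs=2e-3)
        assert ours_se[term] == pytest.approx(se_map[term], rel=0.02)
    assert fit.tau00 == pytest.approx(float(ref.tau.iloc[0]), rel=0.01)
    assert fit.loglik == pytest.approx(float(ref.ll.iloc[0]), abs=1e-3)


def test_recovery_from_known_parameters():
    """Median fitted log-odds and tau00 land near the generating values."""
    truth = {"(Intercept)": -0.6, "group[CP_LCU]": 1.4, "group[CP_HCU]": 0.5}
    rec = parameter_recovery(
        {"TD": 150, "CP_LCU": 150, "CP_HCU": 150}, truth, tau00=3.96,
        n_replicates=40, seed=11,
    )
    med = rec.median(numeric_only=True)
    for term, val in truth.items():
        assert abs(med[term] - val) < 0.15, term
    assert abs(med["tau00"] - 3.96) / 3.96 < 0.15


def test_group_effect_coverage_under_the_null():
    """With identical groups, the 95% CI for a group effect covers 0 ~95%
    of the time."""
    truth = {"(Intercept)": -0.8}
    cover = 0
    n_rep = 60
    seeds = np.random.SeedSequence(23).spawn(n_rep)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        df = simulate_strategy_outcomes({"TD": 45, "CP_LCU": 31, "CP_HCU": 32},
                                        truth, tau00=3.96, rng=rng)
        X = np.column_stack([
            np.ones(len(df)),
            (df.group == "CP_LCU").to_numpy(float),
            (df.group == "CP_HCU").to_numpy(float),
        ])
        fit = fit_logistic_random_intercept(X, df.y.to_numpy(float),
                                            df.participant_id.to_numpy())
        b, se = fit.params[1], fit.bse[1]
        cover += (b - 1.96 * se) <= 0.0 <= (b + 1.96 * se)
    assert cover / n_rep >= 0.85


# ---------------------------------------------------------------------------
# Model battery on cohorts
# ---------------------------------------------------------------------------

def test_adjustment_model_intercept_recovers_td_mean():
    """A TD-only simulation targeted at mean s 0.36 fits that intercept."""
    cfg = SimulationConfig(group_sizes={"TD": 500, "CP_LCU": 100}, rng_seed=29)
    retained, _ = filter_participants(score_cohort(simulate_cohort(cfg)))
    fit = fit_adjustment_model(retained)
    assert fit.fixed_effect("(Intercept)").estimate == pytest.approx(0.36, abs=0.02)
    assert fit.n_observations == sum(
        1 for p in retained.participants for r in p.rounds if r.is_valid
    )


def test_strategy_model_reports_latent_scale_components(scored_cohort):
    fit = fit_strategy_model(scored_cohort)
    assert fit.sigma2 == pytest.approx(math.pi**2 / 3)
    assert 0.0 <= fit.icc <= 1.0
    assert fit.r2_marginal <= fit.r2_conditional <= 1.0
    assert fit.lr_group_df == 2 and fit.lr_group_chi2 >= 0.0
    ors = {fe.term: fe.odds_ratio for fe in fit.fixed_effects}
    assert all(v > 0 for v in ors.values())


def test_zero_variance_covariate_leaves_estimates_unchanged(scored_cohort):
    """Adding a constant covariate must not move the group estimates."""
    const = CohortDataset(
        participants=[
            dataclasses.replace(p, age_years=14.0) for p in scored_cohort.participants
        ]
    )
    base = fit_strategy_model(const)
    with_cov = fit_strategy_model(const, covariates=("age",))
    for term in ("(Intercept)", "group[CP_LCU]", "group[CP_HCU]"):
        assert with_cov.fixed_effect(term).estimate == pytest.approx(
            base.fixed_effect(term).estimate, abs=1e-3
        )


def test_constant_outcome_triggers_penalized_fallback():
    p = [make_participant(f"p{i}", [(40, 50, 40)] * 5) for i in range(20)]
    cohort, _ = filter_participants(score_cohort(CohortDataset(participants=p)))
    cohort = CohortDataset(
        participants=[
            dataclasses.replace(q, group="CP_LCU") if i >= 10 else q
            for i, q in enumerate(cohort.participants)
        ]
    )
    fit = fit_strategy_model(cohort, coding="stay_vs_rest")
    assert any("penalized" in w or "constant" in w for w in fit.warnings)


def test_lr_chi2_invariant_to_reference_level(scored_cohort):
    """Relabelling groups permutes coefficients but not the LR test."""
    swap = {"TD": "CP_LCU", "CP_LCU": "TD", "CP_HCU": "CP_HCU"}
    swapped = CohortDataset(
        participants=[
            dataclasses.replace(p, group=swap[p.group])
            for p in scored_cohort.participants
        ]
    )
    a = fit_strategy_model(scored_cohort)
    b = fit_strategy_model(swapped)
    assert a.lr_group_chi2 == pytest.approx(b.lr_group_chi2, abs=1e-2)


# ---------------------------------------------------------------------------
# Tukey contrasts
# ---------------------------------------------------------------------------

def test_tukey_adjusted_p_dominates_unadjusted(scored_cohort):
    fit = fit_strategy_model(scored_cohort)
    assert len(fit.contrasts) == 3
    for c in fit.contrasts:
        assert c.p_adjusted >= c.p_unadjusted - 1e-12
        assert 0.0 <= c.p_adjusted <= 1.0


def test_tukey_adjusted_p_monotone_in_z(scored_cohort):
    fit = fit_strategy_model(scored_cohort)
    by_z = sorted(fit.contrasts, key=lambda c: abs(c.z))
    ps = [c.p_adjusted for c in by_z]
    assert ps == sorted(ps, reverse=True)


def test_contrast_antisymmetry(scored_cohort):
    """estimate(A - B) = -(estimate of the reversed difference B - A)."""
    fit = fit_strategy_model(scored_cohort)
    est = {c.pair: c.estimate for c in fit.contrasts}
    td_lcu = est[("TD", "CP_LCU")]
    lcu_hcu = est[("CP_LCU", "CP_HCU")]
    td_hcu = est[("TD", "CP_HCU")]
    assert td_lcu + lcu_hcu == pytest.approx(td_hcu, abs=1e-10)


def test_two_group_contrast_reduces_to_wald(scored_cohort):
    two = CohortDataset(
        participants=[p for p in scored_cohort.participants if p.group != "CP_HCU"]
    )
    fit = fit_strategy_model(two)
    assert len(fit.contrasts) == 1
    c = fit.contrasts[0]
    assert c.p_adjusted == pytest.approx(c.p_unadjusted, abs=1e-12)


# ---------------------------------------------------------------------------
# Accuracy ANOVA
# ---------------------------------------------------------------------------

class _S:
    def __init__(self, group, acc):
        self.group = group
        self.accuracy_ratio = acc


def test_anova_two_group_hand_example():
    sums = [_S("a", v) for v in (1, 2, 3)] + [_S("b", v) for v in (4, 5, 6)]
    res = anova_accuracy(sums)
    assert res["F"] == pytest.approx(13.5)
    assert res["eta_squared"] == pytest.approx(27 / 35)
    assert (res["df1"], res["df2"]) == (1, 4)


def test_anova_identical_groups_gives_zero_f():
    sums = [_S(g, v) for g in ("a", "b", "c") for v in (0.6, 0.7, 0.8)]
    res = anova_accuracy(sums)
    assert res["F"] == pytest.approx(0.0, abs=1e-12)
    assert res["eta_squared"] == pytest.approx(0.0, abs=1e-12)
    assert (res["df1"], res["df2"]) == (2, 6)


def test_anova_degrees_of_freedom_on_cohort(scored_cohort):
    res = anova_accuracy(summarize_cohort(scored_cohort))
    n = len(scored_cohort.participants)
    assert (res["df1"], res["df2"]) == (2, n - 3)


def test_anova_rejects_degenerate_input():
    with pytest.raises(ValueError):
        anova_accuracy([_S("a", 1.0)])
    with pytest.raises(ValueError):
        anova_accuracy([_S("a", 1.0), _S("a", 1.0), _S("b", 1.0), _S("b", 1.0)])
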