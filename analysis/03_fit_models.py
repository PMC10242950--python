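"""Fit the model battery to the scored cohort.

Model 1: linear mixed model of round-level s on group (participant random
intercept, REML).  Model 2: random-intercept logistic model of
all-or-nothing vs compromise choice, plus the exploratory stay-vs-rest and
copy-vs-rest codings and age/IQ covariate re-runs.  Writes the tidy
coefficient table, a two-model summary table, and the Tukey contrasts.
"""

from pathlib import Path

import pandas as pd

from beastlab.cli_pipeline import contrasts_markdown, fit_all_models, model_table_markdown
from beastlab.core_model import load_cohort
from beastlab.inference import anova_accuracy
from beastlab.scoring import filter_participants, score_cohort, summarize_cohort

OUT = Path("results")


def main() -> None:
    retained, _ = filter_participants(score_cohort(load_cohort(OUT / "cohort.csv")))
    summaries = summarize_cohort(retained)

    anova = anova_accuracy(summaries)
    print("accuracy of first estimates (one-way ANOVA on E1/true):")
    print(f"  F({anova['df1']}, {anova['df2']}) = {anova['F']:.2f}, "
          f"p = {anova['p']:.3f}, eta^2 = {anova['eta_squared']:.3f}")

    fits = fit_all_models(
        retained,
        codings=("aon_vs_comp", "stay_vs_rest", "copy_vs_rest"),
        covariate_sets=((), ("age", "iq")),
    )
    pd.concat([f.to_frame() for f in fits.values()], ignore_index=True).to_csv(
        OUT / "fits.csv", index=False
    )
    m1, m2 = fits["adjustment"], fits["aon_vs_comp"]
    (OUT / "table2_style.md").write_text(model_table_markdown(m1, m2))
    (OUT / "contrasts.md").write_text(contrasts_markdown(m2))

    print("\nstrategy model (all-or-nothing vs compromise):")
    for fe in m2.fixed_effects:
        print(f"  {fe.term}: OR {fe.odds_ratio:.2f} "
              f"[{fe.or_ci_low:.2f}, {fe.or_ci_high:.2f}], p = {fe.p:.4f}")
    print(f"  tau00 = {m2.tau00:.2f}, latent ICC = {m2.icc:.2f}, "
          f"R2 = {m2.r2_marginal:.3f}/{m2.r2_conditional:.3f}")
    print(f"  group factor: LR chi2({m2.lr_group_df}) = {m2.lr_group_chi2:.2f}, "
          f"p = {m2.lr_group_p:.4f}")
    print("\nTukey contrasts (link scale):")
    for c in m2.contrasts:
        print(f"  {c.pair[0]} - {c.pair[1]}: {c.estimate:+.2f}, "
              f"p_adj = {c.p_adjusted:.3f}")
    for coding in ("stay_vs_rest", "copy_vs_rest"):
        f = fits[coding]
        print(f"\n{coding}: LR chi2({f.lr_group_df}) = {f.lr_group_chi2:.2f}, "
              f"p = {f.lr_group_p:.3f}")
    mc = fits["aon_vs_comp+age+iq"]
    print(f"\nage/IQ-adjusted strategy model: LR chi2({mc.lr_group_df}) = "
          f"{mc.lr_group_chi2:.2f}, p = {mc.lr_group_p:.4f}")
    print(f"\nwrote fits.csv, table2_style.md, contrasts.md in {OUT}/")


if __name__ == "__main__":
    main()
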