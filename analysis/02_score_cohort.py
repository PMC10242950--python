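"""Score the simulated cohort: adjustment weights, strategy labels, exclusions.

Reads results/cohort.csv, computes s = (E2-E1)/(X-E1) per round, labels
stay/copy/compromise (or the invalid categories), applies the >= 3 invalid
rounds exclusion rule, and writes the scored table, exclusion log,
participant summaries and the group strategy-frequency table.
"""

from pathlib import Path

from beastlab.core_model import load_cohort, write_exclusion_log
from beastlab.scoring import (
    filter_participants,
    score_cohort,
    strategy_table,
    summarize_cohort,
    write_scored,
    write_summaries,
)

OUT = Path("results")


def main() -> None:
    scored = score_cohort(load_cohort(OUT / "cohort.csv"))
    retained, report = filter_participants(scored)
    write_scored(scored, OUT / "scored.csv")
    write_exclusion_log(retained, OUT / "exclusions.csv")
    write_summaries(summarize_cohort(retained), OUT / "summaries.csv")
    table = strategy_table(retained)
    table.to_csv(OUT / "strategy_table.csv", index=False)

    print(f"retained {report.n_retained}/{report.n_input} participants; "
          f"{report.n_rounds_valid}/{report.n_rounds_total} valid rounds")
    if report.invalid_round_counts:
        print(f"invalid rounds by type: {report.invalid_round_counts}")
    print("\nround-level strategy shares (percent of valid rounds):")
    shares = table[table.label == "compromise"][["group", "n_rounds", "pct_of_valid"]]
    for _, row in shares.iterrows():
        print(f"  {row.group}: compromise {row.pct_of_valid:.1f}% "
              f"({row.n_rounds} rounds)")
    print(f"\nwrote scored.csv, exclusions.csv, summaries.csv, "
          f"strategy_table.csv in {OUT}/")


if __name__ == "__main__":
    main()
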