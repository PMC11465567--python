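#!/usr/bin/env python
"""Per-treatment accounting of the simulated study, against the shipped
full-scale reference counts.

Runs the whole pipeline (best-fit-per-spectrum consolidation, blank-noise
correction, random-spectrum Monte Carlo correction, score thresholds) and
writes the per-treatment accounting table in the same layout as the
reference study summary, plus that reference table's own totals and derived
acceptance percentages.  Writes results/accounting_simulated.tsv and
results/accounting_reference.tsv.
"""

from pathlib import Path

from trypstat.pipeline import Config, accounting_report, run_pipeline
from trypstat.reference import reference_accounting, reference_engine_totals

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    reference = accounting_report(reference_accounting())
    reference.to_csv(RESULTS / "accounting_reference.tsv", sep="\t", index=False)
    total = reference[reference["treatment"] == "Total"].iloc[0]
    print("reference full-scale study:")
    print(f"  {total['msms_count']:,} MS/MS over {total['ms_runs']} runs; "
          f"{total['matched_distinct_spectra']:,} matched distinct spectra; "
          f"{total['score_accepted']:,} accepted "
          f"({total['accepted_pct_msms']}% of MS/MS)")
    engines = reference_engine_totals().set_index("engine")
    for engine in ("GOF", "XCORR"):
        pct = 100 * engines.loc[engine, "score_accepted"] / engines.loc[engine, "msms_count"]
        print(f"  {engine}: {engines.loc[engine, 'score_accepted']:,} accepted "
              f"({pct:.1f}% of MS/MS)")

    result = run_pipeline(Config(), seed=SEED)
    acc = result.manifest.accounting
    acc.to_csv(RESULTS / "accounting_simulated.tsv", sep="\t", index=False)
    print("\nsimulated study (default reduced scale):")
    print(acc.to_string(index=False))
    audit = result.consolidated["GOF"].audit
    print(f"\nBFPS: {audit['input']:,} candidate rows -> "
          f"{audit['selected']:,} spectra ({audit['discarded']:,} redundant "
          "candidates discarded); every spectrum now supports one peptide")
    print("wrote results/accounting_simulated.tsv, accounting_reference.tsv")


if __name__ == "__main__":
    main()
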