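#!/usr/bin/env python
"""Ground-truth validation of the corrected inference, and the albumin
suppression readout.

Scores the pipeline against the simulator's per-spectrum truth (protein
recovery at q <= 0.01, false-symbol fraction, blank-filter noise removal,
giant-protein removal by the Monte Carlo filter), then measures the albumin
spectral-count ratio between trypsin-alone and reduced+alkylated digestion
across 10 seeds and compares it with the full-scale reference counts.
Writes results/recovery_metrics.tsv and results/albumin_ratio.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from trypstat.pipeline import Config, recovery_metrics, run_pipeline
from trypstat.reference import reference_albumin_counts
from trypstat.simulate import SimParams, TreatmentDesign, albumin_ratio_t_dat

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    result = run_pipeline(Config(), seed=SEED)
    metrics = recovery_metrics(result)
    pd.DataFrame([metrics]).T.rename(columns={0: "value"}).to_csv(
        RESULTS / "recovery_metrics.tsv", sep="\t"
    )
    print(f"true proteins with >=3 sampled peptides: "
          f"{metrics['n_true_proteins_ge_3_peptides']}")
    print(f"recovered at n>=3 peptides and q<=0.01: {metrics['n_recovered']} "
          f"({metrics['recovery_rate']:.1%})")
    print(f"false symbols among recoveries: "
          f"{metrics['false_symbol_fraction']:.2%}")
    print(f"noise-only peptides removed by blank filter: "
          f"{metrics['noise_removal_rate']:.1%} of "
          f"{metrics['noise_peptides_present']}")
    print(f"giant symbols reaching the Monte Carlo filter: "
          f"{metrics['giants_before_random_filter']}; surviving: "
          f"{metrics['giants_recovered']}")

    params, design = SimParams(), TreatmentDesign()
    rows = []
    for seed in range(SEED, SEED + 10):
        ratio = albumin_ratio_t_dat(params, design, seed)
        rows.append({"seed": seed, "t_dat_ratio": ratio})
    table = pd.DataFrame(rows)
    counts = reference_albumin_counts().set_index("treatment")
    ref_ratio = counts.loc["T", "gof_count"] / counts.loc["DAT", "gof_count"]
    table.to_csv(RESULTS / "albumin_ratio.tsv", sep="\t", index=False)
    print(f"\nalbumin T:DAT spectral-count ratio, simulated: "
          f"{table['t_dat_ratio'].mean():.3f} "
          f"(range {table['t_dat_ratio'].min():.3f}-"
          f"{table['t_dat_ratio'].max():.3f} over 10 seeds)")
    print(f"reference full-scale counts give {ref_ratio:.3f} (~30%)")
    print("wrote results/recovery_metrics.tsv, albumin_ratio.tsv")


if __name__ == "__main__":
    main()
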