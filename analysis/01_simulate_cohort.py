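"""Generate the synthetic pneumonia-like cohort used by the downstream steps.

Five subjects x 200 clones with the default pattern mix (50% P1A interstitium-
to-airway, 20% P1B lung-restricted, 30% P2 blood-interstitium), written to
scratch/cohort/ (bulky per-cell files) with a small summary in results/.
"""

from pathlib import Path

import pandas as pd

import cloneshare as cs

ROOT = Path(__file__).resolve().parents[1]
SEED = 2026


def main() -> None:
    outdir = ROOT / "scratch" / "cohort"
    cohort = cs.simulate_cohort(cs.SimulationConfig(), seed=SEED, outdir=outdir)
    truth = cohort.truth

    sizes = truth.clones.groupby("subject_id")["size"]
    summary = pd.DataFrame({
        "n_clones": sizes.size(),
        "n_cells": sizes.sum(),
        "n_expanded_clones": truth.clones[truth.clones["size"] >= 2]
        .groupby("subject_id").size(),
        "max_clone_size": sizes.max(),
    })
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "cohort_summary.tsv", sep="\t")
    print(f"cohort written to {outdir}")
    print(summary.to_string())
    mix = truth.clones["pattern"].value_counts(normalize=True).round(3)
    print(f"clone pattern mix (all clones, incl. singletons):\n{mix.to_string()}")


if __name__ == "__main__":
    main()
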