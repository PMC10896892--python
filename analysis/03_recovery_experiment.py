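#!/usr/bin/env python
"""Parameter-recovery experiment across seeded replicates.

Nine traits, three of which truly drive the death hazard, n = 2,000 per
replicate.  For each seed: does the Cox screen keep the causal traits (and
little else)?  Do the three largest elastic-net mixing weights land on the
causal traits?  Does the metaPRS beat the best single PRS on a held-out
cohort?  Writes results/recovery.tsv and prints the success fractions.
"""

import os

import pandas as pd

from metaprs.experiments import run_recovery_replicate

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
N_SEEDS = 20


def main() -> None:
    rows = [run_recovery_replicate(seed) for seed in range(1, N_SEEDS + 1)]
    table = pd.DataFrame(rows)
    os.makedirs(OUT, exist_ok=True)
    table.to_csv(os.path.join(OUT, "recovery.tsv"), sep="\t", index=False)
    print(table.to_string(index=False, float_format="%.3f"))
    print(
        f"\nscreen kept all causal traits: "
        f"{table['causal_retained'].mean():.0%} of {N_SEEDS} seeds "
        f"(mean null traits retained {table['n_null_retained'].mean():.2f})"
    )
    print(
        f"top-3 |mixing weights| on causal traits: "
        f"{table['top_mix_on_causal'].mean():.0%}"
    )
    wins = (table["heldout_auc_meta"] > table["heldout_auc_best_single"]).mean()
    print(f"held-out metaPRS beats best single PRS: {wins:.0%}")


if __name__ == "__main__":
    main()
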