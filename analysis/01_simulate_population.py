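#!/usr/bin/env python
"""Step 1: simulate a panmictic population and its MAG-degraded twin.

Writes one genome FASTA per member plus metadata under results/01_populations/:
`isolates/` holds the un-degraded genomes, `mags/` the same genomes after
consensus collapse (f=0.5), variable-family loss (q=0.2, p=0.5), and no extra
completeness loss. Downstream steps read these directories.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from magne.experiment import undegraded_family_diversity
from magne.io import write_genomes, write_json
from magne.simulate import (
    DegradationConfig,
    SimulationConfig,
    degrade_to_mag,
    simulate_population,
)
from magne._rng import child_seed

RESULTS = Path(__file__).resolve().parents[1] / "results" / "01_populations"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=RESULTS)
    args = parser.parse_args()

    sim = SimulationConfig(
        n_genomes=10, n_families=200, codons_per_family=300,
        theta4=0.02, seed=child_seed(args.seed, "simulate"),
    )
    genomes, truth = simulate_population(sim)
    write_genomes(genomes, args.out / "isolates")
    write_json(
        {
            "true_theta4": truth.true_theta4,
            "genealogy": truth.genealogy_used,
            "mean_realized_pi": sum(truth.per_family_true_pi) / len(truth.per_family_true_pi),
            "seed": truth.seed,
        },
        args.out / "isolates" / "truth.json",
    )

    deg = DegradationConfig(
        consensus_collapse_fraction=0.5,
        variable_loss_quantile=0.2,
        variable_loss_prob=0.5,
        target_completeness=1.0,
        seed=child_seed(args.seed, "degrade"),
    )
    fam_div = undegraded_family_diversity(genomes)
    mags = degrade_to_mag(genomes, deg, fam_div)
    write_genomes(mags, args.out / "mags")

    print(f"wrote {len(genomes)} isolates and {len(mags)} MAGs under {args.out}")


if __name__ == "__main__":
    main()
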