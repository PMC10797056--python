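#!/usr/bin/env python
"""Step 2: estimate neutral diversity and Ne for the step-1 populations.

For each class (isolates, MAGs) this runs the full estimation pipeline:
single-copy ortholog families -> codon-aware alignment -> pi_s at
fourfold-degenerate sites -> Ne = pi_s / (2 mu). Writes a per-family diversity
table and a one-row population summary per class under results/02_ne/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from magne.diversity import DEFAULT_MU
from magne.experiment import estimate_population_ne
from magne.io import read_genomes, sig

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="indir", type=Path,
                        default=ROOT / "results" / "01_populations")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "02_ne")
    parser.add_argument("--mu", type=float, default=DEFAULT_MU)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    for cls in ("isolates", "mags"):
        genomes = read_genomes(args.indir / cls)
        result = estimate_population_ne(genomes, mu=args.mu, population_id=cls)
        est = result.estimate

        fam_rows = [
            {
                "family_id": e.family_id,
                "n_fourfold_sites": e.n_fourfold_sites,
                "pi_s": sig(e.pi_s, 6),
            }
            for e in sorted(result.per_family, key=lambda e: e.family_id)
        ]
        pd.DataFrame(fam_rows).to_csv(
            args.out / f"{cls}_family_diversity.tsv", sep="\t", index=False
        )

        summary_rows.append(
            {
                "class": cls,
                "n_genomes": len(genomes),
                "n_families_used": est.n_families_used,
                "n_families_zero": est.n_families_zero,
                "median_pi_s": sig(est.median_pi_s, 6),
                "mean_pi_s": sig(est.mean_pi_s, 6),
                "mu": f"{args.mu:g}",
                "ne_median": sig(est.ne_median, 3),
                "ne_mean": sig(est.ne_mean, 3),
                "mean_ani": sig(result.ani.mean_offdiagonal(), 6),
            }
        )
        print(f"{cls}: median pi_s={est.median_pi_s:.6g}  Ne={est.ne_median:.4g}")

    pd.DataFrame(summary_rows).to_csv(args.out / "ne_summary.tsv", sep="\t", index=False)
    print(f"wrote {args.out}/ne_summary.tsv")


if __name__ == "__main__":
    main()
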