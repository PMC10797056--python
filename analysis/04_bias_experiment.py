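#!/usr/bin/env python
"""Step 4: the isolate-vs-MAG bias experiment.

Runs three replicate studies:

  degraded   - MAG class gets consensus collapse f=0.5 and variable-family
               loss q=0.2, p=0.5; 20 replicate studies, 10 populations/class.
  null       - no degradation; checks the comparison's false-positive rate.
  regression - populations spread across a theta4 grid; isolate-class OLS of
               Ne on whole-genome divergence (100 - ANI%).

Writes per-population rows, per-study statistics, and JSON summaries under
results/04_bias/. Pass --plot to also write scatter/box figures (requires
matplotlib; off by default so the default run produces text only).
"""

from __future__ import annotations

import argparse
from pathlib import Path

from magne._rng import child_seed
from magne.experiment import ExperimentConfig, run_bias_study, write_experiment
from magne.simulate import DegradationConfig

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "04_bias")
    parser.add_argument("--plot", action="store_true",
                        help="also write PNG figures (requires matplotlib)")
    args = parser.parse_args()

    runs = {
        "degraded": ExperimentConfig(
            n_populations_per_class=10,
            degradation=DegradationConfig(0.5, 0.2, 0.5, 1.0),
            replicates=20,
            seed=child_seed(args.seed, "degraded"),
        ),
        "null": ExperimentConfig(
            n_populations_per_class=10,
            degradation=DegradationConfig(0.0, 0.0, 0.0, 1.0),
            replicates=20,
            seed=child_seed(args.seed, "null"),
        ),
        "regression": ExperimentConfig(
            n_populations_per_class=12,
            degradation=DegradationConfig(0.0, 0.0, 0.0, 1.0),
            theta4_grid=(0.005, 0.01, 0.02, 0.04),
            replicates=1,
            seed=child_seed(args.seed, "regression"),
        ),
    }

    results = {}
    for name, cfg in runs.items():
        print(f"running {name} ...", flush=True)
        res = run_bias_study(cfg)
        write_experiment(res, args.out / name)
        results[name] = res
        for key, val in sorted(res.summary.items()):
            print(f"  {key}: {val}")

    reg_row = results["regression"].stats.iloc[0]
    print(
        f"  isolate regression: slope={reg_row['isolate_slope']:.4g} "
        f"R2={reg_row['isolate_r2']:.3f} p={reg_row['isolate_reg_p']:.3g}"
    )

    if args.plot:
        plot(results, args.out)


def plot(results: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = results["degraded"].rows
    fig, ax = plt.subplots(figsize=(5, 4))
    data = [rows[rows.source_class == c]["bias"] for c in ("isolate", "MAG")]
    ax.boxplot(data, tick_labels=["isolate", "MAG"])
    ax.axhline(1.0, ls="--", c="grey")
    ax.set_ylabel("Ne bias (estimate / truth)")
    fig.tight_layout()
    fig.savefig(outdir / "bias_by_class.png", dpi=150)

    reg = results["regression"].rows
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, marker in (("isolate", "o"), ("MAG", "x")):
        part = reg[reg.source_class == cls]
        ax.scatter(part["divergence"], part["ne_median"], marker=marker, label=cls)
    ax.set_xlabel("whole-genome divergence (100 - ANI%)")
    ax.set_ylabel("Ne (median)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "ne_vs_divergence.png", dpi=150)
    print(f"wrote figures under {outdir}")


if __name__ == "__main__":
    main()
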