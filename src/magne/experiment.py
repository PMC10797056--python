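"""The isolate-vs-MAG simulation study and its comparative statistics.

Each replicate study simulates matched sets of panmictic populations, leaves
one set as isolates, degrades the other into MAG-like genomes, runs both
through the same family -> codon alignment -> pi_s -> Ne pipeline, and then
compares the two classes: a Mann-Whitney U test on Ne, and an ordinary
least-squares regression of Ne on whole-genome divergence (100 - ANI%) per
class. Simulated populations are exchangeable by construction, so there is no
phylogenetic signal to correct for and the rank test applies directly;
tree-based comparative statistics are deliberately out of scope.

The per-population bias is ne_median / ne_true with ne_true = theta4/(2*mu)
using the same mu as the estimator, so bias isolates pipeline effects from
mutation-rate misspecification.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_seed
from .diversity import (
    DEFAULT_MU,
    DiversityEstimate,
    NoDefinedFamiliesError,
    PopulationNeEstimate,
    estimate_ne,
    family_diversity,
    fourfold_mask,
    pi_s,
    population_ne,
)
from .families import GenomeRecord, build_codon_alignment, families_from_genomes
from .populations import ANIMatrix, ani_matrix
from .simulate import DegradationConfig, SimulationConfig, degrade_to_mag, simulate_population

logger = logging.getLogger("magne")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def estimated_genome_size(
    assembly_size: float, completeness_pct: float, contamination_pct: float
) -> float:
    """Assembly size divided by (completeness + contamination), percents in."""
    if not 0.0 < completeness_pct <= 100.0:
        raise ValueError(f"completeness must be in (0, 100], got {completeness_pct}")
    if contamination_pct < 0.0:
        raise ValueError(f"contamination must be >= 0, got {contamination_pct}")
    denom = (completeness_pct + contamination_pct) / 100.0
    if denom == 0.0:
        raise ValueError("completeness + contamination must be positive")
    return assembly_size / denom


@lru_cache(maxsize=None)
def _u_counts(n_x: int, n_y: int) -> tuple[int, ...]:
    """Null distribution counts of the Mann-Whitney U statistic.

    Classical recurrence: c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u).
    """
    table: dict[tuple[int, int], list[int]] = {}
    for i in range(n_x + 1):
        for j in range(n_y + 1):
            if i == 0 or j == 0:
                table[(i, j)] = [1]
                continue
            counts = [0] * (i * j + 1)
            for u, c in enumerate(table[(i - 1, j)]):
                counts[u + j] += c
            for u, c in enumerate(table[(i, j - 1)]):
                counts[u] += c
            table[(i, j)] = counts
    return tuple(table[(n_x, n_y)])


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of x, p-value).

    The p-value is exact (full null enumeration via the counting recurrence)
    when there are no ties and n_x + n_y <= 16; otherwise the tie-corrected
    normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n_x, n_y = len(x), len(y)

    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0)

    if not has_ties and n_x + n_y <= 16:
        counts = np.array(_u_counts(n_x, n_y), dtype=float)
        total = counts.sum()
        u = int(round(u_x))
        p_le = counts[: u + 1].sum() / total
        p_ge = counts[u:].sum() / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        return u_x, float(p)

    if np.all(pooled == pooled[0]):
        return u_x, 1.0  # no information, no separation
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    ok: bool = True


def regress_ne_on_divergence(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of Ne on divergence (100 - ANI%); p from the slope t-statistic."""
    if len(points) < 3:
        raise ValueError("regression requires at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0.0:
        logger.warning("zero variance in divergence; regression undefined")
        return RegressionResult(math.nan, math.nan, math.nan, math.nan, len(points), ok=False)
    if np.ptp(y) == 0.0:
        # constant response: zero slope explains all (zero) variance
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(points))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(points),
    )


# ---------------------------------------------------------------------------
# Pipeline over one population of genomes
# ---------------------------------------------------------------------------

@dataclass
class PopulationResult:
    estimate: PopulationNeEstimate
    per_family: list[DiversityEstimate]
    ani: ANIMatrix

    @property
    def divergence(self) -> float:
        return 100.0 - self.ani.mean_offdiagonal()


def estimate_population_ne(
    genomes: Sequence[GenomeRecord],
    mu: float = DEFAULT_MU,
    population_id: str = "population",
    jc69: bool = False,
) -> PopulationResult:
    """Full pipeline: families -> codon alignments -> pi_s -> median/mean Ne + ANI."""
    fams = [f for f in families_from_genomes(genomes) if f.single_copy]
    estimates = []
    alignments = []
    for fam in fams:
        aln = build_codon_alignment(fam, method="auto")
        if aln is None:
            continue
        alignments.append(aln)
        estimates.append(pi_s(aln, fourfold_mask(aln), jc69=jc69))
    est = population_ne(
        estimates, mu=mu, population_id=population_id, member_ids=[g.genome_id for g in genomes]
    )
    ani = ani_matrix(genomes)
    return PopulationResult(estimate=est, per_family=estimates, ani=ani)


def undegraded_family_diversity(genomes: Sequence[GenomeRecord]) -> dict[str, float]:
    """Per-family pi_s on the un-degraded genome set (input to degradation)."""
    fams = [f for f in families_from_genomes(genomes) if f.single_copy]
    alignments = [a for a in (build_codon_alignment(f, "auto") for f in fams) if a is not None]
    return dict(family_diversity(alignments))


# ---------------------------------------------------------------------------
# Replicate studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    n_populations_per_class: int = 10
    sim_template: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_genomes=6, n_families=50, codons_per_family=150
        )
    )
    degradation: DegradationConfig = field(default_factory=DegradationConfig)
    # Populations within a study share one theta4 by default so the pooled
    # Mann-Whitney compares exchangeable samples (its null requires
    # identically distributed groups). Pass several values to spread
    # populations across diversities, e.g. for the Ne-vs-divergence
    # regression; the pooled rank test is then a mixture comparison and its
    # p-value is conservative.
    theta4_grid: tuple[float, ...] = (0.02,)
    replicates: int = 1
    mu: float = DEFAULT_MU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_populations_per_class < 1:
            raise ValueError("n_populations_per_class must be >= 1")


@dataclass
class ExperimentResult:
    rows: pd.DataFrame  # one row per population instance
    stats: pd.DataFrame  # one row per replicate study
    summary: dict


def run_bias_study(config: ExperimentConfig) -> ExperimentResult:
    """Run the replicate isolate-vs-MAG studies defined by ``config``."""
    rows = []
    stat_rows = []
    grid = config.theta4_grid
    for rep in range(config.replicates):
        for cls_idx, cls in enumerate(("isolate", "MAG")):
            for i in range(config.n_populations_per_class):
                theta4 = grid[i % len(grid)]
                sim_cfg = replace(
                    config.sim_template,
                    theta4=theta4,
                    seed=child_seed(config.seed, "pop", rep, cls_idx, i),
                )
                genomes, _ = simulate_population(sim_cfg)
                if cls == "MAG":
                    fam_div = undegraded_family_diversity(genomes)
                    dcfg = replace(
                        config.degradation, seed=child_seed(config.seed, "degrade", rep, i)
                    )
                    genomes = degrade_to_mag(genomes, dcfg, fam_div)
                pop_id = f"{'I' if cls == 'isolate' else 'M'}-{rep}-{i}"
                try:
                    result = estimate_population_ne(genomes, mu=config.mu, population_id=pop_id)
                except NoDefinedFamiliesError:
                    logger.warning("population %s excluded: no defined families", pop_id)
                    continue
                ne_true = estimate_ne(theta4, config.mu)
                est = result.estimate
                rows.append(
                    {
                        "replicate": rep,
                        "population_id": pop_id,
                        "source_class": cls,
                        "true_theta4": theta4,
                        "divergence": result.divergence,
                        "median_pi_s": est.median_pi_s,
                        "mean_pi_s": est.mean_pi_s,
                        "ne_median": est.ne_median,
                        "ne_mean": est.ne_mean,
                        "ne_true": ne_true,
                        "bias": est.ne_median / ne_true,
                        "n_families_used": est.n_families_used,
                        "n_families_zero": est.n_families_zero,
                    }
                )
    df = pd.DataFrame(rows)

    for rep in range(config.replicates):
        sub = df[df["replicate"] == rep]
        iso = sub[sub["source_class"] == "isolate"]
        mag = sub[sub["source_class"] == "MAG"]
        if iso.empty or mag.empty:
            continue
        u, p = mann_whitney_u(iso["ne_median"].to_numpy(), mag["ne_median"].to_numpy())
        u_mean, p_mean = mann_whitney_u(iso["ne_mean"].to_numpy(), mag["ne_mean"].to_numpy())
        # divergence-matched comparison: populations are paired by theta4 slot
        k = min(len(iso), len(mag))
        paired_diff = float(
            np.mean(iso["ne_median"].to_numpy()[:k] - mag["ne_median"].to_numpy()[:k])
        )
        reg_rows = {}
        for cls, part in (("isolate", iso), ("MAG", mag)):
            if len(part) >= 3 and np.ptp(part["divergence"].to_numpy()) > 0:
                reg = regress_ne_on_divergence(
                    list(zip(part["divergence"], part["ne_median"]))
                )
            else:
                reg = RegressionResult(math.nan, math.nan, math.nan, math.nan, len(part), ok=False)
            reg_rows[cls] = reg
        stat_rows.append(
            {
                "replicate": rep,
                "u_median": u,
                "p_median": p,
                "u_mean": u_mean,
                "p_mean": p_mean,
                "paired_mean_diff": paired_diff,
                "mean_bias_isolate": float(iso["bias"].mean()),
                "mean_bias_mag": float(mag["bias"].mean()),
                "isolate_slope": reg_rows["isolate"].slope,
                "isolate_r2": reg_rows["isolate"].r_squared,
                "isolate_reg_p": reg_rows["isolate"].p_value,
                "mag_slope": reg_rows["MAG"].slope,
                "mag_r2": reg_rows["MAG"].r_squared,
                "mag_reg_p": reg_rows["MAG"].p_value,
            }
        )
    stats_df = pd.DataFrame(stat_rows)

    summary = {}
    if not stats_df.empty:
        detect = (stats_df["p_median"] < 0.05) & (
            stats_df["mean_bias_isolate"] > stats_df["mean_bias_mag"]
        )
        summary = {
            "replicates": int(len(stats_df)),
            "mean_bias_isolate": float(stats_df["mean_bias_isolate"].mean()),
            "mean_bias_mag": float(stats_df["mean_bias_mag"].mean()),
            "frac_replicates_mag_bias_lt_1": float(
                (stats_df["mean_bias_mag"] < 1.0).mean()
            ),
            "frac_replicates_p_lt_0.05": float((stats_df["p_median"] < 0.05).mean()),
            "detection_rate_isolate_gt_mag": float(detect.mean()),
            "median_p": float(stats_df["p_median"].median()),
        }
    return ExperimentResult(rows=df, stats=stats_df, summary=summary)


def write_experiment(result: ExperimentResult, outdir) -> None:
    """experiment_results.tsv + experiment_stats.tsv + experiment_summary.json."""
    from pathlib import Path

    from .io import sig, write_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = result.rows.copy()
    for col in ("median_pi_s", "mean_pi_s"):
        rows[col] = rows[col].map(lambda v: sig(v, 6))
    for col in ("ne_median", "ne_mean", "ne_true", "bias"):
        rows[col] = rows[col].map(lambda v: sig(v, 3))
    rows["divergence"] = rows["divergence"].map(lambda v: sig(v, 6))
    rows.to_csv(outdir / "experiment_results.tsv", sep="\t", index=False)
    result.stats.to_csv(
        outdir / "experiment_stats.tsv", sep="\t", index=False, float_format="%.6g"
    )
    write_json(result.summary, outdir / "experiment_summary.json")
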