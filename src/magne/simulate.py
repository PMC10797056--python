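"""Synthetic panmictic populations and MAG-like genome degradation.

The generator emulates the input a direct Ne estimator expects: a set of
closely related genomes sharing single-copy gene families of codon sequences,
with neutral diversity concentrated at fourfold-degenerate third positions
(target pairwise diversity ``theta4``) and reduced diversity at constrained
positions. The degradation operator then turns such genomes into MAG-like
ones via the two mechanisms hypothesized to bias Ne downward: per-genome
consensus allele collapse (metagenomic assemblies report the most abundant
variant) and preferential loss of the most diverse gene families (mobile,
frequently transferred segments rarely survive binning), plus random
completeness loss.

Under the default star genealogy each tip mutates independently from a common
ancestor. With per-branch substitution probability b at an eligible site and
a uniform choice among the three alternative bases, two tips differ with
probability 2b - (4/3) b^2; the generator inverts this exactly,
b = 3/4 * (1 - sqrt(1 - 4*theta4/3)), so the expected pairwise difference per
eligible site equals theta4 without small-theta error. A Kingman coalescent
genealogy is available for realism: the realized tree is rescaled so the mean
pairwise coalescence time is one, and branches then mutate at rate theta4/2
per site (last-write-wins along root-to-tip paths).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._codons import (
    FOURFOLD_CODON_IDX,
    FOURFOLD_PREFIX_IDX,
    INDEX_TO_BASE,
    SENSE_CODON_IDX,
    STOP_CODON_IDX,
)
from ._rng import child_rng
from .families import GenomeRecord


@dataclass(frozen=True)
class SimulationConfig:
    n_genomes: int = 10
    n_families: int = 200
    codons_per_family: int = 300
    theta4: float = 0.02  # target expected pairwise diversity per fourfold site
    constrained_rate_ratio: float = 0.1  # diversity multiplier at non-fourfold positions
    genealogy: str = "star"  # "star" or "coalescent"
    min_fourfold_fraction: float = 0.4  # ancestor codons drawn from fourfold families
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genomes", "n_families", "codons_per_family"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.theta4 < 0.5:
            raise ValueError(
                f"theta4 must be in [0, 0.5) (pairwise diversity saturates), got {self.theta4}"
            )
        if not 0.0 <= self.constrained_rate_ratio <= 1.0:
            raise ValueError("constrained_rate_ratio must be in [0, 1]")
        if self.genealogy not in ("star", "coalescent"):
            raise ValueError(f"genealogy must be 'star' or 'coalescent', got {self.genealogy!r}")
        if not 0.0 <= self.min_fourfold_fraction <= 1.0:
            raise ValueError("min_fourfold_fraction must be in [0, 1]")
        if self.codons_per_family < 10:
            warnings.warn(
                "codons_per_family < 10 yields very few fourfold sites per family",
                stacklevel=2,
            )


@dataclass
class TruthRecord:
    true_theta4: float
    per_family_true_pi: list[float]  # realized pairwise diversity at eligible sites
    genealogy_used: str
    seed: int


@dataclass(frozen=True)
class DegradationConfig:
    consensus_collapse_fraction: float = 0.5  # f: segregating columns collapsed per genome
    variable_loss_quantile: float = 0.2  # q: top diversity quantile eligible for loss
    variable_loss_prob: float = 0.5  # p: per-genome loss probability for those families
    target_completeness: float = 1.0  # c: retained family fraction after random loss
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "consensus_collapse_fraction",
            "variable_loss_quantile",
            "variable_loss_prob",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.target_completeness <= 1.0:
            raise ValueError("target_completeness must be in (0, 1]")

    @property
    def is_noop(self) -> bool:
        return (
            self.consensus_collapse_fraction == 0.0
            and self.variable_loss_prob == 0.0
            and self.target_completeness == 1.0
        )


def branch_substitution_prob(theta: float) -> float:
    """Per-branch substitution probability giving expected pairwise diff theta.

    Inverts E[diff] = 2b(1-b) + (2/3)b^2 for two tips mutating independently
    with uniform choice among the three alternative bases.
    """
    if not 0.0 <= theta < 0.75:
        raise ValueError(f"theta out of invertible range [0, 0.75): {theta}")
    return 0.75 * (1.0 - math.sqrt(1.0 - 4.0 * theta / 3.0))


def _draw_ancestor(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(total_codons, 3) base-index array of the ancestral genome."""
    total = cfg.n_families * cfg.codons_per_family
    from_ff = rng.random(total) < cfg.min_fourfold_fraction
    codons = np.empty((total, 3), dtype=np.uint8)
    n_ff = int(from_ff.sum())
    codons[from_ff] = FOURFOLD_CODON_IDX[rng.integers(0, len(FOURFOLD_CODON_IDX), n_ff)]
    codons[~from_ff] = SENSE_CODON_IDX[rng.integers(0, len(SENSE_CODON_IDX), total - n_ff)]
    return codons


def _apply_constrained(
    codons: np.ndarray,
    flat_positions: np.ndarray,
    offsets: np.ndarray,
) -> None:
    """Apply constrained-position substitutions in place, skipping stops.

    For each hit the proposed base is old + 1 + k (mod 4); if the resulting
    codon would be a stop, the other two alternatives are tried in order.
    """
    flat = codons.reshape(-1)
    for pos, k in zip(flat_positions, offsets):
        codon_i, within = divmod(int(pos), 3)
        old = int(flat[pos])
        for dk in range(3):
            new = (old + 1 + (int(k) + dk) % 3) % 4
            trial = codons[codon_i].copy()
            trial[within] = new
            if (int(trial[0]), int(trial[1]), int(trial[2])) not in STOP_CODON_IDX:
                flat[pos] = new
                break


def _mutate_branch(
    codons: np.ndarray,
    neutral_sites: np.ndarray,
    constrained_sites: np.ndarray,
    p_neutral: float,
    p_constrained: float,
    rng: np.random.Generator,
) -> np.ndarray:
    tip = codons.copy()
    flat = tip.reshape(-1)
    if p_neutral > 0 and len(neutral_sites):
        hits = neutral_sites[rng.random(len(neutral_sites)) < p_neutral]
        if len(hits):
            k = rng.integers(1, 4, len(hits)).astype(np.uint8)
            flat[hits] = (flat[hits] + k) % 4
    if p_constrained > 0 and len(constrained_sites):
        mask = rng.random(len(constrained_sites)) < p_constrained
        hits = constrained_sites[mask]
        if len(hits):
            k = rng.integers(0, 3, len(hits))
            _apply_constrained(tip, hits, k)
    return tip


def _kingman_tree(n: int, rng: np.random.Generator):
    """Random Kingman genealogy; returns (parent, branch_len, children, tmrca).

    Times are in coalescent units; the caller rescales so that the mean
    pairwise coalescence time over all tip pairs equals one.
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, 2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    branch_len = np.zeros(n_nodes)
    for v in range(n_nodes - 1):
        branch_len[v] = node_time[parent[v]] - node_time[v]
    # pairwise tMRCA via ancestor sets (n is small)
    ancestors = []
    for tip in range(n):
        chain = {}
        v = tip
        while v != -1:
            chain[v] = node_time[v]
            v = parent[v]
        ancestors.append(chain)
    times = []
    for i in range(n):
        for j in range(i + 1, n):
            common = [node_time[v] for v in ancestors[i] if v in ancestors[j]]
            times.append(min(common))
    return parent, branch_len, float(np.mean(times))


def simulate_population(config: SimulationConfig) -> tuple[list[GenomeRecord], TruthRecord]:
    """Generate a panmictic population with known neutral diversity.

    Returns the genomes (CDS keyed by family ID, no internal stop codons) and
    a :class:`TruthRecord` holding the realized per-family pairwise diversity
    at the eligible (ancestrally fourfold) third positions.
    """
    cfg = config
    ancestor = _draw_ancestor(cfg, child_rng(cfg.seed, "ancestor"))
    total = ancestor.shape[0]

    ff_codon = np.array(
        [(int(c[0]), int(c[1])) in FOURFOLD_PREFIX_IDX for c in ancestor], dtype=bool
    )
    flat_idx = np.arange(total * 3)
    within = flat_idx % 3
    codon_of = flat_idx // 3
    neutral_sites = flat_idx[(within == 2) & ff_codon[codon_of]]
    constrained_sites = flat_idx[~((within == 2) & ff_codon[codon_of])]

    b = branch_substitution_prob(cfg.theta4)
    b_c = branch_substitution_prob(cfg.theta4 * cfg.constrained_rate_ratio)

    tips = []
    if cfg.genealogy == "star":
        for g in range(cfg.n_genomes):
            rng = child_rng(cfg.seed, "tip", g)
            tips.append(
                _mutate_branch(ancestor, neutral_sites, constrained_sites, b, b_c, rng)
            )
    else:
        if cfg.n_genomes == 1:
            tips.append(ancestor.copy())
        else:
            tree_rng = child_rng(cfg.seed, "tree")
            parent, branch_len, mean_pair_time = _kingman_tree(cfg.n_genomes, tree_rng)
            scale = 1.0 / mean_pair_time if mean_pair_time > 0 else 0.0
            rate_n = cfg.theta4 / 2.0
            rate_c = cfg.theta4 * cfg.constrained_rate_ratio / 2.0
            n_nodes = 2 * cfg.n_genomes - 1
            seqs: list[np.ndarray | None] = [None] * n_nodes
            seqs[n_nodes - 1] = ancestor
            for v in range(n_nodes - 2, -1, -1):
                rng = child_rng(cfg.seed, "branch", v)
                t = branch_len[v] * scale
                seqs[v] = _mutate_branch(
                    seqs[parent[v]],
                    neutral_sites,
                    constrained_sites,
                    min(rate_n * t, 0.75),
                    min(rate_c * t, 0.75),
                    rng,
                )
            tips = [seqs[g] for g in range(cfg.n_genomes)]

    stack = np.stack(tips)  # (n_genomes, total, 3)

    # realized per-family diversity at eligible third positions
    per_family_pi: list[float] = []
    n = cfg.n_genomes
    n_pairs = n * (n - 1) // 2
    third = stack[:, :, 2]
    for f in range(cfg.n_families):
        lo, hi = f * cfg.codons_per_family, (f + 1) * cfg.codons_per_family
        cols = np.flatnonzero(ff_codon[lo:hi]) + lo
        if len(cols) == 0 or n < 2:
            per_family_pi.append(float("nan"))
            continue
        sub = third[:, cols]
        counts = np.stack([(sub == v).sum(axis=0) for v in range(4)])
        same = (counts * (counts - 1) // 2).sum(axis=0)
        diffs = (n_pairs - same).sum()
        per_family_pi.append(float(diffs / (n_pairs * len(cols))))

    width = max(3, len(str(cfg.n_genomes - 1)))
    fwidth = max(4, len(str(cfg.n_families - 1)))
    genomes = []
    for g in range(cfg.n_genomes):
        bases = INDEX_TO_BASE[stack[g].reshape(-1)]
        cds = {}
        for f in range(cfg.n_families):
            lo, hi = f * cfg.codons_per_family * 3, (f + 1) * cfg.codons_per_family * 3
            cds[f"F{f:0{fwidth}d}"] = bases[lo:hi].tobytes().decode("ascii")
        genomes.append(
            GenomeRecord(
                genome_id=f"G{g:0{width}d}",
                source_class="isolate",
                cds=cds,
                completeness=100.0,
                contamination=0.0,
            )
        )
    truth = TruthRecord(
        true_theta4=cfg.theta4,
        per_family_true_pi=per_family_pi,
        genealogy_used=cfg.genealogy,
        seed=cfg.seed,
    )
    return genomes, truth


def degrade_to_mag(
    genomes: Sequence[GenomeRecord],
    dconfig: DegradationConfig,
    family_diversity: Mapping[str, float],
) -> list[GenomeRecord]:
    """Degrade isolate-like genomes into MAG-like ones.

    Three operators, applied in order with independent seeded streams:

    1. consensus collapse — per genome, a fraction f of segregating alignment
       columns (across all shared families) has the genome's allele replaced
       by the population-wide majority allele (ties toward the alphabetically
       smallest base);
    2. variable-segment loss — the top q-quantile most diverse families
       (ranked by ``family_diversity``, computed on the un-degraded set) are
       deleted from each genome independently with probability p;
    3. completeness loss — further families are deleted uniformly at random
       per genome until the retained fraction is at most c.

    With f = p = 0 and c = 1 the output sequences are byte-identical copies.
    """
    if not genomes:
        raise ValueError("degrade_to_mag requires at least one genome")
    fam_ids = list(genomes[0].cds)
    for g in genomes:
        if list(g.cds) != fam_ids:
            raise ValueError("genomes must share the same family structure")

    from ._codons import encode

    f = dconfig.consensus_collapse_fraction
    mats: dict[str, np.ndarray] = {}
    majority: dict[str, np.ndarray] = {}
    seg_registry: list[tuple[str, int]] = []
    if f > 0:
        for fid in fam_ids:
            lengths = {len(g.cds[fid]) for g in genomes}
            if len(lengths) != 1:
                raise ValueError(f"family {fid}: members differ in length; collapse undefined")
            mat = np.stack([_ASCII_IDX[encode(g.cds[fid])] for g in genomes])
            if (mat == 255).any():
                raise ValueError(
                    f"family {fid}: consensus collapse requires unambiguous A/C/G/T sequences"
                )
            counts = np.stack([(mat == v).sum(axis=0) for v in range(4)])
            maj = counts.argmax(axis=0).astype(np.uint8)  # argmax ties -> smallest base
            seg = counts.max(axis=0) < len(genomes)
            mats[fid] = mat
            majority[fid] = maj
            seg_registry.extend((fid, int(c)) for c in np.flatnonzero(seg))

    q, p = dconfig.variable_loss_quantile, dconfig.variable_loss_prob
    k_top = int(round(q * len(fam_ids)))
    ranked = sorted(
        fam_ids,
        key=lambda fid: (-_diversity_key(family_diversity.get(fid)), fid),
    )
    top_families = set(ranked[:k_top]) if p > 0 else set()

    n_orig = len(fam_ids)
    target_retained = math.floor(dconfig.target_completeness * n_orig)

    out = []
    for gi, g in enumerate(genomes):
        cds = dict(g.cds)
        if f > 0 and seg_registry:
            rng = child_rng(dconfig.seed, "collapse", gi)
            n_pick = int(round(f * len(seg_registry)))
            picked = rng.choice(len(seg_registry), size=n_pick, replace=False)
            by_family: dict[str, list[int]] = {}
            for idx in sorted(picked):
                fid, col = seg_registry[idx]
                by_family.setdefault(fid, []).append(col)
            for fid, cols in by_family.items():
                arr = mats[fid][gi].copy()
                arr[cols] = majority[fid][cols]
                cds[fid] = INDEX_TO_BASE[arr].tobytes().decode("ascii")

        if top_families:
            rng = child_rng(dconfig.seed, "varloss", gi)
            drops = rng.random(len(ranked[:k_top])) < p
            for fid, drop in zip(ranked[:k_top], drops):
                if drop:
                    cds.pop(fid, None)

        retained = list(cds)
        if len(retained) > target_retained:
            rng = child_rng(dconfig.seed, "completeness", gi)
            n_drop = len(retained) - target_retained
            drop_idx = rng.choice(len(retained), size=n_drop, replace=False)
            for idx in sorted(drop_idx, reverse=True):
                cds.pop(retained[idx])

        out.append(
            GenomeRecord(
                genome_id=g.genome_id,
                source_class="MAG",
                cds=cds,
                completeness=100.0 * len(cds) / n_orig,
                contamination=g.contamination,
            )
        )
    return out


def _diversity_key(value: float | None) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return -math.inf
    return float(value)


# ASCII -> base-index map shared with degrade_to_mag
_ASCII_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ASCII_IDX[ord(_b)] = _i
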