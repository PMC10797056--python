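"""Synonymous diversity at fourfold-degenerate sites and Ne estimation.

The neutral diversity of a population, pi_s, is the mean pairwise difference
proportion among its genomes at fourfold-degenerate third codon positions of
single-copy ortholog families. Under neutral equilibrium pi_s = 2 * Ne * mu,
so Ne = pi_s / (2 * mu), with mu the spontaneous mutation rate per site per
cell division measured by mutation-accumulation experiments.

A third-position alignment column is counted as fourfold only when, in every
row, the codon is gap-free and unambiguous, belongs to one of the eight
fourfold codon families of the standard code, and its first two positions are
identical across rows — a strict rule that guarantees any third-position
change is synonymous in every sequence. Columns with a gap or N in any row
are dropped entirely (complete deletion), keeping the site count shared
across all genome pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._codons import BASE_TO_INDEX, FOURFOLD_PREFIX_IDX
from .families import CodonAlignment

logger = logging.getLogger("magne")

#: Spontaneous mutation rate (base substitutions per cell division per site)
#: measured for Thermococcus eurythermalis A501; the package default.
DEFAULT_MU = 71.57e-10

_ASCII_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_TO_INDEX.items():
    _ASCII_TO_INDEX[ord(_b)] = _i

_FF_PREFIX_LOOKUP = np.zeros((4, 4), dtype=bool)
for _p0, _p1 in FOURFOLD_PREFIX_IDX:
    _FF_PREFIX_LOOKUP[_p0, _p1] = True


@dataclass
class FourfoldSiteMask:
    family_id: str
    columns: list[int]  # 0-based alignment column indices, each ≡ 2 (mod 3)

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class DiversityEstimate:
    family_id: str
    pi_s: float  # NaN when undefined
    n_sequences: int
    n_fourfold_sites: int

    @property
    def defined(self) -> bool:
        return self.n_fourfold_sites > 0


@dataclass
class MutationRate:
    mu: float  # base substitutions per cell division per nucleotide site

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mutation rate must be positive, got {self.mu}")


@dataclass
class PopulationNeEstimate:
    population_id: str
    member_ids: list[str]
    median_pi_s: float
    mean_pi_s: float
    mu: float
    ne_median: float
    ne_mean: float
    n_families_used: int
    n_families_zero: int


class NoDefinedFamiliesError(ValueError):
    """Every family in the population had an empty fourfold mask."""


def fourfold_mask(alignment: CodonAlignment) -> FourfoldSiteMask:
    """Fourfold-degenerate third-position columns usable for pi_s."""
    mat = _ASCII_TO_INDEX[alignment.matrix()]  # (n, L); 255 marks gap/ambiguous
    n, length = mat.shape
    codons = mat.reshape(n, length // 3, 3)
    valid = (codons < 4).all(axis=(0, 2))  # gap-free, unambiguous in every row
    p0 = codons[:, :, 0]
    p1 = codons[:, :, 1]
    conserved = (p0 == p0[0]).all(axis=0) & (p1 == p1[0]).all(axis=0)
    ok = valid & conserved
    ok[ok] &= _FF_PREFIX_LOOKUP[p0[0, ok].astype(np.intp) % 4, p1[0, ok].astype(np.intp) % 4]
    cols = [3 * int(c) + 2 for c in np.flatnonzero(ok)]
    return FourfoldSiteMask(family_id=alignment.family_id, columns=cols)


def pi_s(
    alignment: CodonAlignment,
    mask: FourfoldSiteMask | None = None,
    jc69: bool = False,
) -> DiversityEstimate:
    """Per-family pi_s: mean pairwise difference proportion on masked columns.

    pi_s = sum over unordered genome pairs of per-pair differences, divided by
    C(n, 2) * L4. No sample-size factor is applied; an optional Jukes-Cantor
    correction (off by default) maps the proportion through
    -3/4 * ln(1 - 4p/3).
    """
    if mask is None:
        mask = fourfold_mask(alignment)
    n = alignment.n_rows
    if n < 2:
        raise ValueError(f"family {alignment.family_id}: pi_s requires >= 2 sequences")
    l4 = len(mask)
    if l4 == 0:
        return DiversityEstimate(alignment.family_id, float("nan"), n, 0)
    mat = alignment.matrix()[:, mask.columns]
    # sum of pairwise differences per column = C(n,2) - sum_b C(count_b, 2)
    n_pairs = n * (n - 1) // 2
    total_diffs = 0
    counts = np.zeros((4, l4), dtype=np.int64)
    idx = _ASCII_TO_INDEX[mat]
    for b in range(4):
        counts[b] = (idx == b).sum(axis=0)
    same = (counts * (counts - 1) // 2).sum(axis=0)
    total_diffs = int((n_pairs - same).sum())
    p = total_diffs / (n_pairs * l4)
    if jc69:
        if p >= 0.75:
            raise ValueError("pi_s saturated; Jukes-Cantor correction undefined")
        p = -0.75 * math.log1p(-4.0 * p / 3.0)
    return DiversityEstimate(alignment.family_id, p, n, l4)


def aggregate_population(estimates: Iterable[DiversityEstimate]) -> tuple[float, float]:
    """(median, mean) pi_s over defined per-family estimates.

    Zero-diversity families count; families with an empty mask are excluded.
    The even-count median is the midpoint of the two central values.
    """
    values = [e.pi_s for e in estimates if e.defined]
    if not values:
        raise NoDefinedFamiliesError("no family had a non-empty fourfold mask")
    return float(np.median(values)), float(np.mean(values))


def estimate_ne(pi: float, mu: float | MutationRate) -> float:
    """Ne = pi_s / (2 * mu)."""
    if isinstance(mu, MutationRate):
        mu = mu.mu
    if not mu > 0:
        raise ValueError(f"mutation rate must be positive, got {mu}")
    if pi < 0:
        raise ValueError(f"pi must be non-negative, got {pi}")
    return pi / (2.0 * mu)


def population_ne(
    estimates: Sequence[DiversityEstimate],
    mu: float = DEFAULT_MU,
    population_id: str = "population",
    member_ids: Sequence[str] = (),
) -> PopulationNeEstimate:
    """Aggregate per-family estimates into the population-level Ne record."""
    median_pi, mean_pi = aggregate_population(estimates)
    defined = [e for e in estimates if e.defined]
    return PopulationNeEstimate(
        population_id=population_id,
        member_ids=list(member_ids),
        median_pi_s=median_pi,
        mean_pi_s=mean_pi,
        mu=mu,
        ne_median=estimate_ne(median_pi, mu),
        ne_mean=estimate_ne(mean_pi, mu),
        n_families_used=len(defined),
        n_families_zero=sum(1 for e in defined if e.pi_s == 0.0),
    )


def family_diversity(alignments: Iterable[CodonAlignment], jc69: bool = False) -> Mapping[str, float]:
    """family_id -> pi_s for ranking families by diversity (NaN when undefined)."""
    return {aln.family_id: pi_s(aln, jc69=jc69).pi_s for aln in alignments}
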