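"""Population delineation from average nucleotide identity (ANI).

Genomes are grouped into preliminary clusters by single-linkage connectivity
at ANI >= 90% (roughly the species floor), then near-identical members —
pairwise nucleotide divergence (100 - ANI%)/100 below 0.0355% — are collapsed
into clonal complexes, each represented by a single genome, because redundant
near-clones depress pi_s and hence Ne. Only populations with at least two
non-redundant members are retained for Ne estimation.

The built-in ANI is an alignment-based stand-in ("ANI-lite"): identity over
the codon alignments of shared single-copy families, length-weighted. A
pre-computed ANI table (e.g. from FastANI) or an external membership table
can be supplied instead through the I/O layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .families import CodonAlignment, GeneFamily, GenomeRecord, build_codon_alignment

logger = logging.getLogger("magne")

ANI_CLUSTER_THRESHOLD = 90.0  # percent
CLONAL_DIVERGENCE_THRESHOLD = 0.000355  # divergence fraction, i.e. 0.0355%

_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID[_b] = True


@dataclass
class ANIMatrix:
    genome_ids: list[str]
    values: np.ndarray  # symmetric percent matrix, diagonal 100

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValueError("ANI matrix shape does not match genome_ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("ANI matrix must be symmetric")

    def ani(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.values[i, j])

    def mean_offdiagonal(self) -> float:
        n = len(self.genome_ids)
        iu = np.triu_indices(n, k=1)
        vals = self.values[iu]
        return float(np.nanmean(vals)) if len(vals) else float("nan")


@dataclass
class PopulationAssignment:
    population_id: str
    members: list[str]
    clonal_complexes: list[list[str]]
    representatives: list[str]
    retained: bool  # >= 2 non-redundant members


def ani_from_alignments(
    alignments: Iterable[CodonAlignment], genome_ids: Sequence[str]
) -> ANIMatrix:
    """Length-weighted ANI over family alignments, skipping gap/N columns."""
    ids = list(genome_ids)
    n = len(ids)
    match = np.zeros((n, n))
    compared = np.zeros((n, n))
    for aln in alignments:
        present = [g for g in ids if g in aln.rows]
        if len(present) < 2:
            continue
        mat = aln.matrix()
        order = {g: k for k, g in enumerate(aln.rows)}
        valid = _VALID[mat]
        for a_i in range(len(present)):
            for b_i in range(a_i + 1, len(present)):
                ga, gb = present[a_i], present[b_i]
                ra, rb = mat[order[ga]], mat[order[gb]]
                both = valid[order[ga]] & valid[order[gb]]
                i, j = ids.index(ga), ids.index(gb)
                compared[i, j] += both.sum()
                match[i, j] += ((ra == rb) & both).sum()
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            if compared[i, j] > 0:
                values[i, j] = values[j, i] = 100.0 * match[i, j] / compared[i, j]
            else:
                logger.warning("no shared aligned columns for %s vs %s", ids[i], ids[j])
    return ANIMatrix(genome_ids=ids, values=values)


def pairwise_ani_lite(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    shared_families: Sequence[GeneFamily] | None = None,
) -> float:
    """ANI percent between two genomes over their shared single-copy families."""
    if shared_families is None:
        from .families import families_from_genomes

        shared_families = [
            fam for fam in families_from_genomes([genome_a, genome_b]) if fam.single_copy
        ]
    alignments = []
    for fam in shared_families:
        aln = build_codon_alignment(fam, method="auto")
        if aln is not None:
            alignments.append(aln)
    if not alignments:
        raise ValueError(
            f"no alignable shared single-copy families between "
            f"{genome_a.genome_id} and {genome_b.genome_id}"
        )
    m = ani_from_alignments(alignments, [genome_a.genome_id, genome_b.genome_id])
    return float(m.values[0, 1])


def ani_matrix(genomes: Sequence[GenomeRecord]) -> ANIMatrix:
    """ANI-lite matrix over all genomes from their shared single-copy families."""
    from .families import families_from_genomes

    ids = [g.genome_id for g in genomes]
    alignments = []
    for fam in families_from_genomes(genomes):
        members = {gid: seq for gid, seq in fam.members.items()}
        if len(members) < 2:
            continue
        aln = build_codon_alignment(
            GeneFamily(fam.family_id, members, single_copy=True), method="auto"
        )
        if aln is not None:
            alignments.append(aln)
    return ani_from_alignments(alignments, ids)


def cluster_preliminary(ani: ANIMatrix, threshold: float = ANI_CLUSTER_THRESHOLD) -> list[list[str]]:
    """Single-linkage clusters: connected components of the ANI >= threshold graph.

    Undefined (NaN) pairs count as below threshold. Clusters and members are
    sorted for deterministic output; the result is a partition.
    """
    vals = np.where(np.isnan(ani.values), -np.inf, ani.values)
    adj = vals >= threshold
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: dict[int, list[str]] = {}
    for gid, lab in zip(ani.genome_ids, labels):
        clusters.setdefault(int(lab), []).append(gid)
    out = [sorted(members) for members in clusters.values()]
    return sorted(out, key=lambda c: c[0])


def collapse_clonal_complexes(
    members: Sequence[str],
    ani: ANIMatrix,
    completeness: Mapping[str, float],
    population_id: str = "population",
    divergence_threshold: float = CLONAL_DIVERGENCE_THRESHOLD,
) -> PopulationAssignment:
    """Collapse clonal complexes and pick one representative per complex.

    Complexes are connected components of the graph with edges where pairwise
    divergence (100 - ANI%)/100 is below the threshold. The representative is
    the member with the highest completeness (ties broken toward the
    lexicographically smallest genome ID). A population is retained only when
    at least two representatives (non-redundant members) remain.
    """
    idx = [ani.genome_ids.index(m) for m in members]
    sub = ani.values[np.ix_(idx, idx)]
    divergence = (100.0 - np.where(np.isnan(sub), -np.inf, sub)) / 100.0
    adj = divergence < divergence_threshold
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    complexes: dict[int, list[str]] = {}
    for m, lab in zip(members, labels):
        complexes.setdefault(int(lab), []).append(m)
    complex_list = sorted((sorted(c) for c in complexes.values()), key=lambda c: c[0])
    reps = [
        min(c, key=lambda m: (-float(completeness.get(m, 0.0)), m)) for c in complex_list
    ]
    return PopulationAssignment(
        population_id=population_id,
        members=sorted(members),
        clonal_complexes=complex_list,
        representatives=sorted(reps),
        retained=len(reps) >= 2,
    )


def delineate_populations(
    ani: ANIMatrix,
    completeness: Mapping[str, float],
    ani_threshold: float = ANI_CLUSTER_THRESHOLD,
    divergence_threshold: float = CLONAL_DIVERGENCE_THRESHOLD,
) -> list[PopulationAssignment]:
    """Full ANI-lite delineation: preliminary clusters, then dereplication."""
    assignments = []
    for k, cluster in enumerate(cluster_preliminary(ani, ani_threshold), start=1):
        assignments.append(
            collapse_clonal_complexes(
                cluster,
                ani,
                completeness,
                population_id=f"P{k}",
                divergence_threshold=divergence_threshold,
            )
        )
    return assignments
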