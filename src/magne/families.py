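"""Single-copy ortholog families and codon-aware alignment.

The pipeline aligns each family at the amino-acid level and threads the
protein alignment back onto the nucleotide sequences, so that every alignment
column is a whole codon. Gene prediction and orthology inference are consumed
as inputs (a family membership table, or family-tagged FASTA headers); the
bespoke computation starts here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._codons import BASES, STOP_CODONS

logger = logging.getLogger("magne")

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TranslationError(ValueError):
    """CDS cannot be translated cleanly; carries a short machine-readable reason."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass
class GenomeRecord:
    """One genome (isolate or MAG) with its coding sequences and quality stats."""

    genome_id: str
    source_class: str  # "isolate" or "MAG"
    cds: dict[str, str]  # family or gene ID -> nucleotide sequence
    completeness: float = 100.0  # percent
    contamination: float = 0.0  # percent
    assembly_size: int = 0

    def __post_init__(self) -> None:
        if self.source_class not in ("isolate", "MAG"):
            raise ValueError(f"source_class must be 'isolate' or 'MAG', got {self.source_class!r}")
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness must be in [0, 100], got {self.completeness}")
        if self.contamination < 0.0:
            raise ValueError(f"contamination must be >= 0, got {self.contamination}")
        if self.assembly_size == 0:
            self.assembly_size = sum(len(s) for s in self.cds.values())


@dataclass
class GeneFamily:
    family_id: str
    members: dict[str, str]  # genome_id -> CDS (only populated for single-copy members)
    single_copy: bool
    gene_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class CodonAlignment:
    """In-frame aligned nucleotide matrix for one family.

    Rows are equal length, the length is divisible by 3, gaps occur only in
    whole-codon triplets, and degapping any row reproduces its input CDS.
    """

    family_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"family {self.family_id}: aligned rows differ in length")
        if self.length % 3:
            raise ValueError(f"family {self.family_id}: alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        """(n_rows, length) uint8 ASCII matrix in row insertion order."""
        return np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in self.rows.values()])


def translate(cds: str) -> str:
    """Translate a CDS under the standard code; the trailing stop is stripped.

    Raises :class:`TranslationError` with reason ``frame`` (length not a
    multiple of 3) or ``internal_stop`` so callers can exclude the member and
    log why, mirroring quality filtering of pseudogenes.
    """
    if len(cds) % 3:
        raise TranslationError("frame", f"CDS length {len(cds)} not divisible by 3")
    if not cds:
        raise TranslationError("frame", "empty CDS")
    protein = str(Seq(cds).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise TranslationError("internal_stop", "internal stop codon in CDS")
    return protein


def _validate_cds_fast(cds: str) -> bool:
    """Frame/stop check without Biopython overhead (A/C/G/T sequences only)."""
    if not cds or len(cds) % 3:
        return False
    limit = len(cds) - 3  # trailing stop is allowed
    for stop in STOP_CODONS:
        idx = cds.find(stop)
        while 0 <= idx < limit:
            if idx % 3 == 0:
                return False
            idx = cds.find(stop, idx + 1)
    return True


def load_family_table(
    table: str | Path | pd.DataFrame, genomes: Sequence[GenomeRecord]
) -> list[GeneFamily]:
    """Build gene families from an ortholog membership TSV.

    The table has a ``family_id`` column and one column per genome holding
    gene IDs (comma-separated for paralogs, empty when absent). A family is
    single-copy iff every genome contributes exactly one gene. A gene ID that
    does not exist in its genome's CDS set is a hard error.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t", dtype=str)
    by_id = {g.genome_id: g for g in genomes}
    missing = [gid for gid in by_id if gid not in table.columns]
    if missing:
        raise ValueError(f"family table lacks columns for genomes: {missing}")
    families = []
    for _, row in table.iterrows():
        fam_id = str(row["family_id"])
        gene_ids: dict[str, tuple[str, ...]] = {}
        members: dict[str, str] = {}
        single = True
        for gid, genome in by_id.items():
            cell = row[gid]
            genes = tuple(
                g.strip() for g in str(cell).split(",") if g.strip() and str(cell) != "nan"
            )
            gene_ids[gid] = genes
            for gene in genes:
                if gene not in genome.cds:
                    raise KeyError(
                        f"family {fam_id}: gene {gene!r} not found in genome {gid!r}"
                    )
            if len(genes) == 1:
                members[gid] = genome.cds[genes[0]]
            else:
                single = False
        if not single:
            members = {}
        families.append(
            GeneFamily(family_id=fam_id, members=members, single_copy=single, gene_ids=gene_ids)
        )
    return families


def families_from_genomes(genomes: Sequence[GenomeRecord]) -> list[GeneFamily]:
    """Families implied by family-keyed CDS maps (the synthetic-data layout).

    Each genome's CDS map is keyed by family ID, so within-genome copy number
    is always one; a family is single-copy iff it is present in every genome.
    """
    fam_ids: list[str] = []
    seen = set()
    for g in genomes:
        for fid in g.cds:
            if fid not in seen:
                seen.add(fid)
                fam_ids.append(fid)
    families = []
    for fid in fam_ids:
        members = {g.genome_id: g.cds[fid] for g in genomes if fid in g.cds}
        single = len(members) == len(genomes)
        families.append(
            GeneFamily(
                family_id=fid,
                members=members,
                single_copy=single,
                gene_ids={gid: (fid,) for gid in members},
            )
        )
    return families


# ---------------------------------------------------------------------------
# Protein alignment: affine-gap Needleman-Wunsch (Gotoh) on profiles,
# progressive along a UPGMA guide order for more than two sequences.
# ---------------------------------------------------------------------------

_NEG = -1e30


def _profile_columns(rows: list[str]) -> list[tuple[str, ...]]:
    return [tuple(col) for col in zip(*rows)]


def _column_score(col_a: tuple[str, ...], col_b: tuple[str, ...]) -> float:
    """Mean BLOSUM62 score over residue pairs; pairs involving a gap score 0."""
    total = 0.0
    for a in col_a:
        if a == "-":
            continue
        for b in col_b:
            if b == "-":
                continue
            total += _BLOSUM62[a, b]
    return total / (len(col_a) * len(col_b))


def _argmax_tiebreak(*values: float) -> int:
    """Index of the maximum; earlier arguments win ties.

    Argument order encodes the preference match/mismatch > gap-in-first >
    gap-in-second, making the traceback deterministic.
    """
    best, best_i = values[0], 0
    for i, v in enumerate(values[1:], start=1):
        if v > best:
            best, best_i = v, i
    return best_i


def _gotoh_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Globally align two alignment profiles with affine gaps (Gotoh)."""
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    n, m = len(cols_a), len(cols_b)

    score = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            score[i, j] = _column_score(cols_a[i], cols_b[j])

    # state 0 = M (column vs column), 1 = X (gap in first profile),
    # 2 = Y (gap in second profile)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    tb = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = -(GAP_OPEN + GAP_EXTEND * j)
        tb[1, 0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        Y[i, 0] = -(GAP_OPEN + GAP_EXTEND * i)
        tb[2, i, 0] = 0 if i == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = _argmax_tiebreak(*cand)
            M[i, j] = cand[k] + score[i - 1, j - 1]
            tb[0, i, j] = k

            cand = (
                M[i, j - 1] - GAP_OPEN - GAP_EXTEND,
                X[i, j - 1] - GAP_EXTEND,
                Y[i, j - 1] - GAP_OPEN - GAP_EXTEND,
            )
            k = _argmax_tiebreak(*cand)
            X[i, j] = cand[k]
            tb[1, i, j] = k

            cand = (
                M[i - 1, j] - GAP_OPEN - GAP_EXTEND,
                X[i - 1, j] - GAP_OPEN - GAP_EXTEND,
                Y[i - 1, j] - GAP_EXTEND,
            )
            k = _argmax_tiebreak(*cand)
            Y[i, j] = cand[k]
            tb[2, i, j] = k

    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = n, m
    state = _argmax_tiebreak(M[n, m], X[n, m], Y[n, m])
    while i > 0 or j > 0:
        prev = tb[state, i, j]
        if state == 0:
            for k in range(len(rows_a)):
                out_a[k].append(cols_a[i - 1][k])
            for k in range(len(rows_b)):
                out_b[k].append(cols_b[j - 1][k])
            i, j = i - 1, j - 1
        elif state == 1:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k in range(len(rows_b)):
                out_b[k].append(cols_b[j - 1][k])
            j -= 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(cols_a[i - 1][k])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            i -= 1
        state = int(prev)
    return ["".join(reversed(r)) for r in out_a], ["".join(reversed(r)) for r in out_b]


def align_proteins(seqs: Mapping[str, str]) -> dict[str, str]:
    """Globally align protein sequences (BLOSUM62, gap open 10 / extend 0.5).

    Two sequences are aligned directly; more are aligned progressively,
    merging profiles in UPGMA order of pairwise p-distances.
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("align_proteins requires at least 2 sequences")
    for name, s in seqs.items():
        if not s:
            raise ValueError(f"empty protein sequence for {name!r}")
    if len(set(seqs.values())) == 1:
        return dict(seqs)  # identical sequences: gapless by construction

    if len(ids) == 2:
        a, b = _gotoh_profiles([seqs[ids[0]]], [seqs[ids[1]]])
        return {ids[0]: a[0], ids[1]: b[0]}

    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = _gotoh_profiles([seqs[ids[i]]], [seqs[ids[j]]])
            pairs = [(x, y) for x, y in zip(ra[0], rb[0]) if x != "-" and y != "-"]
            mism = sum(1 for x, y in pairs if x != y)
            dist[i, j] = dist[j, i] = mism / max(len(pairs), 1)
    z = linkage(squareform(dist, checks=False), method="average")

    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(n)
    }
    for k, (left, right, _, _) in enumerate(z):
        ids_l, rows_l = profiles.pop(int(left))
        ids_r, rows_r = profiles.pop(int(right))
        new_l, new_r = _gotoh_profiles(rows_l, rows_r)
        profiles[n + k] = (ids_l + ids_r, new_l + new_r)
    final_ids, final_rows = profiles.popitem()[1]
    aligned = dict(zip(final_ids, final_rows))
    return {name: aligned[name] for name in ids}


def protein_alignment_score(row_a: str, row_b: str) -> float:
    """Score of a pairwise protein alignment under the module's scheme.

    Gap runs cost ``open + extend * length``; used by tests against an
    exhaustive-search oracle.
    """
    score = 0.0
    in_gap_a = in_gap_b = False
    for a, b in zip(row_a, row_b):
        if a == "-" and b == "-":
            raise ValueError("double-gap column")
        if a == "-":
            score -= (GAP_OPEN + GAP_EXTEND) if not in_gap_a else GAP_EXTEND
            in_gap_a, in_gap_b = True, False
        elif b == "-":
            score -= (GAP_OPEN + GAP_EXTEND) if not in_gap_b else GAP_EXTEND
            in_gap_b, in_gap_a = True, False
        else:
            score += _BLOSUM62[a, b]
            in_gap_a = in_gap_b = False
    return score


def backthread(aa_alignment: Mapping[str, str], cds_map: Mapping[str, str]) -> CodonAlignment:
    """Impose an amino-acid alignment onto the underlying nucleotide CDSs.

    Every amino-acid column expands to one codon column; a protein gap becomes
    ``---``. The translation of each CDS must equal its degapped protein row.
    A trailing stop codon in the CDS is dropped (it has no aligned residue).
    """
    rows: dict[str, str] = {}
    for name, aa_row in aa_alignment.items():
        cds = cds_map[name]
        protein = translate(cds)
        if aa_row.replace("-", "") != protein:
            raise ValueError(
                f"{name}: protein alignment row does not match the CDS translation"
            )
        codons = [cds[3 * i : 3 * i + 3] for i in range(len(protein))]
        out = []
        k = 0
        for aa in aa_row:
            if aa == "-":
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        rows[name] = "".join(out)
    return CodonAlignment(family_id="", rows=rows)


def build_codon_alignment(family: GeneFamily, method: str = "auto") -> CodonAlignment | None:
    """Codon alignment for a single-copy family.

    Members failing the frame/stop checks are excluded (with a logged reason);
    the family is dropped (returns None) if fewer than two members survive.

    ``method="auto"`` stacks equal-length CDSs gaplessly — orthologs from the
    synthetic generator are indel-free, so their alignment is the identity —
    and falls back to the protein-alignment route when lengths differ.
    ``method="nw"`` always aligns; ``method="gapless"`` requires equal lengths.
    """
    valid: dict[str, str] = {}
    for gid, cds in family.members.items():
        if _validate_cds_fast(cds):
            valid[gid] = cds
        else:
            try:
                translate(cds)
                valid[gid] = cds
            except TranslationError as exc:
                logger.info(
                    "family %s: excluding %s (%s)", family.family_id, gid, exc.reason
                )
    if len(valid) < 2:
        logger.info("family %s: fewer than 2 valid members, dropped", family.family_id)
        return None

    lengths = {len(s) for s in valid.values()}
    if method == "gapless" and len(lengths) != 1:
        raise ValueError(f"family {family.family_id}: unequal CDS lengths for gapless stacking")
    if method in ("auto", "gapless") and len(lengths) == 1:
        aln = CodonAlignment(family_id=family.family_id, rows=dict(valid))
        return aln

    proteins = {gid: translate(cds) for gid, cds in valid.items()}
    aa_aln = align_proteins(proteins)
    cds_trimmed = {gid: valid[gid][: 3 * len(proteins[gid])] for gid in valid}
    aln = backthread(aa_aln, cds_trimmed)
    aln.family_id = family.family_id
    return aln
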