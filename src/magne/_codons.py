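"""Standard genetic-code constants shared across modules.

Bases are encoded as uint8 indices in alphabetical order (A=0, C=1, G=2, T=3)
so that ``np.argmax`` over per-base counts breaks majority ties toward the
alphabetically smallest base.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}
INDEX_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {TAA, TAG, TGA}

SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))

# Fourfold-degenerate codon families: the third position is free because the
# first two bases determine the amino acid (Ala GCN, Arg CGN, Gly GGN, Leu CTN,
# Pro CCN, Ser TCN, Thr ACN, Val GTN). 8 families, 32 codons.
FOURFOLD_PREFIXES = frozenset({"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"})
FOURFOLD_CODONS = tuple(sorted(p + b for p in FOURFOLD_PREFIXES for b in BASES))


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 ASCII array (no base-index translation)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def codon_index_array(codons: tuple[str, ...]) -> np.ndarray:
    """(n_codons, 3) array of base indices for a tuple of codon strings."""
    return np.array([[BASE_TO_INDEX[b] for b in c] for c in codons], dtype=np.uint8)


SENSE_CODON_IDX = codon_index_array(SENSE_CODONS)
FOURFOLD_CODON_IDX = codon_index_array(FOURFOLD_CODONS)
STOP_CODON_IDX = {tuple(BASE_TO_INDEX[b] for b in c) for c in STOP_CODONS}
FOURFOLD_PREFIX_IDX = {
    (BASE_TO_INDEX[p[0]], BASE_TO_INDEX[p[1]]) for p in FOURFOLD_PREFIXES
}


def is_stop_idx(codon: np.ndarray) -> bool:
    return (int(codon[0]), int(codon[1]), int(codon[2])) in STOP_CODON_IDX
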