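"""Translation, protein alignment, and codon back-threading."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magne.families import (
    GeneFamily,
    GenomeRecord,
    TranslationError,
    align_proteins,
    backthread,
    build_codon_alignment,
    families_from_genomes,
    load_family_table,
    protein_alignment_score,
    translate,
)

from conftest import SENSE_CODONS, random_cds


# --- translation -----------------------------------------------------------

def test_translate_strips_trailing_stop():
    assert translate("ATGGCTTAA") == "MA"
    assert translate("ATGGCT") == "MA"


@pytest.mark.parametrize(
    "cds,reason",
    [("ATGGC", "frame"), ("ATGTAAGCT", "internal_stop"), ("", "frame")],
)
def test_translate_rejects_bad_cds(cds, reason):
    with pytest.raises(TranslationError) as exc:
        translate(cds)
    assert exc.value.reason == reason


# --- family table ----------------------------------------------------------

def _toy_genomes():
    return [
        GenomeRecord("gA", "isolate", {"a1": "ATGGCT", "a2": "ATGCCT"}),
        GenomeRecord("gB", "isolate", {"b1": "ATGGCA"}),
        GenomeRecord("gC", "isolate", {"c1": "ATGGCG"}),
    ]


def test_family_table_single_copy_classification():
    genomes = _toy_genomes()
    table = pd.DataFrame(
        [
            {"family_id": "F1", "gA": "a1", "gB": "b1", "gC": "c1"},  # single copy
            {"family_id": "F2", "gA": "a1,a2", "gB": "b1", "gC": "c1"},  # paralogs in gA
            {"family_id": "F3", "gA": "a1", "gB": "b1", "gC": ""},  # absent from gC
        ]
    )
    fams = {f.family_id: f for f in load_family_table(table, genomes)}
    assert fams["F1"].single_copy
    assert fams["F1"].members == {"gA": "ATGGCT", "gB": "ATGGCA", "gC": "ATGGCG"}
    assert not fams["F2"].single_copy
    assert not fams["F3"].single_copy


def test_family_table_unknown_gene_is_hard_error():
    genomes = _toy_genomes()
    table = pd.DataFrame([{"family_id": "F1", "gA": "missing", "gB": "b1", "gC": "c1"}])
    with pytest.raises(KeyError, match="missing.*gA|gA.*missing"):
        load_family_table(table, genomes)


def test_families_from_headers_presence_rule():
    genomes = [
        GenomeRecord("g1", "isolate", {"F1": "ATGGCT", "F2": "ATGCCT"}),
        GenomeRecord("g2", "isolate", {"F1": "ATGGCA"}),
    ]
    fams = {f.family_id: f for f in families_from_genomes(genomes)}
    assert fams["F1"].single_copy
    assert not fams["F2"].single_copy


# --- protein alignment -----------------------------------------------------

def test_identical_proteins_align_gapless():
    aligned = align_proteins({"a": "MKVLW", "b": "MKVLW", "c": "MKVLW"})
    assert set(aligned.values()) == {"MKVLW"}


def test_known_single_gap_alignment():
    aligned = align_proteins({"x": "MKV", "y": "MV"})
    assert aligned == {"x": "MKV", "y": "M-V"}


def test_pairwise_alignment_symmetric_under_input_order(rng):
    for _ in range(5):
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 12))
        b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 9))
        fwd = align_proteins({"a": a, "b": b})
        rev = align_proteins({"b": b, "a": a})
        assert protein_alignment_score(fwd["a"], fwd["b"]) == pytest.approx(
            protein_alignment_score(rev["a"], rev["b"])
        )


def _enumerate_alignments(a: str, b: str):
    """Every global alignment of a and b (no double-gap columns)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


@pytest.mark.parametrize("lengths", [(3, 2), (4, 4), (5, 3), (6, 6), (8, 7)])
def test_alignment_score_matches_exhaustive_optimum(rng, lengths):
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(alphabet, lengths[0]))
    b = "".join(rng.choice(alphabet, lengths[1]))
    aligned = align_proteins({"a": a, "b": b})
    got = protein_alignment_score(aligned["a"], aligned["b"])
    best = max(
        protein_alignment_score(ra, rb) for ra, rb in _enumerate_alignments(a, b)
    )
    assert got == pytest.approx(best, abs=1e-9)


def test_empty_protein_rejected():
    with pytest.raises(ValueError, match="empty|2 sequences"):
        align_proteins({"a": "", "b": "MK"})


# --- back-threading --------------------------------------------------------

def test_backthread_expands_gaps_to_codons():
    aln = backthread(
        {"x": "M-V", "y": "MKV"}, {"x": "ATGGTT", "y": "ATGAAAGTA"}
    )
    assert aln.rows["x"] == "ATG---GTT"
    assert aln.rows["y"] == "ATGAAAGTA"
    assert aln.length == 9


def test_backthread_mismatch_is_hard_error():
    with pytest.raises(ValueError, match="translation"):
        backthread({"x": "MV"}, {"x": "ATGGCT"})  # translates to MA, not MV


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.data())
def test_backthread_round_trip_on_random_families(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    base = random_cds(rng, data.draw(st.integers(min_value=8, max_value=20)))
    members = {}
    for k in range(data.draw(st.integers(2, 4))):
        codons = [base[i : i + 3] for i in range(0, len(base), 3)]
        # random whole-codon deletions create indels
        keep = rng.random(len(codons)) > 0.1
        keep[0] = True
        cds = "".join(c for c, k_ in zip(codons, keep) if k_)
        members[f"g{k}"] = cds
    fam = GeneFamily("fam", members, single_copy=True)
    aln = build_codon_alignment(fam, method="nw")
    assert aln is not None
    for gid, row in aln.rows.items():
        assert row.replace("-", "") == members[gid]
        # gap runs are whole codons starting on codon boundaries
        pos = 0
        while pos < len(row):
            if row[pos] == "-":
                run = len(row[pos:]) - len(row[pos:].lstrip("-"))
                assert pos % 3 == 0 and run % 3 == 0
                pos += run
            else:
                pos += 1


# --- build_codon_alignment -------------------------------------------------

def test_gapless_fast_path_matches_alignment_route(small_population):
    _, genomes, _ = small_population
    fam = families_from_genomes(genomes)[0]
    auto = build_codon_alignment(fam, method="auto")
    nw = build_codon_alignment(fam, method="nw")
    assert auto.rows == nw.rows


def test_stop_codon_member_excluded_with_family_kept():
    fam = GeneFamily(
        "fam",
        {
            "good1": "ATGGCTGCA",
            "good2": "ATGGCAGCT",
            "broken": "ATGTAAGCA",  # internal stop
        },
        single_copy=True,
    )
    aln = build_codon_alignment(fam)
    assert set(aln.rows) == {"good1", "good2"}


def test_family_dropped_below_two_members():
    fam = GeneFamily(
        "fam", {"good": "ATGGCT", "broken": "ATGTAAGCA"}, single_copy=True
    )
    assert build_codon_alignment(fam) is None
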