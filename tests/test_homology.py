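import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmhistone.homology import (
    AlignmentError,
    AlignmentParams,
    ClassifierParams,
    align_pair,
    classify_family,
    map_positions,
    segment_indels,
)
from nmhistone.seqio import SequenceRecord
from nmhistone.synthetic_data import IndelEvent, MutationSpec, mutate_reference

from oracles import brute_force_global_score

AA4 = "ARKS"
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def rec(seq: str, rid: str = "q") -> SequenceRecord:
    return SequenceRecord(rid, seq)


# ---------------------------------------------------------------------------
# align_pair

def test_identity_alignment_score_is_diagonal_sum():
    aln = align_pair(rec("ARTK", "a"), rec("ARTK", "b"))
    assert aln.score == 19  # BLOSUM62 A:4 + R:5 + T:5 + K:5
    assert "-" not in aln.gapped_ref + aln.gapped_query


def test_single_deletion_matches_brute_force():
    aln = align_pair(rec("ARTK", "a"), rec("ARK", "b"))
    assert aln.score == brute_force_global_score("ARTK", "ARK")
    assert aln.gapped_query.count("-") == 1


def test_empty_query_scores_one_gap_run():
    aln = align_pair(rec("ARTK", "a"), "")
    assert aln.score == -10 + 4 * -1
    aln = align_pair("", rec("ARTK", "b"))
    assert aln.score == -14


def test_unknown_matrix_rejected():
    with pytest.raises(AlignmentError, match="matrix"):
        align_pair(rec("AR"), rec("AR"), AlignmentParams(matrix="NOSUCH62"))


def test_invalid_gap_params_rejected():
    with pytest.raises(AlignmentError):
        AlignmentParams(gap_open=-1, gap_extend=-10)  # open must be <= extend


def test_exhaustive_optimality_short_pairs():
    """DP score equals the enumeration oracle on every pair of length <= 3
    over a 4-letter alphabet."""
    seqs = [
        "".join(p)
        for n in (1, 2, 3)
        for p in itertools.product(AA4, repeat=n)
    ]
    for a in seqs:
        for b in seqs:
            got = align_pair(rec(a, "a"), rec(b, "b")).score
            want = brute_force_global_score(a, b)
            assert got == want, (a, b, got, want)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.text(alphabet=AA20, min_size=1, max_size=40),
    st.text(alphabet=AA20, min_size=1, max_size=40),
    st.sampled_from(["global", "local"]),
)
def test_degap_recovers_inputs(a, b, mode):
    try:
        aln = align_pair(rec(a, "a"), rec(b, "b"), AlignmentParams(mode=mode))
    except AlignmentError:
        assert mode == "local"  # no positive-scoring local alignment exists
        return
    if mode == "global":
        assert aln.ref_ungapped == a
        assert aln.query_ungapped == b
    else:
        assert aln.ref_ungapped in a
        assert aln.query_ungapped in b


def test_determinism_bit_stable():
    a, b = rec("ARTKQTARKSTGG", "a"), rec("ARTKTARKSTG", "b")
    alns = [align_pair(a, b) for _ in range(3)]
    assert len({(x.gapped_ref, x.gapped_query, x.score) for x in alns}) == 1


# ---------------------------------------------------------------------------
# map_positions

def test_identity_map(panel):
    ref = panel["H3"]
    pm = map_positions(align_pair(ref, ref))
    assert all(pm.get(p) == p for p in range(1, 136))


def test_map_with_nterminal_deletion(panel):
    ref = panel["H3"]
    q = rec(ref.residues[9:])
    pm = map_positions(align_pair(ref, q))
    assert all(pm.get(p) is None for p in range(1, 10))
    assert pm.get(10) == 1


def test_map_with_core_insertion(panel):
    ref = panel["H3"]
    q = rec(ref.residues[:80] + "W" * 10 + ref.residues[80:])
    pm = map_positions(align_pair(ref, q))
    assert pm.get(80) == 80
    assert pm.get(81) == 91


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_map_monotonic_on_random_mutants(panel, catalog, seed):
    rng = np.random.default_rng(seed)
    spec = MutationSpec(theta=float(rng.uniform(0, 0.4)), seed=seed)
    q, _ = mutate_reference("H3", spec, panel, catalog, restrict_background=False)
    pm = map_positions(align_pair(panel["H3"], q))
    mapped = [v for _, v in sorted(pm.items()) if v is not None]
    assert mapped == sorted(set(mapped))


# ---------------------------------------------------------------------------
# segment_indels

def test_identity_has_no_indels(panel):
    ref = panel["H3"]
    assert segment_indels(align_pair(ref, ref), family="H3") == []


def test_planted_tail_deletion_recovered(panel, catalog):
    spec = MutationSpec(indels=(IndelEvent(10, "deletion", 29),))
    q, truth = mutate_reference("H3", spec, panel, catalog)
    blocks = segment_indels(align_pair(panel["H3"], q), family="H3")
    assert len(blocks) == 1
    blk = blocks[0]
    assert (blk.kind, blk.ref_start, blk.ref_end, blk.length, blk.region) == (
        "deletion_in_query", 10, 38, 29, "n_tail",
    )
    assert blocks == truth.indel_blocks


def test_planted_core_insertion_recovered(panel, catalog):
    spec = MutationSpec(indels=(IndelEvent(80, "insertion", 10, "W" * 10),))
    q, truth = mutate_reference("H3", spec, panel, catalog)
    blocks = segment_indels(align_pair(panel["H3"], q), family="H3")
    assert blocks == truth.indel_blocks
    assert blocks[0].kind == "insertion_in_query"
    assert blocks[0].length == 10
    assert blocks[0].region == "core"


def test_blocks_partition_gap_columns(panel, catalog):
    spec = MutationSpec(
        indels=(IndelEvent(10, "deletion", 5), IndelEvent(60, "insertion", 3, "WWW")),
    )
    q, _ = mutate_reference("H3", spec, panel, catalog)
    aln = align_pair(panel["H3"], q)
    blocks = segment_indels(aln, family="H3")
    n_gap_cols = aln.gapped_ref.count("-") + aln.gapped_query.count("-")
    assert sum(b.length for b in blocks) == n_gap_cols
    ins = sum(b.length for b in blocks if b.kind == "insertion_in_query")
    dele = sum(b.length for b in blocks if b.kind == "deletion_in_query")
    assert len(q) == len(panel["H3"]) + ins - dele


# ---------------------------------------------------------------------------
# classify_family

def test_panel_self_identification(panel):
    for fam in panel.families:
        call = classify_family(panel[fam], panel)
        assert call.family == fam
        assert call.identity == 1.0


def test_diverged_h3_still_classified(panel, catalog):
    spec = MutationSpec(theta=0.2, seed=11)
    q, _ = mutate_reference("H3", spec, panel, catalog, restrict_background=False)
    assert classify_family(q, panel).family == "H3"


def test_random_sequence_not_classified(panel):
    rng = np.random.default_rng(5)
    q = rec("".join(rng.choice(list(AA20), size=150)), "random150")
    call = classify_family(q, panel)
    assert call.family == "none"


def test_classifier_param_validation():
    with pytest.raises(AlignmentError):
        ClassifierParams(tau=0.0)
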