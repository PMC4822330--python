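import pytest

from nmhistone.ctd_scan import ScanParams, scan_heptads
from nmhistone.homology import align_pair, classify_family, segment_indels
from nmhistone.conservation import score_matrix
from nmhistone.homology import FamilyCall
from nmhistone.synthetic_data import (
    IndelEvent,
    MutationSpec,
    SyntheticError,
    make_ctd,
    make_panel,
    mutate_reference,
)
from nmhistone.cli_report import default_panel_specs


def test_empty_spec_reproduces_reference(panel, catalog):
    q, truth = mutate_reference("H4", MutationSpec(), panel, catalog)
    assert q.residues == panel["H4"].residues
    assert all(v == 1 for v in truth.site_scores.values())
    assert truth.indel_blocks == []


def test_single_substitution_changes_one_residue(panel, catalog):
    q, truth = mutate_reference(
        "H3", MutationSpec(substitutions=((9, "A"),)), panel, catalog
    )
    diffs = [i for i, (x, y) in enumerate(zip(panel["H3"].residues, q.residues)) if x != y]
    assert diffs == [8]
    assert truth.site_scores[(9, 0)] == 0
    assert truth.site_scores[(4, 2)] == 1  # K4's 5-aa window stops at position 6


def test_determinism_identical_bytes(panel, catalog):
    spec = MutationSpec(theta=0.1, seed=42, indels=(IndelEvent(60, "insertion", 4),))
    q1, t1 = mutate_reference("H3", spec, panel, catalog)
    q2, t2 = mutate_reference("H3", spec, panel, catalog)
    assert q1.residues == q2.residues
    assert t1.site_scores == t2.site_scores and t1.indel_blocks == t2.indel_blocks


def test_background_avoids_site_neighborhoods(panel, catalog):
    q, truth = mutate_reference("H3", MutationSpec(theta=0.3, seed=8), panel, catalog)
    assert truth.n_background > 0
    assert all(v == 1 for v in truth.site_scores.values())
    ref = panel["H3"].residues
    protected = {
        p for s in catalog.for_family("H3") for p in range(s.position - 2, s.position + 3)
    }
    for p in protected:
        if 1 <= p <= len(ref):
            assert q.residues[p - 1] == ref[p - 1]


def test_no_op_substitution_rejected(panel, catalog):
    with pytest.raises(SyntheticError, match="no-op"):
        mutate_reference("H3", MutationSpec(substitutions=((9, "K"),)), panel, catalog)


def test_overlapping_indels_rejected(panel, catalog):
    spec = MutationSpec(
        indels=(IndelEvent(10, "deletion", 10), IndelEvent(15, "deletion", 3))
    )
    with pytest.raises(SyntheticError, match="overlap"):
        mutate_reference("H3", spec, panel, catalog)


def test_out_of_range_event_rejected(panel, catalog):
    with pytest.raises(SyntheticError):
        mutate_reference("H4", MutationSpec(substitutions=((999, "A"),)), panel, catalog)


def test_tail_truncation_is_leading_deletion(panel, catalog):
    q, truth = mutate_reference("H3", MutationSpec(tail_truncation=10), panel, catalog)
    assert q.residues == panel["H3"].residues[9:]
    blk = truth.indel_blocks[0]
    assert (blk.kind, blk.ref_start, blk.ref_end, blk.region) == (
        "deletion_in_query", 1, 9, "n_tail",
    )


def test_make_panel_counts_and_absences(panel, catalog):
    records, truth = make_panel(default_panel_specs(theta=0.0, seed=0), panel, catalog)
    assert len(records) == 2 * 2 + 4 * 3  # 2 species H3/H4, 4 species H3/H4/H2B
    chloro = truth.per_species["chloro_taildel"]
    assert "H2B" not in chloro
    expected = truth.expected_records(catalog)
    h2b_absent = [t for t in expected
                  if t[0] == "chloro_taildel" and t[1] == "H2B"]
    assert len(h2b_absent) == 15 and all(t[4] == "no_homolog" for t in h2b_absent)


def test_make_panel_duplicate_labels_rejected(panel, catalog):
    specs = [("sp", {"H3": MutationSpec()}), ("sp", {"H4": MutationSpec()})]
    with pytest.raises(SyntheticError, match="duplicate"):
        make_panel(specs, panel, catalog)


def test_full_pipeline_recovers_truth(panel, catalog):
    """Central recovery property: identification + alignment + scoring on a
    generated panel reproduces the planted truth exactly, including indels."""
    records, truth = make_panel(default_panel_specs(theta=0.05, seed=3), panel, catalog)
    queries = []
    for species, rec in records:
        call = classify_family(rec, panel)
        assert call.family == rec.id.split("_")[-1]
        queries.append((species, rec, call))
    m = score_matrix(queries, catalog, panel)
    got = {(r.species, r.site.family, r.site.position, r.r, r.status, r.score)
           for r in m.records}
    assert got == truth.expected_records(catalog)
    for species, rec in records:
        fam = rec.id.split("_")[-1]
        blocks = segment_indels(align_pair(panel[fam], rec), family=fam)
        assert blocks == truth.per_species[species][fam].indel_blocks


def test_make_ctd_length_and_flanks():
    rec = make_ctd(5, sub_rate=0.0, flanks=(30, 7), seed=1)
    assert len(rec) == 30 + 35 + 7


def test_make_ctd_full_substitution_kills_exact_hits():
    rec = make_ctd(5, sub_rate=1.0, seed=1)
    res = scan_heptads(rec, params=ScanParams(m=0, min_run=1))
    assert res.n_exact == 0


def test_make_ctd_determinism():
    assert make_ctd(3, 0.2, seed=9).residues == make_ctd(3, 0.2, seed=9).residues
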