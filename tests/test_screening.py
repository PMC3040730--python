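import random

import pytest

from srda import (
    NucleotideRecord,
    SrdaError,
    TranslatedFrame,
    build_precursor,
    embed_as_est,
    extract_fragments,
    match_motif,
    sample_mature_for_motif,
    sample_stop_split_pair,
    scan_bank,
    scan_protein_set,
    scan_record,
    srda_convert,
    strip_stops,
)


def tf(aa, frame=1, rid="r"):
    return TranslatedFrame(rid, frame, aa)


def test_extract_fragments_rules():
    frags = extract_fragments(tf("MAAC.KKC.GG"))
    assert [f.seq for f in frags] == ["MAAC.", "KKC."]
    assert [(f.aa_start, f.aa_end) for f in frags] == [(1, 5), (6, 9)]
    # trailing run without a stop is rejected as partially identified
    assert extract_fragments(tf("MAAC")) == []
    # empty runs between stops are removed
    assert extract_fragments(tf("...")) == []
    # min_len excludes the terminating stop
    assert [f.seq for f in extract_fragments(tf("MAAC.KKC.GG"), min_len=4)] == [
        "MAAC."
    ]


def test_fragment_invariants():
    for frag in extract_fragments(tf("MAC.A.CCDD.X")):
        assert frag.seq.endswith(".")
        assert "." not in frag.seq[:-1]
        assert frag.pattern == srda_convert(frag.seq)


def test_scan_record_single_planted_frame(registry, rng):
    mature = sample_mature_for_motif(registry.get("motif 2"), rng)
    precursor, _, _ = build_precursor(mature, rng)
    rec, frame, _, _ = embed_as_est(precursor, 2, "+", rng, "planted")
    hits = [h for h in scan_record(rec, registry) if h.motif_id == "motif 2"]
    assert {h.frame for h in hits} == {frame} == {2}
    assert all(precursor in h.fragment_seq for h in hits)


def test_stop_spanning_shapes_are_never_hits(registry, rng):
    """A cysteine run that matches a motif only across an internal stop
    must produce zero hits; the intact peptide must produce one."""
    motif = registry.get("motif 1")
    intact, split = sample_stop_split_pair(motif, rng)
    rec_ok, _, _, _ = embed_as_est(intact, 1, "+", rng, "intact")
    rec_bad, _, _, _ = embed_as_est(split, 1, "+", rng, "split")
    assert any(h.motif_id == "motif 1" for h in scan_record(rec_ok, registry))
    assert not any(
        h.motif_id == "motif 1" for h in scan_record(rec_bad, registry)
    )


def test_scan_record_no_keys_no_line_hits(registry):
    rec = NucleotideRecord("plain", "", "GGAGGTGGAGGTTGAGGAGGT" * 3)
    hits = scan_record(rec, registry)
    assert [h for h in hits if h.motif_id != "motif K"] == []


def test_scan_bank_determinism_and_counts(registry, rng):
    records = []
    for i in range(3):
        records.append(
            NucleotideRecord(f"n{i}", "", "".join(rng.choice("ACGT") for _ in range(200)))
        )
    mature = sample_mature_for_motif(registry.get("motif 2"), rng)
    precursor, _, _ = build_precursor(mature, rng)
    rec, _, _, _ = embed_as_est(precursor, 1, "+", rng, "plt")
    records.append(rec)

    hits1, report1 = scan_bank(records, registry)
    hits2, report2 = scan_bank(records, registry)
    assert hits1 == hits2
    assert report1.count("motif 2", "retrieved") == 1
    # report is order-independent in record order
    _, report3 = scan_bank(list(reversed(records)), registry)
    assert report3.count("motif 2", "retrieved") == 1


def test_hit_nt_coordinates_cover_the_fragment(registry, rng):
    mature = sample_mature_for_motif(registry.get("motif 3"), rng)
    precursor, _, _ = build_precursor(mature, rng)
    for strand in "+-":
        rec, frame, nt_start, nt_end = embed_as_est(precursor, 3, strand, rng, "c")
        hits = [h for h in scan_record(rec, registry) if h.motif_id == "motif 3"]
        assert hits
        h = hits[0]
        # fragment spans the ORF plus its bounding codons on the same strand
        assert h.nt_start <= min(nt_start, nt_end)
        assert h.nt_end >= max(nt_start, nt_end) - 2
        assert (h.nt_end - h.nt_start + 1) % 3 == 0


def test_scan_protein_set(registry, rng):
    mature = sample_mature_for_motif(registry.get("motif 2"), rng)
    hits = scan_protein_set([("tox", mature)], registry)
    assert any(h.motif_id == "motif 2" for h in hits)
    with pytest.raises(SrdaError, match="stop symbol"):
        scan_protein_set([("bad", "AAC.")], registry)


def test_est_match_implies_protein_match(registry, rng):
    """Stripping stop symbols only loosens a motif: every stop-free
    sequence retrieved in EST mode (with '.' appended) is retrieved in
    protein mode too."""
    for motif in registry.enabled():
        if not motif.is_line:
            continue
        for _ in range(10):
            seq = sample_mature_for_motif(motif, rng)
            est = match_motif(motif, srda_convert(seq + "."))
            if est.matched:
                stripped = strip_stops(motif)
                assert match_motif(stripped, srda_convert(seq)).matched
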