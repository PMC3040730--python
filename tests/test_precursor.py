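import pytest

from srda import (
    PrecursorCall,
    SignalCall,
    SrdaError,
    build_precursor,
    call_precursors,
    dedup_matures,
    embed_as_est,
    load_signalp_output,
    mature_chain,
    predict_mature_start,
    sample_mature_for_motif,
    scan_bank,
    signal_from,
)
from srda.precursor import DEFAULT_SIGNAL_PARAMS, signal_from_vba


def test_signal_no_met_in_range_gives_no_call():
    assert signal_from("A" * 40 + ".") is None
    # a Met beyond the search depth does not rescue the fragment
    assert signal_from("A" * 35 + "M" + "L" * 20 + "ASA" + "DDD.") is None


def test_signal_hydrophobic_core_with_asa_cleavage():
    frag = "M" + "L" * 12 + "ASA" + "DDENNQDDENNQ" + "."
    call = signal_from(frag)
    assert call is not None and call.accepted
    assert call.met_pos == 1
    assert call.cleavage_after == 16  # after the second Ala of the A-S-A box
    # best 8-residue core window sums eight leucines; cleavage box adds w2
    assert call.score == pytest.approx(8 * 3.8 + 8.0)


def test_signal_hydrophilic_fragment_scores_below_threshold():
    call = signal_from("M" + "D" * 20 + "NNQED" + ".")
    assert call is not None
    assert not call.accepted and call.score < DEFAULT_SIGNAL_PARAMS.threshold


def test_signal_vba_format_switch():
    frag = "M" + "L" * 12 + "ASA" + "DDENNQDDENNQ" + "."
    assert signal_from_vba(frag, 30, 1, 1) == 1
    assert signal_from_vba(frag, 30, 1, 3) == 16
    assert signal_from_vba(frag, 30, 1, 0, record_length=120) == 1
    assert signal_from_vba(frag, 30, 1, 2, record_length=120) == 48
    assert signal_from_vba(frag, 30, 1, 9) == pytest.approx(8 * 3.8 + 8.0)


@pytest.mark.parametrize(
    "seq,start,chain,end",
    [("MAACD.", 4, "CD", 5), ("MAACD.", 1, "MAACD", 5)],
)
def test_mature_chain(seq, start, chain, end):
    assert mature_chain(seq, start) == (chain, end)


def test_mature_chain_unterminated():
    with pytest.raises(SrdaError, match="unterminated"):
        mature_chain("MAACD", 2)


@pytest.mark.parametrize(
    "seq,offset",
    [
        ("EAKRGVCCAAAA", 5),   # dibasic KR
        ("EAGRSVCCAAAA", 5),   # R with E at -3
        ("GGGGCCAAAAAA", 1),   # no processing site: mature starts at once
        ("QQKKQQKRCCCC", 5),   # nearest site to the signal wins (the KK)
    ],
)
def test_predict_mature_start(seq, offset):
    assert predict_mature_start(seq) == offset


def _call(rid, mature, signal_end=16):
    sig = SignalCall(1, signal_end, 40.0, True)
    frag = "M" * signal_end + "KR" + mature + "."
    return PrecursorCall(rid, 1, ("motif 1",), sig, None, mature, fragment_seq=frag)


def test_dedup_matures():
    calls = [_call("a", "CCAA"), _call("b", "CCAA"), _call("c", "CCGG")]
    unique = dedup_matures(calls)
    assert [(c.record_id, c.multiplicity) for c in unique] == [("a", 2), ("c", 1)]
    assert dedup_matures([]) == []


def test_call_precursors_end_to_end(registry, rng):
    """Two clones of one precursor collapse to one call; the report stays
    monotone and the domains reconstitute the fragment."""
    mature = sample_mature_for_motif(registry.get("motif 4"), rng)
    precursor, _, _ = build_precursor(mature, rng)
    records = [
        embed_as_est(precursor, 1, "+", rng, "cloneA")[0],
        embed_as_est(precursor, 2, "-", rng, "cloneB")[0],
    ]
    hits, _ = scan_bank(records, registry)
    calls, report = call_precursors(hits, registry)
    report.assert_monotone()
    m4 = [c for c in calls if c.mature_seq == mature]
    assert len(m4) == 1 and m4[0].multiplicity == 2
    assert report.count("motif 4", "retrieved") == 2
    assert report.count("motif 4", "signal_approved") == 2
    assert report.count("motif 4", "deduplicated") == 1
    c = m4[0]
    body = c.fragment_seq.rstrip(".")
    signal = body[: c.signal.cleavage_after]
    prop = (
        body[c.propeptide_span[0] - 1 : c.propeptide_span[1]]
        if c.propeptide_span
        else ""
    )
    assert signal + prop + c.mature_seq == body


def test_call_precursors_empty_input(registry):
    calls, report = call_precursors([], registry)
    assert calls == []
    assert report.totals["retrieved"] == 0
    report.assert_monotone()


SIGNALP_SHORT = """\
# SignalP-4.1 euk predictions
# name  Cmax  pos  Ymax  pos  Smax  pos  Smean  D  ?  Dmaxcut  Networks-used
frag1  0.82  23  0.85  23  0.91  15  0.88  0.86  Y  0.450  SignalP-noTM
frag2  0.11  17  0.10  17  0.12  3  0.09  0.10  N  0.450  SignalP-noTM
"""


def test_load_signalp_output(tmp_path):
    path = tmp_path / "signalp.short"
    path.write_text(SIGNALP_SHORT)
    calls = load_signalp_output(path)
    assert set(calls) == {"frag1", "frag2"}
    assert calls["frag1"].accepted and calls["frag1"].cleavage_after == 22
    assert not calls["frag2"].accepted

    empty = tmp_path / "empty.short"
    empty.write_text("# nothing\n")
    assert load_signalp_output(empty) == {}

    bad = tmp_path / "bad.short"
    bad.write_text("frag1 only three fields\n")
    with pytest.raises(SrdaError, match="line 1"):
        load_signalp_output(bad)


def test_external_signalp_overrides_heuristic(registry, rng):
    mature = sample_mature_for_motif(registry.get("motif 1"), rng)
    precursor, _, _ = build_precursor(mature, rng)
    rec, frame, _, _ = embed_as_est(precursor, 1, "+", rng, "clone")
    hits, _ = scan_bank([rec], registry)
    key_hit = next(h for h in hits if h.motif_id == "motif 1")
    frag_id = f"{key_hit.record_id}|{key_hit.frame}|{key_hit.aa_start}"
    # an external rejection silences a fragment the heuristic accepts
    external = {frag_id: SignalCall(1, 16, 0.1, False)}
    calls, _ = call_precursors(hits, registry, signalp=external)
    assert not any("motif 1" in c.motif_ids for c in calls)
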