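import random

import pytest

from srda import (
    PatternSyntaxError,
    SrdaError,
    evaluate_specificity,
    generalize_patterns,
    load_registry,
    match_compound,
    match_motif,
    parse_motif,
    strip_stops,
)

from _oracles import oracle_match, random_motif, random_pattern_text

#: the shipped cysteine-scaffold screening lines, in registry order
EXPECTED_LINES = [
    "C1C##C6C#CC",
    "C1C##C9C#CC#.",
    "C8C#C*C3C#C.",
    "C8C*C#C*C3C",
    "C8C#C*C1C#C#.",
    "CC#C#CC*C1C*C.",
    "CC1C*C*C*C*C1C#.",
    "CC1C#C5C*C#.",
    "C6C*C*C*C6C#.",
    "C8C3C#C.",
    "C#C#C#C#C#C#C#C#.",
    "C6C#C#C1C*C1C",
    "C#C#C#C#.",
    "###.",
    "##C",
]


def test_registry_fidelity(registry):
    """Golden check: shipped screening lines are byte-identical."""
    assert registry.lines() == EXPECTED_LINES
    compound = registry.get("motif K")
    assert str(compound) == "K>=6 AND C<=2"
    # degenerate cytolysin lines ship disabled, the compound query enabled
    assert not registry.get("motif 0").enabled_by_default
    assert not registry.get("motif 14").enabled_by_default
    assert compound.enabled_by_default


def test_parse_motif_examples():
    q = parse_motif("C1C##C6C#CC")
    assert q.is_line and q.line.count("C") == 6
    k = parse_motif("K > = 6 AND C < = 2")
    assert not k.is_line
    assert [(p.residue, p.comparator, p.threshold) for p in k.compound] == [
        ("K", "ge", 6),
        ("C", "le", 2),
    ]
    with pytest.raises(PatternSyntaxError):
        parse_motif("C**C")
    with pytest.raises(PatternSyntaxError):
        parse_motif("C!C")


@pytest.mark.parametrize(
    "line,pattern,matched,span",
    [
        ("###.", "175.", True, (1, 4)),
        ("C1C##C6C#CC", "22C1C13C6C2CC7.", True, (3, 13)),
        ("C1C##C6C#CC", "22C1C5C6C2CC7.", False, None),
        ("CC", "1C2C3.", False, None),
        ("C#C", "C12C", False, None),  # '#' is one digit, not a whole count
        ("#C", "12C", True, (2, 3)),   # ...but may match part of a count
    ],
)
def test_match_motif(line, pattern, matched, span):
    res = match_motif(parse_motif(line), pattern)
    assert res.matched is matched
    assert res.span == span


def test_strict_mode_guards_token_boundaries():
    q = parse_motif("#C")
    assert match_motif(q, "12C").matched
    assert not match_motif(q, "12C", strict=True).matched
    assert match_motif(q, "5C", strict=True).matched


@pytest.mark.parametrize(
    "seq,matched",
    [
        ("K" * 7 + "C" + "AAA", True),
        ("K" * 6 + "CC" + "AAA", True),   # both thresholds at the boundary
        ("K" * 5 + "AAA", False),
        ("K" * 8 + "CCC", False),
    ],
)
def test_match_compound_thresholds(registry, seq, matched):
    assert match_compound(registry.get("motif K"), seq + ".").matched is matched


def test_strip_stops(registry):
    assert strip_stops(registry.get("motif 2")).line == "C1C##C9C#CC#"
    assert strip_stops(parse_motif("###.")).line == "###"
    q = registry.get("motif K")
    assert strip_stops(q) is q
    once = strip_stops(registry.get("motif 13"))
    assert strip_stops(once) == once


@pytest.mark.parametrize(
    "patterns,expected",
    [
        (["C1C12C6C2CC", "C1C13C6C3CC"], "C1C##C6C#CC"),
        (["3C.", "3C."], "3C."),
        (["C5C", "C12C"], "C*C"),
        (["C5C3C", "C5C"], "C5C*"),  # unequal token counts gap the tail
    ],
)
def test_generalize_patterns(patterns, expected):
    assert generalize_patterns(patterns) == expected
    # order independence
    assert generalize_patterns(list(reversed(patterns))) == expected


def test_generalize_requires_input():
    with pytest.raises(SrdaError):
        generalize_patterns([])


def test_matcher_agrees_with_regex_oracle(registry):
    """Dual-route check on random (motif, pattern) pairs plus the shipped
    registry lines; both the verdict and the leftmost-lazy span agree."""
    rng = random.Random(1)
    lines = [m.line for m in registry if m.is_line]
    checked = 0
    for i in range(2000):
        line = lines[i % len(lines)] if i % 4 == 0 else random_motif(rng)
        text = random_pattern_text(rng)
        got = match_motif(parse_motif(line), text)
        want_matched, want_span = oracle_match(line, text)
        assert got.matched == want_matched, (line, text)
        if want_matched:
            assert got.span == want_span, (line, text)
        checked += 1
    assert checked == 2000


def test_wildcard_monotonicity(rng):
    """Replacing a literal digit with '#', or any character with '*',
    never turns a match into a non-match."""
    for _ in range(300):
        line = random_motif(rng)
        text = random_pattern_text(rng)
        if not match_motif(parse_motif(line), text).matched:
            continue
        i = rng.randrange(len(line))
        if line[i].isdigit():
            relaxed = line[:i] + "#" + line[i + 1 :]
        else:
            relaxed = line[:i] + "*" + line[i + 1 :]
        relaxed = relaxed.replace("**", "*")
        assert match_motif(parse_motif(relaxed), text).matched, (line, relaxed, text)


def test_evaluate_specificity_counts():
    reg = load_registry()
    labeled = [
        # four anemone toxin-like sequences carrying the motif-13 scaffold
        *[
            (f"anemone{i}", "AA" + "CA" * 3 + "CDD", "anemone")
            for i in range(4)
        ],
        # sixteen unrelated sequences
        *[(f"other{i}", "AAADDDEEE", "other") for i in range(16)],
    ]
    table = evaluate_specificity(reg, labeled, target_group="anemone")
    row = table.loc["motif 13"]
    assert row["total"] == 4 and row["anemone"] == 4
    assert row["specificity_pct"] == 100
    assert table.loc["distinct", "total"] <= table["total"].iloc[:-1].sum()


def test_evaluate_specificity_rejects_stops_in_protein_mode():
    reg = load_registry()
    with pytest.raises(SrdaError):
        evaluate_specificity(reg, [("a", "AC.A", "g")], target_group="g")
    with pytest.raises(SrdaError):
        evaluate_specificity(reg, [("a", "ACA", "g")], "g", mode="bogus")
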