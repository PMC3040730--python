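"""Independent reference implementations used only to check the package.

The motif matcher oracle compiles a screening line token-by-token to a
regular expression with lazy gaps, so agreement with the package's
character-level matcher is a genuine dual-route check.
"""

import random
import re


def motif_to_regex(line: str):
    parts = []
    for ch in line:
        if ch == "?":
            parts.append(".")
        elif ch == "#":
            parts.append(r"\d")
        elif ch == "*":
            parts.append(".*?")
        else:
            parts.append(re.escape(ch))
    return re.compile("".join(parts))


def oracle_match(line: str, text: str):
    """(matched, 1-based closed span or None) per the regex oracle."""
    m = motif_to_regex(line).search(text)
    if m is None:
        return False, None
    return True, (m.start() + 1, m.end())


def random_motif(rng: random.Random) -> str:
    """A random screening line over the published grammar: key letters,
    literal counts, '#'/'##' digit wildcards, single gaps, optional '?',
    optional terminal stop."""
    units = []
    n_keys = rng.randint(2, 6)
    for i in range(n_keys):
        units.append(rng.choice("CCCK"))
        if i < n_keys - 1:
            r = rng.random()
            if r < 0.3:
                units.append(str(rng.randint(1, 12)))
            elif r < 0.55:
                units.append("#")
            elif r < 0.7:
                units.append("##")
            elif r < 0.85:
                units.append("*")
            elif r < 0.9:
                units.append("?")
            # else: adjacent keys
    if rng.random() < 0.4:
        if rng.random() < 0.5:
            units.append(rng.choice(["#", str(rng.randint(1, 9))]))
        units.append(".")
    line = "".join(units)
    return line.replace("**", "*")


def random_pattern_text(rng: random.Random) -> str:
    """A random syntactically valid SRDA pattern, optionally stop-ended."""
    parts = []
    for _ in range(rng.randint(0, 8)):
        if rng.random() < 0.5:
            parts.append(rng.choice("CK"))
        else:
            parts.append(str(rng.randint(1, 120)))
    out = []
    last_digit = False
    for p in parts:
        if p.isdigit() and last_digit:
            continue  # keep counts maximal
        out.append(p)
        last_digit = p.isdigit()
    if rng.random() < 0.5:
        out.append(".")
    return "".join(out) or "1"
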