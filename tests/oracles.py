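"""Independent oracles the implementation is tested against.

Everything here is deliberately written as direct transcription / brute
force, structurally different from the package's own code paths.
"""
from __future__ import annotations

#: Explicit rule patterns of the five-tier combining table; each pattern is
#: a minimum-count requirement over (very strong, strong, moderate,
#: supporting) pathogenic criteria.
PATHOGENIC_PATTERNS = [
    {"vs": 1, "s": 1},
    {"vs": 1, "m": 2},
    {"vs": 1, "m": 1, "p": 1},
    {"vs": 1, "p": 2},
    {"s": 2},
    {"s": 1, "m": 3},
    {"s": 1, "m": 2, "p": 2},
    {"s": 1, "m": 1, "p": 4},
]
LIKELY_PATHOGENIC_PATTERNS = [
    {"vs": 1, "m": 1},
    {"s": 1, "m": 1},
    {"s": 1, "p": 2},
    {"m": 3},
    {"m": 2, "p": 2},
    {"m": 1, "p": 4},
]


def _satisfies(counts: dict[str, int], pattern: dict[str, int]) -> bool:
    return all(counts.get(k, 0) >= v for k, v in pattern.items())


def combine_oracle(
    vs: int, s: int, m: int, p: int, ba: int, bs: int, bp: int
) -> str:
    """Brute-force tier from criterion counts per strength level."""
    counts = {"vs": vs, "s": s, "m": m, "p": p}
    pathogenic = any(_satisfies(counts, r) for r in PATHOGENIC_PATTERNS)
    likely_pathogenic = any(_satisfies(counts, r) for r in LIKELY_PATHOGENIC_PATTERNS)
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2
    if (pathogenic or likely_pathogenic) and (benign or likely_benign):
        return "VUS"
    if pathogenic:
        return "P"
    if likely_pathogenic:
        return "LP"
    if benign:
        return "B"
    if likely_benign:
        return "LB"
    return "VUS"


def naive_snapshot_diff(old, new):
    """Field-by-field comparison of two snapshots (no materiality rule).

    Returns (added_entry_keys, changed_assertion_keys, changed_freq_keys,
    affected_genes) as plain sets.
    """
    added_entries = set()
    for key in new.entries:
        if key not in old.entries or old.entries[key] != new.entries[key]:
            added_entries.add(key)
    changed_assertions = set()
    for key in new.assertions:
        if key not in old.assertions or old.assertions[key] != new.assertions[key]:
            changed_assertions.add(key)
    changed_freqs = set()
    for key in new.frequencies:
        if key not in old.frequencies or old.frequencies[key] != new.frequencies[key]:
            changed_freqs.add(key)
    genes = {g for g, _ in added_entries}
    genes |= {k.split("|")[0] for k in changed_assertions}
    genes |= {k.split("|")[0] for k in changed_freqs}
    return added_entries, changed_assertions, changed_freqs, genes


def indel_frame_oracle(length: int) -> str:
    """Frameshift vs in-frame for a pure deletion/duplication of ``length``."""
    return "frameshift" if length % 3 else "inframe_indel"
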