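"""Small sequence helpers shared across modules."""
from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def interval_union_length(spans) -> int:
    """Total length covered by a collection of half-open intervals."""
    spans = sorted(spans)
    total = 0
    cur_start = cur_end = None
    for s, e in spans:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total
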