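"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the miner oracle is a
scalar O(n^2)-style scan testing every (start, unit length) pair, and the
selection rule is re-stated from the locus contract (greedy left-to-right,
smaller unit first, then longer run; each base consumed once).
"""

from __future__ import annotations

_VALID = set("ACGT")


def _primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def brute_force_ssrs(seq: str, min_rcn: dict[int, int]) -> list[tuple[int, int, str]]:
    """All perfect SSRs of a sequence as (start, end, motif), 1-based."""
    seq = seq.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int, str]] = []  # (start0, k, -span, motif)
    for k in range(1, 7):
        for i in range(n - k + 1):
            unit = seq[i : i + k]
            if set(unit) - _VALID or not _primitive(unit):
                continue
            # left maximality at the unit phase
            if i >= 1 and seq[i - 1] in _VALID and i - 1 + k < n and seq[i - 1] == seq[i - 1 + k]:
                continue
            t = i
            while t + k < n and seq[t + k] in _VALID and seq[t] in _VALID and seq[t] == seq[t + k]:
                t += 1
            run_len = t - i + k
            rcn = run_len // k
            if rcn < min_rcn[k]:
                continue
            candidates.append((i, k, -(rcn * k), unit))
    candidates.sort()
    out: list[tuple[int, int, str]] = []
    consumed = -1
    for i, k, neg_span, unit in candidates:
        if i <= consumed:
            continue
        span = -neg_span
        out.append((i + 1, i + span, unit))
        consumed = i + span - 1
    return out


def point_region_label(intervals: list[tuple[str, int, int, str]], seq_id: str, pos: int) -> str:
    """Label of the interval containing a point (linear scan)."""
    for sid, start, end, label in intervals:
        if sid == seq_id and start <= pos <= end:
            return label
    return "intergenic"
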