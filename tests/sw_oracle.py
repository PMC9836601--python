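"""Independent brute-force oracles used by the test suite.

The Smith-Waterman oracle is a plain O(nm) Gotoh dynamic program kept
deliberately separate from the package's aligner: same scoring convention
(a gap of length L costs open + L * extend), no seeding, no banding, no
windows.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_score(target: str, query: str, match: int = 1, mismatch: int = -2,
             gap_open: int = 4, gap_extend: int = 2) -> float:
    """Optimal local alignment score of query against target."""
    n, m = len(target), len(query)
    best = 0.0
    prev_m = [0.0] * (m + 1)
    prev_ix = [NEG] * (m + 1)
    prev_iy = [NEG] * (m + 1)
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        cur_m = [0.0] * (m + 1)
        cur_ix = [NEG] * (m + 1)
        cur_iy = [NEG] * (m + 1)
        ti = target[i - 1]
        for j in range(1, m + 1):
            s = match if ti == query[j - 1] else mismatch
            diag = max(prev_m[j - 1], prev_ix[j - 1], prev_iy[j - 1])
            cur_m[j] = max(0.0, diag + s)
            # gap in query (consume target)
            cur_ix[j] = max(prev_m[j] - first_gap, prev_ix[j] - gap_extend)
            # gap in target (consume query)
            cur_iy[j] = max(cur_m[j - 1] - first_gap, cur_iy[j - 1] - gap_extend)
            if cur_m[j] > best:
                best = cur_m[j]
        prev_m, prev_ix, prev_iy = cur_m, cur_ix, cur_iy
    return best


def sw_best_score_both_strands(target: str, query: str, **scores) -> float:
    """Max local score over the read and its reverse complement."""
    comp = str.maketrans("ACGT", "TGCA")
    rc = query.translate(comp)[::-1]
    return max(sw_score(target, query, **scores),
               sw_score(target, rc, **scores))
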