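"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written as a direct transcription of the operation's
definition — exhaustive enumeration and explicit string comparison — and
deliberately shares no code with the package internals it checks.
"""

from __future__ import annotations

from collections import Counter

_DNA_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def brute_aba_patterns(seq, lo, hi, min_a, max_a, min_motif, max_motif):
    """All maximal A-B-A' patterns by exhaustive triple enumeration.

    Returns (a_start, a_len, b_len) triples in rank order.  A candidate is
    valid when A and A' match exactly, every bound holds, and the whole span
    lies in [lo, hi]; it survives when neither a rightward extension (same
    A/A' starts, one base of B converted to A) nor a leftward extension
    (both copies of A grown one base 5'-ward) is itself a valid candidate.
    """

    def valid(a_start, a_len, b_len):
        if a_len < 1 or b_len < 0:
            return False
        if not (min_a <= a_len <= max_a):
            return False
        d = a_len + b_len
        if not (min_motif <= d <= max_motif):
            return False
        aprime = a_start + d
        if a_start < lo or aprime + a_len - 1 > hi:
            return False
        a = seq[a_start - 1 : a_start - 1 + a_len]
        ap = seq[aprime - 1 : aprime - 1 + a_len]
        return a == ap

    out = []
    for a_start in range(lo, hi + 1):
        for a_len in range(min_a, max_a + 1):
            for b_len in range(0, max_motif - a_len + 1):
                if not valid(a_start, a_len, b_len):
                    continue
                # rightward extension: one base of B relabeled as A
                if valid(a_start, a_len + 1, b_len - 1):
                    continue
                # leftward extension: both copies of A grown one base 5'-ward
                if valid(a_start - 1, a_len + 1, b_len - 1):
                    continue
                out.append((a_start, a_len, b_len))
    out.sort(key=lambda t: (-t[1], t[2], t[0]))
    return out


def brute_scan_one_strand(seq: str, motif: str):
    """Greedy non-overlapping exact scan by per-position comparison."""
    hits, i, m = [], 0, len(motif)
    while i <= len(seq) - m:
        if seq[i : i + m] == motif:
            hits.append(i)
            i += m
        else:
            i += 1
    return hits


def brute_scan(seq: str, motif: str):
    """Both-orientation scan; more hits wins, ties go forward."""
    fwd = brute_scan_one_strand(seq, motif)
    rev = brute_scan_one_strand(rc(seq), motif)
    return rev if len(rev) > len(fwd) else fwd


def brute_longest_run(hits, motif_len: int) -> int:
    best = 0
    for start in range(len(hits)):
        run = 1
        for j in range(start, len(hits) - 1):
            if hits[j + 1] - hits[j] == motif_len:
                run += 1
            else:
                break
        best = max(best, run)
    return best


def brute_position_counts(read_seqs, motif: str, read_len: int):
    counts = [0] * read_len
    for s in read_seqs:
        hits = brute_scan(s, motif)
        if hits:
            for h in hits:
                counts[h - hits[0]] += 1
    return counts


def brute_period(counts) -> int:
    nz = [i for i, c in enumerate(counts) if c > 0]
    assert len(nz) >= 2
    tally = Counter()
    for a, b in zip(nz, nz[1:]):
        tally[b - a] += min(counts[a], counts[b])
    best = max(tally.values())
    return min(d for d, w in tally.items() if w == best)
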