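"""Sequencing-read analysis of tandem-repeat cDNA products.

Repeat cDNAs synthesized by DRT10-like reverse transcriptases do not map to
the expression plasmid: the repeat motif is embedded in long tandem arrays
that match no contiguous stretch of the reference.  The analysis therefore
(1) partitions reads into reference-mapping and unmapped sets, (2) discovers
motifs differentially enriched in WT versus RT-dead *unmapped* reads by a
transparent differential k-mer procedure, and (3) quantifies the discovered
motif: per-read hit positions (motif position graphs), longest tandem runs,
reads with >= k consecutive repeats, flanking-context position frequency
matrices, and the dominant repeat period.  Counts are normalized per million
reference-mapping reads (CPM) so conditions with different sequencing depth
are comparable.

Read coordinates are 0-based; position graphs place each read's first motif
hit at coordinate 0.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Read, ReadSet
from .templates import revcomp_dna

__all__ = [
    "EnrichedMotif",
    "MotifPositionGraph",
    "RepeatRunHistogram",
    "ContextLogo",
    "partition_unmapped",
    "discover_motifs",
    "scan_hits",
    "position_graph",
    "repeat_run_histogram",
    "count_min_repeat_reads",
    "context_logo",
    "estimate_period",
]

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class EnrichedMotif:
    """A differentially enriched motif.

    ``frac_wt``/``frac_ctrl`` are the fractions of WT/control unmapped reads
    containing the consensus in either orientation.  ``p_value`` is the
    one-sided two-proportion probability multiplied by the number of
    distinct k-mers tested at this width (a Bonferroni-style analogue of a
    motif-discovery E-value); ``p_raw`` is the uncorrected probability.
    ``n_sites`` counts motif occurrences across WT unmapped reads.
    """

    consensus: str
    width: int
    n_sites: int
    frac_wt: float
    frac_ctrl: float
    p_value: float
    p_raw: float = 0.0

    def __post_init__(self) -> None:
        if self.width != len(self.consensus):
            raise ValueError("width must equal consensus length")
        for name in ("frac_wt", "frac_ctrl"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class MotifPositionGraph:
    """Per-position motif hit counts, relative to each read's first hit.

    ``counts[i]`` is the number of hits starting at coordinate ``i`` after
    shifting every read so its first hit sits at 0; ``counts[0]`` therefore
    equals the number of motif-containing reads.  ``cpm`` is the same array
    scaled by 1e6 / n_reference_mapping (``None`` when the denominator is
    unavailable).
    """

    counts: np.ndarray
    cpm: Optional[np.ndarray]
    motif: str

    def to_frame(self) -> pd.DataFrame:
        data = {"position": np.arange(len(self.counts)), "count": self.counts}
        if self.cpm is not None:
            data["cpm"] = self.cpm
        return pd.DataFrame(data)


@dataclass
class RepeatRunHistogram:
    """Distribution over reads of the longest tandem motif run.

    ``bins`` maps run length (0 for motif-free reads, 1 for a single
    isolated hit) to read count; bin counts sum to the number of reads.
    """

    bins: Dict[int, int]
    median_run: int

    @property
    def n_reads(self) -> int:
        return sum(self.bins.values())


@dataclass
class ContextLogo:
    """Position frequency matrix of motif hits plus symmetric flanks.

    Rows are A/C/G/T; columns span ``motif_len + 2 * flank`` positions.
    Sites truncated at read edges contribute only to covered columns, so
    each column sums to the number of sites overlapping it.
    """

    pfm: np.ndarray
    motif: str
    flank: int

    def to_frame(self) -> pd.DataFrame:
        cols = np.arange(self.pfm.shape[1]) - self.flank
        return pd.DataFrame(self.pfm, index=list(_ALPHABET), columns=cols)


# ---------------------------------------------------------------------------
# partitioning


def partition_unmapped(
    reads: ReadSet, reference: str, min_anchor: int = 30
) -> Tuple[ReadSet, ReadSet]:
    """Split reads into reference-mapping and unmapped sets.

    A read maps when it shares an exact contiguous substring of at least
    ``min_anchor`` bases with the reference or its reverse complement — a
    deliberately simple anchor criterion standing in for a full aligner.
    Both returned sets carry ``n_reference_mapping`` equal to the mapped
    read count, the CPM denominator for all downstream quantities.
    """
    if len(reference) < min_anchor:
        raise ValueError(
            f"reference length {len(reference)} shorter than min_anchor {min_anchor}"
        )
    if min_anchor < 10:
        warnings.warn(
            f"min_anchor={min_anchor} < 10 invites spurious matches", stacklevel=2
        )
    anchors = set()
    for src in (reference, revcomp_dna(reference)):
        for i in range(len(src) - min_anchor + 1):
            anchors.add(src[i : i + min_anchor])
    mapped: list[Read] = []
    unmapped: list[Read] = []
    for read in reads:
        s = read.sequence
        hit = any(
            s[i : i + min_anchor] in anchors for i in range(len(s) - min_anchor + 1)
        )
        (mapped if hit else unmapped).append(read)
    n = len(mapped)
    return (
        ReadSet(reads=mapped, reference_id=reads.reference_id, n_reference_mapping=n),
        ReadSet(reads=unmapped, reference_id=reads.reference_id, n_reference_mapping=n),
    )


# ---------------------------------------------------------------------------
# motif discovery


def _kmer_read_counts(reads: Sequence[Read], w: int) -> Counter:
    """Number of reads containing each w-mer in either orientation."""
    counts: Counter = Counter()
    for read in reads:
        s = read.sequence
        if len(s) < w:
            continue
        kmers = {s[i : i + w] for i in range(len(s) - w + 1)}
        rc = revcomp_dna(s)
        kmers.update(rc[i : i + w] for i in range(len(rc) - w + 1))
        counts.update(kmers)
    return counts


def _two_proportion_one_sided(
    x1: np.ndarray, n1: int, x2: np.ndarray, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled one-sided z-test for p1 > p2; returns (z, p)."""
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / se, 0.0)
    return z, stats.norm.sf(z)


def _overlap_related(a: str, b: str, min_overlap: int = 5) -> bool:
    """True when two k-mers share a perfect ungapped overlap of at least
    ``min_overlap`` bases (containment included) in either orientation, or
    when one lies within a tandem concatemer of the other (rotations and
    junction-spanning words of the same repeat unit)."""
    for s in (b, revcomp_dna(b)):
        if a in s or s in a:
            return True
        if a in s * 3 or s in a * 3:
            return True
        top = min(len(a), len(s))
        for o in range(min_overlap, top):
            if a[-o:] == s[:o] or s[-o:] == a[:o]:
                return True
    return False


def _canonical_orientation(motif: str) -> str:
    """Deterministic strand choice: the lexicographically greater of the
    motif and its reverse complement (the data are strand-symmetric, so the
    choice is a reporting convention)."""
    return max(motif, revcomp_dna(motif))


def _trim_to_period(motif: str, min_period: int = 4, min_confirm: int = 3) -> str:
    """Collapse a k-mer that is itself tandem-periodic to one period, when at
    least ``min_confirm`` positions confirm the periodicity."""
    w = len(motif)
    for p in range(min_period, w - min_confirm + 1):
        if all(motif[i] == motif[i + p] for i in range(w - p)):
            return motif[:p]
    return motif


def _contains_either(read_seq: str, motif: str, motif_rc: str) -> bool:
    return motif in read_seq or motif_rc in read_seq


def discover_motifs(
    wt_unmapped: ReadSet,
    ctrl_unmapped: ReadSet,
    widths: Iterable[int] = range(6, 13),
    top_n: int = 5,
    support_retention: float = 0.95,
    max_candidates_per_width: int = 60,
) -> List[EnrichedMotif]:
    """Discover motifs differentially enriched in WT versus control unmapped
    reads by a transparent differential k-mer procedure.

    For each width, every k-mer (either orientation) is scored by the number
    of reads containing it and a one-sided two-proportion test of its WT
    versus control containment fractions.  Top-scoring k-mers across widths
    are then greedily clustered: a candidate joins the first (higher-scoring)
    cluster whose seed it perfectly overlaps by >= 5 bases or matches in
    reverse complement, so that rotations, sub-words and junction-spanning
    extensions of one tandem motif collapse into one cluster.

    The cluster consensus is the *longest* member whose WT read support is at
    least ``support_retention`` of the cluster's maximum.  For a tandem
    repeat this pins both the unit width and its phase: products carrying a
    single repeat unit contain the true unit but neither its rotations nor
    any junction-spanning extension, so the true unit is the unique longest
    k-mer retaining near-maximal support.  The consensus is reported in the
    lexicographically greater orientation and, if itself tandem-periodic,
    collapsed to one period.

    Reported significance is Bonferroni-scaled by the number of distinct
    k-mers tested at the consensus width (an E-value analogue); under a null
    where both sets come from the same generator no motif reaches small
    ``p_value``.
    """
    if len(wt_unmapped) == 0 or len(ctrl_unmapped) == 0:
        raise ValueError("discover_motifs requires nonempty WT and control read sets")
    n1, n2 = len(wt_unmapped), len(ctrl_unmapped)
    max_len = max(len(r.sequence) for r in list(wt_unmapped) + list(ctrl_unmapped))

    candidates: list[dict] = []
    wt_tables: dict[int, Counter] = {}
    ctrl_tables: dict[int, Counter] = {}
    n_tests: dict[int, int] = {}
    for w in widths:
        if w > max_len:
            warnings.warn(f"width {w} exceeds the longest read; skipped", stacklevel=2)
            continue
        cwt = _kmer_read_counts(wt_unmapped.reads, w)
        cctrl = _kmer_read_counts(ctrl_unmapped.reads, w)
        wt_tables[w], ctrl_tables[w] = cwt, cctrl
        keys = sorted(set(cwt) | set(cctrl))
        if not keys:
            continue
        n_tests[w] = len(keys)
        x1 = np.array([cwt.get(k, 0) for k in keys], dtype=float)
        x2 = np.array([cctrl.get(k, 0) for k in keys], dtype=float)
        z, p_raw = _two_proportion_one_sided(x1, n1, x2, n2)
        order = np.lexsort((np.array(keys, dtype=object), -x1, -z))
        for idx in order[:max_candidates_per_width]:
            if z[idx] <= 0:
                break
            candidates.append(
                {
                    "kmer": keys[idx],
                    "width": w,
                    "z": float(z[idx]),
                    "x1": int(x1[idx]),
                    "x2": int(x2[idx]),
                    "p_raw": float(p_raw[idx]),
                }
            )

    candidates.sort(key=lambda c: (-c["z"], -c["x1"], c["kmer"]))
    clusters: list[dict] = []
    for cand in candidates:
        for cluster in clusters:
            if _overlap_related(cand["kmer"], cluster["seed"]["kmer"]):
                cluster["members"].append(cand)
                break
        else:
            clusters.append({"seed": cand, "members": [cand]})

    motifs: list[EnrichedMotif] = []
    seen: set[str] = set()
    for cluster in clusters:
        members = cluster["members"]
        max_support = max(m["x1"] for m in members)
        if max_support == 0:
            continue
        qualified = [m for m in members if m["x1"] >= support_retention * max_support]
        best = max(qualified, key=lambda m: (len(m["kmer"]), m["x1"], m["z"], m["kmer"]))
        consensus = _canonical_orientation(_trim_to_period(best["kmer"]))
        # suppress rotations / sub-words / rc-forms of an already-reported motif
        if any(_overlap_related(consensus, prev) for prev in seen):
            continue
        seen.add(consensus)
        w = len(consensus)
        rc = revcomp_dna(consensus)
        wt_hits = sum(1 for r in wt_unmapped if _contains_either(r.sequence, consensus, rc))
        ctrl_hits = sum(1 for r in ctrl_unmapped if _contains_either(r.sequence, consensus, rc))
        z, p_raw = _two_proportion_one_sided(
            np.array([float(wt_hits)]), n1, np.array([float(ctrl_hits)]), n2
        )
        tests = n_tests.get(w, max(n_tests.values(), default=1))
        p_corr = float(min(1.0, p_raw[0] * tests))
        n_sites = sum(len(scan_hits(r.sequence, consensus)) for r in wt_unmapped)
        motifs.append(
            EnrichedMotif(
                consensus=consensus,
                width=w,
                n_sites=n_sites,
                frac_wt=wt_hits / n1,
                frac_ctrl=ctrl_hits / n2,
                p_value=p_corr,
                p_raw=float(p_raw[0]),
            )
        )
        if len(motifs) >= top_n:
            break
    return motifs


# ---------------------------------------------------------------------------
# scanning and quantification


def _scan_oriented(seq: str, motif: str, max_mismatches: int) -> List[int]:
    """Greedy left-to-right non-overlapping exact (or Hamming-tolerant) scan."""
    m = len(motif)
    hits: list[int] = []
    if max_mismatches <= 0:
        i = seq.find(motif)
        while i != -1:
            hits.append(i)
            i = seq.find(motif, i + m)
        return hits
    i = 0
    limit = len(seq) - m
    while i <= limit:
        window = seq[i : i + m]
        mism = sum(1 for a, b in zip(window, motif) if a != b)
        if mism <= max_mismatches:
            hits.append(i)
            i += m
        else:
            i += 1
    return hits


def _orient_and_scan(
    seq: str, motif: str, max_mismatches: int = 0
) -> Tuple[str, List[int]]:
    """Scan both orientations; keep the one with more hits (ties: forward)."""
    fwd = _scan_oriented(seq, motif, max_mismatches)
    rc = revcomp_dna(seq)
    rev = _scan_oriented(rc, motif, max_mismatches)
    if len(rev) > len(fwd):
        return rc, rev
    return seq, fwd


def scan_hits(read: str, motif: str, max_mismatches: int = 0) -> List[int]:
    """0-based start positions of non-overlapping motif hits in a read.

    Matching is greedy left-to-right; the read is scanned in both
    orientations and the orientation with more hits is used (ties resolve to
    the forward strand).  Positions refer to the chosen orientation.
    """
    if not motif:
        raise ValueError("motif must be nonempty")
    _, hits = _orient_and_scan(read, motif, max_mismatches)
    return hits


def position_graph(
    readset: ReadSet, motif: str, read_len: Optional[int] = None
) -> MotifPositionGraph:
    """Motif position graph: hit-start counts relative to each read's first hit.

    CPM scaling uses the read set's ``n_reference_mapping``; when that is
    zero the raw counts are still returned with ``cpm=None``.
    """
    if read_len is None:
        read_len = max((len(r.sequence) for r in readset), default=len(motif))
    counts = np.zeros(read_len, dtype=np.int64)
    for read in readset:
        hits = scan_hits(read.sequence, motif)
        if not hits:
            continue
        first = hits[0]
        for h in hits:
            counts[h - first] += 1
    if readset.n_reference_mapping > 0:
        cpm = counts * (1e6 / readset.n_reference_mapping)
    else:
        cpm = None
    return MotifPositionGraph(counts=counts, cpm=cpm, motif=motif)


def _longest_run(hits: Sequence[int], motif_len: int, max_interruptions: int = 0) -> int:
    """Longest chain of hits at exact motif spacing.

    With ``max_interruptions > 0``, up to that many skipped units (spacing an
    exact multiple of the motif length) may interrupt a chain.
    """
    if not hits:
        return 0
    best = 1
    run = 1
    budget = max_interruptions
    for prev, cur in zip(hits, hits[1:]):
        gap = cur - prev
        if gap == motif_len:
            run += 1
        elif (
            max_interruptions > 0
            and gap % motif_len == 0
            and (gap // motif_len - 1) <= budget
        ):
            budget -= gap // motif_len - 1
            run += 1
        else:
            run = 1
            budget = max_interruptions
        best = max(best, run)
    return best


def repeat_run_histogram(
    readset: ReadSet, motif: str, max_interruptions: int = 0
) -> RepeatRunHistogram:
    """Per-read longest tandem run of the motif, histogrammed over reads.

    A run is a chain of hits spaced exactly one motif length apart; a single
    isolated hit is a run of 1 and a motif-free read scores 0, so the bins
    always sum to the number of reads.
    """
    runs = [
        _longest_run(scan_hits(r.sequence, motif), len(motif), max_interruptions)
        for r in readset
    ]
    bins: Dict[int, int] = dict(sorted(Counter(runs).items()))
    median = int(np.median(runs)) if runs else 0
    return RepeatRunHistogram(bins=bins, median_run=median)


def count_min_repeat_reads(
    readset: ReadSet, motif: str, k: int = 3, max_interruptions: int = 0
) -> float:
    """Reads whose longest tandem run reaches ``k``, per million
    reference-mapping reads."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if readset.n_reference_mapping <= 0:
        raise ValueError("count_min_repeat_reads requires n_reference_mapping > 0")
    hist = repeat_run_histogram(readset, motif, max_interruptions)
    n = sum(count for run, count in hist.bins.items() if run >= k)
    return n * 1e6 / readset.n_reference_mapping


def context_logo(readset: ReadSet, motif: str, flank: int = 9) -> ContextLogo:
    """Position frequency matrix of every motif hit and its flanking context.

    For tandem-repeat products the flanks reproduce the motif shifted by one
    period — the direct-repeat signature.  Windows truncated by read edges
    contribute only to the columns they cover.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    m = len(motif)
    width = m + 2 * flank
    pfm = np.zeros((4, width), dtype=np.int64)
    for read in readset:
        oriented, hits = _orient_and_scan(read.sequence, motif)
        for h in hits:
            left = h - flank
            for col in range(width):
                pos = left + col
                if 0 <= pos < len(oriented):
                    base = oriented[pos]
                    idx = _BASE_INDEX.get(base)
                    if idx is not None:
                        pfm[idx, col] += 1
    return ContextLogo(pfm=pfm, motif=motif, flank=flank)


def estimate_period(graph: MotifPositionGraph) -> int:
    """Dominant repeat period of a motif position graph.

    The period is the mode of the spacings between successive nonzero
    positions, each spacing weighted by the smaller of the two flanking
    counts; ties break toward the smaller period.  Raises when fewer than
    two positions are nonzero (no spacing is defined).
    """
    nz = np.nonzero(graph.counts)[0]
    if len(nz) < 2:
        raise ValueError("period undefined: fewer than 2 nonzero positions in the graph")
    weights: Dict[int, int] = {}
    for a, b in zip(nz, nz[1:]):
        d = int(b - a)
        weights[d] = weights.get(d, 0) + int(min(graph.counts[a], graph.counts[b]))
    best_weight = max(weights.values())
    return min(d for d, wgt in weights.items() if wgt == best_weight)
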