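"""Stochastic model of protein-primed, telomerase-like cDNA repeat addition.

The DRT10 reverse transcriptase initiates cDNA synthesis from a serine side
chain (leaving a covalent 5′ protein–DNA linkage) and copies the A–B segment
of its ncRNA template.  The nascent cDNA then dissociates and its 3′ end
re-anneals at the downstream A′ register, priming the next round of
extension.  Iterative cycles of extension, dissociation, and template
resetting append one repeat unit — the reverse complement of A–B — per
cycle, producing kilobase tandem-repeat single-stranded DNA.

The model here makes that cycle explicit and testable:

* **Extension** always runs to the 5′ template boundary (the start of A,
  set by the upstream stem-loop in the real ncRNA).
* **Realignment** scans candidate annealing registers from the start of B
  through A′ and scores each by the contiguous Watson–Crick match length at
  the primer 3′ terminus.  Position-specific rules encode the experimentally
  observed asymmetries: the two 3′-terminal bases must pair; at the next
  depth a purine:purine clash aborts while a pyrimidine:pyrimidine mismatch
  is tolerated; deeper mismatches are free.
* **Reset success** decays sigmoidally with template (A+B) length; long B
  spacers (20-mers) abolish processive repeat addition while 10-mers only
  attenuate it.
* **Continuation** follows a geometric law with probability ``p_continue``
  per completed repeat, capped at ``max_cycles``.

The same module provides the synthetic sequencing layer: miniprep-seq-like
WT and RT-dead read sets mixing reference-derived background reads (plus a
small fraction of random-sequence library artifacts) with reads sampled from
simulated repeat products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np

from .templates import ABAPattern, NcRNATemplate, revcomp_dna, rna_to_cdna

__all__ = [
    "RealignRules",
    "SimConfig",
    "SimProduct",
    "Read",
    "ReadSet",
    "simulate_product",
    "generate_dataset",
]

# DNA primer base that pairs a given RNA template base (Watson-Crick).
_RNA_PARTNER = {"A": "T", "U": "A", "C": "G", "G": "C"}
_PURINES = frozenset("AG")

_DNA_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")


def _pairs(dna_base: str, rna_base: str) -> bool:
    return _RNA_PARTNER.get(rna_base) == dna_base


@dataclass(frozen=True)
class RealignRules:
    """Position-specific rules for primer re-annealing at a candidate register.

    Depth is counted from the primer 3′ terminus (depth 1 = 3′-most base).

    ``strict_positions``
        Depths that must pair exactly (default 2: mutating either of the
        first two bases of A or A′ abolishes repeat addition).
    ``purine_purine_block_depth``
        Up to this depth a purine:purine mismatch (greater steric clash)
        aborts realignment, while a pyrimidine:pyrimidine mismatch is
        tolerated (default 3: an A:A clash at depth 3 blocks, T:U does not).
    ``free_depth``
        From this depth on any mismatch is tolerated (default 4: the fourth
        base of A/A′ is dispensable).
    ``p_success_by_matchlen``
        Realignment success probability given the contiguous 3′-terminal
        match length; lengths above the largest key use the largest key's
        value, lengths below the smallest key have probability 0.
    """

    strict_positions: int = 2
    purine_purine_block_depth: int = 3
    free_depth: int = 4
    p_success_by_matchlen: Dict[int, float] = field(
        default_factory=lambda: {2: 0.05, 3: 0.5, 4: 0.95}
    )

    def __post_init__(self) -> None:
        if not (
            self.strict_positions
            <= self.purine_purine_block_depth
            <= self.free_depth
        ):
            raise ValueError(
                "need strict_positions <= purine_purine_block_depth <= free_depth, got "
                f"({self.strict_positions}, {self.purine_purine_block_depth}, {self.free_depth})"
            )
        for k, v in self.p_success_by_matchlen.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"p_success_by_matchlen[{k}]={v} outside [0, 1]")

    def success_prob(self, match_len: int) -> float:
        if not self.p_success_by_matchlen:
            return 0.0
        keys = sorted(self.p_success_by_matchlen)
        if match_len < keys[0]:
            return 0.0
        if match_len >= keys[-1]:
            return self.p_success_by_matchlen[keys[-1]]
        return self.p_success_by_matchlen.get(match_len, 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the repeat-addition simulator and read generator.

    ``p_continue``
        Probability of attempting another cycle after each completed repeat
        (geometric cycle-count law).
    ``template_len_midpoint`` / ``template_len_slope``
        Template (A+B) length, in nt, at which reset success has decayed to
        50%, and the nt scale of the logistic decay.  With the defaults a
        native-length 9-nt template resets at ~97% of the rule-based rate, a
        14-nt template at 50%, and a 24-nt template at ~0.1%.
    ``seq_error_rate``
        Per-base substitution probability applied to emitted reads.
    ``background_fraction``
        Fraction of WT reads drawn from the reference; the RT-dead condition
        is background-only.
    ``artifact_fraction``
        Fraction of background reads that are random-sequence library
        artifacts rather than reference windows.  These emulate the
        reference-unmappable junk that dominates real miniprep-seq unmapped
        sets and give the control condition a nonempty unmapped fraction.
    ``seed``
        Seed for all randomness; required for dataset generation.
    """

    p_continue: float = 0.98
    max_cycles: int = 500
    realign_rules: RealignRules = field(default_factory=RealignRules)
    template_len_midpoint: float = 14.0
    template_len_slope: float = 1.5
    seq_error_rate: float = 0.001
    read_len: int = 150
    background_fraction: float = 0.7
    artifact_fraction: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("p_continue", "seq_error_rate", "background_fraction", "artifact_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.max_cycles < 1:
            raise ValueError(f"max_cycles must be >= 1, got {self.max_cycles}")
        if self.read_len < 1:
            raise ValueError(f"read_len must be >= 1, got {self.read_len}")
        if self.template_len_slope <= 0:
            raise ValueError("template_len_slope must be positive")

    def reset_decay(self, template_len: int) -> float:
        """Logistic decay of reset success with A+B template length."""
        x = (template_len - self.template_len_midpoint) / self.template_len_slope
        # clamp to avoid overflow for extreme template lengths
        if x > 60:
            return 0.0
        if x < -60:
            return 1.0
        return 1.0 / (1.0 + math.exp(x))


@dataclass(frozen=True)
class SimProduct:
    """One simulated single-stranded cDNA product.

    ``sequence`` is the cDNA 5′→3′; ``realign_sites`` records the 1-based
    template position chosen at each successful reset (the canonical site is
    the start of A′; sites inside B mark cryptic re-annealing).  Unit lengths
    may therefore vary within one product, so ``len(sequence)`` need not be
    ``n_repeats`` times the motif length.  ``protein_primed_5prime`` is
    always true and documents the covalent 5′ protein linkage (priming
    chemistry itself is not modeled).
    """

    sequence: str
    n_repeats: int
    realign_sites: tuple[int, ...]
    protein_primed_5prime: bool = True


Condition = Literal["WT", "RT_dead"]
Truth = Literal["repeat_product", "background"]


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    condition: Condition
    truth: Truth


@dataclass
class ReadSet:
    """Labeled sequencing reads plus the normalization denominator.

    ``n_reference_mapping`` is the count of reference-mapping reads used for
    counts-per-million normalization.  The generator sets it to the number
    of reference-derived background reads; the read pipeline's partition
    step replaces it with the empirically mapped count.
    """

    reads: List[Read]
    reference_id: str = "reference"
    n_reference_mapping: int = 0

    def __post_init__(self) -> None:
        if self.n_reference_mapping < 0:
            raise ValueError("n_reference_mapping must be >= 0")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


def _coerce_rng(
    rng: Optional[np.random.Generator], seed: Optional[int]
) -> np.random.Generator:
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError("a seed (or an explicit rng) is required for stochastic simulation")
    return np.random.default_rng(seed)


def _match_len_and_admissible(
    primer: str, seq: str, p: int, rules: RealignRules
) -> tuple[int, bool]:
    """Contiguous 3′-terminal match length for the primer annealed with its
    3′ base at template position ``p`` (1-based), plus rule admissibility."""
    n_t = len(seq)
    k = 0
    while (
        k < len(primer)
        and p - 1 + k < n_t
        and _pairs(primer[-1 - k], seq[p - 1 + k])
    ):
        k += 1
    if k < rules.strict_positions:
        return k, False
    depth = k + 1  # depth of the first mismatch, if one exists
    if (
        depth < rules.free_depth
        and depth <= rules.purine_purine_block_depth
        and k < len(primer)
        and p - 1 + k < n_t
    ):
        primer_base = primer[-1 - k]
        tmpl_base = seq[p - 1 + k]
        if primer_base in _PURINES and tmpl_base in _PURINES:
            return k, False
    return k, True


def simulate_product(
    template: NcRNATemplate,
    pattern: ABAPattern,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimProduct:
    """Simulate one repeat-addition product from a template and pattern.

    Cycle 1 reverse-transcribes A+B from the 3′ end of B to the 5′ end of A,
    yielding one repeat unit.  Each further cycle requires (a) a continuation
    draw below ``p_continue``, (b) an admissible annealing register — the
    highest-scoring position from the start of B through the end of A′, ties
    broken by proximity to the canonical A′ start and then by a seeded random
    draw — and (c) a success draw below
    ``p_success_by_matchlen[score] * reset_decay(a_len + b_len)``.
    Extension then copies the template from just 5′ of the register down to
    the template boundary.

    The pattern's coordinates are trusted even when A and A′ mismatch on the
    given sequence (mutant templates); templating always uses the actual A+B
    sequence and realignment always reads the actual A′/B bases, so mutating
    A alone, A′ alone, or both in compensation reproduces the experimentally
    observed loss and rescue of repeat addition.
    """
    rng = _coerce_rng(rng, config.seed)
    seq = template.sequence
    if pattern.span_end > len(seq) or pattern.a_start < 1:
        raise ValueError(
            f"pattern span {pattern.a_start}..{pattern.span_end} out of bounds for "
            f"template {template.id!r} (length {len(seq)})"
        )
    a0 = pattern.a_start - 1  # 0-based template boundary (start of A)
    b_start = pattern.a_start + pattern.a_len  # first position of B (or A' if B empty)
    aprime_start = pattern.aprime_start
    aprime_end = pattern.span_end
    template_len = pattern.a_len + pattern.b_len
    decay = config.reset_decay(template_len)
    rules = config.realign_rules

    # cycle 1: one full unit, templated by the actual A+B sequence
    unit = rna_to_cdna(seq[a0 : a0 + template_len])
    chunks = [unit]
    primer = unit
    n_repeats = 1
    realign_sites: list[int] = []

    while n_repeats < config.max_cycles:
        if rng.random() >= config.p_continue:
            break
        candidates: list[tuple[int, int]] = []  # (site, score)
        best_score = -1
        for p in range(b_start, aprime_end + 1):
            score, ok = _match_len_and_admissible(primer, seq, p, rules)
            if ok:
                candidates.append((p, score))
                best_score = max(best_score, score)
        if not candidates:
            break
        top = [p for p, s in candidates if s == best_score]
        min_dist = min(abs(p - aprime_start) for p in top)
        top = [p for p in top if abs(p - aprime_start) == min_dist]
        site = top[0] if len(top) == 1 else int(top[rng.integers(len(top))])
        p_succ = rules.success_prob(best_score) * decay
        if rng.random() >= p_succ:
            break
        ext = rna_to_cdna(seq[a0 : site - 1])
        chunks.append(ext)
        # the scoring loop only ever inspects the primer's 3'-terminal bases;
        # keep a generous tail so contiguous-match scores are never truncated
        primer = (primer + ext)[-64:]
        realign_sites.append(site)
        n_repeats += 1

    sequence = "".join(chunks)
    return SimProduct(sequence=sequence, n_repeats=n_repeats, realign_sites=tuple(realign_sites))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_DNA_ALPHABET, size=n).tobytes().decode()


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def generate_dataset(
    template: Optional[NcRNATemplate],
    pattern: Optional[ABAPattern],
    reference: str,
    config: SimConfig,
    n_reads: int,
    condition: Condition = "WT",
    rng: Optional[np.random.Generator] = None,
) -> ReadSet:
    """Generate a miniprep-seq-like read set for one condition.

    WT reads are background (reference windows on either strand, with an
    ``artifact_fraction`` of random-sequence artifacts) with probability
    ``background_fraction``, otherwise windows of independently simulated
    repeat products (products shorter than ``read_len`` are emitted whole,
    on either strand).  The RT-dead condition is background only.
    Substitution errors are applied at ``seq_error_rate``.  Fully
    reproducible from ``config.seed``.
    """
    if n_reads <= 0:
        raise ValueError(f"n_reads must be positive, got {n_reads}")
    if len(reference) < config.read_len:
        raise ValueError(
            f"reference length {len(reference)} shorter than read_len {config.read_len}"
        )
    if condition == "WT":
        if pattern is None or template is None:
            raise ValueError("WT condition requires a template and an A-B-A' pattern")
        if config.read_len < pattern.motif_len:
            raise ValueError(
                f"read_len {config.read_len} shorter than the {pattern.motif_len}-nt motif"
            )
    rng = _coerce_rng(rng, config.seed)

    reads: list[Read] = []
    n_reference = 0
    ref_rc = revcomp_dna(reference)
    max_ref_start = len(reference) - config.read_len
    for i in range(n_reads):
        is_background = condition == "RT_dead" or rng.random() < config.background_fraction
        if is_background:
            truth: Truth = "background"
            if rng.random() < config.artifact_fraction:
                s = _random_dna(rng, config.read_len)
            else:
                start = int(rng.integers(max_ref_start + 1))
                src = reference if rng.random() < 0.5 else ref_rc
                s = src[start : start + config.read_len]
                n_reference += 1
        else:
            truth = "repeat_product"
            product = simulate_product(template, pattern, config, rng)  # type: ignore[arg-type]
            s = product.sequence
            if len(s) > config.read_len:
                start = int(rng.integers(len(s) - config.read_len + 1))
                s = s[start : start + config.read_len]
            if rng.random() < 0.5:
                s = revcomp_dna(s)
        s = _apply_errors(s, config.seq_error_rate, rng)
        reads.append(Read(id=f"{condition}_{i:06d}", sequence=s, condition=condition, truth=truth))
    return ReadSet(reads=reads, reference_id="reference", n_reference_mapping=n_reference)
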