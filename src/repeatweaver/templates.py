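"""ncRNA templates and A–B–A′ direct-repeat pattern analysis.

DRT10-class antiphage reverse transcriptases synthesize long tandem-repeat
single-stranded cDNAs from a short template embedded in the unpaired loop of
their associated ncRNA.  The template architecture is a direct repeat,
written A–B–A′: the enzyme reverse-transcribes the A–B segment, the nascent
cDNA dissociates, and its 3′ end re-anneals to the downstream copy A′ of the
A segment — priming another round of synthesis, exactly as in telomerase
repeat addition processivity.  Each cycle therefore appends one cDNA repeat
unit equal to the reverse complement of A–B.

This module finds A–B–A′ patterns in ncRNA sequences, predicts the encoded
cDNA repeat motif, designs templates that encode arbitrary repeats (e.g. the
telomeric ``TTAGGG``), and screens ncRNA collections for pattern prevalence.

Conventions
-----------
* ncRNA coordinates are 1-based inclusive, matching the field's mutation
  nomenclature (e.g. "U110A").
* Detection requires *exact* A = A′ identity.  Tolerance to mismatched
  realignment is a property of the polymerase, modeled in
  :mod:`repeatweaver.simulate`, not of the pattern detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "NcRNATemplate",
    "ABAPattern",
    "ABASearchParams",
    "PrevalenceResult",
    "find_aba_patterns",
    "predict_repeat_motif",
    "design_template",
    "batch_aba_prevalence",
    "revcomp_dna",
    "rna_to_cdna",
    "dna_to_template_rna",
]

RNA_BASES = frozenset("ACGU")
DNA_BASES = frozenset("ACGT")

_RNA_TO_CDNA = str.maketrans("ACGU", "TGCA")
_DNA_COMP = str.maketrans("ACGT", "TGCA")
_DNA_TO_TEMPLATE = str.maketrans("ACGT", "UGCA")

_CLOSING = {")": "(", "]": "[", "}": "{", ">": "<"}
_OPENING = frozenset(_CLOSING.values())


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_DNA_COMP)[::-1]


def rna_to_cdna(seq: str) -> str:
    """cDNA (5′→3′ DNA) templated by an RNA segment given 5′→3′.

    Reverse transcription reads the template 3′→5′, so the cDNA is the
    reverse complement of the segment with U→A, A→T, C→G, G→C.
    """
    return seq.translate(_RNA_TO_CDNA)[::-1]


def dna_to_template_rna(seq: str) -> str:
    """RNA template segment (5′→3′) whose reverse transcript is ``seq``."""
    return seq.translate(_DNA_TO_TEMPLATE)[::-1]


def check_balanced_structure(structure: str) -> None:
    """Validate a dot-bracket string (``.`` plus balanced bracket pairs)."""
    stack: list[str] = []
    for i, ch in enumerate(structure):
        if ch == ".":
            continue
        if ch in _OPENING:
            stack.append(ch)
        elif ch in _CLOSING:
            if not stack or stack[-1] != _CLOSING[ch]:
                raise ValueError(
                    f"unbalanced bracket {ch!r} at position {i + 1} in dot-bracket string"
                )
            stack.pop()
        else:
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {i + 1}")
    if stack:
        raise ValueError(f"{len(stack)} unclosed bracket(s) in dot-bracket string")


def _max_unpaired_run(structure: str) -> Optional[tuple[int, int]]:
    """Longest run of '.' in a dot-bracket string, 1-based inclusive (first on tie)."""
    best: Optional[tuple[int, int]] = None
    start = None
    for i, ch in enumerate(structure + "("):  # sentinel terminates a trailing run
        if ch == "." and start is None:
            start = i
        elif ch != "." and start is not None:
            if best is None or i - start > best[1] - best[0] + 1:
                best = (start + 1, i)
            start = None
    return best


@dataclass(frozen=True)
class NcRNATemplate:
    """An ncRNA sequence, with optional structure and template-loop annotation.

    Parameters
    ----------
    id:
        Record identifier.
    sequence:
        RNA sequence over {A, C, G, U}, 5′→3′.
    structure:
        Optional dot-bracket string of the same length with balanced brackets.
    loop_interval:
        Optional 1-based inclusive ``(start, end)`` delimiting the template
        loop that is searched for A–B–A′ patterns.
    """

    id: str
    sequence: str
    structure: Optional[str] = None
    loop_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"template {self.id!r}: sequence is empty")
        bad = set(self.sequence) - RNA_BASES
        if bad:
            raise ValueError(
                f"template {self.id!r}: non-RNA characters {sorted(bad)} in sequence "
                "(expected A/C/G/U; DNA input should be normalized with T->U)"
            )
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise ValueError(
                    f"template {self.id!r}: structure length {len(self.structure)} "
                    f"!= sequence length {len(self.sequence)}"
                )
            check_balanced_structure(self.structure)
        if self.loop_interval is not None:
            lo, hi = self.loop_interval
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise ValueError(
                    f"template {self.id!r}: loop_interval {self.loop_interval} outside "
                    f"[1, {len(self.sequence)}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def effective_loop(self) -> Optional[tuple[int, int]]:
        """Template-loop interval: the annotation if present, else the maximal
        unpaired run of the dot-bracket structure, else ``None``."""
        if self.loop_interval is not None:
            return self.loop_interval
        if self.structure is not None:
            return _max_unpaired_run(self.structure)
        return None


@dataclass(frozen=True)
class ABAPattern:
    """A located A–B–A′ direct repeat and the cDNA repeat motif it encodes.

    ``a_start`` and ``aprime_start`` are 1-based template positions of the two
    copies of A; ``b_len`` may be zero (A′ directly follows A).  Geometry:
    ``aprime_start = a_start + a_len + b_len`` and
    ``len(motif_dna) = a_len + b_len``.
    """

    a_start: int
    a_len: int
    b_len: int
    aprime_start: int
    motif_dna: str

    def __post_init__(self) -> None:
        if self.a_len < 1 or self.b_len < 0 or self.a_start < 1:
            raise ValueError(f"invalid A-B-A' geometry: {self}")
        if self.aprime_start != self.a_start + self.a_len + self.b_len:
            raise ValueError(
                f"A' start {self.aprime_start} != a_start + a_len + b_len "
                f"= {self.a_start + self.a_len + self.b_len}"
            )
        if len(self.motif_dna) != self.a_len + self.b_len:
            raise ValueError(
                f"motif length {len(self.motif_dna)} != a_len + b_len "
                f"= {self.a_len + self.b_len}"
            )
        bad = set(self.motif_dna) - DNA_BASES
        if bad:
            raise ValueError(f"non-DNA characters {sorted(bad)} in motif {self.motif_dna!r}")

    @property
    def motif_len(self) -> int:
        return self.a_len + self.b_len

    @property
    def span_end(self) -> int:
        """1-based inclusive end of the full A–B–A′ span (last base of A′)."""
        return self.aprime_start + self.a_len - 1

    @property
    def midpoint(self) -> float:
        """Midpoint of the A–B–A′ span, used for non-redundant prevalence plots."""
        return (self.a_start + self.span_end) / 2

    @classmethod
    def from_coords(
        cls,
        template: NcRNATemplate,
        a_start: int,
        a_len: int,
        b_len: int,
        check_identity: bool = True,
    ) -> "ABAPattern":
        """Build a pattern from coordinates on a template.

        ``check_identity=False`` permits mutated templates whose A and A′
        copies no longer match (used when simulating mutant ncRNAs); the
        motif is always re-derived from the actual A–B sequence.
        """
        aprime_start = a_start + a_len + b_len
        end = aprime_start + a_len - 1
        if a_start < 1 or end > len(template):
            raise ValueError(
                f"pattern ({a_start}, a_len={a_len}, b_len={b_len}) out of bounds "
                f"for template {template.id!r} of length {len(template)}"
            )
        seq = template.sequence
        a = seq[a_start - 1 : a_start - 1 + a_len]
        aprime = seq[aprime_start - 1 : aprime_start - 1 + a_len]
        if check_identity and a != aprime:
            raise ValueError(
                f"A ({a}) and A' ({aprime}) differ on template {template.id!r}; "
                "pass check_identity=False for mutated templates"
            )
        motif = rna_to_cdna(seq[a_start - 1 : a_start - 1 + a_len + b_len])
        return cls(a_start, a_len, b_len, aprime_start, motif)


@dataclass(frozen=True)
class ABASearchParams:
    """Bounds for the A–B–A′ search.

    ``min_a``/``max_a`` bound the A = A′ homology length (natural systems use
    2–4 nt); ``min_motif``/``max_motif`` bound the repeat-unit length
    ``a_len + b_len``.  When ``restrict_to_loop`` is set, the search runs
    within the template-loop interval (annotated or structure-derived), where
    A–B–A′ patterns concentrate in native ncRNAs.
    """

    min_a: int = 2
    max_a: int = 10
    min_motif: int = 4
    max_motif: int = 30
    restrict_to_loop: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_a <= self.max_a):
            raise ValueError(f"need 1 <= min_a <= max_a, got ({self.min_a}, {self.max_a})")
        if not (1 <= self.min_motif <= self.max_motif):
            raise ValueError(
                f"need 1 <= min_motif <= max_motif, got ({self.min_motif}, {self.max_motif})"
            )


def _search_interval(template: NcRNATemplate, params: ABASearchParams) -> tuple[int, int]:
    if params.restrict_to_loop:
        loop = template.effective_loop()
        if loop is None:
            raise ValueError(
                f"template {template.id!r}: restrict_to_loop requires a loop_interval "
                "or a dot-bracket structure"
            )
        return loop
    return (1, len(template))


def find_aba_patterns(
    template: NcRNATemplate, params: ABASearchParams | None = None
) -> list[ABAPattern]:
    """Enumerate maximal A–B–A′ direct-repeat patterns on a template.

    Returns every pattern with exact A = A′ identity, ``a_len`` within
    ``[min_a, max_a]``, repeat-unit length within ``[min_motif, max_motif]``,
    fully contained in the search interval.  Two redundancy filters apply:

    * For a fixed pair of A/A′ start positions, only the longest admissible A
      is reported (a shorter A with the same starts is the same repeat with
      part of A relabeled as B).
    * A pattern is suppressed when both copies of A can be extended one base
      leftward (5′-ward) while preserving identity and all bounds — the
      extended pattern, which converts the last base of B into A, subsumes it.

    Output is ordered by ``a_len`` descending, then ``b_len`` ascending, then
    ``a_start`` ascending.  Longest-A-first ranking reflects that A–A′
    homology length drives realignment efficiency, and recovers the native
    pattern first on characterized DRT10 ncRNAs.
    """
    params = params or ABASearchParams()
    lo, hi = _search_interval(template, params)
    seq = template.sequence

    def max_a_len(a_start: int, d: int) -> int:
        """Longest admissible A for A at ``a_start`` and A′ at ``a_start + d``."""
        aprime_start = a_start + d
        # containment of A′ within [lo, hi]; b_len >= 0 caps a_len at d
        cap = min(params.max_a, d, hi - aprime_start + 1)
        m = 0
        while (
            m < cap
            and seq[a_start - 1 + m] == seq[aprime_start - 1 + m]
        ):
            m += 1
        return m

    found: list[ABAPattern] = []
    for d in range(params.min_motif, params.max_motif + 1):
        for a_start in range(lo, hi - d + 1):
            a_len = max_a_len(a_start, d)
            if a_len < params.min_a:
                continue
            b_len = d - a_len
            # leftward-maximality: drop if (a_start-1, a_len+1, b_len-1) is valid
            if (
                b_len >= 1
                and a_len + 1 <= params.max_a
                and a_start - 1 >= lo
                and seq[a_start - 2] == seq[a_start + d - 2]
            ):
                continue
            found.append(ABAPattern.from_coords(template, a_start, a_len, b_len))
    found.sort(key=lambda p: (-p.a_len, p.b_len, p.a_start))
    return found


def predict_repeat_motif(pattern: ABAPattern, template: NcRNATemplate) -> str:
    """cDNA repeat motif encoded by a pattern: the DNA reverse complement of
    the A+B template segment (5′→3′ of the cDNA)."""
    end = pattern.a_start - 1 + pattern.motif_len
    if pattern.a_start < 1 or pattern.span_end > len(template):
        raise ValueError(
            f"pattern out of bounds for template {template.id!r} "
            f"(span {pattern.a_start}..{pattern.span_end}, length {len(template)})"
        )
    return rna_to_cdna(template.sequence[pattern.a_start - 1 : end])


def design_template(motif_dna: str, a_len: int) -> str:
    """Design an RNA template segment whose repeat product is ``motif_dna``.

    The segment is the reverse-complement RNA of the motif (the A–B template)
    followed by a copy of its own first ``a_len`` bases (the A′ realignment
    register).  Running :func:`find_aba_patterns` on the result recovers a
    pattern whose :func:`predict_repeat_motif` equals ``motif_dna``.
    """
    bad = set(motif_dna) - DNA_BASES
    if bad:
        raise ValueError(f"non-DNA characters {sorted(bad)} in motif {motif_dna!r}")
    if not (1 <= a_len < len(motif_dna)):
        raise ValueError(
            f"a_len must satisfy 1 <= a_len < motif length; got a_len={a_len} "
            f"for a {len(motif_dna)}-nt motif"
        )
    ab = dna_to_template_rna(motif_dna)
    return ab + ab[:a_len]


class PrevalenceResult(NamedTuple):
    """Per-ncRNA pattern table plus the aggregate fraction with a pattern.

    ``fraction`` is ``None`` (not zero) for empty input.
    """

    table: pd.DataFrame
    fraction: Optional[float]


def batch_aba_prevalence(
    templates: Sequence[NcRNATemplate], params: ABASearchParams | None = None
) -> PrevalenceResult:
    """Screen a collection of ncRNAs for A–B–A′ patterns.

    One row per ncRNA with its top-ranked pattern (if any) and the pattern
    midpoint (one midpoint per ncRNA, for non-redundant position plots), plus
    the aggregate fraction of ncRNAs harboring an identifiable pattern.
    """
    rows = []
    for t in templates:
        patterns = find_aba_patterns(t, params)
        if patterns:
            p = patterns[0]
            rows.append(
                {
                    "id": t.id,
                    "has_pattern": True,
                    "a_start": p.a_start,
                    "a_len": p.a_len,
                    "b_len": p.b_len,
                    "aprime_start": p.aprime_start,
                    "motif_dna": p.motif_dna,
                    "motif_midpoint": p.midpoint,
                }
            )
        else:
            rows.append(
                {
                    "id": t.id,
                    "has_pattern": False,
                    "a_start": pd.NA,
                    "a_len": pd.NA,
                    "b_len": pd.NA,
                    "aprime_start": pd.NA,
                    "motif_dna": pd.NA,
                    "motif_midpoint": pd.NA,
                }
            )
    columns = [
        "id",
        "has_pattern",
        "a_start",
        "a_len",
        "b_len",
        "aprime_start",
        "motif_dna",
        "motif_midpoint",
    ]
    table = pd.DataFrame(rows, columns=columns)
    fraction = float(table["has_pattern"].mean()) if len(table) else None
    return PrevalenceResult(table, fraction)
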