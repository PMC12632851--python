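"""File I/O: FASTA/FASTQ records, dot-bracket sidecar tables, TSV/JSON.

Alphabet normalization happens exactly once, at ingest: sequences are
uppercased and T/U are interconverted according to the declared molecule
type.  Parse failures name the file, record index, and offending content.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Read, ReadSet
from .templates import NcRNATemplate, check_balanced_structure

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_dot_bracket_tsv",
    "read_templates",
    "write_tsv",
    "write_json",
    "write_readset",
    "read_readset",
]

PathLike = Union[str, Path]

_T_TO_U = str.maketrans("Tt", "Uu")
_U_TO_T = str.maketrans("Uu", "Tt")


def _normalize(seq: str, molecule: Optional[str]) -> str:
    if molecule == "rna":
        seq = seq.translate(_T_TO_U)
    elif molecule == "dna":
        seq = seq.translate(_U_TO_T)
    elif molecule is not None:
        raise ValueError(f"molecule must be 'dna', 'rna', or None, got {molecule!r}")
    return seq.upper()


def read_fasta(path: PathLike, molecule: Optional[str] = "dna") -> List[Tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs.

    ``molecule`` selects the output alphabet: ``"dna"`` maps U->T, ``"rna"``
    maps T->U, ``None`` leaves bases untouched; all are uppercased.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            seq = _normalize(str(rec.seq), molecule)
            if not seq:
                raise ValueError(f"{path}: record {i + 1} ({rec.id!r}) has an empty sequence")
            records.append((rec.id, seq))
    except ValueError as exc:
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    return records


def write_fasta(path: PathLike, records: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path: PathLike) -> List[Tuple[str, str, str]]:
    """Read FASTQ records as ``(id, sequence, quality_string)`` triples."""
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    count = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            count += 1
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            records.append((rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ in {path} at record {count + 1}: {exc}"
        ) from exc
    return records


def write_fastq(
    path: PathLike,
    records: Iterable[Union[Tuple[str, str], Tuple[str, str, str]]],
    default_quality: str = "I",
) -> None:
    """Write FASTQ; records lacking a quality string get a constant one."""
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 2:
                rec_id, seq = rec  # type: ignore[misc]
                qual = default_quality * len(seq)
            else:
                rec_id, seq, qual = rec  # type: ignore[misc]
            if len(qual) != len(seq):
                raise ValueError(
                    f"record {rec_id!r}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            fh.write(f"@{rec_id}\n{seq}\n+\n{qual}\n")


def read_dot_bracket_tsv(path: PathLike) -> dict:
    """Read a sidecar TSV with columns id, loop_start, loop_end, dot_bracket.

    ``loop_start``/``loop_end`` may be empty (structure-only records) and
    ``dot_bracket`` may be empty (interval-only records).  Returns a mapping
    id -> dict(loop_interval, structure).  Unbalanced structures raise an
    error naming the record.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "loop_start", "loop_end", "dot_bracket"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict = {}
    for i, row in df.iterrows():
        rec_id = row["id"]
        structure = row["dot_bracket"] or None
        if structure is not None:
            try:
                check_balanced_structure(structure)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: record {i + 1} ({rec_id!r}), line {i + 2}: {exc}"
                ) from exc
        interval = None
        if row["loop_start"] or row["loop_end"]:
            try:
                interval = (int(row["loop_start"]), int(row["loop_end"]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: record {i + 1} ({rec_id!r}): non-integer loop bounds"
                ) from exc
        out[rec_id] = {"loop_interval": interval, "structure": structure}
    return out


def read_templates(
    fasta_path: PathLike, sidecar_path: Optional[PathLike] = None
) -> List[NcRNATemplate]:
    """Load ncRNA templates from FASTA (T normalized to U) with an optional
    dot-bracket / loop-interval sidecar TSV."""
    sidecar = read_dot_bracket_tsv(sidecar_path) if sidecar_path else {}
    templates = []
    for rec_id, seq in read_fasta(fasta_path, molecule="rna"):
        extra = sidecar.get(rec_id, {})
        templates.append(
            NcRNATemplate(
                id=rec_id,
                sequence=seq,
                structure=extra.get("structure"),
                loop_interval=extra.get("loop_interval"),
            )
        )
    return templates


def write_tsv(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_json(path: PathLike, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_readset(
    readset: ReadSet, fastq_path: PathLike, truth_path: Optional[PathLike] = None
) -> None:
    """Write a read set as FASTQ (constant quality) plus an optional paired
    truth table (id, condition, truth)."""
    write_fastq(fastq_path, ((r.id, r.sequence) for r in readset))
    if truth_path is not None:
        table = pd.DataFrame(
            [{"id": r.id, "condition": r.condition, "truth": r.truth} for r in readset]
        )
        table["n_reference_mapping"] = readset.n_reference_mapping
        write_tsv(truth_path, table)


def read_readset(
    fastq_path: PathLike,
    condition: str = "WT",
    truth_path: Optional[PathLike] = None,
    n_reference_mapping: int = 0,
) -> ReadSet:
    """Load a read set from FASTQ, optionally restoring labels from a truth
    table written by :func:`write_readset`."""
    truth_map = {}
    if truth_path is not None:
        table = pd.read_csv(truth_path, sep="\t", dtype=str)
        truth_map = {row["id"]: row for _, row in table.iterrows()}
        if len(table) and "n_reference_mapping" in table.columns:
            n_reference_mapping = int(table["n_reference_mapping"].iloc[0])
    reads = []
    for rec_id, seq, _ in read_fastq(fastq_path):
        row = truth_map.get(rec_id)
        reads.append(
            Read(
                id=rec_id,
                sequence=seq,
                condition=(row["condition"] if row is not None else condition),  # type: ignore[arg-type]
                truth=(row["truth"] if row is not None else "background"),  # type: ignore[arg-type]
            )
        )
    return ReadSet(reads=reads, n_reference_mapping=n_reference_mapping)
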