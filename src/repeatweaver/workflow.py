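"""End-to-end pipeline: simulate -> partition -> discover -> quantify.

A :class:`RunConfig` binds the stage parameter blocks, a mandatory seed for
any stochastic stage, and an output directory.  ``run_pipeline`` executes
the requested stage subset, writes every artifact (FASTQ, truth tables,
pattern/motif/graph/histogram TSVs, PFM) plus a JSON run report with the
exact parameters and seed, and is byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .pipeline import (
    context_logo,
    count_min_repeat_reads,
    discover_motifs,
    estimate_period,
    partition_unmapped,
    position_graph,
    repeat_run_histogram,
)
from .seqio import read_fasta, read_templates, write_json, write_readset, write_tsv
from .simulate import RealignRules, SimConfig, generate_dataset
from .templates import ABASearchParams, NcRNATemplate, find_aba_patterns

__all__ = ["RunConfig", "run_pipeline", "demo_template", "derive_seed", "random_reference"]

logger = logging.getLogger("repeatweaver")

ALL_STAGES = ("simulate", "partition", "discover", "quantify")

#: Template-loop segment of the characterized E. coli DRT10 ncRNA,
#: reconstructed as the reverse complement of its 9-nt cDNA repeat motif
#: (GAATCATTG) followed by the A' copy of the 4-nt A segment.
DEMO_TEMPLATE_RNA = "CAAUGAUUCCAAU"


def demo_template() -> NcRNATemplate:
    """Built-in demo ncRNA template-loop segment (A=CAAU, B=GAUUC, A'=CAAU)."""
    return NcRNATemplate(id="demo_drt10_loop", sequence=DEMO_TEMPLATE_RNA)


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic per-stage child seed (kept below 2**31)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] % (2**31))


def random_reference(seed: int, length: int = 3000) -> str:
    """Seeded random reference sequence (stands in for an expression plasmid)."""
    rng = np.random.default_rng(seed)
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length).tobytes().decode()


@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    Only ``seed`` and ``outdir`` are mandatory; every other field has a
    demo-friendly default.  ``template_fasta``/``template_sidecar`` override
    the built-in template; ``reference_fasta`` overrides the seeded random
    reference of ``reference_len`` nt.
    """

    seed: Optional[int]
    outdir: Path
    stages: Sequence[str] = ALL_STAGES
    template_fasta: Optional[Path] = None
    template_sidecar: Optional[Path] = None
    template_id: Optional[str] = None
    reference_fasta: Optional[Path] = None
    reference_len: int = 3000
    n_reads: int = 10000
    aba_params: ABASearchParams = field(
        default_factory=lambda: ABASearchParams(restrict_to_loop=False)
    )
    sim: SimConfig = field(default_factory=SimConfig)
    widths: Sequence[int] = tuple(range(6, 13))
    top_n: int = 5
    min_anchor: int = 30
    min_run_k: int = 3
    flank: int = 9

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {ALL_STAGES}")
        stochastic = "simulate" in self.stages or self.reference_fasta is None
        if stochastic and self.seed is None:
            raise ValueError("a seed is mandatory when any stochastic stage is enabled")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "aba_params" in raw and isinstance(raw["aba_params"], dict):
            raw["aba_params"] = ABASearchParams(**raw["aba_params"])
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim = dict(raw["sim"])
            if "realign_rules" in sim and isinstance(sim["realign_rules"], dict):
                rules = dict(sim["realign_rules"])
                if "p_success_by_matchlen" in rules:
                    rules["p_success_by_matchlen"] = {
                        int(k): float(v) for k, v in rules["p_success_by_matchlen"].items()
                    }
                sim["realign_rules"] = RealignRules(**rules)
            raw["sim"] = SimConfig(**sim)
        for key in ("outdir", "template_fasta", "template_sidecar", "reference_fasta"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage subset and write all artifacts.

    Returns the run report (also written to ``report.json``).  Any stage
    failure raises a stage-named error; artifacts written before the failure
    are listed in the exception message as partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": _jsonable(
            {k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"}
        ),
        "stages": {},
    }
    artifacts: list[str] = []

    def _write_report() -> None:
        report["artifacts"] = artifacts
        write_json(outdir / "report.json", report)

    stage = "setup"
    try:
        # --- template and pattern -------------------------------------------------
        if config.template_fasta is not None:
            templates = read_templates(config.template_fasta, config.template_sidecar)
            if config.template_id is not None:
                templates = [t for t in templates if t.id == config.template_id]
            if not templates:
                raise ValueError("no template records matched the configuration")
            template = templates[0]
        else:
            template = demo_template()
        patterns = find_aba_patterns(template, config.aba_params)
        pattern = patterns[0] if patterns else None
        rows = [
            {
                "id": template.id,
                "a_start": p.a_start,
                "a_len": p.a_len,
                "b_len": p.b_len,
                "aprime_start": p.aprime_start,
                "motif_dna": p.motif_dna,
            }
            for p in patterns
        ]
        write_tsv(outdir / "patterns.tsv", pd.DataFrame(rows))
        artifacts.append("patterns.tsv")
        report["stages"]["setup"] = {
            "template_id": template.id,
            "n_patterns": len(patterns),
            "top_motif": pattern.motif_dna if pattern else None,
        }
        logger.info("setup: template %s, %d pattern(s)", template.id, len(patterns))

        if config.reference_fasta is not None:
            reference = read_fasta(config.reference_fasta, molecule="dna")[0][1]
        else:
            reference = random_reference(derive_seed(config.seed, 0), config.reference_len)

        readsets: Dict[str, object] = {}
        stage = "simulate"
        if stage in config.stages:
            if pattern is None:
                raise ValueError("no A-B-A' pattern found on the template; cannot simulate WT")
            sim_wt = dataclasses.replace(config.sim, seed=derive_seed(config.seed, 1))
            sim_ctrl = dataclasses.replace(config.sim, seed=derive_seed(config.seed, 2))
            wt = generate_dataset(template, pattern, reference, sim_wt, config.n_reads, "WT")
            ctrl = generate_dataset(None, None, reference, sim_ctrl, config.n_reads, "RT_dead")
            readsets = {"WT": wt, "RT_dead": ctrl}
            for name, rs in readsets.items():
                write_readset(rs, outdir / f"{name}.fastq", outdir / f"{name}.truth.tsv")
                artifacts += [f"{name}.fastq", f"{name}.truth.tsv"]
            report["stages"]["simulate"] = {
                name: {
                    "n_reads": len(rs),
                    "n_repeat_product": sum(1 for r in rs if r.truth == "repeat_product"),
                    "n_reference_background": rs.n_reference_mapping,
                }
                for name, rs in readsets.items()
            }
            logger.info("simulate: %d reads per condition", config.n_reads)

        stage = "partition"
        unmapped: Dict[str, object] = {}
        if stage in config.stages and readsets:
            part_report = {}
            for name, rs in readsets.items():
                mapped, unm = partition_unmapped(rs, reference, config.min_anchor)
                unmapped[name] = unm
                part_report[name] = {
                    "n_mapped": len(mapped),
                    "n_unmapped": len(unm),
                    "n_reference_mapping": unm.n_reference_mapping,
                }
            report["stages"]["partition"] = part_report
            logger.info(
                "partition: WT %d unmapped, RT_dead %d unmapped",
                len(unmapped["WT"].reads),
                len(unmapped["RT_dead"].reads),
            )

        stage = "discover"
        motif = None
        if stage in config.stages and unmapped:
            motifs = discover_motifs(
                unmapped["WT"], unmapped["RT_dead"], config.widths, config.top_n
            )
            table = pd.DataFrame([dataclasses.asdict(m) for m in motifs])
            write_tsv(outdir / "motifs.tsv", table)
            artifacts.append("motifs.tsv")
            motif = motifs[0].consensus if motifs else None
            report["stages"]["discover"] = {
                "n_motifs": len(motifs),
                "top_consensus": motif,
                "top_width": motifs[0].width if motifs else None,
                "top_frac_wt": motifs[0].frac_wt if motifs else None,
                "top_frac_ctrl": motifs[0].frac_ctrl if motifs else None,
            }
            logger.info("discover: top motif %s", motif)

        stage = "quantify"
        if stage in config.stages and unmapped and motif:
            wt_unm = unmapped["WT"]
            graph = position_graph(wt_unm, motif)
            write_tsv(outdir / "position_graph.tsv", graph.to_frame())
            hist = repeat_run_histogram(wt_unm, motif)
            write_tsv(
                outdir / "repeat_run_histogram.tsv",
                pd.DataFrame(
                    {"run_length": list(hist.bins), "n_reads": list(hist.bins.values())}
                ),
            )
            logo = context_logo(wt_unm, motif, config.flank)
            logo.to_frame().to_csv(outdir / "context_pfm.tsv", sep="\t")
            artifacts += ["position_graph.tsv", "repeat_run_histogram.tsv", "context_pfm.tsv"]
            period = estimate_period(graph)
            cpm_min_k = count_min_repeat_reads(wt_unm, motif, config.min_run_k)
            report["stages"]["quantify"] = {
                "motif": motif,
                "period": period,
                "median_run": hist.median_run,
                f"reads_with_ge_{config.min_run_k}_repeats_cpm": cpm_min_k,
                "n_motif_reads": int(graph.counts[0]),
            }
            logger.info("quantify: period %d, median run %d", period, hist.median_run)
    except Exception as exc:
        _write_report()
        raise RuntimeError(
            f"pipeline stage '{stage}' failed ({exc}); partial outputs: {artifacts}"
        ) from exc

    _write_report()
    artifacts.append("report.json")
    return report
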