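"""Pipeline orchestration: skew -> ori/ter -> rotation -> boxes -> stats ->
density -> codon-usage ranking -> tree, driven by one flat config.

Every output file carries the config hash and package version; stage
failures abort with the stage name in the error. Re-running with the same
config and seed reproduces the summary byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

from . import __version__
from . import annotation_stats, codon_usage, io, motifs, phylogeny, skew, stable_rna

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("replichore")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat run configuration; defaults follow the standard parameters
    (10 kb windows in 200 nt steps, 100 bootstrap replicates, survey
    threshold 2.9 operons/Mbp, operon gap 3 kb)."""

    fasta: str = ""
    annotations: str = ""
    annotation_format: str = "gff3"
    alignment: str = ""            # aligned 16S FASTA; optional
    survey_tsv: str = ""           # genome metadata table; optional
    out_dir: str = "replichore-out"
    window: int = 10_000
    step: int = 200
    sign_convention: str = "G_minus_C"
    operon_gap: int = stable_rna.DEFAULT_OPERON_GAP
    survey_threshold: float = stable_rna.DEFAULT_DENSITY_THRESHOLD
    cub_reference_pattern: str = "ribosomal protein"
    cub_top_k: int = 80
    bootstrap_replicates: int = 100
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def validate(self) -> None:
        if not self.fasta:
            raise ValueError("config requires a fasta path")
        for name in ("fasta", "annotations", "alignment", "survey_tsv"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.sign_convention not in skew.SIGN_CONVENTIONS:
            raise ValueError(f"bad sign convention {self.sign_convention!r}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - add stage context
                raise PipelineError(name, str(err)) from err
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def _extract_cds(seq: io.CircularSequence, f: io.FeatureAnnotation) -> str:
    text = "".join(seq.fetch(s, e) for s, e in f.segments(seq.length))
    if f.strand == "-":
        text = motifs.reverse_complement(text)
    return text


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all applicable stages; returns (and writes) the summary."""
    try:
        config.validate()
    except Exception as err:
        raise PipelineError("config", str(err)) from err

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.digest(),
        "config": asdict(config),
    }

    @_stage("load")
    def load():
        seqs = io.read_fasta(config.fasta)
        seq = seqs[0]
        ann = (
            io.read_annotations(config.annotations, config.annotation_format)
            if config.annotations
            else None
        )
        if ann is not None:
            ann.validate(seq)
        return seq, ann

    seq, ann = load()

    @_stage("skew-profile")
    def profile_stage():
        prof = skew.windowed_profile(
            seq, config.window, config.step, config.sign_convention
        )
        io.write_track(prof, out / "skew.bedgraph", "bedgraph")
        return prof

    profile_stage()

    @_stage("ori-ter")
    def oric_stage():
        cs = skew.cumulative_skew(seq)
        cs.sign_convention = config.sign_convention
        pred = skew.predict_ori_ter(cs, ann)
        summary["replication"] = {
            "ori": pred.ori,
            "ter": pred.ter,
            "replichore_1_len": pred.replichore_1_len,
            "replichore_2_len": pred.replichore_2_len,
            "sign_convention": pred.sign_convention,
            "dnaA_distance": pred.dnaA_distance,
            "dnaA_supported": pred.dnaA_supported,
            "lead_strand_cds_fraction": pred.lead_strand_cds_fraction,
        }
        return pred

    pred = oric_stage()

    if ann is not None:
        @_stage("dnaa-boxes")
        def boxes_stage():
            try:
                rep = motifs.dnaa_box_report(seq, ann)
            except ValueError as err:
                log.info("dnaa-boxes skipped: %s", err)
                return None
            summary["dnaA_boxes"] = {
                "upstream": rep.upstream_count,
                "intergenic": rep.intergenic_count,
                "consensus": rep.consensus,
            }
            return rep

        boxes_stage()

        @_stage("genome-stats")
        def stats_stage():
            gs = annotation_stats.genome_stats(seq, ann, operon_gap=config.operon_gap)
            annotation_stats.compare_table([gs], out / "genome_stats.tsv")
            summary["genome_stats"] = asdict(gs)
            return gs

        stats_stage()

        @_stage("rna-density")
        def density_stage():
            operons = stable_rna.group_rrna_operons(
                ann, seq.length, config.operon_gap
            )
            summary["rrn_density_per_mbp"] = round(
                stable_rna.rrn_density(len(operons), seq.length), 2
            )

        density_stage()

        @_stage("codon-usage")
        def cub_stage():
            cds_feats = ann.of_type("CDS")
            tables = [
                codon_usage.codon_counts(_extract_cds(seq, f), f.locus_tag)
                for f in cds_feats
            ]
            pat = config.cub_reference_pattern.lower()
            ref = [
                t
                for t, f in zip(tables, cds_feats)
                if t.valid and pat in f.product.lower()
            ]
            if not ref:
                log.info("codon-usage: no reference genes match %r", pat)
                return None
            w = codon_usage.relative_adaptiveness(ref)
            ranked = codon_usage.rank_optimized(tables, w, top_k=config.cub_top_k)
            ranked.table.to_csv(out / "cub.tsv", sep="\t", index=False)
            summary["cub"] = {
                "metric": "reference-set adaptation index (geometric mean of w)",
                "reference_size": len(ref),
                "top_k": config.cub_top_k,
                "top_gene_ids": ranked.top["gene_id"].tolist(),
            }
            return ranked

        cub_stage()

    if config.survey_tsv:
        @_stage("survey")
        def survey_stage():
            records = stable_rna.read_survey_tsv(config.survey_tsv)
            table = stable_rna.survey(records, threshold=config.survey_threshold)
            stable_rna.write_survey_tsv(table, out / "survey.tsv")
            summary["survey"] = {
                "n_input": table.n_input,
                "n_ranked": len(table.ranked),
                "threshold": table.threshold,
                "top_genome_ids": table.top["genome_id"].tolist(),
            }

        survey_stage()

    if config.alignment:
        @_stage("phylogeny")
        def tree_stage():
            aln = phylogeny.read_alignment(config.alignment)
            boot = phylogeny.bootstrap_support(
                aln, replicates=config.bootstrap_replicates, seed=config.seed
            )
            phylogeny.write_newick(boot.tree, out / "tree.nwk")
            summary["phylogeny"] = {
                "taxa": boot.tree.taxa,
                "replicates": boot.replicates,
                "completed": boot.completed,
                "tree_path": str(out / "tree.nwk"),
            }

        tree_stage()

    def _json_default(o):
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    text = json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
    (out / "summary.json").write_text(text + "\n")
    return summary
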