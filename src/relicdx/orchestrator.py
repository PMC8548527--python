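"""End-to-end pipeline wiring, demo-dataset generation and reporting.

:func:`run_pipeline` executes authentication -> QC -> prioritization ->
phase inference over whichever inputs a :class:`PipelineConfig` provides,
skipping stages whose inputs are absent and capturing per-stage errors
without aborting independent stages.  :func:`make_demo_dataset` writes a
complete synthetic fixture bundle (reads, pileups, variant table, phased
panel, truth) that exercises every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from relicdx import authentication, io, phase_inference, prioritization, wes_qc
from relicdx import synthetic_data as sd

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_demo_dataset", "depth_over_targets"]


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run (all paths optional;
    stages without inputs are skipped)."""

    alignments: str | None = None  # SAM
    reference: str | None = None  # FASTA
    targets: str | None = None  # BED
    depth_tsv: str | None = None  # per-base depth (columns chrom, pos, depth)
    variants: str | None = None  # annotated VCF or TSV sidecar
    panel: str | None = None  # phased panel VCF
    sex_counts: str | None = None  # JSON {"nX": int, "nY": int}
    mt_pileup: str | None = None  # TSV (pos, endo, cont, bases)
    x_pileup_poly: str | None = None  # TSV (mismatches, depth)
    x_pileup_mono: str | None = None
    library_counts: str | None = None  # JSON {n_fragments, mapped_before, mapped_after}
    anchor: str | None = None  # "chrom:pos[:ref:alt]"
    query: str | None = None
    anchor_freq: float | None = None
    query_freq: float | None = None
    sample_genotypes: dict = field(
        default_factory=lambda: {"anchor": "het", "query": "het"}
    )
    phase_threshold: float = 0.98
    min_callable_depth: int = 4
    damage_window: int = 15
    modifier_genes: list = field(
        default_factory=lambda: list(prioritization.DEFAULT_MODIFIER_GENES)
    )
    seed: int = 0
    output_dir: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _parse_locus(s: str) -> tuple[str, int]:
    parts = s.split(":")
    return parts[0], int(parts[1])


def depth_over_targets(reads, targets: list[tuple[str, int, int]]) -> np.ndarray:
    """Per-base depth over 0-based half-open target intervals."""
    arrays = {i: np.zeros(end - start, dtype=np.int64) for i, (_, start, end) in enumerate(targets)}
    for read in reads:
        if getattr(read, "is_unmapped", False):
            continue
        for i, (chrom, start, end) in enumerate(targets):
            if read.reference_name != chrom:
                continue
            lo = max(read.reference_start, start)
            hi = min(read.reference_end or read.reference_start, end)
            if hi > lo:
                arrays[i][lo - start : hi - start] += 1
    return np.concatenate([arrays[i] for i in range(len(targets))])


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _asdict(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [None if isinstance(x, float) and np.isnan(x) else x for x in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return None  # likelihood curves etc. are dropped from the JSON report
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _read_bed(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are present; return the analysis report.

    The report embeds each stage's outputs verbatim (no renormalisation),
    records per-stage errors and skips, and carries provenance (config
    hash, seed, package version).  If ``config.output_dir`` is set, the
    report is also written as ``report.json`` and a flat ``report.tsv``.
    """
    from relicdx import __version__

    report: dict = {
        "authentication": {},
        "qc": {},
        "prioritization": {},
        "phase": {},
        "errors": {},
        "skipped": [],
    }
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
                logger.exception("stage %s failed", name)
                report["errors"][name] = f"{type(exc).__name__}: {exc}"
            timings[name] = round(time.perf_counter() - t0, 4)

        return deco

    reads = header = None
    if config.alignments:
        reads, header = io.read_sam(config.alignments)

    @stage("authentication.damage")
    def _damage():
        if not (config.alignments and config.reference):
            report["skipped"].append("authentication.damage")
            return
        import pyfaidx

        ref = pyfaidx.Fasta(config.reference)
        profile = authentication.compute_misincorporation_profile(
            reads, ref, window=config.damage_window
        )
        report["authentication"]["damage_profile"] = _asdict(profile)
        report["authentication"]["fragment_lengths"] = _asdict(
            authentication.summarize_fragment_lengths(reads)
        )

    @stage("authentication.sex")
    def _sex():
        if config.sex_counts:
            counts = json.loads(Path(config.sex_counts).read_text())
            call = authentication.determine_genetic_sex(counts["nX"], counts["nY"])
        elif config.alignments:
            call = authentication.determine_genetic_sex(alignments=reads)
        else:
            report["skipped"].append("authentication.sex")
            return
        report["authentication"]["sex"] = _asdict(call)

    @stage("authentication.mt_contamination")
    def _mt():
        if not config.mt_pileup:
            report["skipped"].append("authentication.mt_contamination")
            return
        pileup = io.read_pileup_tsv(config.mt_pileup)
        est = authentication.estimate_mt_contamination(pileup)
        report["authentication"]["mt_contamination"] = _asdict(est)

    @stage("authentication.x_contamination")
    def _x():
        if not (config.x_pileup_poly and config.x_pileup_mono):
            report["skipped"].append("authentication.x_contamination")
            return
        poly = pd.read_csv(config.x_pileup_poly, sep="\t")
        mono = pd.read_csv(config.x_pileup_mono, sep="\t")
        est = authentication.estimate_x_contamination(poly, mono)
        report["authentication"]["x_contamination"] = _asdict(est)

    @stage("qc.library")
    def _library():
        if not config.library_counts:
            report["skipped"].append("qc.library")
            return
        c = json.loads(Path(config.library_counts).read_text())
        m = wes_qc.compute_library_metrics(
            c["n_fragments"], c["mapped_before"], c["mapped_after"]
        )
        report["qc"]["library"] = m.report()

    @stage("qc.coverage")
    def _coverage():
        if config.depth_tsv:
            depths = pd.read_csv(config.depth_tsv, sep="\t")["depth"].to_numpy()
        elif config.alignments and config.targets:
            depths = depth_over_targets(reads, _read_bed(config.targets))
        else:
            report["skipped"].append("qc.coverage")
            return
        report["qc"]["coverage"] = _asdict(
            wes_qc.compute_coverage_summary(depths, config.min_callable_depth)
        )

    variants = None
    if config.variants:
        p = str(config.variants)
        variants = io.read_variant_tsv(p) if p.endswith(".tsv") else io.read_variant_vcf(p)

    @stage("qc.variants")
    def _vsummary():
        if variants is None:
            report["skipped"].append("qc.variants")
            return
        report["qc"]["variant_set"] = _asdict(wes_qc.summarize_variant_set(variants))

    @stage("prioritization")
    def _prioritize():
        if variants is None:
            report["skipped"].append("prioritization")
            return
        cfg = prioritization.PrioritizationConfig()
        ann = prioritization.annotated_pipeline(variants, cfg)
        pred = prioritization.predicted_pipeline(variants, cfg)
        inter = prioritization.clinical_intersection(ann, config=cfg)
        candidates = prioritization.recessive_candidates(inter.rare_clinical)
        modifier = prioritization.modifier_scan(variants, config.modifier_genes, cfg)
        report["prioritization"] = {
            "annotated_retained": len(ann.variants),
            "annotated_rare": sum(ann.rare_flags.values()),
            "predicted_retained": len(pred.variants),
            "predicted_rare": sum(pred.rare_flags.values()),
            "clinical_counts": inter.counts,
            "severity_filtered": inter.severity_filtered,
            "recessive_candidates": [
                {"gene": c.gene, "mechanism": c.mechanism,
                 "variants": [v.key for v in c.variants]}
                for c in candidates
            ],
            "modifier_scan": modifier,
            "annotated_keys": sorted(ann.keys),
            "predicted_keys": sorted(pred.keys),
        }

    @stage("phase")
    def _phase():
        if not (config.panel and config.anchor and config.query):
            report["skipped"].append("phase")
            return
        panel = io.read_panel_vcf(config.panel)
        _, anchor_pos = _parse_locus(config.anchor)
        _, query_pos = _parse_locus(config.query)
        block = phase_inference.find_anchor_block(
            panel, anchor_pos, threshold=config.phase_threshold
        )
        call = phase_inference.infer_configuration(
            block,
            query_pos,
            panel,
            sample_genotypes=config.sample_genotypes,
            freq_anchor=config.anchor_freq,
            freq_query=config.query_freq,
        )
        report["phase"] = {
            "configuration": call.configuration,
            "spanning": call.spanning,
            "carrier_query_allele_fraction": call.carrier_query_allele_fraction,
            "block_interval": list(block.interval),
            "block_length_bp": block.length_bp,
            "block_n_sites": int(block.member_positions.size),
            "n_carriers": block.n_carriers,
            "frequency_evidence": _asdict(call.frequency_evidence),
        }

    cfg_yaml = yaml.safe_dump(dataclasses.asdict(config))
    report["provenance"] = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "stage_seconds": timings,
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        rows = _flatten(report)
        pd.DataFrame(rows, columns=["key", "value"]).to_csv(
            out / "report.tsv", sep="\t", index=False
        )
    return report


def _flatten(d: dict, prefix: str = "") -> list[tuple[str, object]]:
    rows: list[tuple[str, object]] = []
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            rows.extend(_flatten(v, key))
        elif isinstance(v, list):
            rows.append((key, json.dumps(v)))
        else:
            rows.append((key, v))
    return rows


def make_demo_dataset(seed: int = 1, outdir: str | Path = "demo_data") -> dict:
    """Write a small complete fixture bundle exercising every stage.

    Returns a dict with the generated file paths, the pipeline config
    (also written as ``config.yaml``) and the combined truth record.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2**31)]

    # reference + damaged reads
    refseq = sd.random_reference(60_000, seed=seeds[0])
    reference = {"chr17": refseq}
    io.write_fasta(reference, out / "reference.fa")
    cfg_reads = sd.DamageModelConfig(
        terminal_ct_rate=0.0217, decay=0.5, udg_mode="partial",
        contamination_fraction=0.01, seed=seeds[1],
    )
    reads, header, reads_truth = sd.simulate_adna_fragments(cfg_reads, reference, 3000)
    io.write_sam(reads, header, out / "reads.sam")
    (out / "targets.bed").write_text("chr17\t10000\t14000\n")

    # sex counts, mt pileup, X pileups
    counts = sd.simulate_sexed_alignment_counts("XY", 100_000, seed=seeds[2])
    (out / "sex_counts.json").write_text(json.dumps(counts))
    mt_pileup, mt_truth = sd.simulate_mt_pileup(
        0.005, depth=200, n_diagnostic_sites=50, error_rate=0.01, seed=seeds[3]
    )
    io.write_pileup_tsv(mt_pileup, out / "mt_pileup.tsv")
    poly, mono, x_truth = sd.simulate_x_pileup(0.005, seed=seeds[4])
    poly.to_csv(out / "x_poly.tsv", sep="\t", index=False)
    mono.to_csv(out / "x_mono.tsv", sep="\t", index=False)

    # demo library counts (arbitrary round numbers for the arithmetic stage)
    (out / "library_counts.json").write_text(
        json.dumps({"n_fragments": 1_000_000, "mapped_before": 234_000,
                    "mapped_after": 113_000})
    )

    # annotated variant table
    vcfg = sd.VariantTableConfig(seed=seeds[5])
    variants, var_truth = sd.simulate_variant_table(vcfg)
    io.write_variant_vcf(variants, out / "variants.vcf")
    io.write_variant_tsv(variants, out / "variants.tsv")

    # phased panel with a planted trans pair
    pcfg = sd.PanelConfig(n_haplotypes=200, planted_configuration="trans", seed=seeds[6])
    panel, panel_truth = sd.simulate_haplotype_panel(pcfg)
    io.write_panel_vcf(panel, out / "panel.vcf")

    config = PipelineConfig(
        alignments=str(out / "reads.sam"),
        reference=str(out / "reference.fa"),
        targets=str(out / "targets.bed"),
        variants=str(out / "variants.vcf"),
        panel=str(out / "panel.vcf"),
        sex_counts=str(out / "sex_counts.json"),
        mt_pileup=str(out / "mt_pileup.tsv"),
        x_pileup_poly=str(out / "x_poly.tsv"),
        x_pileup_mono=str(out / "x_mono.tsv"),
        library_counts=str(out / "library_counts.json"),
        anchor=f"{panel_truth['anchor']['chrom']}:{panel_truth['anchor']['pos']}",
        query=f"{panel_truth['query']['chrom']}:{panel_truth['query']['pos']}",
        anchor_freq=pcfg.anchor_frequency,
        query_freq=0.0,
        seed=seed,
        output_dir=str(out / "results"),
    )
    config.to_yaml(out / "config.yaml")

    truth = {
        "seed": seed,
        "reads": {"config": reads_truth["config"], "n": reads_truth["n"],
                  "n_contaminant": reads_truth["n_contaminant"]},
        "sex": {"karyotype": "XY", **counts},
        "mt": mt_truth,
        "x": x_truth,
        "variants": var_truth,
        "panel": {k: v for k, v in panel_truth.items() if k != "sample"},
    }
    io.write_truth_json(truth, out / "truth.json")

    return {"outdir": str(out), "config": config, "truth": truth,
            "config_path": str(out / "config.yaml")}
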