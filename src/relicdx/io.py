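"""File-format round-trips for simulated and real inputs.

SAM via pysam; variant tables and haplotype panels as VCF (pysam
VariantFile) with a TSV sidecar mirror for the variant annotations;
pileups as TSV; truth records as JSON.  VCF positions are 1-based; the
in-memory containers keep whatever convention their module defines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from relicdx.phase_inference import HaplotypePanel
from relicdx.prioritization import POP_DBS, PREDICTORS, AnnotatedVariant

__all__ = [
    "write_sam",
    "read_sam",
    "write_fasta",
    "write_pileup_tsv",
    "read_pileup_tsv",
    "write_variant_vcf",
    "read_variant_vcf",
    "write_variant_tsv",
    "read_variant_tsv",
    "write_panel_vcf",
    "read_panel_vcf",
    "write_truth_json",
    "read_truth_json",
]


def write_sam(reads, header: pysam.AlignmentHeader, path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            fh.write(read)


def read_sam(path) -> tuple[list, pysam.AlignmentHeader]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        reads = list(fh)
        return reads, fh.header


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_pileup_tsv(pileup: pd.DataFrame, path) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- annotated variant tables -------------------------------------------------

_INFO_FIELDS = [
    ("GENE", "String", "Gene symbol"),
    ("EFFECT", "String", "Variant effect (LOF/Missense/Splice_region/other)"),
    ("REGION", "String", "Region class (exonic/splice-site/other)"),
    ("CLNSIG", "String", "ClinVar classification"),
    ("HGMD_CLASS", "String", "HGMD classification"),
    ("AF_INTERNAL", "Float", "Internal database alternate allele frequency"),
    ("AF_FG", "Float", "Functional-genomics cohort alternate allele frequency"),
]


def _variant_header(chroms: list[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in chroms:
        h.contigs.add(c, length=300_000_000)
    for name, typ, desc in _INFO_FIELDS:
        h.info.add(name, 1, typ, desc)
    for db in POP_DBS:
        h.info.add(f"AF_{db.upper().replace('.', '_')}", 1, "Float",
                   f"Alternate allele frequency in {db}")
    for tool in PREDICTORS:
        h.info.add(f"PRED_{tool.upper()}", 1, "String", f"{tool} call")
    h.formats.add("GT", 1, "String", "Genotype")
    h.add_sample("SAMPLE")
    return h


def _spaceless(s: str) -> str:
    # INFO values must not contain whitespace or semicolons
    return s.replace(" ", "_").replace(";", "|")


def write_variant_vcf(variants: list[AnnotatedVariant], path) -> None:
    chroms = sorted({v.chrom for v in variants})
    header = _variant_header(chroms)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["GENE"] = _spaceless(v.gene)
            rec.info["EFFECT"] = v.effect
            rec.info["REGION"] = v.region
            if v.clinvar:
                rec.info["CLNSIG"] = _spaceless(v.clinvar)
            if v.hgmd:
                rec.info["HGMD_CLASS"] = v.hgmd
            for db, f in v.pop_freqs.items():
                if f is not None:
                    rec.info[f"AF_{db.upper().replace('.', '_')}"] = f
            if v.internal_freq is not None:
                rec.info["AF_INTERNAL"] = v.internal_freq
            if v.fg_freq is not None:
                rec.info["AF_FG"] = v.fg_freq
            for tool, call in v.predictor_calls.items():
                if call != "missing":
                    rec.info[f"PRED_{tool.upper()}"] = call
            rec.samples["SAMPLE"]["GT"] = (1, 1) if v.genotype == "hom" else (0, 1)
            out.write(rec)


def read_variant_vcf(path) -> list[AnnotatedVariant]:
    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            gt = rec.samples["SAMPLE"]["GT"]
            pop = {
                db: (
                    float(info[f"AF_{db.upper().replace('.', '_')}"])
                    if f"AF_{db.upper().replace('.', '_')}" in info
                    else None
                )
                for db in POP_DBS
            }
            preds = {
                tool: str(info.get(f"PRED_{tool.upper()}", "missing"))
                for tool in PREDICTORS
            }
            clnsig = info.get("CLNSIG")
            out.append(
                AnnotatedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotype="hom" if gt == (1, 1) else "het",
                    gene=str(info.get("GENE", "")),
                    effect=str(info.get("EFFECT", "other")),
                    region=str(info.get("REGION", "other")),
                    clinvar=str(clnsig).replace("_", " ") if clnsig else None,
                    hgmd=str(info["HGMD_CLASS"]) if "HGMD_CLASS" in info else None,
                    pop_freqs=pop,
                    internal_freq=(
                        float(info["AF_INTERNAL"]) if "AF_INTERNAL" in info else None
                    ),
                    fg_freq=float(info["AF_FG"]) if "AF_FG" in info else None,
                    predictor_calls=preds,
                )
            )
    return out


def write_variant_tsv(variants: list[AnnotatedVariant], path) -> None:
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "genotype": v.genotype, "gene": v.gene, "effect": v.effect,
            "region": v.region, "clinvar": v.clinvar, "hgmd": v.hgmd,
            "internal_freq": v.internal_freq, "fg_freq": v.fg_freq,
        }
        for db in POP_DBS:
            row[f"af_{db}"] = v.pop_freqs.get(db)
        for tool in PREDICTORS:
            row[f"pred_{tool}"] = v.predictor_calls.get(tool, "missing")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(x):
            return None if pd.isna(x) else x

        out.append(
            AnnotatedVariant(
                chrom=str(d["chrom"]), pos=int(d["pos"]), ref=str(d["ref"]),
                alt=str(d["alt"]), genotype=str(d["genotype"]), gene=str(d["gene"]),
                effect=str(d["effect"]), region=str(d["region"]),
                clinvar=opt(d["clinvar"]), hgmd=opt(d["hgmd"]),
                pop_freqs={db: opt(d[f"af_{db}"]) for db in POP_DBS},
                internal_freq=opt(d["internal_freq"]),
                fg_freq=opt(d["fg_freq"]),
                predictor_calls={t: str(d[f"pred_{t}"]) for t in PREDICTORS},
            )
        )
    return out


# --- phased haplotype panels --------------------------------------------------


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as a phased VCF (GT with '|')."""
    h = pysam.VariantHeader()
    h.contigs.add(panel.chrom, length=300_000_000)
    h.formats.add("GT", 1, "String", "Phased genotype")
    n_hap = panel.n_haplotypes
    labels = panel.sample_labels or [f"S{i:04d}" for i in range((n_hap + 1) // 2)]
    for s in labels:
        h.add_sample(s)
    refs = panel.ref_alleles or ["A"] * panel.n_sites
    alts = panel.alt_alleles or ["G"] * panel.n_sites
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for s in range(panel.n_sites):
            rec = out.new_record(
                contig=panel.chrom,
                start=int(panel.positions[s]) - 1,
                stop=int(panel.positions[s]),
                alleles=(refs[s], alts[s]),
            )
            for i, label in enumerate(labels):
                a = int(panel.alleles[2 * i, s])
                b = int(panel.alleles[2 * i + 1, s]) if 2 * i + 1 < n_hap else a
                rec.samples[label]["GT"] = (None if a < 0 else a, None if b < 0 else b)
                rec.samples[label].phased = True
            out.write(rec)


def read_panel_vcf(path) -> HaplotypePanel:
    positions, rows, refs, alts = [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chrom = None
        for rec in vf:
            chrom = rec.chrom
            positions.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            col = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                col.extend(-1 if g is None else int(g) for g in gt)
            rows.append(col)
    if not positions:
        raise ValueError(f"empty panel VCF: {path}")
    alleles = np.array(rows, dtype=np.int8).T  # (haplotypes, sites)
    return HaplotypePanel(
        chrom=chrom,
        positions=np.array(positions),
        alleles=alleles,
        sample_labels=samples,
        ref_alleles=refs,
        alt_alleles=alts,
    )


# --- truth records ------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_truth_json(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1, sort_keys=True))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
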