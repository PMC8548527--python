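"""Simulated annotated exome variant tables with rule-level ground truth.

The generator plants a compound-heterozygous pathogenic pair in one gene
(modelled on the classic pattern: one pathogenic/likely-pathogenic + DM
allele at vanishing frequency, one benign-labelled + DM? allele at ~3%)
plus configurable counts of rare and common exonic missense variants in a
lysosomal-modifier gene list, against a background of random annotated
variants.  Alongside the table it returns a *truth* record listing which
variants each prioritization rule should retain — computed here by a
direct, independent transliteration of the filtering rules, so recovery
tests compare pipeline output against bookkeeping rather than against the
implementation under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from relicdx.prioritization import (
    DEFAULT_MODIFIER_GENES,
    POP_DBS,
    PREDICTORS,
    AnnotatedVariant,
)

__all__ = ["PlantedVariant", "PlantedPair", "VariantTableConfig", "simulate_variant_table"]

_CLINVAR_LABELS = (
    "Pathogenic",
    "Likely pathogenic",
    "Pathogenic/Likely pathogenic",
    "Uncertain significance",
    "Conflicting interpretations of pathogenicity",
    "Benign",
    "Likely benign",
    "Benign/Likely benign",
)
_HGMD_LABELS = ("DM", "DM?", "DP", "FP")

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class PlantedVariant:
    clinvar: str | None
    hgmd: str | None
    freq: float | None  # used for every population database
    genotype: str = "het"
    effect: str = "Missense"
    region: str = "exonic"


@dataclass
class PlantedPair:
    """The compound-het pair planted in one gene (defaults mirror a
    pathogenic+DM allele at 0.0015% and a benign+DM? allele at 3%)."""

    gene: str = "GAA"
    first: PlantedVariant = field(
        default_factory=lambda: PlantedVariant(
            clinvar="Pathogenic/Likely pathogenic", hgmd="DM", freq=1.5e-5
        )
    )
    second: PlantedVariant = field(
        default_factory=lambda: PlantedVariant(
            clinvar="Benign/Likely benign", hgmd="DM?", freq=0.03
        )
    )


@dataclass
class VariantTableConfig:
    n_variants: int = 300
    fraction_clinical: float = 0.15
    planted_pair: PlantedPair = field(default_factory=PlantedPair)
    modifier_rare: dict[str, int] = field(
        default_factory=lambda: {"ATP6": 6, "RUNX1": 1}
    )
    modifier_common: int = 28
    modifier_genes: tuple[str, ...] = DEFAULT_MODIFIER_GENES
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_clinical <= 1.0):
            raise ValueError("fraction_clinical must be in [0, 1]")
        n_planted = (
            2 + sum(self.modifier_rare.values()) + self.modifier_common
        )
        if self.n_variants < n_planted:
            raise ValueError(
                f"n_variants={self.n_variants} cannot hold {n_planted} planted variants"
            )


# --- independent truth bookkeeping -------------------------------------------
# These helpers restate the prioritization rules directly from their
# definitions; they deliberately do not call relicdx.prioritization so that
# recovery tests have an independent oracle.

_RETAINED_CLINVAR = (
    "pathogenic",
    "likely pathogenic",
    "uncertain significance",
    "conflicting",
    "other",
)


def _truth_clinvar_retained(label: str | None) -> bool:
    if not label:
        return False
    parts = [p.strip().lower() for p in label.replace(";", "/").split("/")]
    return any(
        p in _RETAINED_CLINVAR or p.startswith("conflicting") for p in parts
    )


def _truth_all_freqs_below(v: AnnotatedVariant, t: float) -> bool:
    return all(f < t for f in v.pop_freqs.values() if f is not None)


def _truth_annotated(v: AnnotatedVariant) -> bool:
    return _truth_clinvar_retained(v.clinvar) or v.hgmd in ("DM", "DM?")


def _truth_predicted(v: AnnotatedVariant) -> bool:
    return (
        v.region in ("exonic", "splice-site")
        and not v.clinvar
        and v.hgmd is None
        and v.effect in ("LOF", "Missense", "Splice_region")
        and sum(c == "damaging" for c in v.predictor_calls.values()) >= 3
        and (v.fg_freq is None or v.fg_freq < 0.02)
    )


def _compute_truth(variants: list[AnnotatedVariant], config: VariantTableConfig) -> dict:
    annotated = [v.key for v in variants if _truth_annotated(v)]
    predicted = [v.key for v in variants if _truth_predicted(v)]
    annotated_rare = [
        v.key
        for v in variants
        if _truth_annotated(v) and _truth_all_freqs_below(v, 0.05)
    ]
    predicted_rare = [
        v.key
        for v in variants
        if _truth_predicted(v) and _truth_all_freqs_below(v, 0.01)
    ]
    clinvar_members = [
        v.key for v in variants if _truth_annotated(v) and _truth_clinvar_retained(v.clinvar)
    ]
    hgmd_members = [
        v.key for v in variants if _truth_annotated(v) and v.hgmd in ("DM", "DM?")
    ]
    modifier = {g: {"rare": 0, "common": 0} for g in config.modifier_genes}
    for v in variants:
        if v.gene in modifier and v.region == "exonic" and v.effect == "Missense":
            common = any(f is not None and f > 0.05 for f in v.pop_freqs.values())
            modifier[v.gene]["common" if common else "rare"] += 1
    return {
        "annotated_retained": sorted(annotated),
        "annotated_rare": sorted(annotated_rare),
        "predicted_retained": sorted(predicted),
        "predicted_rare": sorted(predicted_rare),
        "clinvar_members": sorted(clinvar_members),
        "hgmd_members": sorted(hgmd_members),
        "both_members": sorted(set(clinvar_members) & set(hgmd_members)),
        "modifier": modifier,
        "modifier_rare_total": sum(m["rare"] for m in modifier.values()),
        "modifier_common_total": sum(m["common"] for m in modifier.values()),
    }


# --- generation ---------------------------------------------------------------


def _freqs(rng: np.random.Generator, fixed: float | None = None) -> dict[str, float | None]:
    if fixed is not None:
        return {db: fixed for db in POP_DBS}
    out: dict[str, float | None] = {}
    for db in POP_DBS:
        out[db] = None if rng.random() < 0.25 else float(10 ** rng.uniform(-5, -0.3))
    return out


def _predictors(rng: np.random.Generator, n_damaging: int | None = None) -> dict[str, str]:
    if n_damaging is not None:
        calls = ["damaging"] * n_damaging + ["tolerated"] * (len(PREDICTORS) - n_damaging)
    else:
        calls = list(
            rng.choice(["damaging", "tolerated", "missing"], size=len(PREDICTORS),
                       p=[0.3, 0.6, 0.1])
        )
    return dict(zip(PREDICTORS, calls))


def simulate_variant_table(config: VariantTableConfig):
    """Generate an annotated variant table and its rule-level truth record.

    Returns ``(variants, truth)``; ``truth`` lists, per prioritization
    rule, exactly which variant keys satisfy it, plus per-gene modifier
    counts and the planted-pair keys.
    """
    rng = np.random.default_rng(config.seed)
    variants: list[AnnotatedVariant] = []
    pos_counter = {c: 1_000_000 for c in _CHROMS}

    def next_locus(chrom: str | None = None) -> tuple[str, int]:
        c = chrom or _CHROMS[int(rng.integers(0, len(_CHROMS)))]
        pos_counter[c] += int(rng.integers(50, 5000))
        return c, pos_counter[c]

    def snv_alleles() -> tuple[str, str]:
        ref = "ACGT"[int(rng.integers(0, 4))]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return ref, str(alt)

    # planted compound-het pair (one gene, chr17 by convention)
    pair_keys = []
    for planted in (config.planted_pair.first, config.planted_pair.second):
        chrom, pos = next_locus("chr17")
        ref, alt = snv_alleles()
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            genotype=planted.genotype,
            gene=config.planted_pair.gene,
            effect=planted.effect,
            region=planted.region,
            clinvar=planted.clinvar,
            hgmd=planted.hgmd,
            pop_freqs=_freqs(rng, fixed=planted.freq),
            internal_freq=planted.freq,
            fg_freq=planted.freq,
            predictor_calls=_predictors(rng, n_damaging=4),
        )
        variants.append(v)
        pair_keys.append(v.key)

    # planted modifier-gene variants: rare and common exonic missense
    genes_cycle = list(config.modifier_genes) or ["MODIFIER"]
    for gene, k in config.modifier_rare.items():
        for _ in range(k):
            chrom, pos = next_locus()
            ref, alt = snv_alleles()
            variants.append(
                AnnotatedVariant(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    genotype="het" if rng.random() < 0.7 else "hom",
                    gene=gene, effect="Missense", region="exonic",
                    clinvar=None, hgmd=None,
                    pop_freqs=_freqs(rng, fixed=float(10 ** rng.uniform(-5, -2))),
                    internal_freq=None, fg_freq=float(rng.uniform(0, 0.02)),
                    predictor_calls=_predictors(rng),
                )
            )
    for i in range(config.modifier_common):
        gene = genes_cycle[i % len(genes_cycle)]
        chrom, pos = next_locus()
        ref, alt = snv_alleles()
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                genotype="het" if rng.random() < 0.7 else "hom",
                gene=gene, effect="Missense", region="exonic",
                clinvar=None, hgmd=None,
                pop_freqs=_freqs(rng, fixed=float(rng.uniform(0.051, 0.5))),
                internal_freq=None, fg_freq=float(rng.uniform(0.05, 0.5)),
                predictor_calls=_predictors(rng),
            )
        )

    # random background variants (never in reserved genes)
    reserved = {config.planted_pair.gene, *config.modifier_genes}
    n_background = config.n_variants - len(variants)
    for _ in range(n_background):
        chrom, pos = next_locus()
        if rng.random() < 0.9:
            ref, alt = snv_alleles()
        else:  # small indel
            ref, alt = ("A", "AT") if rng.random() < 0.5 else ("AT", "A")
        gene = f"GENE{int(rng.integers(0, config.n_variants // 3)):04d}"
        while gene in reserved:  # pragma: no cover - names never collide
            gene += "X"
        region = str(rng.choice(["exonic", "splice-site", "other"], p=[0.7, 0.05, 0.25]))
        if region == "other":
            effect = "other"
        else:
            effect = str(
                rng.choice(["Missense", "LOF", "Splice_region", "other"],
                           p=[0.55, 0.1, 0.1, 0.25])
            )
        clinvar = hgmd = None
        if rng.random() < config.fraction_clinical:
            if rng.random() < 0.8:
                clinvar = str(rng.choice(_CLINVAR_LABELS))
            if rng.random() < 0.5:
                hgmd = str(rng.choice(_HGMD_LABELS))
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                genotype="het" if rng.random() < 0.6 else "hom",
                gene=gene, effect=effect, region=region,
                clinvar=clinvar, hgmd=hgmd,
                pop_freqs=_freqs(rng),
                internal_freq=None if rng.random() < 0.5 else float(10 ** rng.uniform(-4, -1)),
                fg_freq=None if rng.random() < 0.3 else float(10 ** rng.uniform(-4, -0.5)),
                predictor_calls=_predictors(rng),
            )
        )

    truth = _compute_truth(variants, config)
    truth["planted_pair_keys"] = pair_keys
    truth["planted_pair_gene"] = config.planted_pair.gene
    return variants, truth
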