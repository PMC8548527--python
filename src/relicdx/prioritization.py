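"""Clinical variant prioritization for an annotated exome call set.

Two parallel pipelines mirror standard clinical-exome triage:

* the **annotated** pipeline keeps variants with a reported clinical
  classification (pathogenic-spectrum / conflicting / uncertain / other in
  ClinVar, or DM / DM? in HGMD), flagging those rare in every population
  frequency database (< 5%);
* the **predicted** pipeline keeps exonic or splice-site variants *without*
  any reported classification whose effect is LOF / missense / splice
  region, called damaging by at least three of five in-silico predictors,
  and rare in a functional-genomics cohort (< 2%), flagging those with
  population frequency < 1%.

Downstream helpers intersect the annotated set with the two clinical
databases, detect recessive diagnosis candidates (compound-heterozygous or
homozygous genotypes per gene), and scan a caller-supplied list of
lysosomal-modifier genes for rare exonic missense variation.

Frequency rules *flag* rather than filter: a variant missing from every
database is treated as rare (absence of evidence of commonness), which is
the behaviour required for truly novel alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "AnnotatedVariant",
    "PrioritizationConfig",
    "PrioritizedSet",
    "ClinicalIntersection",
    "DiagnosisCandidate",
    "annotated_pipeline",
    "predicted_pipeline",
    "clinical_intersection",
    "recessive_candidates",
    "modifier_scan",
    "clinvar_category",
    "PREDICTORS",
    "POP_DBS",
    "DEFAULT_MODIFIER_GENES",
]

#: the five dbNSFP predictors consulted by the >=3-damaging rule
PREDICTORS = ("SIFT", "Polyphen2", "MutationTaster", "MutationAssessor", "FATHMM")

#: population frequency databases carried on each variant
POP_DBS = ("1000G", "gnomAD", "ESP")

#: default lysosomal-enzyme modifier genes scanned by :func:`modifier_scan`
DEFAULT_MODIFIER_GENES = ("ATP6", "RUNX1", "TFEB", "CTSB", "GBA", "LAMP1")

_DAMAGING_EFFECTS = frozenset({"LOF", "Missense", "Splice_region"})
_CODING_REGIONS = frozenset({"exonic", "splice-site"})


@dataclass
class AnnotatedVariant:
    """One called variant with its clinical and population annotations.

    ``pop_freqs`` maps database name -> alternative-allele frequency (None
    = variant absent from that database).  ``predictor_calls`` maps tool
    name -> {"damaging", "tolerated", "missing"}.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" | "hom"
    gene: str
    effect: str  # "LOF" | "Missense" | "Splice_region" | "other"
    region: str  # "exonic" | "splice-site" | "other"
    clinvar: str | None = None  # raw ClinVar label, e.g. "Pathogenic/Likely pathogenic"
    hgmd: str | None = None  # "DM" | "DM?" | other | None
    pop_freqs: dict[str, float | None] = field(default_factory=dict)
    internal_freq: float | None = None
    fg_freq: float | None = None
    predictor_calls: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def n_damaging(self) -> int:
        return sum(1 for c in self.predictor_calls.values() if c == "damaging")


@dataclass
class PrioritizationConfig:
    """Thresholds of the two pipelines (all frequencies as proportions)."""

    annotated_maf_flag_threshold: float = 0.05
    predicted_maf_flag_threshold: float = 0.01
    fg_freq_threshold: float = 0.02
    min_damaging_predictors: int = 3
    modifier_common_threshold: float = 0.05
    #: ClinVar labels (lower-case components) retained by the annotated arm
    clinvar_retained_labels: frozenset[str] = frozenset(
        {"pathogenic", "likely pathogenic", "conflicting", "uncertain significance", "other"}
    )

    def __post_init__(self) -> None:
        for name in (
            "annotated_maf_flag_threshold",
            "predicted_maf_flag_threshold",
            "fg_freq_threshold",
            "modifier_common_threshold",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (1 <= self.min_damaging_predictors <= len(PREDICTORS)):
            raise ValueError("min_damaging_predictors must be between 1 and 5")


@dataclass
class PrioritizedSet:
    """Variants retained by one pipeline, with per-variant provenance."""

    pipeline: str
    variants: list[AnnotatedVariant]
    rare_flags: dict[str, bool]
    provenance: dict[str, list[str]]  # variant key -> rules satisfied

    @property
    def keys(self) -> set[str]:
        return {v.key for v in self.variants}

    def rare_variants(self) -> list[AnnotatedVariant]:
        return [v for v in self.variants if self.rare_flags.get(v.key, False)]


@dataclass
class ClinicalIntersection:
    clinvar_only: list[AnnotatedVariant]
    hgmd_only: list[AnnotatedVariant]
    both: list[AnnotatedVariant]
    rare_clinical: list[AnnotatedVariant]
    severity_filtered: bool

    @property
    def counts(self) -> dict[str, int]:
        return {
            "clinvar": len(self.clinvar_only) + len(self.both),
            "hgmd": len(self.hgmd_only) + len(self.both),
            "both": len(self.both),
            "rare_clinical": len(self.rare_clinical),
        }


@dataclass
class DiagnosisCandidate:
    gene: str
    mechanism: str  # "possible-compound-het" | "homozygous"
    variants: list[AnnotatedVariant]


def clinvar_category(
    raw: str | None,
    retained_labels: frozenset[str] = PrioritizationConfig.__dataclass_fields__[
        "clinvar_retained_labels"
    ].default,
) -> str:
    """Map a raw ClinVar label to {"retained", "benign", "none"}.

    Multi-component labels ("Pathogenic/Likely pathogenic") are retained if
    *any* component is in the retained set; "Benign/Likely benign" and kin
    collapse to the benign spectrum.  "Conflicting interpretations of
    pathogenicity" matches the "conflicting" label.
    """
    if raw is None or raw == "":
        return "none"
    parts = [p.strip().lower() for p in re.split(r"[/;,|]", raw) if p.strip()]
    for p in parts:
        if p in retained_labels or (
            p.startswith("conflicting") and "conflicting" in retained_labels
        ):
            return "retained"
    if all(p in ("benign", "likely benign") for p in parts):
        return "benign"
    return "benign" if any("benign" in p for p in parts) else "none"


def _all_nonmissing_below(freqs: dict[str, float | None], threshold: float) -> bool:
    """True when every reported population frequency is < threshold.

    A variant absent from every database is rare by this rule: missing is
    not evidence of commonness.
    """
    return all(f < threshold for f in freqs.values() if f is not None)


def annotated_pipeline(
    variants: list[AnnotatedVariant],
    config: PrioritizationConfig | None = None,
) -> PrioritizedSet:
    """Retain variants with a reported clinical classification.

    A variant is retained when its ClinVar label maps to the retained
    category or its HGMD class is DM or DM?.  Retained variants whose
    reported population frequencies are all below the 5% threshold are
    rare-flagged.
    """
    config = config or PrioritizationConfig()
    retained: list[AnnotatedVariant] = []
    rare: dict[str, bool] = {}
    prov: dict[str, list[str]] = {}
    for v in variants:
        rules = []
        if clinvar_category(v.clinvar, config.clinvar_retained_labels) == "retained":
            rules.append("clinvar-retained-class")
        if v.hgmd in ("DM", "DM?"):
            rules.append("hgmd-dm")
        if not rules:
            continue
        retained.append(v)
        prov[v.key] = rules
        rare[v.key] = _all_nonmissing_below(
            v.pop_freqs, config.annotated_maf_flag_threshold
        )
    return PrioritizedSet("annotated", retained, rare, prov)


def predicted_pipeline(
    variants: list[AnnotatedVariant],
    config: PrioritizationConfig | None = None,
) -> PrioritizedSet:
    """Retain damaging-predicted coding variants with no clinical record.

    Requires: exonic or splice-site region, no ClinVar and no HGMD class,
    LOF/missense/splice-region effect, >= ``min_damaging_predictors``
    damaging calls, and functional-genomics cohort frequency below the 2%
    threshold (missing treated as below).  Rare-flag threshold is 1%.
    """
    config = config or PrioritizationConfig()
    retained: list[AnnotatedVariant] = []
    rare: dict[str, bool] = {}
    prov: dict[str, list[str]] = {}
    for v in variants:
        if v.region not in _CODING_REGIONS:
            continue
        if clinvar_category(v.clinvar, config.clinvar_retained_labels) != "none":
            continue
        if v.hgmd is not None:
            continue
        if v.effect not in _DAMAGING_EFFECTS:
            continue
        if v.n_damaging() < config.min_damaging_predictors:
            continue
        if v.fg_freq is not None and v.fg_freq >= config.fg_freq_threshold:
            continue
        retained.append(v)
        prov[v.key] = [
            "coding-region",
            "no-clinical-class",
            "damaging-effect",
            f">={config.min_damaging_predictors}-damaging-predictors",
            "fg-rare",
        ]
        rare[v.key] = _all_nonmissing_below(
            v.pop_freqs, config.predicted_maf_flag_threshold
        )
    return PrioritizedSet("predicted", retained, rare, prov)


def clinical_intersection(
    annotated_set: PrioritizedSet,
    severity_lookup: dict[str, bool] | None = None,
    config: PrioritizationConfig | None = None,
) -> ClinicalIntersection:
    """Partition the annotated retained set by clinical-database membership.

    Variants are split into ClinVar-only, HGMD-only, and common-to-both
    groups.  The rare-clinical subset keeps rare-flagged members of any
    group; ``severity_lookup`` (gene -> keep?) optionally restricts it to
    genes curated as severe — without a lookup the subset is
    severity-unfiltered and marked as such.
    """
    config = config or PrioritizationConfig()
    cv_only, hg_only, both = [], [], []
    for v in annotated_set.variants:
        in_cv = clinvar_category(v.clinvar, config.clinvar_retained_labels) == "retained"
        in_hg = v.hgmd in ("DM", "DM?")
        if in_cv and in_hg:
            both.append(v)
        elif in_cv:
            cv_only.append(v)
        elif in_hg:
            hg_only.append(v)
    rare_clinical = [
        v
        for v in cv_only + hg_only + both
        if annotated_set.rare_flags.get(v.key, False)
        and (severity_lookup is None or severity_lookup.get(v.gene, False))
    ]
    return ClinicalIntersection(
        clinvar_only=cv_only,
        hgmd_only=hg_only,
        both=both,
        rare_clinical=rare_clinical,
        severity_filtered=severity_lookup is not None,
    )


def recessive_candidates(
    rare_clinical_variants: list[AnnotatedVariant],
) -> list[DiagnosisCandidate]:
    """Detect per-gene genotypes compatible with a recessive diagnosis.

    A gene yields a candidate when it carries at least two retained
    heterozygous variants (possible compound heterozygote — phase still
    unresolved, to be settled by phase inference) or at least one
    homozygous retained variant.
    """
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in rare_clinical_variants:
        by_gene.setdefault(v.gene, []).append(v)
    out: list[DiagnosisCandidate] = []
    for gene in sorted(by_gene):
        vs = by_gene[gene]
        homs = [v for v in vs if v.genotype == "hom"]
        hets = [v for v in vs if v.genotype == "het"]
        for h in homs:
            out.append(DiagnosisCandidate(gene, "homozygous", [h]))
        if len(hets) >= 2:
            out.append(DiagnosisCandidate(gene, "possible-compound-het", hets))
    return out


def modifier_scan(
    all_variants: list[AnnotatedVariant],
    modifier_genes: tuple[str, ...] | list[str] = DEFAULT_MODIFIER_GENES,
    config: PrioritizationConfig | None = None,
) -> dict:
    """Split exonic missense variants in modifier genes into common vs rare.

    A variant is *common* when any reported population frequency strictly
    exceeds ``modifier_common_threshold`` (a frequency exactly at the
    threshold is rare).  Returns per-gene counts plus totals.
    """
    config = config or PrioritizationConfig()
    genes = list(modifier_genes)
    report: dict = {
        "per_gene": {g: {"rare": 0, "common": 0} for g in genes},
        "rare_total": 0,
        "common_total": 0,
    }
    if not genes:
        report["per_gene"] = {}
        return report
    geneset = set(genes)
    for v in all_variants:
        if v.gene not in geneset or v.region != "exonic" or v.effect != "Missense":
            continue
        common = any(
            f is not None and f > config.modifier_common_threshold
            for f in v.pop_freqs.values()
        )
        bucket = "common" if common else "rare"
        report["per_gene"][v.gene][bucket] += 1
        report[f"{bucket}_total"] += 1
    return report
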