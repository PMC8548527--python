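"""Library, coverage and variant-set QC metrics for capture sequencing.

Implements the report-level arithmetic of a whole-exome QC table: human
sequence content and PCR-duplicate percentages from read counts, target
coverage summaries (mean depth, fraction at >=10x, depth-threshold
genotypability, FOLD80 uniformity penalty) and variant-set composition
(hom/het by SNV/indel, Ti/Tv).

Percentages destined for a report are rounded half-up to two decimals;
full precision is retained on the dataclasses themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "LibraryMetrics",
    "CoverageSummary",
    "VariantSetSummary",
    "compute_library_metrics",
    "compute_coverage_summary",
    "summarize_variant_set",
    "round_half_up",
]

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as printed in QC reports."""
    if x is None or not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LibraryMetrics:
    n_fragments: int
    mapped_before_dedup: int
    mapped_after_dedup: int
    human_percent: float | None  # 100 * mapped_before / n_fragments
    duplicate_percent: float | None  # 100 * (1 - after/before)
    gc_percent: float | None = None
    mean_coverage: float | None = None

    def report(self) -> dict:
        """Report-precision view (percentages rounded half-up, 2 decimals)."""
        return {
            "n_fragments": self.n_fragments,
            "mapped_before_dedup": self.mapped_before_dedup,
            "mapped_after_dedup": self.mapped_after_dedup,
            "human_percent": round_half_up(self.human_percent)
            if self.human_percent is not None
            else None,
            "duplicate_percent": round_half_up(self.duplicate_percent)
            if self.duplicate_percent is not None
            else None,
            "gc_percent": round_half_up(self.gc_percent)
            if self.gc_percent is not None
            else None,
            "mean_coverage": self.mean_coverage,
        }


@dataclass
class CoverageSummary:
    mean_coverage: float
    pct_ge_10x: float
    genotypability: float
    fold80: float
    n_target_bases: int


@dataclass
class VariantSetSummary:
    n_variants: int
    pct_hom: float
    pct_het: float
    pct_hom_snv: float
    pct_hom_indel: float
    pct_het_snv: float
    pct_het_indel: float
    titv: float  # NaN when undefined (no transversions)
    n_transitions: int
    n_transversions: int


def compute_library_metrics(
    n_fragments: int,
    mapped_before: int,
    mapped_after: int,
    read_gc_contents=None,
    mean_coverage: float | None = None,
) -> LibraryMetrics:
    """Human-content and duplicate percentages from read counts.

    human_percent = 100 * mapped_before / n_fragments;
    duplicate_percent = 100 * (1 - mapped_after / mapped_before).
    Zero denominators leave the corresponding field None rather than
    raising.  ``read_gc_contents`` (per-read GC fractions of mapped reads)
    optionally yields the GC percentage.
    """
    if min(n_fragments, mapped_before, mapped_after) < 0:
        raise ValueError("counts must be non-negative")
    if mapped_after > mapped_before:
        raise ValueError("mapped_after cannot exceed mapped_before")
    human = 100.0 * mapped_before / n_fragments if n_fragments > 0 else None
    dup = 100.0 * (1.0 - mapped_after / mapped_before) if mapped_before > 0 else None
    gc = None
    if read_gc_contents is not None:
        arr = np.asarray(list(read_gc_contents), dtype=float)
        if arr.size:
            gc = 100.0 * float(arr.mean())
    return LibraryMetrics(
        n_fragments=n_fragments,
        mapped_before_dedup=mapped_before,
        mapped_after_dedup=mapped_after,
        human_percent=human,
        duplicate_percent=dup,
        gc_percent=gc,
        mean_coverage=mean_coverage,
    )


def compute_coverage_summary(depths, min_callable_depth: int = 4) -> CoverageSummary:
    """Coverage summary over per-base target depths.

    FOLD80 = mean depth / 20th percentile of the depth distribution
    (linear interpolation between order statistics); 1.0 means perfectly
    uniform capture.  Genotypability approximates callability as the
    fraction of target bases at depth >= ``min_callable_depth``.
    """
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty target: no per-base depths")
    mean = float(arr.mean())
    p20 = float(np.percentile(arr, 20))
    if p20 == 0:
        warnings.warn("20th percentile of depth is 0; FOLD80 is infinite", stacklevel=2)
        fold80 = float("inf")
    else:
        fold80 = mean / p20
    return CoverageSummary(
        mean_coverage=mean,
        pct_ge_10x=100.0 * float(np.mean(arr >= 10)),
        genotypability=100.0 * float(np.mean(arr >= min_callable_depth)),
        fold80=fold80,
        n_target_bases=int(arr.size),
    )


def summarize_variant_set(variants) -> VariantSetSummary:
    """Genotype composition and Ti/Tv of a called variant set.

    ``variants`` is an iterable with ``ref``, ``alt`` and ``genotype``
    attributes (e.g. :class:`relicdx.prioritization.AnnotatedVariant`).
    Ti/Tv is computed over biallelic SNVs (transitions A<->G, C<->T); with
    zero transversions it is NaN and a warning is issued.
    """
    n = n_hom = n_het = 0
    hom_snv = hom_indel = het_snv = het_indel = 0
    ti = tv = 0
    for v in variants:
        n += 1
        is_snv = len(v.ref) == 1 and len(v.alt) == 1
        if v.genotype == "hom":
            n_hom += 1
            hom_snv, hom_indel = hom_snv + is_snv, hom_indel + (not is_snv)
        else:
            n_het += 1
            het_snv, het_indel = het_snv + is_snv, het_indel + (not is_snv)
        if is_snv:
            if (v.ref.upper(), v.alt.upper()) in TRANSITIONS:
                ti += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("empty variant set")
    if tv == 0:
        warnings.warn("no transversions; Ti/Tv undefined", stacklevel=2)
        titv = float("nan")
    else:
        titv = ti / tv
    pct = lambda k: 100.0 * k / n  # noqa: E731
    return VariantSetSummary(
        n_variants=n,
        pct_hom=pct(n_hom),
        pct_het=pct(n_het),
        pct_hom_snv=pct(hom_snv),
        pct_hom_indel=pct(hom_indel),
        pct_het_snv=pct(het_snv),
        pct_het_indel=pct(het_indel),
        titv=titv,
        n_transitions=ti,
        n_transversions=tv,
    )
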