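"""Cis/trans phase inference from a phased reference haplotype panel.

When a sample is heterozygous for two variants in the same gene, the
clinical interpretation hinges on whether they sit on the same chromosome
(cis) or on opposite chromosomes (trans, i.e. compound heterozygosity for a
recessive disorder).  Statistical phasing cannot place a variant that is
absent from the reference panel, so this module implements the indirect
strategy used for such "panel-absent" variants:

1. Take the panel-present variant as the *anchor* and collect all panel
   haplotypes carrying it.
2. Grow the maximal interval of panel sites over which the carriers are
   mutually concordant (an identity-by-descent / linkage-disequilibrium
   block), :func:`find_anchor_block`.
3. If that block spans the position of the panel-absent *query* variant,
   the carrier haplotypes predict the allele the anchor chromosome should
   carry there.  A query allele absent from (or near-absent from) the
   carrier haplotypes supports trans; near-fixed among carriers supports
   cis, :func:`infer_configuration`.
4. Independently, grossly different population frequencies of the two
   alleles make co-occurrence on one haplotype a priori unlikely,
   :func:`frequency_cooccurrence`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypePanel",
    "AnchorBlock",
    "PhaseCall",
    "CooccurrenceEvidence",
    "find_anchor_block",
    "infer_configuration",
    "frequency_cooccurrence",
]

MISSING = -1  # allele code for an unphased / missing panel genotype


@dataclass
class HaplotypePanel:
    """A phased reference panel: haplotype x site allele matrix.

    ``alleles[h, s]`` is 0 (ref), 1 (alt) or -1 (missing) for haplotype
    ``h`` at site ``s``.  Haplotypes ``2i`` and ``2i+1`` belong to diploid
    individual ``sample_labels[i]``.  Positions are 1-based genomic
    coordinates, strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_labels: list[str] = field(default_factory=list)
    ref_alleles: list[str] | None = None
    alt_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (haplotypes x sites)")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError(
                f"{self.alleles.shape[1]} allele columns but "
                f"{self.positions.size} positions"
            )
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("panel positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, int(self.positions[0]), int(self.positions[-1]))

    def site_index(self, position: int) -> int | None:
        """Index of the panel site at ``position`` (1-based), or None."""
        i = int(np.searchsorted(self.positions, position))
        if i < self.positions.size and self.positions[i] == position:
            return i
        return None


@dataclass
class AnchorBlock:
    """Maximal carrier-concordant interval around an anchor site."""

    chrom: str
    anchor_position: int
    anchor_index: int
    start_index: int  # first member site (inclusive)
    end_index: int  # last member site (inclusive)
    member_positions: np.ndarray
    concordance: np.ndarray  # per member site, fraction of carriers at modal allele
    n_carriers: int
    threshold: float
    unit: str  # "haplotype" or "individual"

    @property
    def interval(self) -> tuple[int, int]:
        return (int(self.member_positions[0]), int(self.member_positions[-1]))

    @property
    def length_bp(self) -> int:
        lo, hi = self.interval
        return hi - lo

    def spans(self, position: int) -> bool:
        lo, hi = self.interval
        return lo <= position <= hi


@dataclass
class CooccurrenceEvidence:
    """Expected same-haplotype frequency of two alleles under independence."""

    freq_anchor: float | None
    freq_query: float | None
    probability: float | None
    support: str  # "supports-trans" | "no-support" | "no-evidence"
    cutoff: float


@dataclass
class PhaseCall:
    """Verdict on the cis/trans configuration of anchor and query variants."""

    configuration: str  # "cis" | "trans" | "indeterminate"
    spanning: bool
    carrier_query_allele_fraction: float
    block: AnchorBlock
    query_position: int
    frequency_evidence: CooccurrenceEvidence | None = None
    warning: str | None = None


def _carrier_concordance(
    alleles: np.ndarray,
    carriers: np.ndarray,
    site: int,
    sample_of: np.ndarray | None,
    unit: str,
) -> float:
    """Fraction of anchor carriers matching the carrier-modal allele at ``site``.

    Missing alleles never match the modal allele.  In ``individual`` mode
    the carrier unit is the diploid individual: an individual is concordant
    when every one of its carrier haplotypes matches the modal allele.
    """
    col = alleles[carriers, site]
    counts = np.bincount(col[col >= 0], minlength=2)
    if counts.sum() == 0:
        return 0.0
    modal = int(np.argmax(counts))
    if unit == "haplotype":
        return float(np.mean(col == modal))
    # individual mode
    carrier_idx = np.flatnonzero(carriers)
    samples = sample_of[carrier_idx]
    ok: dict[int, bool] = {}
    for hap, smp in zip(carrier_idx, samples):
        match = alleles[hap, site] == modal
        ok[smp] = ok.get(smp, True) and bool(match)
    return sum(ok.values()) / len(ok)


def find_anchor_block(
    panel: HaplotypePanel,
    anchor_position: int,
    threshold: float = 0.98,
    unit: str = "haplotype",
) -> AnchorBlock:
    """Grow the maximal carrier-concordant site interval around the anchor.

    Starting from the anchor site, the interval is extended one panel site
    at a time in each direction; a site is included while the fraction of
    anchor-carrier haplotypes (or individuals, ``unit="individual"``)
    matching the carrier-modal allele is at least ``threshold``, and
    extension in that direction stops at the first failing site.  Because
    membership is a per-site property, this greedy scan returns the maximal
    contiguous interval containing the anchor in which every site passes.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0.5, 1], got {threshold}")
    if unit not in ("haplotype", "individual"):
        raise ValueError(f"unknown concordance unit {unit!r}")
    a = panel.site_index(anchor_position)
    if a is None:
        raise ValueError(f"anchor position {anchor_position} is not a panel site")
    carriers = panel.alleles[:, a] == 1
    n_carriers = int(carriers.sum())
    if n_carriers == 0:
        raise ValueError("anchor allele has no carrier haplotypes in the panel")

    sample_of = None
    if unit == "individual":
        sample_of = np.arange(panel.n_haplotypes) // 2

    conc = {a: _carrier_concordance(panel.alleles, carriers, a, sample_of, unit)}
    lo = a
    while lo - 1 >= 0:
        c = _carrier_concordance(panel.alleles, carriers, lo - 1, sample_of, unit)
        if c < threshold:
            break
        lo -= 1
        conc[lo] = c
    hi = a
    while hi + 1 < panel.n_sites:
        c = _carrier_concordance(panel.alleles, carriers, hi + 1, sample_of, unit)
        if c < threshold:
            break
        hi += 1
        conc[hi] = c

    members = np.arange(lo, hi + 1)
    return AnchorBlock(
        chrom=panel.chrom,
        anchor_position=anchor_position,
        anchor_index=a,
        start_index=lo,
        end_index=hi,
        member_positions=panel.positions[lo : hi + 1].copy(),
        concordance=np.array([conc[i] for i in members]),
        n_carriers=n_carriers,
        threshold=threshold,
        unit=unit,
    )


def infer_configuration(
    block: AnchorBlock,
    query_position: int,
    panel: HaplotypePanel,
    sample_genotypes: dict[str, str] | None = None,
    freq_anchor: float | None = None,
    freq_query: float | None = None,
    threshold: float | None = None,
) -> PhaseCall:
    """Call cis/trans for a query variant relative to the anchor block.

    ``sample_genotypes`` maps ``"anchor"`` and ``"query"`` to genotype
    labels; both must be heterozygous (``"het"``, ``"0/1"`` or ``"0|1"``
    style), otherwise the configuration is undefined and a ``ValueError``
    is raised.  The decision uses the fraction of anchor-carrier haplotypes
    bearing the query alt allele: with ``t`` the concordance threshold,
    a spanning block with fraction <= 1-t supports trans and a fraction
    >= t supports cis; anything else (including a non-spanning block) is
    indeterminate.  A query allele absent from the panel has fraction 0.
    """
    if threshold is None:
        threshold = block.threshold
    if sample_genotypes is not None:
        het = {"het", "0/1", "1/0", "0|1", "1|0"}
        for k in ("anchor", "query"):
            g = str(sample_genotypes.get(k, "")).lower()
            if g not in het:
                raise ValueError(
                    f"sample must be heterozygous for the {k} variant "
                    f"(got {sample_genotypes.get(k)!r}); configuration undefined"
                )

    evidence = None
    if freq_anchor is not None or freq_query is not None:
        evidence = frequency_cooccurrence(freq_anchor, freq_query)

    lo, hi = panel.region[1], panel.region[2]
    warning = None
    if not (lo <= query_position <= hi):
        warning = (
            f"query position {query_position} lies outside the panel region "
            f"{panel.chrom}:{lo}-{hi}"
        )
        warnings.warn(warning, stacklevel=2)
        return PhaseCall(
            configuration="indeterminate",
            spanning=False,
            carrier_query_allele_fraction=0.0,
            block=block,
            query_position=query_position,
            frequency_evidence=evidence,
            warning=warning,
        )

    carriers = panel.alleles[:, block.anchor_index] == 1
    q = panel.site_index(query_position)
    if q is None:
        fraction = 0.0  # query allele absent from the panel altogether
    else:
        fraction = float(np.mean(panel.alleles[carriers, q] == 1))

    spanning = block.spans(query_position)
    if spanning and fraction <= 1.0 - threshold:
        configuration = "trans"
    elif spanning and fraction >= threshold:
        configuration = "cis"
    else:
        configuration = "indeterminate"

    return PhaseCall(
        configuration=configuration,
        spanning=spanning,
        carrier_query_allele_fraction=fraction,
        block=block,
        query_position=query_position,
        frequency_evidence=evidence,
        warning=warning,
    )


def frequency_cooccurrence(
    freq_anchor: float | None,
    freq_query: float | None,
    cutoff: float = 1e-5,
) -> CooccurrenceEvidence:
    """Expected frequency of a haplotype carrying both alleles, assuming
    linkage equilibrium (the product of the two population frequencies).

    When this product is below ``cutoff`` yet both variants are observed in
    a single individual, chance co-occurrence on one inherited chromosome
    is implausible and the evidence qualitatively supports a trans
    configuration.  A missing frequency on either side yields no evidence;
    a query frequency of exactly 0 (allele absent from the database) is
    valid input and gives product 0.
    """
    for name, f in (("anchor", freq_anchor), ("query", freq_query)):
        if f is not None and not (0.0 <= f <= 1.0):
            raise ValueError(f"{name} frequency must be in [0, 1], got {f}")
    if freq_anchor is None or freq_query is None:
        if freq_anchor is None and freq_query is None:
            support = "no-evidence"
        else:
            support = "no-evidence"
        return CooccurrenceEvidence(freq_anchor, freq_query, None, support, cutoff)
    product = freq_anchor * freq_query
    support = "supports-trans" if product < cutoff else "no-support"
    return CooccurrenceEvidence(freq_anchor, freq_query, product, support, cutoff)
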