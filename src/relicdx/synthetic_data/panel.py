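"""Simulated phased haplotype panels with a planted cis/trans configuration.

The panel is a founder-mosaic model: every haplotype is a mosaic of a small
set of founder haplotypes with random breakpoints.  The rare *anchor*
allele is confined to a single founder lineage, so anchor carriers share an
identical stretch of sequence around the anchor site — the
identity-by-descent block that block discovery should recover.  Each
carrier's shared segment extends an exponentially distributed genomic
distance to either side of the anchor (mean ``region_span / recomb_rate``),
which reproduces the decay of haplotype sharing with distance without a
full coalescent simulation.

The *query* variant position lies inside the expected block.  In the
planted ``trans`` configuration the query allele is absent from every
panel haplotype (its position falls between panel sites); in the ``cis``
configuration the query site is added to the panel with the alternate
allele on every anchor-carrier haplotype.  A sample record carries both
variants heterozygous, with the planted configuration as truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from relicdx.phase_inference import HaplotypePanel

__all__ = ["PanelConfig", "simulate_haplotype_panel"]


@dataclass
class PanelConfig:
    n_haplotypes: int = 500
    n_sites: int = 120
    region_span: int = 20_000
    n_founders: int = 8
    recomb_rate: float = 0.2  # expected breakpoints per haplotype across the region
    anchor_frequency: float = 0.03
    planted_configuration: str = "trans"  # "cis" | "trans"
    chrom: str = "chr17"
    region_start: int = 80_096_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.planted_configuration not in ("cis", "trans"):
            raise ValueError(
                f"planted_configuration must be cis or trans, got "
                f"{self.planted_configuration!r}"
            )
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if round(self.anchor_frequency * self.n_haplotypes) < 1:
            raise ValueError(
                "anchor_frequency * n_haplotypes < 1: the anchor would have no carriers"
            )


def _mosaic(
    rng: np.random.Generator,
    founders: np.ndarray,
    founder_pool: np.ndarray,
    positions: np.ndarray,
    rate: float,
    span: int,
) -> np.ndarray:
    """One haplotype as a breakpoint mosaic over ``founder_pool`` lineages."""
    n_bp = rng.poisson(rate) if rate > 0 else 0
    if n_bp == 0:
        return founders[rng.choice(founder_pool)].copy()
    cuts = np.sort(rng.integers(positions[0], positions[0] + span, size=n_bp))
    hap = np.empty(positions.size, dtype=np.int8)
    seg_edges = np.concatenate(([positions[0] - 1], cuts, [positions[-1] + 1]))
    for lo, hi in zip(seg_edges[:-1], seg_edges[1:]):
        sel = (positions > lo) & (positions <= hi)
        if sel.any():
            hap[sel] = founders[rng.choice(founder_pool)][sel]
    return hap


def _carrier_haplotype(
    rng: np.random.Generator,
    founders: np.ndarray,
    positions: np.ndarray,
    anchor_pos: int,
    rate: float,
    span: int,
) -> np.ndarray:
    """An anchor-carrier haplotype: founder 0 over an exponential IBD
    segment around the anchor, other founders outside it."""
    if rate > 0:
        scale = span / rate
        left = rng.exponential(scale)
        right = rng.exponential(scale)
    else:
        left = right = np.inf
    hap = np.empty(positions.size, dtype=np.int8)
    inside = (positions >= anchor_pos - left) & (positions <= anchor_pos + right)
    hap[inside] = founders[0][inside]
    others = np.arange(1, founders.shape[0])
    if (~inside & (positions < anchor_pos)).any():
        f = founders[rng.choice(others)]
        sel = ~inside & (positions < anchor_pos)
        hap[sel] = f[sel]
    if (~inside & (positions > anchor_pos)).any():
        f = founders[rng.choice(others)]
        sel = ~inside & (positions > anchor_pos)
        hap[sel] = f[sel]
    return hap


def simulate_haplotype_panel(config: PanelConfig):
    """Generate a phased panel, a doubly heterozygous sample, and truth.

    Returns ``(panel, truth)``.  ``truth`` records the anchor and query
    loci, the planted configuration, the carrier haplotype indices and the
    sample record (two haplotypes; anchor and query both heterozygous).
    """
    rng = np.random.default_rng(config.seed)
    n_hap, n_sites, span = config.n_haplotypes, config.n_sites, config.region_span

    positions = config.region_start + np.sort(
        rng.choice(np.arange(1, span, 2), size=n_sites, replace=False)
    )
    anchor_idx = n_sites // 2
    anchor_pos = int(positions[anchor_idx])

    # founder haplotypes; the anchor allele lives only on founder 0
    maf = rng.uniform(0.05, 0.5, size=n_sites)
    founders = (rng.random((config.n_founders, n_sites)) < maf).astype(np.int8)
    founders[0, anchor_idx] = 1
    founders[1:, anchor_idx] = 0

    n_carriers = int(round(config.anchor_frequency * n_hap))
    carrier_idx = np.sort(rng.choice(n_hap, size=n_carriers, replace=False))
    carrier_set = set(carrier_idx.tolist())

    alleles = np.empty((n_hap, n_sites), dtype=np.int8)
    non_anchor = np.arange(1, config.n_founders)
    for h in range(n_hap):
        if h in carrier_set:
            alleles[h] = _carrier_haplotype(
                rng, founders, positions, anchor_pos, config.recomb_rate, span
            )
        else:
            alleles[h] = _mosaic(
                rng, founders, non_anchor, positions, config.recomb_rate, span
            )
    # the mosaic may have dropped a carrier's anchor allele only if the IBD
    # segment excluded the anchor site, which cannot happen by construction
    alleles[carrier_idx, anchor_idx] = 1

    # query position: between the anchor site and its right neighbour
    qpos = int((positions[anchor_idx] + positions[anchor_idx + 1]) // 2)
    if qpos in (positions[anchor_idx], positions[anchor_idx + 1]):
        qpos = int(positions[anchor_idx]) + 1

    # sample: one anchor-carrier haplotype, one non-carrier haplotype
    sample_a = _carrier_haplotype(
        rng, founders, positions, anchor_pos, config.recomb_rate, span
    )
    sample_a[anchor_idx] = 1
    sample_b = _mosaic(rng, founders, non_anchor, positions, config.recomb_rate, span)

    query_on_carrier_haplotype = config.planted_configuration == "cis"
    if config.planted_configuration == "cis":
        # the query allele exists in the population: add the site to the
        # panel, alternate on every carrier haplotype
        insert_at = int(np.searchsorted(positions, qpos))
        qcol = np.zeros(n_hap, dtype=np.int8)
        qcol[carrier_idx] = 1
        alleles = np.insert(alleles, insert_at, qcol, axis=1)
        positions = np.insert(positions, insert_at, qpos)
        sample_a = np.insert(sample_a, insert_at, 1)
        sample_b = np.insert(sample_b, insert_at, 0)

    labels = [f"S{i:04d}" for i in range(n_hap // 2 + n_hap % 2)]
    panel = HaplotypePanel(
        chrom=config.chrom,
        positions=positions,
        alleles=alleles,
        sample_labels=labels,
    )
    truth = {
        "config": asdict(config),
        "anchor": {"chrom": config.chrom, "pos": anchor_pos},
        "query": {"chrom": config.chrom, "pos": qpos},
        "configuration": config.planted_configuration,
        "carrier_indices": carrier_idx.tolist(),
        "n_carriers": n_carriers,
        "sample": {
            "anchor_genotype": "het",
            "query_genotype": "het",
            "query_on_anchor_haplotype": query_on_carrier_haplotype,
            "haplotype_a": sample_a.tolist(),
            "haplotype_b": sample_b.tolist(),
        },
    }
    return panel, truth
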