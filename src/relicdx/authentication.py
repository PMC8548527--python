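"""Ancient-DNA authentication statistics.

Degraded endogenous DNA has a characteristic signature: short fragments and
cytosine deamination concentrated at fragment ends, read as C>T
substitutions at the 5' terminus and G>A at the 3' terminus.  This module
computes the standard battery of authentication statistics from aligned
reads and pileups:

* position-wise terminal misincorporation profiles
  (:func:`compute_misincorporation_profile`);
* fragment-length summaries (:func:`summarize_fragment_lengths`);
* molecular sex from the Ry statistic nY/(nX+nY)
  (:func:`determine_genetic_sex`);
* present-day contamination of the mitochondrial data by a grid
  maximum-likelihood mixture estimator (:func:`estimate_mt_contamination`);
* nuclear contamination from excess X-chromosome heterozygosity in a male
  (:func:`estimate_x_contamination`).

All internal coordinates are 0-based half-open; pileup/VCF I/O converts
from 1-based at the boundary.  Alignment-based statistics apply a mapping
quality >= 30 filter by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DamageProfile",
    "FragmentLengthSummary",
    "SexCall",
    "ContaminationEstimate",
    "compute_misincorporation_profile",
    "summarize_fragment_lengths",
    "determine_genetic_sex",
    "estimate_mt_contamination",
    "estimate_x_contamination",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class DamageProfile:
    """Terminal substitution frequencies over a window from each fragment end.

    ``five_prime_ct[i]`` is the fraction of reads with reference C read as
    T at position ``i+1`` from the 5' end; ``three_prime_ga`` mirrors this
    for G>A from the 3' end.  Positions with zero opportunities are NaN
    (undefined), never 0 — tiny inputs must not masquerade as undamaged.
    """

    five_prime_ct: np.ndarray
    three_prime_ga: np.ndarray
    five_prime_opportunities: np.ndarray
    three_prime_opportunities: np.ndarray
    other_subst: float
    n_fragments: int
    window: int
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.window + 1),
                "five_prime_ct": self.five_prime_ct,
                "five_prime_opportunities": self.five_prime_opportunities,
                "three_prime_ga": self.three_prime_ga,
                "three_prime_opportunities": self.three_prime_opportunities,
            }
        )


@dataclass
class FragmentLengthSummary:
    mean: float
    median: float
    histogram: dict[int, int]  # length -> count
    n: int


@dataclass
class SexCall:
    nX: int
    nY: int
    ry: float
    se: float
    classification: str  # consistent-with-XY | consistent-with-XX | indeterminate


@dataclass
class ContaminationEstimate:
    estimate: float
    stderr: float
    method: str  # "mt-likelihood" | "x-heterozygosity"
    n_sites: int
    log_likelihood_curve: pd.DataFrame | None = field(default=None, repr=False)


def _oriented_pairs(read, reference) -> list[tuple[str, str]] | None:
    """(ref_base, read_base) pairs in original-molecule orientation.

    For reverse-strand alignments the stored sequence is the reverse
    complement of the sequenced molecule, so pairs are complemented and
    reversed to put the molecule's 5' end first.
    """
    seq = read.query_sequence
    if seq is None:
        return None
    chrom = read.reference_name
    try:
        refseq = _fetch(reference, chrom, read.reference_start, read.reference_end)
    except (KeyError, ValueError):
        return None
    pairs: list[tuple[str, str]] = []
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        rb = refseq[rpos - read.reference_start].upper()
        qb = seq[qpos].upper()
        pairs.append((rb, qb))
    if read.is_reverse:
        pairs = [
            (rb.translate(_COMPLEMENT), qb.translate(_COMPLEMENT))
            for rb, qb in reversed(pairs)
        ]
    return pairs


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Reference slice supporting dict[str, str], pyfaidx.Fasta or pysam.FastaFile."""
    if isinstance(reference, dict):
        return reference[chrom][start:end]
    if hasattr(reference, "fetch"):  # pysam.FastaFile
        return reference.fetch(chrom, start, end)
    return str(reference[chrom][start:end])  # pyfaidx.Fasta


def compute_misincorporation_profile(
    alignments,
    reference,
    window: int = 15,
    min_mapping_quality: int = 30,
) -> DamageProfile:
    """Position-wise C>T (5') and G>A (3') frequencies near fragment ends.

    For each position ``i`` from an end, the frequency is the number of
    reads whose reference base is C (resp. G) *and* read base is T (resp.
    A) divided by the number of reads with reference C (resp. G) at that
    position — i.e. conditional on opportunity.  ``other_subst`` is the
    overall mismatch rate excluding terminal-window C>T/G>A, a proxy for
    the background error rate.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ct_hits = np.zeros(window)
    ct_opps = np.zeros(window)
    ga_hits = np.zeros(window)
    ga_opps = np.zeros(window)
    other_mism = 0
    other_opps = 0
    n = 0
    n_skipped = 0
    for read in alignments:
        if read.is_unmapped or read.mapping_quality < min_mapping_quality:
            continue
        pairs = _oriented_pairs(read, reference)
        if pairs is None:
            n_skipped += 1
            continue
        n += 1
        L = len(pairs)
        w5 = min(window, L)
        for i in range(w5):
            rb, qb = pairs[i]
            if rb == "C":
                ct_opps[i] += 1
                if qb == "T":
                    ct_hits[i] += 1
        for i in range(w5):
            rb, qb = pairs[L - 1 - i]
            if rb == "G":
                ga_opps[i] += 1
                if qb == "A":
                    ga_hits[i] += 1
        for j, (rb, qb) in enumerate(pairs):
            is_terminal_ct = rb == "C" and qb == "T" and j < window
            is_terminal_ga = rb == "G" and qb == "A" and j >= L - window
            if is_terminal_ct or is_terminal_ga:
                continue
            other_opps += 1
            if rb != qb and rb != "N" and qb != "N":
                other_mism += 1
    if n == 0:
        raise ValueError("no usable aligned reads")
    if n_skipped:
        logger.warning("skipped %d reads without reference context", n_skipped)
    with np.errstate(invalid="ignore", divide="ignore"):
        five = np.where(ct_opps > 0, ct_hits / np.maximum(ct_opps, 1), np.nan)
        three = np.where(ga_opps > 0, ga_hits / np.maximum(ga_opps, 1), np.nan)
    return DamageProfile(
        five_prime_ct=five,
        three_prime_ga=three,
        five_prime_opportunities=ct_opps.astype(int),
        three_prime_opportunities=ga_opps.astype(int),
        other_subst=other_mism / other_opps if other_opps else float("nan"),
        n_fragments=n,
        window=window,
        n_skipped=n_skipped,
    )


def summarize_fragment_lengths(alignments) -> FragmentLengthSummary:
    """Mean/median/histogram of aligned fragment spans."""
    lengths = []
    for read in alignments:
        if getattr(read, "is_unmapped", False):
            continue
        span = read.reference_length
        if span:
            lengths.append(int(span))
    if not lengths:
        raise ValueError("no aligned fragments to summarize")
    arr = np.array(lengths)
    values, counts = np.unique(arr, return_counts=True)
    return FragmentLengthSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        histogram={int(v): int(c) for v, c in zip(values, counts)},
        n=len(lengths),
    )


def determine_genetic_sex(
    nX: int | None = None,
    nY: int | None = None,
    alignments=None,
    min_total: int = 100,
    min_mapping_quality: int = 30,
    xx_threshold: float = 0.016,
    xy_threshold: float = 0.075,
) -> SexCall:
    """Molecular sex from sex-chromosome alignment counts.

    Ry = nY/(nX+nY) with binomial standard error; the 95% confidence
    interval must fall entirely below ``xx_threshold`` (consistent with
    XX) or entirely above ``xy_threshold`` (consistent with XY), otherwise
    the call is indeterminate.  Counts may be given directly or derived
    from an alignment iterable (reference names X/chrX and Y/chrY, mapping
    quality filtered).
    """
    if alignments is not None:
        nX = nY = 0
        for read in alignments:
            if read.is_unmapped or read.mapping_quality < min_mapping_quality:
                continue
            name = (read.reference_name or "").lstrip("chr")
            if name == "X":
                nX += 1
            elif name == "Y":
                nY += 1
    if nX is None or nY is None:
        raise ValueError("provide nX/nY counts or an alignment iterable")
    total = nX + nY
    if total < min_total:
        warnings.warn(
            f"only {total} sex-chromosome alignments (< {min_total}); "
            "sex call is indeterminate",
            stacklevel=2,
        )
        ry = nY / total if total else float("nan")
        se = np.sqrt(ry * (1 - ry) / total) if total else float("nan")
        return SexCall(nX, nY, ry, se, "indeterminate")
    ry = nY / total
    se = float(np.sqrt(ry * (1 - ry) / total))
    if ry + 1.96 * se < xx_threshold:
        cls = "consistent-with-XX"
    elif ry - 1.96 * se > xy_threshold:
        cls = "consistent-with-XY"
    else:
        cls = "indeterminate"
    return SexCall(nX, nY, ry, se, cls)


def _base_given_allele(base: str, allele: str, error_rate: float) -> float:
    return 1.0 - error_rate if base == allele else error_rate / 3.0


def estimate_mt_contamination(
    pileup: pd.DataFrame,
    endogenous_consensus: dict[int, str] | None = None,
    contaminant_allele_frequencies: dict[int, dict[str, float]] | None = None,
    error_rate: float = 0.01,
    grid_step: float = 0.001,
) -> ContaminationEstimate:
    """Maximum-likelihood contaminant fraction from a mitochondrial pileup.

    The pileup must be restricted to diagnostic sites where the endogenous
    consensus and the contaminant allele pool differ.  Each read base is
    modelled as a two-component mixture: with probability ``1-c`` it comes
    from the endogenous consensus base, with probability ``c`` from the
    contaminant allele pool, in both cases subject to a uniform
    sequencing-error rate.  The log-likelihood is maximized over a grid
    c in {0, grid_step, ..., 1}; the standard error comes from the
    curvature (quadratic fit) of the log-likelihood at the maximum.

    ``pileup`` columns: ``pos`` (1-based), ``bases`` (string of read
    bases); endogenous consensus and contaminant frequencies either as
    argument dicts keyed by ``pos`` or as pileup columns ``endo`` and
    ``cont`` (single contaminant allele, frequency 1).
    """
    if not (0.0 <= error_rate <= 0.25):
        raise ValueError(f"error_rate must be in [0, 0.25], got {error_rate}")
    if len(pileup) == 0:
        raise ValueError("no diagnostic sites in pileup")

    bases_order = "ACGT"
    site_rows = []
    for _, row in pileup.iterrows():
        pos = int(row["pos"])
        endo = (
            endogenous_consensus[pos]
            if endogenous_consensus is not None
            else row["endo"]
        )
        if contaminant_allele_frequencies is not None:
            cfreqs = contaminant_allele_frequencies[pos]
        else:
            cfreqs = {row["cont"]: 1.0}
        if max(cfreqs, key=cfreqs.get) == endo:
            continue  # not diagnostic
        counts = np.array([row["bases"].count(b) for b in bases_order], dtype=float)
        p_endo = np.array(
            [_base_given_allele(b, endo, error_rate) for b in bases_order]
        )
        p_cont = np.array(
            [
                sum(
                    f * _base_given_allele(b, a, error_rate)
                    for a, f in cfreqs.items()
                )
                for b in bases_order
            ]
        )
        site_rows.append((counts, p_endo, p_cont))
    if not site_rows:
        raise ValueError("no diagnostic sites (consensus equals contaminant everywhere)")

    counts = np.stack([r[0] for r in site_rows])  # (S, 4)
    p_endo = np.stack([r[1] for r in site_rows])
    p_cont = np.stack([r[2] for r in site_rows])

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    # (G, S, 4) mixture probabilities, reduced with observed counts
    mix = (1 - grid[:, None, None]) * p_endo[None] + grid[:, None, None] * p_cont[None]
    ll = np.sum(counts[None] * np.log(np.maximum(mix, 1e-300)), axis=(1, 2))

    i = int(np.argmax(ll))
    estimate = float(grid[i])
    curve = pd.DataFrame({"c": grid, "log_likelihood": ll})

    if ll.max() - ll.min() < 1e-9:
        warnings.warn("flat contamination likelihood; estimate unconstrained", stacklevel=2)
        return ContaminationEstimate(estimate, 0.5, "mt-likelihood", counts.shape[0], curve)

    j = min(max(i, 1), len(grid) - 2)  # interior point for the second difference
    d2 = (ll[j - 1] - 2 * ll[j] + ll[j + 1]) / grid_step**2
    stderr = float(1.0 / np.sqrt(-d2)) if d2 < 0 else 0.5
    return ContaminationEstimate(estimate, stderr, "mt-likelihood", counts.shape[0], curve)


def _as_site_arrays(sites) -> tuple[np.ndarray, np.ndarray]:
    """(mismatches, depth) per site from a DataFrame or array pair."""
    if isinstance(sites, pd.DataFrame):
        return (
            sites["mismatches"].to_numpy(dtype=float),
            sites["depth"].to_numpy(dtype=float),
        )
    mism, depth = sites
    return np.asarray(mism, dtype=float), np.asarray(depth, dtype=float)


def estimate_x_contamination(
    polymorphic_sites,
    monomorphic_sites,
    sample_is_male: bool = True,
    n_blocks: int = 20,
) -> ContaminationEstimate:
    """Nuclear contamination from X-chromosome heterozygosity in a male.

    A male carries one X, so any minor-allele signal at polymorphic X sites
    beyond the background mismatch rate (measured at flanking monomorphic
    sites) indicates contamination: estimate = max(0, polymorphic mismatch
    rate - monomorphic mismatch rate).  Uncertainty by a delete-one block
    jackknife over polymorphic sites (default 20 blocks).

    Both site collections are (mismatches, depth) arrays or DataFrames
    with those columns.
    """
    if not sample_is_male:
        raise ValueError("X-heterozygosity contamination is undefined for XX samples")
    poly_m, poly_d = _as_site_arrays(polymorphic_sites)
    mono_m, mono_d = _as_site_arrays(monomorphic_sites)
    covered = poly_d > 0
    if not covered.any():
        raise ValueError("no covered polymorphic sites")
    poly_m, poly_d = poly_m[covered], poly_d[covered]

    def point(pmask: np.ndarray, mmask: np.ndarray) -> float:
        mono_rate = (
            mono_m[mmask].sum() / mono_d[mmask].sum() if mono_d[mmask].sum() > 0 else 0.0
        )
        return max(0.0, poly_m[pmask].sum() / poly_d[pmask].sum() - mono_rate)

    all_poly = np.ones(poly_m.size, dtype=bool)
    all_mono = np.ones(mono_m.size, dtype=bool)
    full = point(all_poly, all_mono)

    # joint delete-one-block jackknife: the background rate is estimated
    # too, so its sampling variance must propagate into the stderr
    n_blocks = max(2, min(n_blocks, poly_m.size))
    pblocks = np.array_split(np.arange(poly_m.size), n_blocks)
    mblocks = np.array_split(np.arange(mono_m.size), n_blocks)
    thetas = []
    for pb, mb in zip(pblocks, mblocks):
        pmask = all_poly.copy()
        pmask[pb] = False
        mmask = all_mono.copy()
        if mb.size:
            mmask[mb] = False
        thetas.append(point(pmask, mmask))
    thetas = np.array(thetas)
    stderr = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((thetas - thetas.mean()) ** 2)))
    return ContaminationEstimate(full, stderr, "x-heterozygosity", int(poly_m.size))
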