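"""Simulated alignment-count and pileup inputs for the authentication stage."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "simulate_sexed_alignment_counts",
    "simulate_mt_pileup",
    "simulate_x_pileup",
]

#: ratio of Y-mappable to (X+Y)-mappable sequence, i.e. the expected Ry in a male
DEFAULT_MALE_Y_SHARE = 0.09
#: fraction of X-derived reads mismapped to Y in a female
DEFAULT_FEMALE_MISMAP = 0.002

_BASES = "ACGT"


def simulate_sexed_alignment_counts(
    sex: str,
    n_sex_chromosome_reads: int,
    seed: int | None = None,
    male_y_share: float = DEFAULT_MALE_Y_SHARE,
    female_mismap_rate: float = DEFAULT_FEMALE_MISMAP,
) -> dict[str, int]:
    """Allocate sex-chromosome reads to X and Y for a given karyotype.

    In an XY individual the Y share reflects the relative mappable length
    of Y versus X+Y (default 0.09); in an XX individual Y receives only
    mismapped reads at ``female_mismap_rate``.
    """
    if n_sex_chromosome_reads < 1:
        raise ValueError("n_sex_chromosome_reads must be >= 1")
    if sex not in ("XX", "XY"):
        raise ValueError(f"unknown sex label {sex!r} (expected 'XX' or 'XY')")
    rng = np.random.default_rng(seed)
    p = male_y_share if sex == "XY" else female_mismap_rate
    nY = int(rng.binomial(n_sex_chromosome_reads, p))
    return {"nX": n_sex_chromosome_reads - nY, "nY": nY}


def simulate_mt_pileup(
    true_contamination: float,
    depth: int,
    n_diagnostic_sites: int,
    error_rate: float = 0.0,
    seed: int | None = None,
):
    """Pileup at mitochondrial diagnostic sites with a planted contaminant mix.

    At each site the endogenous consensus base and the contaminant allele
    differ.  Each read base is contaminant-derived with probability
    ``true_contamination`` and independently flipped to a uniformly chosen
    other base with probability ``error_rate``.  Returns ``(pileup,
    truth)`` where the pileup DataFrame has columns ``pos`` (1-based),
    ``endo``, ``cont``, ``bases``.
    """
    if not (0.0 <= true_contamination <= 1.0):
        raise ValueError("true_contamination must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n_cont_bases = 0
    for s in range(n_diagnostic_sites):
        endo, cont = rng.choice(list(_BASES), size=2, replace=False)
        from_cont = rng.random(depth) < true_contamination
        n_cont_bases += int(from_cont.sum())
        bases = np.where(from_cont, cont, endo).astype(object)
        flip = np.flatnonzero(rng.random(depth) < error_rate)
        for j in flip:
            others = [b for b in _BASES if b != bases[j]]
            bases[j] = others[int(rng.integers(0, 3))]
        rows.append(
            {"pos": 100 + 10 * s, "endo": endo, "cont": cont, "bases": "".join(bases)}
        )
    truth = {
        "true_contamination": true_contamination,
        "depth": depth,
        "n_sites": n_diagnostic_sites,
        "error_rate": error_rate,
        "n_contaminant_bases": n_cont_bases,
        "n_bases": depth * n_diagnostic_sites,
    }
    return pd.DataFrame(rows), truth


def simulate_x_pileup(
    true_contamination: float,
    n_polymorphic_sites: int = 1344,
    depth: int = 30,
    n_monomorphic_sites: int | None = None,
    error_rate: float = 0.001,
    seed: int | None = None,
):
    """Per-site mismatch counts on the X chromosome of a male sample.

    At polymorphic sites the contaminant carries the alternate allele, so
    a base mismatches the (single-copy) endogenous consensus when it is
    contaminant-derived and not error-flipped back, or endogenous and
    error-flipped; at monomorphic sites only errors mismatch.  The default
    error rate reflects base-quality >= 30 filtered data.  Returns
    ``(polymorphic_df, monomorphic_df, truth)`` with columns
    ``mismatches``/``depth``.
    """
    if not (0.0 <= true_contamination <= 1.0):
        raise ValueError("true_contamination must be in [0, 1]")
    if n_monomorphic_sites is None:
        n_monomorphic_sites = n_polymorphic_sites
    rng = np.random.default_rng(seed)
    c, e = true_contamination, error_rate
    # contaminant base mismatches unless flipped onto the endogenous base (e/3)
    p_poly = c * (1 - e / 3) + (1 - c) * e
    p_mono = e
    poly = pd.DataFrame(
        {
            "mismatches": rng.binomial(depth, p_poly, size=n_polymorphic_sites),
            "depth": depth,
        }
    )
    mono = pd.DataFrame(
        {
            "mismatches": rng.binomial(depth, p_mono, size=n_monomorphic_sites),
            "depth": depth,
        }
    )
    truth = {
        "true_contamination": c,
        "error_rate": e,
        "p_polymorphic_mismatch": p_poly,
        "p_monomorphic_mismatch": p_mono,
    }
    return poly, mono, truth
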