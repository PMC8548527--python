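"""Simulated ancient-DNA read sets with known ground truth.

Fragments are drawn from a log-normal length distribution (degraded DNA is
short and right-skewed), placed uniformly on the reference, and damaged
with the standard single-exponential terminal deamination model: the C>T
probability at 5' position ``i`` (1-based) is ``terminal_ct_rate *
decay**(i-1)``, with the symmetric G>A process at the 3' end.  Partial
uracil-DNA glycosylase (UDG) treatment removes internal uracils, so in
``udg_mode="partial"`` damage is confined to the terminal base of each
end.  A configurable fraction of fragments are undamaged "modern"
contaminants.  Each read's damage events and contaminant status are
recorded in a truth structure so downstream estimators can be validated
against exactly what was simulated.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pysam

__all__ = ["DamageModelConfig", "simulate_adna_fragments", "random_reference"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_MAX_DAMAGE_SPAN = 30  # decay makes damage beyond this numerically negligible


@dataclass
class DamageModelConfig:
    """Parameters of the ancient-DNA fragment and damage simulator."""

    terminal_ct_rate: float = 0.0217
    decay: float = 0.5
    udg_mode: str = "none"  # "none" | "partial"
    mean_fragment_length: float = 90.0
    length_dispersion: float = 0.25  # sigma of log length
    contamination_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.terminal_ct_rate <= 1.0):
            raise ValueError("terminal_ct_rate must be in [0, 1]")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay must be in (0, 1]")
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise ValueError("contamination_fraction must be in [0, 1]")
        if self.mean_fragment_length <= 0:
            raise ValueError("mean_fragment_length must be positive")
        if self.udg_mode not in ("none", "partial"):
            raise ValueError(f"unknown udg_mode {self.udg_mode!r}")


def random_reference(length: int = 100_000, gc: float = 0.41, seed: int | None = None) -> str:
    """Random reference sequence with the given GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _normalize_reference(reference) -> dict[str, str]:
    if isinstance(reference, str):
        return {"chr1": reference}
    return dict(reference)


def simulate_adna_fragments(
    config: DamageModelConfig,
    reference,
    n: int,
    error_rate: float = 0.0,
):
    """Simulate ``n`` aligned ancient-DNA fragments against ``reference``.

    ``reference`` is a chromosome-name -> sequence dict or a bare sequence
    (treated as a single chromosome "chr1").  Returns ``(reads, header,
    truth)``: SAM-convention :class:`pysam.AlignedSegment` records (half on
    each strand; damage is applied in original-molecule orientation), the
    matching :class:`pysam.AlignmentHeader`, and a truth dict with per-read
    damage events, contaminant status and origin.

    ``error_rate`` adds a uniform independent base error on top of the
    damage model (default 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ref = _normalize_reference(reference)
    if not ref or any(len(s) == 0 for s in ref.values()):
        raise ValueError("reference must be non-empty")
    rng = np.random.default_rng(config.seed)

    chroms = list(ref)
    lengths = np.array([len(ref[c]) for c in chroms], dtype=float)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(len(ref[c]))} for c in chroms],
        }
    )

    sigma = config.length_dispersion
    mu = np.log(config.mean_fragment_length) - sigma**2 / 2
    frag_lens = np.rint(rng.lognormal(mu, sigma, size=n)).astype(int)
    frag_lens = np.clip(frag_lens, 2, int(lengths.max()))
    chrom_idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    is_contaminant = rng.random(n) < config.contamination_fraction
    is_reverse = rng.random(n) < 0.5

    # per-position damage probabilities in molecule orientation
    span = 1 if config.udg_mode == "partial" else _MAX_DAMAGE_SPAN
    probs = config.terminal_ct_rate * config.decay ** np.arange(span)

    reads: list[pysam.AlignedSegment] = []
    truth_reads = []
    for k in range(n):
        chrom = chroms[chrom_idx[k]]
        chrom_len = len(ref[chrom])
        L = min(int(frag_lens[k]), chrom_len)
        start = int(rng.integers(0, chrom_len - L + 1))
        forward = ref[chrom][start : start + L].upper()
        molecule = (
            forward.translate(_COMPLEMENT)[::-1] if is_reverse[k] else forward
        )
        bases = list(molecule)
        hits5: list[int] = []
        hits3: list[int] = []
        if not is_contaminant[k]:
            m = min(span, L)
            u5 = rng.random(m)
            u3 = rng.random(m)
            for i in range(m):
                if bases[i] == "C" and u5[i] < probs[i]:
                    bases[i] = "T"
                    hits5.append(i + 1)
            for i in range(m):
                j = L - 1 - i
                if bases[j] == "G" and u3[i] < probs[i]:
                    bases[j] = "A"
                    hits3.append(i + 1)
        if error_rate > 0:
            err = np.flatnonzero(rng.random(L) < error_rate)
            for j in err:
                alt = [b for b in "ACGT" if b != bases[j]]
                bases[j] = alt[int(rng.integers(0, 3))]
        molecule = "".join(bases)

        a = pysam.AlignedSegment(header)
        a.query_name = f"frag{k:07d}"
        a.query_sequence = (
            molecule.translate(_COMPLEMENT)[::-1] if is_reverse[k] else molecule
        )
        a.flag = 16 if is_reverse[k] else 0
        a.reference_id = chrom_idx[k]
        a.reference_start = start
        a.mapping_quality = 60
        a.cigartuples = [(0, L)]
        reads.append(a)
        truth_reads.append(
            {
                "name": a.query_name,
                "chrom": chrom,
                "start": start,
                "length": L,
                "strand": "-" if is_reverse[k] else "+",
                "contaminant": bool(is_contaminant[k]),
                "damage_positions_5p": hits5,
                "damage_positions_3p": hits3,
            }
        )

    truth = {
        "config": asdict(config),
        "n": n,
        "error_rate": error_rate,
        "n_contaminant": int(is_contaminant.sum()),
        "reads": truth_reads,
    }
    return reads, header, truth
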