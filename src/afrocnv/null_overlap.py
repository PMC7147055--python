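"""Random-placement null for the shared CNVR length between two callers.

How much of caller A's total CNVR length would land inside caller B's regions
by chance alone?  Each replicate re-places every A-interval length uniformly
over all valid genome positions (a chromosome is chosen with probability
proportional to its number of valid start positions, ``length - L + 1``), and
the overlap statistic is the summed full length of placed intervals touching
any B-region by >= 1 bp — the same retained-set semantics used for the
observed value.  Placements are independent, so replicate A-intervals may
overlap one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    GenomeLayout,
    GenomicInterval,
    ValidationError,
    merge_intervals,
    _sorted_arrays,
    overlaps_any,
    total_overlap_length,
)


@dataclass
class OverlapNullResult:
    observed_bp: int
    mean_bp: float
    sd_bp: float
    n_sims: int
    seed: int

    @property
    def z(self) -> float:
        return (self.observed_bp - self.mean_bp) / self.sd_bp if self.sd_bp > 0 else float("nan")


def place_random(lengths, layout: GenomeLayout, rng: np.random.Generator) -> list[GenomicInterval]:
    """Place each length uniformly over all valid start positions genome-wide."""
    lengths = np.asarray(lengths, dtype=np.int64)
    chrom_lengths = np.asarray(layout.lengths, dtype=np.int64)
    max_len = int(chrom_lengths.max())
    too_long = lengths[lengths > max_len]
    if too_long.size:
        raise ValidationError(
            f"interval length {int(too_long[0])} exceeds every chromosome "
            f"(longest is {max_len} bp)"
        )
    out = []
    for L in lengths:
        valid = np.maximum(chrom_lengths - L + 1, 0)
        probs = valid / valid.sum()
        ci = int(rng.choice(len(chrom_lengths), p=probs))
        start = int(rng.integers(0, valid[ci]))
        out.append(GenomicInterval(layout.chromosomes[ci], start, start + int(L)))
    return out


def expected_overlap(
    lengths,
    set_b,
    layout: GenomeLayout,
    n_sims: int = 100,
    seed: int = 0,
    observed_bp: int | None = None,
) -> OverlapNullResult:
    """Monte-Carlo expectation of the shared length under random placement.

    ``lengths`` are the observed A-interval lengths; ``set_b`` the B regions.
    SD is the sample standard deviation across replicate totals (n-1).
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    b_merged = merge_intervals(set_b) if list(set_b) else []
    b_sorted = _sorted_arrays(b_merged) if b_merged else {}
    totals = np.empty(n_sims, dtype=np.int64)
    for i in range(n_sims):
        placed = place_random(lengths, layout, rng)
        if b_sorted:
            totals[i] = sum(iv.length for iv in placed if overlaps_any(iv, b_sorted))
        else:
            totals[i] = 0
    sd = float(totals.std(ddof=1)) if n_sims > 1 else 0.0
    return OverlapNullResult(
        observed_bp=int(observed_bp) if observed_bp is not None else 0,
        mean_bp=float(totals.mean()),
        sd_bp=sd,
        n_sims=n_sims,
        seed=seed,
    )


def observed_and_expected(set_a, set_b, layout, n_sims=100, seed=0) -> OverlapNullResult:
    """Convenience wrapper: observed retained-set length plus its null."""
    set_a = list(set_a)
    observed = total_overlap_length(set_a, set_b)
    return expected_overlap(
        [iv.length for iv in set_a], set_b, layout,
        n_sims=n_sims, seed=seed, observed_bp=observed,
    )
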