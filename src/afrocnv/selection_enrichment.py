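"""Enrichment of selection signatures in CNV regions.

Selection evidence arrives as per-SNP scores (-log10 p of |iHS|); a SNP is
"under selection" when its score exceeds a threshold (default 3, i.e.
p < 10^-3).  Three questions are answered:

* are selected SNPs over-represented inside CNVRs (plus 5 kb flanks)? —
  a 2x2 SNP-level chi-square;
* do CNVRs containing selected SNPs carry CNVs at higher frequency? —
  a 2x3 (selected x deletion/wild-type/insertion) chi-square over
  (CNVR, sample) states, with mean CNV frequency per row;
* do tagging and selection co-occur in the same CNVRs beyond independence? —
  the expected joint count n_tagged * n_selected / n_total and a 2x2
  chi-square on the CNVR cross-classification (Fisher's exact by flag).

Every (CNVR, sample) pair contributes exactly one count to the 2x3 table;
samples without a call at a CNVR are wild type by the reference convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    REFERENCE_COPY,
    ContingencyTable,
    GenomeLayout,
    GenomicInterval,
    ValidationError,
    merge_intervals,
    _sorted_arrays,
)
from .taghap import candidate_window


def flank_regions(cnvrs, layout: GenomeLayout, flank: int = 5000) -> list[GenomicInterval]:
    """Each CNVR extended by ``flank`` bp per side; NOT merged (membership is
    tested against the union, so overlap between flanked regions is harmless)."""
    return [candidate_window(r.region, layout, flank) for r in cnvrs]


def snp_region_table(scores, regions, threshold: float = 3.0) -> ContingencyTable:
    """2x2 counts of SNPs in/out of regions by score above/below threshold.

    Each SNP is counted exactly once; score positions are 1-based so a SNP at
    position p is inside [s, e) iff s < p <= e.
    """
    merged = merge_intervals(regions) if list(regions) else []
    sorted_set = _sorted_arrays(merged) if merged else {}
    counts = np.zeros((2, 2), dtype=np.int64)
    for s in scores:
        inside = False
        if s.chrom in sorted_set:
            starts, ends = sorted_set[s.chrom]
            i = int(np.searchsorted(starts, s.pos - 1, side="right")) - 1
            inside = i >= 0 and s.pos <= ends[i]
        sig = s.score > threshold
        counts[0 if inside else 1, 0 if sig else 1] += 1
    return ContingencyTable(
        counts,
        row_labels=["in_region", "out_region"],
        col_labels=[f"score>{threshold:g}", f"score<={threshold:g}"],
    )


def chi_square(table: ContingencyTable):
    """Pearson chi-square without continuity correction.

    Returns ``(statistic, df, p)``.  Zero marginal totals are refused.
    """
    counts = np.asarray(table.counts, dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValidationError("chi_square: zero row or column total")
    statistic, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(statistic), int(df), float(p)


def cnv_state_by_selection(cnvrs, selected_flags: dict, sample_ids):
    """2x3 table of per-(CNVR, sample) copy states by CNVR selection status.

    Columns are deletions (< 2 copies), wild type (= 2), insertions (> 2);
    rows are CNVRs with / without a selected SNP.  Also returns the mean CNV
    frequency per row, ``(deletions + insertions) / row_total`` in percent.
    """
    counts = np.zeros((2, 3), dtype=np.int64)
    for r in cnvrs:
        row = 0 if selected_flags.get(r.id, False) else 1
        n_del = n_ins = 0
        for s in r.carriers:
            c = r.copy_state[s]
            if c < REFERENCE_COPY:
                n_del += 1
            elif c > REFERENCE_COPY:
                n_ins += 1
        counts[row, 0] += n_del
        counts[row, 2] += n_ins
        counts[row, 1] += len(sample_ids) - n_del - n_ins
    table = ContingencyTable(
        counts,
        row_labels=["selected", "not_selected"],
        col_labels=["deletions", "wild_type", "insertions"],
    )
    freqs = row_cnv_frequency(table)
    return table, freqs


def row_cnv_frequency(table: ContingencyTable) -> dict[str, float]:
    """Mean CNV frequency per row: (deletions + insertions) / row total, %."""
    out = {}
    for label, row in zip(table.row_labels, np.asarray(table.counts, dtype=float)):
        total = row.sum()
        out[label] = 100.0 * (row[0] + row[2]) / total if total > 0 else float("nan")
    return out


def cnvr_selected_flags(cnvrs, scores, layout, flank: int = 5000, threshold: float = 3.0) -> dict[str, bool]:
    """Per-CNVR flag: does the CNVR (plus flanks) contain a SNP above threshold?"""
    hot = [(s.chrom, s.pos) for s in scores if s.score > threshold]
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {c for c, _ in hot}:
        by_chrom[chrom] = np.sort([p for c, p in hot if c == chrom])
    out = {}
    for r in cnvrs:
        w = candidate_window(r.region, layout, flank)
        pos = by_chrom.get(w.chrom)
        if pos is None:
            out[r.id] = False
            continue
        lo = int(np.searchsorted(pos, w.start, side="right"))  # pos > start (1-based in (s, e])
        hi = int(np.searchsorted(pos, w.end, side="right"))
        out[r.id] = hi > lo
    return out


def joint_expected(n_tagged: int, n_selected: int, n_total: int) -> float:
    """Expected count of CNVRs both tagged and selected under independence."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    if n_tagged > n_total or n_selected > n_total:
        raise ValidationError("margin exceeds total")
    return n_tagged * n_selected / n_total


def joint_excess_test(observed_both: int, n_tagged: int, n_selected: int, n_total: int,
                      method: str = "chi2"):
    """Test excess co-occurrence of tagging and selection across CNVRs.

    Builds the 2x2 CNVR cross-classification and applies a Pearson chi-square
    (default) or Fisher's exact test.  Returns ``(statistic_or_odds, p)``.
    """
    if observed_both > min(n_tagged, n_selected):
        raise ValidationError("observed joint count exceeds a margin")
    a = observed_both
    b = n_tagged - observed_both
    c = n_selected - observed_both
    d = n_total - n_tagged - n_selected + observed_both
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValidationError("degenerate margins in joint cross-classification")
    counts = np.array([[a, b], [c, d]], dtype=float)
    if method == "fisher":
        res = stats.fisher_exact(counts)
        return float(res[0]), float(res[1])
    statistic, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(statistic), float(p)
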