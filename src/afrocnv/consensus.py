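"""Two-caller consensus CNV-region construction.

A CNV region (CNVR) is the maximal union of overlapping (>= 1 bp) per-sample
CNV call intervals from one caller.  The consensus pipeline runs in a fixed
order: merge calls per caller, drop outlier samples (samples with grossly
inflated call counts, a hallmark of failed library prep or coverage
artefacts), re-merge, drop singleton regions (carried by < 2 samples), then
keep the fine-grained caller's regions that overlap the coarse caller's
regions by at least 1 bp.

Conventions the rest of the pipeline relies on:

* a sample with no call at a CNVR has the reference copy number 2;
* a sample with multiple overlapping calls inside one CNVR contributes the
  copy number of its longest call;
* region class is ``deletion_only`` if every non-reference copy state is < 2,
  ``insertion_only`` if every one is > 2, else ``mixed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    REFERENCE_COPY,
    CnvCall,
    GenomicInterval,
    ValidationError,
    merge_intervals,
    _sorted_arrays,
    overlaps_any,
)

logger = logging.getLogger("afrocnv")

DELETION_ONLY = "deletion_only"
INSERTION_ONLY = "insertion_only"
MIXED = "mixed"


@dataclass
class CnvRegion:
    """A merged CNV locus with per-sample copy states."""

    id: str
    region: GenomicInterval
    copy_state: dict[str, int]  # only non-reference carriers are stored
    fractional: dict[str, float] = field(default_factory=dict)

    @property
    def carrier_count(self) -> int:
        return sum(1 for c in self.copy_state.values() if c != REFERENCE_COPY)

    @property
    def carriers(self) -> list[str]:
        return [s for s, c in self.copy_state.items() if c != REFERENCE_COPY]

    @property
    def region_class(self) -> str:
        return classify_region(list(self.copy_state.values()))

    def copy_of(self, sample: str) -> int:
        """Copy number of ``sample``; absent call means reference (2)."""
        return self.copy_state.get(sample, REFERENCE_COPY)

    def fractional_of(self, sample: str) -> float:
        return self.fractional.get(sample, float(REFERENCE_COPY))

    def frequency(self, denominator: int) -> float:
        """Carrier frequency as a percentage of ``denominator`` samples."""
        if denominator <= 0:
            raise ValidationError("frequency denominator must be positive")
        return 100.0 * self.carrier_count / denominator


def classify_region(copy_states) -> str:
    """deletion_only / insertion_only / mixed from the non-reference copies."""
    non_ref = [c for c in copy_states if c != REFERENCE_COPY]
    if not non_ref:
        raise ValidationError("region with no non-reference copy state")
    if all(c < REFERENCE_COPY for c in non_ref):
        return DELETION_ONLY
    if all(c > REFERENCE_COPY for c in non_ref):
        return INSERTION_ONLY
    return MIXED


def merge_calls_to_cnvr(calls, id_prefix: str = "cnvr") -> list[CnvRegion]:
    """Merge one caller's calls into CNVRs (maximal >=1 bp overlap unions).

    Per sample, overlapping calls inside one CNVR contribute the longest
    call's copy number.
    """
    calls = list(calls)
    if not calls:
        return []
    regions = merge_intervals(c.region for c in calls)
    regions.sort(key=lambda iv: (iv.chrom, iv.start))
    # assign each call to its (unique, since regions are maximal) region
    sorted_set = _sorted_arrays(regions)
    index = {(iv.chrom, iv.start): i for i, iv in enumerate(regions)}
    assigned: list[list[CnvCall]] = [[] for _ in regions]
    for call in calls:
        starts, _ends = sorted_set[call.region.chrom]
        i = int(np.searchsorted(starts, call.region.end, side="left")) - 1
        assigned[index[(call.region.chrom, int(starts[i]))]].append(call)

    out = []
    for i, (iv, members) in enumerate(zip(regions, assigned)):
        copy_state: dict[str, int] = {}
        fractional: dict[str, float] = {}
        best_len: dict[str, int] = {}
        for c in members:
            if c.region.length > best_len.get(c.sample, -1):
                best_len[c.sample] = c.region.length
                copy_state[c.sample] = c.copy_number
                fractional[c.sample] = c.fractional_copy
        out.append(CnvRegion(f"{id_prefix}_{i:05d}", iv, copy_state, fractional))
    return out


def detect_outlier_samples(calls, k: float = 5.0):
    """Flag samples whose total call count exceeds median + k * MAD.

    Returns ``(outlier_ids, report)``.  The report carries group means and a
    Welch two-sample t-test p-value contrasting flagged against retained
    samples, mirroring the count-based validation of outliers.
    """
    counts = pd.Series([c.sample for c in calls]).value_counts()
    if len(counts) < 10:
        raise ValidationError(
            f"outlier detection needs >= 10 samples with calls, got {len(counts)}"
        )
    med = float(counts.median())
    mad = float((counts - med).abs().median())
    threshold = med + k * mad
    flagged = counts[counts > threshold]
    retained = counts[counts <= threshold]
    report = {
        "median": med,
        "mad": mad,
        "threshold": threshold,
        "n_flagged": int(len(flagged)),
        "mean_flagged": float(flagged.mean()) if len(flagged) else float("nan"),
        "mean_retained": float(retained.mean()),
    }
    if len(flagged) >= 2 and len(retained) >= 2:
        t, p = stats.ttest_ind(flagged.values, retained.values, equal_var=False)
        report["welch_t"] = float(t)
        report["welch_p"] = float(p)
    logger.info(
        "outlier detection: %d flagged (median=%.1f, MAD=%.1f, threshold=%.1f)",
        len(flagged), med, mad, threshold,
    )
    return sorted(flagged.index), report


def filter_singletons(cnvrs) -> list[CnvRegion]:
    """Keep only CNVRs carried by more than one sample."""
    return [r for r in cnvrs if r.carrier_count >= 2]


def consensus_intersect(cnvrs_a, cnvrs_b) -> list[CnvRegion]:
    """A-regions (boundaries from A) with >= 1 bp overlap in any B-region."""
    b_set = _sorted_arrays(merge_intervals(r.region for r in cnvrs_b)) if cnvrs_b else {}
    if not b_set:
        return []
    return [r for r in cnvrs_a if overlaps_any(r.region, b_set)]


def region_summary(cnvrs, n_samples: int) -> pd.DataFrame:
    """Descriptive statistics of a CNVR set (per-caller summary table).

    Lengths are per CNVR; total CNV count is the number of (region, carrier)
    pairs; ``mean_cnvr_per_individual`` is total CNV divided by sample count.
    """
    cnvrs = list(cnvrs)
    if not cnvrs:
        raise ValidationError("region_summary requires a non-empty CNVR set")
    lengths = np.array([r.region.length for r in cnvrs], dtype=float)
    carriers = np.array([r.carrier_count for r in cnvrs], dtype=float)
    total_cnv = float(carriers.sum())
    classes = pd.Series([r.region_class for r in cnvrs]).value_counts()
    rows = {
        "n_cnvr": len(cnvrs),
        "total_cnv": total_cnv,
        "mean_cnv_per_cnvr": total_cnv / len(cnvrs),
        "mean_cnvr_per_individual": total_cnv / n_samples,
        "mean_length_kb": lengths.mean() / 1e3,
        "sd_length_kb": lengths.std(ddof=1) / 1e3 if len(lengths) > 1 else 0.0,
        "median_length_kb": float(np.median(lengths)) / 1e3,
        "total_length_mb": lengths.sum() / 1e6,
        "n_deletion_only": int(classes.get(DELETION_ONLY, 0)),
        "n_insertion_only": int(classes.get(INSERTION_ONLY, 0)),
        "n_mixed": int(classes.get(MIXED, 0)),
    }
    return pd.DataFrame({"value": rows})


def run_consensus(calls_a, calls_b, n_samples: int, outlier_k: float = 5.0):
    """Full consensus chain: merge, outlier removal, re-merge, singleton
    filter, intersect.  Returns ``(consensus_cnvrs, outliers, report)``."""
    all_calls = list(calls_a) + list(calls_b)
    outliers, outlier_report = detect_outlier_samples(all_calls, k=outlier_k)
    drop = set(outliers)
    calls_a = [c for c in calls_a if c.sample not in drop]
    calls_b = [c for c in calls_b if c.sample not in drop]
    cnvrs_a = filter_singletons(merge_calls_to_cnvr(calls_a, id_prefix="a"))
    cnvrs_b = filter_singletons(merge_calls_to_cnvr(calls_b, id_prefix="b"))
    consensus = consensus_intersect(cnvrs_a, cnvrs_b)
    report = {
        "outliers": outliers,
        "outlier_report": outlier_report,
        "n_cnvr_a": len(cnvrs_a),
        "n_cnvr_b": len(cnvrs_b),
        "n_consensus": len(consensus),
        "n_retained_samples": n_samples - len(outliers),
    }
    logger.info(
        "consensus: %d A-regions, %d B-regions, %d consensus",
        len(cnvrs_a), len(cnvrs_b), len(consensus),
    )
    return consensus, outliers, report


def copy_matrix(cnvrs, sample_ids) -> pd.DataFrame:
    """CNVR x sample integer copy-number matrix (reference = 2)."""
    data = {
        r.id: [r.copy_of(s) for s in sample_ids] for r in cnvrs
    }
    return pd.DataFrame(data, index=sample_ids).T


def fractional_matrix(cnvrs, sample_ids) -> pd.DataFrame:
    """CNVR x sample fractional copy-number matrix (reference = 2.0)."""
    data = {
        r.id: [r.fractional_of(s) for s in sample_ids] for r in cnvrs
    }
    return pd.DataFrame(data, index=sample_ids).T
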