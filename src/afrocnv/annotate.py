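"""CNVR annotation: novelty, carrier frequency, sharing, density, features.

Novelty is strict: a CNVR is novel iff it overlaps no interval of the
known-region database by even a single bp.  Population sharing follows the
fixed-bin convention: the genome is cut into fixed-origin bins (default
5 kb; the last partial bin is kept) and a group occupies a bin iff any of its
CNVRs overlaps it.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    GenomeLayout,
    GenomicInterval,
    ValidationError,
    merge_intervals,
    _sorted_arrays,
    overlaps_any,
)


def flag_novel(cnvrs, known_regions) -> dict[str, bool]:
    """Per-CNVR novelty flag: True iff zero bp overlap with every known region."""
    known = list(known_regions)
    known_sorted = _sorted_arrays(merge_intervals(known)) if known else {}
    return {
        r.id: not (known_sorted and overlaps_any(r.region, known_sorted))
        for r in cnvrs
    }


def carrier_frequency(carrier_count: float, denominator: int) -> float:
    """Carrier frequency as a percentage; summaries round to whole percent."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    return 100.0 * carrier_count / denominator


def _bins_touched(iv: GenomicInterval, bin_size: int):
    return range(iv.start // bin_size, (iv.end - 1) // bin_size + 1)


def population_sharing(cnvrs_by_group, layout: GenomeLayout, bin_size: int = 5000):
    """Occupancy of fixed 5 kb genome bins per group, with Venn counts.

    ``cnvrs_by_group`` maps group label -> iterable of CnvRegion.  Returns
    ``(occupancy, venn)``: ``occupancy`` is a DataFrame indexed by
    (chrom, bin_index) with one boolean column per group; ``venn`` maps each
    non-empty group combination (a frozenset) to its exclusive bin count.
    """
    groups = list(cnvrs_by_group)
    if not groups:
        raise ValidationError("population_sharing needs at least one group")
    occupied: dict[tuple[str, int], set[str]] = {}
    for group, cnvrs in cnvrs_by_group.items():
        for r in cnvrs:
            for b in _bins_touched(r.region, bin_size):
                occupied.setdefault((r.region.chrom, b), set()).add(group)
    rows = sorted(occupied)
    occ = pd.DataFrame(
        {g: [g in occupied[k] for k in rows] for g in groups},
        index=pd.MultiIndex.from_tuples(rows, names=["chrom", "bin"]),
    )
    venn: dict[frozenset, int] = {}
    for n in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, n):
            venn[frozenset(combo)] = 0
    for k, present in occupied.items():
        venn[frozenset(present)] += 1
    return occ, venn


def density_by_chromosome(cnvrs, calls, layout: GenomeLayout) -> pd.DataFrame:
    """Per-chromosome CNVR/Mb and CNV/Mb densities."""
    rows = []
    cnvr_counts = pd.Series([r.region.chrom for r in cnvrs]).value_counts()
    call_counts = pd.Series([c.region.chrom for c in calls]).value_counts()
    for chrom, length in zip(layout.chromosomes, layout.lengths):
        if length <= 0:
            raise ValidationError(f"zero-length chromosome {chrom}")
        mb = length / 1e6
        rows.append(
            {
                "chrom": chrom,
                "cnvr_per_mb": cnvr_counts.get(chrom, 0) / mb,
                "cnv_per_mb": call_counts.get(chrom, 0) / mb,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")


def density_correlation(density_a: pd.Series, density_b: pd.Series) -> float:
    """Squared Pearson correlation between two per-chromosome density vectors."""
    a, b = density_a.align(density_b, join="inner")
    if len(a) < 3:
        raise ValidationError("need >= 3 chromosomes for a density correlation")
    r = stats.pearsonr(a.values, b.values).statistic
    return float(r * r)


def window_counts(calls, layout: GenomeLayout, window: int = 10_000_000) -> pd.Series:
    """CNV call counts in fixed-origin genomic windows (last partial kept)."""
    idx = []
    for chrom, length in zip(layout.chromosomes, layout.lengths):
        for w in range(math.ceil(length / window)):
            idx.append((chrom, w))
    counts = pd.Series(0, index=pd.MultiIndex.from_tuples(idx, names=["chrom", "window"]))
    for c in calls:
        mid = (c.region.start + c.region.end) // 2
        counts.loc[(c.region.chrom, mid // window)] += 1
    return counts


def window_correlation(calls_by_population, layout: GenomeLayout, window: int = 10_000_000) -> pd.DataFrame:
    """Population x population Pearson r of CNV counts in genomic windows.

    A population with a constant count vector yields NaN against every other
    (undefined correlation is reported as missing, never as zero).
    """
    pops = list(calls_by_population)
    if len(pops) < 2:
        raise ValidationError("window_correlation needs >= 2 populations")
    vectors = {
        p: window_counts(calls_by_population[p], layout, window).values.astype(float)
        for p in pops
    }
    mat = pd.DataFrame(np.eye(len(pops)), index=pops, columns=pops)
    for i, p in enumerate(pops):
        for q in pops[i + 1:]:
            a, b = vectors[p], vectors[q]
            if a.std() == 0 or b.std() == 0:
                r = float("nan")
            else:
                r = float(stats.pearsonr(a, b).statistic)
            mat.loc[p, q] = mat.loc[q, p] = r
    return mat


def intersect_features(cnvrs, features) -> dict[str, list[str]]:
    """Names of features (>= 1 bp overlap) per CNVR.

    ``features`` is ``[(GenomicInterval, name), ...]``.  Half-open adjacency
    (distance 0) does not count as overlap.
    """
    by_chrom: dict[str, list] = {}
    for iv, name in features:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, name))
    for lst in by_chrom.values():
        lst.sort()
    out: dict[str, list[str]] = {}
    for r in cnvrs:
        hits = []
        for s, e, name in by_chrom.get(r.region.chrom, []):
            if s >= r.region.end:
                break
            if e > r.region.start:
                hits.append(name)
        out[r.id] = hits
    return out


def gene_type_ratio(observed_counts: dict, background_counts: dict) -> pd.DataFrame:
    """Observed:expected ratio of feature-type counts against a background.

    ``expected_t = total_observed * background_t / total_background``.  Types
    missing from the background are flagged (``ratio`` NaN) rather than
    silently given a ratio.
    """
    total_obs = sum(observed_counts.values())
    total_bg = sum(background_counts.values())
    if total_bg <= 0:
        raise ValidationError("background counts must be positive")
    rows = []
    for t, obs in observed_counts.items():
        bg = background_counts.get(t)
        if bg is None or bg == 0:
            rows.append({"type": t, "observed": obs, "expected": float("nan"),
                         "ratio": float("nan"), "in_background": False})
            continue
        expected = total_obs * bg / total_bg
        rows.append({"type": t, "observed": obs, "expected": expected,
                     "ratio": obs / expected, "in_background": True})
    return pd.DataFrame(rows).set_index("type")
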