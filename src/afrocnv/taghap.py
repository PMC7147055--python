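"""SNP-haplotype tagging of copy number.

The premise: a CNV that arose once, on a single haplotype background, travels
with that background, so the per-sample dosage (0/1/2) of the right phased
allele combination predicts copy number.  A CNV that arose recurrently on
multiple backgrounds does not admit such a tag.

The engine, per CNVR:

1. take SNPs within a candidate window (the CNVR plus 5 kb flanks; an
   interior-excluded mode is available because SNP calls inside deletions are
   unreliable);
2. compute LD r-squared between SNP pairs no more than ``ld_window`` apart,
   on phased chromosomes (squared Pearson correlation of allele indicators —
   phase is known so no EM is needed);
3. single-linkage cluster SNPs joined by any edge with r2 above threshold,
   dropping SNPs with no partner;
4. every distinct per-chromosome allele string observed over a cluster's SNPs
   defines one haplotype; a sample's dosage is the count of its two
   chromosomes matching the string exactly;
5. drop uninformative haplotypes (all carriers share one copy number) — these
   are excluded from the Bonferroni denominator as well;
6. regress fractional copy number on dosage (OLS); the CNVR is tagged iff any
   haplotype reaches Bonferroni-adjusted p < alpha, where the correction is
   for the number of informative haplotypes tested at that CNVR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomeLayout, GenomicInterval, ValidationError


@dataclass
class HaplotypeDef:
    """A phased allele combination over an LD cluster of SNPs."""

    positions: tuple[int, ...]  # 0-based, ascending
    alleles: tuple[int, ...]
    dosage: np.ndarray  # per-sample 0/1/2, NaN where any cluster SNP missing
    chrom_count: int  # chromosomes carrying the exact string

    @property
    def label(self) -> str:
        return "".join(str(a) for a in self.alleles)


@dataclass
class TagAssociation:
    cnvr_id: str
    haplotype: HaplotypeDef
    slope: float
    r_squared: float
    p_slope: float
    n_tested_at_cnvr: int

    @property
    def p_adjusted(self) -> float:
        return min(1.0, self.p_slope * self.n_tested_at_cnvr)


def ld_r2(snp_a, snp_b) -> float:
    """Squared Pearson correlation of phased allele indicators.

    Chromosomes from samples missing at either SNP are excluded pairwise.
    Returns NaN if either SNP is monomorphic on the shared chromosomes or
    fewer than 4 chromosomes remain.
    """
    ok = ~(snp_a.missing | snp_b.missing)
    a = snp_a.genotypes[ok].reshape(-1).astype(float)
    b = snp_b.genotypes[ok].reshape(-1).astype(float)
    if a.size < 4 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def candidate_window(region: GenomicInterval, layout: GenomeLayout, flank: int = 5000) -> GenomicInterval:
    """CNVR extended by ``flank`` bp each side, clipped to the chromosome."""
    start = max(0, region.start - flank)
    end = min(layout.length_of(region.chrom), region.end + flank)
    return GenomicInterval(region.chrom, start, end)


def _single_linkage_clusters(n: int, edges) -> list[list[int]]:
    """Connected components over edge list; singleton components dropped."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [sorted(c) for c in comps.values() if len(c) >= 2]


def build_haplotypes(
    snps,
    r2_threshold: float = 0.8,
    ld_window: int = 50_000,
    min_chromosomes: int = 2,
) -> list[HaplotypeDef]:
    """Assemble haplotypes from SNPs in LD within a candidate window.

    ``snps`` are SnpRecords on one chromosome.  Strings observed on fewer
    than ``min_chromosomes`` chromosomes are discarded as a noise floor.
    """
    snps = sorted(snps, key=lambda s: s.pos)
    n = len(snps)
    if n < 2:
        return []
    # pairwise-complete r^2 matrix over per-chromosome allele indicators
    mat = np.stack([s.genotypes.reshape(-1) for s in snps]).astype(float)
    mask = np.stack([np.repeat(s.missing, 2) for s in snps])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.ma.corrcoef(np.ma.masked_array(mat, mask))
    r2_mat = np.asarray(np.ma.filled(r, np.nan)) ** 2
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if snps[j].pos - snps[i].pos > ld_window:
                break
            if np.isfinite(r2_mat[i, j]) and r2_mat[i, j] > r2_threshold:
                edges.append((i, j))
    haplotypes: list[HaplotypeDef] = []
    for cluster in _single_linkage_clusters(n, edges):
        members = [snps[i] for i in cluster]
        geno = np.stack([m.genotypes for m in members])       # (m, n_samples, 2)
        miss = np.stack([m.missing for m in members]).any(axis=0)  # (n_samples,)
        positions = tuple(m.pos for m in members)
        # distinct strings over complete chromosomes
        complete = geno[:, ~miss, :]                           # (m, n_ok, 2)
        strings = complete.transpose(1, 2, 0).reshape(-1, len(members))
        uniq, counts = np.unique(strings, axis=0, return_counts=True)
        for allele_row, count in zip(uniq, counts):
            if count < min_chromosomes:
                continue
            match = (geno == allele_row[:, None, None]).all(axis=0)  # (n_samples, 2)
            dosage = match.sum(axis=1).astype(float)
            dosage[miss] = np.nan
            haplotypes.append(
                HaplotypeDef(
                    positions=positions,
                    alleles=tuple(int(a) for a in allele_row),
                    dosage=dosage,
                    chrom_count=int(count),
                )
            )
    return haplotypes


def informative_filter(haplotype: HaplotypeDef, copy_numbers) -> bool:
    """True iff the haplotype is informative (keep), False to drop.

    Uninformative: every sample carrying the haplotype has the same copy
    number.  A haplotype with zero carriers violates the build contract.
    """
    copy_numbers = np.asarray(copy_numbers)
    carriers = (haplotype.dosage > 0) & ~np.isnan(haplotype.dosage)
    if not carriers.any():
        raise ValidationError("haplotype with no carriers reached informative_filter")
    return len(np.unique(copy_numbers[carriers])) > 1


def copy_regression(dosage, fractional_copy):
    """OLS of fractional copy number on haplotype dosage.

    Returns ``(slope, r_squared, p_slope)`` with the p-value from the
    two-sided t-test on the slope (n-2 df).  Pairs with missing dosage are
    excluded; constant dosage is refused.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(fractional_copy, dtype=float)
    ok = ~np.isnan(dosage) & ~np.isnan(y)
    x, y = dosage[ok], y[ok]
    if x.size < 3:
        raise ValidationError("copy_regression needs >= 3 complete samples")
    if np.all(x == x[0]):
        raise ValidationError("constant dosage (should be caught by informative_filter)")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue ** 2), float(fit.pvalue)


def tag_cnvrs(
    cnvrs,
    snps,
    sample_ids,
    layout: GenomeLayout,
    flank: int = 5000,
    r2_threshold: float = 0.8,
    ld_window: int = 50_000,
    alpha: float = 0.05,
    include_interior: bool = True,
):
    """Run the full tag chain per CNVR.

    Returns ``(associations, tagged)``: a DataFrame with one row per tested
    haplotype and a dict mapping CNVR id to its tagged flag (any haplotype
    with Bonferroni-adjusted p < alpha).
    """
    snps_by_chrom: dict[str, list] = {}
    for s in snps:
        snps_by_chrom.setdefault(s.chrom, []).append(s)
    for lst in snps_by_chrom.values():
        lst.sort(key=lambda s: s.pos)

    rows = []
    tagged: dict[str, bool] = {}
    for cnvr in cnvrs:
        window = candidate_window(cnvr.region, layout, flank)
        cands = [
            s
            for s in snps_by_chrom.get(cnvr.region.chrom, [])
            if window.start <= s.pos < window.end
            and (include_interior or not cnvr.region.start <= s.pos < cnvr.region.end)
        ]
        copies = np.array([cnvr.copy_of(s) for s in sample_ids])
        fractional = np.array([cnvr.fractional_of(s) for s in sample_ids])
        haps = build_haplotypes(cands, r2_threshold, ld_window)
        informative = [h for h in haps if informative_filter(h, copies)]
        m = len(informative)
        tagged[cnvr.id] = False
        for h in informative:
            try:
                slope, r2, p = copy_regression(h.dosage, fractional)
            except ValidationError:
                continue
            assoc = TagAssociation(cnvr.id, h, slope, r2, p, m)
            rows.append(
                {
                    "cnvr": cnvr.id,
                    "positions": ",".join(str(p1 + 1) for p1 in h.positions),
                    "alleles": h.label,
                    "slope": slope,
                    "r_squared": r2,
                    "p_slope": p,
                    "p_adjusted": assoc.p_adjusted,
                    "significant": assoc.p_adjusted < alpha,
                }
            )
            if assoc.p_adjusted < alpha:
                tagged[cnvr.id] = True
    columns = [
        "cnvr", "positions", "alleles", "slope",
        "r_squared", "p_slope", "p_adjusted", "significant",
    ]
    return pd.DataFrame(rows, columns=columns), tagged


def tag_cnvrs_by_population(cnvrs, snps, samples, layout, **kwargs):
    """Per-population re-runs of :func:`tag_cnvrs`.

    ``samples`` are Sample objects in genotype column order.  Returns a dict
    mapping population label to ``(associations, tagged)``; missing-genotype
    subsetting is by column mask so phase order is preserved.
    """
    from .core_io import SnpRecord

    out = {}
    pops = sorted({s.population for s in samples})
    for pop in pops:
        mask = np.array([s.population == pop for s in samples])
        ids = [s.id for s, m in zip(samples, mask) if m]
        sub_snps = [
            SnpRecord(
                chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                genotypes=r.genotypes[mask], missing=r.missing[mask], id=r.id,
            )
            for r in snps
        ]
        out[pop] = tag_cnvrs(cnvrs, sub_snps, ids, layout, **kwargs)
    return out
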