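"""Domain types, coordinate conventions, interval arithmetic and file IO.

Every genomic span in this package is 0-based half-open (``[start, end)``),
the BED convention.  VCF positions are 1-based and are converted exactly once,
on read: a SNP printed at VCF position ``p`` has internal position ``p - 1``
and therefore lies inside interval ``[s, e)`` iff ``s < p <= e``.

The types here are deliberately thin: a :class:`GenomeLayout` names the
chromosomes and their lengths, a :class:`CnvCall` is one caller's claim that
one sample deviates from the diploid reference of two copies over an
interval, and a :class:`SnpRecord` keeps phased biallelic genotypes as an
``(n_samples, 2)`` array of allele indices with an explicit missing mask.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__version__ = "0.1.0"

#: Diploid reference copy number for autosomes.
REFERENCE_COPY = 2


def output_header(seed=None) -> str:
    """One-line comment header recording tool version (and seed) for outputs."""
    extra = f" seed={seed}" if seed is not None else ""
    return f"# afrocnv {__version__}{extra}"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths in bp."""

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chromosomes) != len(set(self.chromosomes)):
            raise ValidationError("duplicate chromosome labels")
        if any(l <= 0 for l in self.lengths):
            raise ValidationError("chromosome lengths must be positive")
        if len(self.chromosomes) != len(self.lengths):
            raise ValidationError("chromosomes and lengths differ in count")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chromosomes.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp (half-open: touching is not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_vcf_pos(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based (VCF) position: s < p <= e."""
        return chrom == self.chrom and self.start < pos_1based <= self.end

    def validate_against(self, layout: GenomeLayout) -> None:
        if self.chrom not in layout:
            raise ValidationError(f"chromosome {self.chrom!r} not in layout")
        if self.end > layout.length_of(self.chrom):
            raise ValidationError(
                f"interval {self.chrom}:[{self.start},{self.end}) exceeds "
                f"chromosome length {layout.length_of(self.chrom)}"
            )


@dataclass(frozen=True)
class Sample:
    id: str
    population: str
    linguistic_group: str


@dataclass(frozen=True)
class CnvCall:
    """One caller's claim that ``sample`` has ``copy_number`` copies over ``region``."""

    sample: str
    region: GenomicInterval
    copy_number: int
    fractional_copy: float
    caller: str

    def __post_init__(self):
        if self.copy_number < 0 or self.fractional_copy < 0:
            raise ValidationError("copy numbers must be non-negative")


@dataclass
class SnpRecord:
    """A phased biallelic SNP.

    ``genotypes`` is an ``(n_samples, 2)`` int8 array of allele indices in
    chromosome-copy order (phase preserved); ``missing`` is an ``(n_samples,)``
    boolean mask.  ``pos`` is 0-based internally.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotypes: np.ndarray
    missing: np.ndarray
    id: str = "."

    @property
    def pos_1based(self) -> int:
        return self.pos + 1


@dataclass(frozen=True)
class SelectionScore:
    """Per-SNP selection evidence as -log10 p of |iHS|; 1-based position."""

    chrom: str
    pos: int
    score: float

    def __post_init__(self):
        if self.score < 0:
            raise ValidationError("selection score must be non-negative")


@dataclass
class ContingencyTable:
    """r x k non-negative counts with row/column labels."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("contingency counts must be 2-D")
        if (self.counts < 0).any():
            raise ValidationError("contingency counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Maximal unions of overlapping (>=1 bp) intervals, per chromosome.

    Half-open convention: abutting intervals ([0,10) and [10,20)) do NOT merge.
    """
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:  # strict: touching does not merge
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def _sorted_arrays(intervals):
    """Per-chromosome sorted (starts, ends) arrays for fast overlap queries."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list] = {}
    for iv in intervals:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in tmp.items():
        pairs.sort()
        arr = np.asarray(pairs, dtype=np.int64)
        by_chrom[chrom] = (arr[:, 0], arr[:, 1])
    return by_chrom


def overlaps_any(interval: GenomicInterval, sorted_set) -> bool:
    """Does ``interval`` share >=1 bp with any interval of a `_sorted_arrays` set?

    The query assumes the set's intervals are non-overlapping (merged), in which
    case the candidate is the last interval starting before the query end.
    """
    if interval.chrom not in sorted_set:
        return False
    starts, ends = sorted_set[interval.chrom]
    i = int(np.searchsorted(starts, interval.end, side="left")) - 1
    return i >= 0 and ends[i] > interval.start


def total_overlap_length(set_a, set_b) -> int:
    """Summed FULL length of A-intervals having >=1 bp overlap with any B-interval.

    This is the retained-set total length, not the intersection bp: an
    A-interval either counts with its whole length or not at all.
    """
    set_a = list(set_a)
    if not set_a:
        return 0
    b_sorted = _sorted_arrays(merge_intervals(set_b)) if list(set_b) else {}
    total = 0
    for iv in set_a:
        if b_sorted and overlaps_any(iv, b_sorted):
            total += iv.length
    return total


# ---------------------------------------------------------------------------
# BED / TSV readers and writers
# ---------------------------------------------------------------------------


def read_bed(path, layout: GenomeLayout | None = None):
    """Read a BED3+ file into ``[(GenomicInterval, [extra, ...]), ...]``.

    Lines beginning with ``#``, ``track`` or ``browser`` are skipped.  Extra
    columns beyond the first three are preserved verbatim as strings.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                iv = GenomicInterval(fields[0], start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            if layout is not None:
                iv.validate_against(layout)
            out.append((iv, fields[3:]))
    return out


def write_bed(path, records, seed=None) -> None:
    """Write ``[(GenomicInterval, [extra, ...]), ...]`` as BED3+."""
    with open(path, "w") as fh:
        fh.write(output_header(seed) + "\n")
        for iv, extra in records:
            cols = [iv.chrom, str(iv.start), str(iv.end)] + [str(x) for x in extra]
            fh.write("\t".join(cols) + "\n")


def read_layout_tsv(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "length"], dtype={"chrom": str})
    return GenomeLayout(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


def write_layout_tsv(path, layout: GenomeLayout, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(seed) + "\n")
        for c, l in zip(layout.chromosomes, layout.lengths):
            fh.write(f"{c}\t{l}\n")


def read_samples_tsv(path) -> list[Sample]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "population", "group"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: sample sheet needs columns {sorted(required)}")
    samples = [Sample(r["sample"], r["population"], r["group"]) for _, r in df.iterrows()]
    ids = [s.id for s in samples]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate sample ids in sample sheet")
    return samples


def write_samples_tsv(path, samples, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(seed) + "\n")
        fh.write("sample\tpopulation\tgroup\n")
        for s in samples:
            fh.write(f"{s.id}\t{s.population}\t{s.linguistic_group}\n")


def read_scores_tsv(path) -> list[SelectionScore]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if not {"chrom", "pos", "score"}.issubset(df.columns):
        raise ParseError(f"{path}: score file needs columns chrom, pos, score")
    return [
        SelectionScore(r.chrom, int(r.pos), float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_scores_tsv(path, scores, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(seed) + "\n")
        fh.write("chrom\tpos\tscore\n")
        for s in scores:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.score:.6g}\n")


def read_calls_bed(path, caller: str, layout: GenomeLayout | None = None) -> list[CnvCall]:
    """CNV calls as BED3 + sample, copy_number, fractional_copy columns."""
    calls = []
    for iv, extra in read_bed(path, layout):
        if len(extra) < 3:
            raise ParseError(f"{path}: call lines need sample, copy_number, fractional_copy")
        calls.append(
            CnvCall(
                sample=extra[0],
                region=iv,
                copy_number=int(extra[1]),
                fractional_copy=float(extra[2]),
                caller=caller,
            )
        )
    return calls


def write_calls_bed(path, calls, seed=None) -> None:
    write_bed(
        path,
        [
            (c.region, [c.sample, c.copy_number, f"{c.fractional_copy:.4f}"])
            for c in calls
        ],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_phased(path, allow_unphased: bool = False):
    """Read a phased biallelic VCF into ``(records, sample_ids)``.

    Multiallelic sites are rejected.  Unphased ``/`` genotypes raise unless
    ``allow_unphased`` (in which case the written order is trusted as phase).
    Missing genotypes are flagged, never imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    sample_ids = list(vcf.samples)
    records = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"multiallelic site at {var.CHROM}:{var.POS}; split or filter first"
            )
        gts = np.asarray(var.genotypes)  # (n, 3): a1, a2, phased flag
        missing = (gts[:, 0] < 0) | (gts[:, 1] < 0)
        if not allow_unphased and not (gts[~missing, 2] == 1).all():
            raise ValidationError(f"unphased genotype at {var.CHROM}:{var.POS}")
        geno = gts[:, :2].astype(np.int8)
        geno[missing] = 0
        records.append(
            SnpRecord(
                chrom=var.CHROM,
                pos=var.POS - 1,
                ref=var.REF,
                alt=var.ALT[0],
                genotypes=geno,
                missing=missing,
                id=var.ID or ".",
            )
        )
    return records, sample_ids


def write_vcf_phased(path, records, sample_ids, layout: GenomeLayout | None = None) -> None:
    """Write SnpRecords as a minimal phased VCF 4.2 (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=afrocnv-{__version__}\n")
        if layout is not None:
            for c, l in zip(layout.chromosomes, layout.lengths):
                fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for rec in records:
            gt_strs = []
            for i in range(len(sample_ids)):
                if rec.missing[i]:
                    gt_strs.append(".|.")
                else:
                    gt_strs.append(f"{rec.genotypes[i, 0]}|{rec.genotypes[i, 1]}")
            fh.write(
                f"{rec.chrom}\t{rec.pos_1based}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gt_strs) + "\n"
            )


# ---------------------------------------------------------------------------
# SNP QC
# ---------------------------------------------------------------------------


def hwe_chi_square(n_ref_hom: int, n_het: int, n_alt_hom: int):
    """1-df chi-square goodness of fit to Hardy-Weinberg proportions.

    Returns ``(statistic, p)``; a monomorphic locus returns ``(0.0, 1.0)``.
    """
    n = n_ref_hom + n_het + n_alt_hom
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_ref_hom + n_het) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_ref_hom, n_het, n_alt_hom], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


def snp_qc(
    records,
    sample_ids,
    max_locus_missing: float = 0.10,
    max_sample_missing: float = 0.10,
    hwe_alpha: float = 0.01,
):
    """Filter SNPs and samples: locus missingness, then sample missingness, then HWE.

    Returns ``(records, sample_ids, report)`` where ``report`` counts removals
    at each step.  An all-loci-removed outcome emits an explicit warning entry
    in the report rather than failing silently.
    """
    if not records:
        raise ValidationError("snp_qc requires at least one SNP record")
    n_samples = len(sample_ids)
    report = {
        "input_loci": len(records),
        "input_samples": n_samples,
    }

    # 1. loci by missingness
    kept = [r for r in records if r.missing.mean() <= max_locus_missing]
    report["loci_removed_missingness"] = len(records) - len(kept)

    # 2. samples by missingness over the surviving loci
    if kept:
        miss_mat = np.stack([r.missing for r in kept])  # loci x samples
        sample_miss = miss_mat.mean(axis=0)
        keep_mask = sample_miss <= max_sample_missing
    else:
        keep_mask = np.ones(n_samples, dtype=bool)
    report["samples_removed_missingness"] = int((~keep_mask).sum())
    kept_sample_ids = [s for s, k in zip(sample_ids, keep_mask) if k]

    # 3. HWE on genotype counts among retained samples
    final = []
    n_hwe_removed = 0
    for rec in kept:
        geno = rec.genotypes[keep_mask]
        miss = rec.missing[keep_mask]
        alt_count = geno.sum(axis=1)[~miss]
        counts = (
            int((alt_count == 0).sum()),
            int((alt_count == 1).sum()),
            int((alt_count == 2).sum()),
        )
        _, p = hwe_chi_square(*counts)
        if p < hwe_alpha:
            n_hwe_removed += 1
            continue
        final.append(
            SnpRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                genotypes=geno,
                missing=miss,
                id=rec.id,
            )
        )
    report["loci_removed_hwe"] = n_hwe_removed
    report["output_loci"] = len(final)
    report["output_samples"] = len(kept_sample_ids)
    if not final:
        report["warning"] = "all loci removed by QC"
    return final, kept_sample_ids, report
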