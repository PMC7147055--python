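"""Synthetic study generator: genome, samples, truth CNVRs, two caller call
sets, phased SNPs with LD structure, selection scores and a known-region
database.

The generator emulates the statistical structure the downstream stages
assume, not a biological mutation process:

* two callers of very different granularity — caller A reports each carried
  CNVR per sample with boundary jitter and continuous copy noise; caller B
  merges true CNVRs lying within a merge distance into single coarse, padded
  intervals (a read-depth caller missing breakpoints);
* population-stratified carrier frequencies via a two-level Balding-Nichols
  model (ancestral frequency -> linguistic-group frequency -> population
  frequency), so group divergence and within-group divergence are separate
  dials;
* phased SNPs from a founder-mosaic haplotype model: the genome is cut into
  LD blocks, each block carries a small founder pool, and every chromosome
  picks one founder per block.  Each SNP's derived allele is private to one
  founder, so SNPs sharing an owner are in perfect LD and every block
  decomposes into discoverable haplotype clusters;
* taggable CNVRs ride a designated founder haplotype at an anchor block:
  copy number is exactly 2 +/- the per-sample dosage of that founder, so the
  tag association is recoverable by construction.  Recurrent CNVRs draw copy
  states independently of any haplotype background;
* selection scores are -log10 p values, uniform on the p scale in the
  background (P(score > 3) = 1e-3) and enriched by a configurable ratio
  inside selected CNVRs (plus 5 kb flanks);
* a handful of outlier samples receive multiplied false-positive call rates,
  giving the consensus stage something to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import (
    CnvCall,
    GenomeLayout,
    GenomicInterval,
    Sample,
    SelectionScore,
    SnpRecord,
    ValidationError,
)

DELETION = "del"
INSERTION = "ins"


@dataclass
class CohortConfig:
    """All generator dials in one place; every default is a named key."""

    seed: int
    chromosomes: tuple[str, ...] = ("chr1", "chr2")
    chrom_length: int = 10_000_000
    populations: tuple[str, ...] = ("POP1", "POP2", "POP3")
    groups: tuple[str, ...] = ("GRP1", "GRP2", "GRP3")
    n_per_population: int = 20
    n_true_cnvrs: int = 300
    cnvr_length_median: float = 5000.0  # log-normal, matches fine-caller scale
    cnvr_length_sigma: float = 0.7
    min_cnvr_gap: int = 2000
    carrier_freq_alpha: float = 0.8  # Beta prior on ancestral carrier frequency
    carrier_freq_beta: float = 6.0  # mean ~0.12
    group_divergence: float = 0.05  # Balding-Nichols F, ancestral -> group
    population_divergence: float = 0.02  # group -> population
    deletion_fraction: float = 0.5
    fraction_taggable: float = 0.6
    fraction_selected: float = 0.05
    selection_enrichment_ratio: float = 3.0
    background_sig_rate: float = 1e-3  # P(score > 3) in the background
    selection_flank: int = 5000
    snp_spacing: int = 500
    snp_missing_rate: float = 0.002
    block_size: int = 25_000
    founders_per_block: int = 5
    tag_window_flank: int = 5000  # matches the tagging stage's candidate window
    caller_a_jitter_sd: float = 200.0
    caller_a_frac_noise_sd: float = 0.15  # rounding recovers truth >99%
    caller_b_merge_distance: int = 20_000
    caller_b_pad: int = 10_000
    fp_rate: float = 0.02  # false-positive calls per sample per true CNVR
    n_outlier_samples: int = 3
    # multiplier sized so outlier samples carry roughly five times the
    # retained-sample mean call count, the regime the consensus stage expects
    outlier_fp_multiplier: float = 40.0
    known_db_coverage: float = 0.97  # fraction of true CNVRs in the known DB
    n_known_decoys: int = 50

    def __post_init__(self):
        for key in (
            "deletion_fraction", "fraction_taggable", "fraction_selected",
            "known_db_coverage", "snp_missing_rate", "group_divergence",
            "population_divergence",
        ):
            v = getattr(self, key)
            if not 0 <= v <= 1:
                raise ValidationError(f"{key}={v} must be in [0, 1]")
        if len(self.populations) != len(self.groups):
            raise ValidationError("populations and groups must align")
        mean_len = self.cnvr_length_median * math.exp(self.cnvr_length_sigma ** 2 / 2)
        genome = self.chrom_length * len(self.chromosomes)
        if self.n_true_cnvrs * (mean_len + self.min_cnvr_gap) > 0.6 * genome:
            raise ValidationError(
                "infeasible config: CNVR count x mean length exceeds 60% of the genome"
            )

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chromosomes, (self.chrom_length,) * len(self.chromosomes))


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    cnvrs: list[GenomicInterval]
    cnvr_type: np.ndarray  # "del" / "ins"
    copies: np.ndarray  # n_cnvr x n_samples integer copies
    taggable: np.ndarray  # bool
    selected: np.ndarray  # bool
    tag_anchor: dict[int, tuple[str, int, int]]  # cnvr index -> (chrom, block, founder)
    tag_dosage: dict[int, np.ndarray]  # cnvr index -> per-sample dosage 0/1/2
    pop_carrier_freq: np.ndarray  # n_cnvr x n_pops configured carrier frequency

    def carriers_of(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.copies[i] != 2)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    layout: GenomeLayout
    samples: list[Sample]
    truth: TruthSet
    calls_a: list[CnvCall]
    calls_b: list[CnvCall]
    snps: list[SnpRecord]
    scores: list[SelectionScore]
    known_regions: list[GenomicInterval]
    outlier_samples: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def write(self, outdir, seed=None) -> None:
        """Write every artefact in the formats the readers consume."""
        import os
        from . import core_io

        os.makedirs(outdir, exist_ok=True)
        j = lambda name: os.path.join(outdir, name)
        seed = self.config.seed if seed is None else seed
        core_io.write_layout_tsv(j("genome.tsv"), self.layout, seed)
        core_io.write_samples_tsv(j("samples.tsv"), self.samples, seed)
        core_io.write_calls_bed(j("caller_a.bed"), self.calls_a, seed)
        core_io.write_calls_bed(j("caller_b.bed"), self.calls_b, seed)
        core_io.write_vcf_phased(j("snps.vcf"), self.snps, self.sample_ids, self.layout)
        core_io.write_scores_tsv(j("scores.tsv"), self.scores, seed)
        core_io.write_bed(j("known.bed"), [(iv, []) for iv in self.known_regions], seed)
        core_io.write_bed(
            j("truth.bed"),
            [
                (iv, [t, int(tg), int(sel)])
                for iv, t, tg, sel in zip(
                    self.truth.cnvrs, self.truth.cnvr_type,
                    self.truth.taggable, self.truth.selected,
                )
            ],
            seed,
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _dirichlet_bn(rng, base: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols style Dirichlet draw around ``base`` with divergence f."""
    if f <= 0:
        return base.copy()
    conc = np.maximum(base * (1 - f) / f, 1e-6)
    return rng.dirichlet(conc)


def _beta_bn(rng, p: float, f: float) -> float:
    if f <= 0:
        return p
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return float(rng.beta(max(a, 1e-6), max(b, 1e-6)))


def _place_cnvrs(rng, cfg: CohortConfig) -> list[GenomicInterval]:
    lengths = rng.lognormal(
        mean=math.log(cfg.cnvr_length_median), sigma=cfg.cnvr_length_sigma,
        size=cfg.n_true_cnvrs,
    ).astype(np.int64)
    lengths = np.maximum(lengths, 100)
    chrom_lengths = np.asarray(cfg.layout.lengths, dtype=np.int64)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chromosomes}
    out = []
    for L in lengths:
        for _attempt in range(1000):
            valid = np.maximum(chrom_lengths - L + 1, 0)
            probs = valid / valid.sum()
            ci = int(rng.choice(len(chrom_lengths), p=probs))
            start = int(rng.integers(0, valid[ci]))
            chrom = cfg.chromosomes[ci]
            s, e = start - cfg.min_cnvr_gap, start + int(L) + cfg.min_cnvr_gap
            if all(e2 <= s or e <= s2 for s2, e2 in placed[chrom]):
                placed[chrom].append((start, start + int(L)))
                out.append(GenomicInterval(chrom, start, start + int(L)))
                break
        else:
            raise ValidationError("could not place CNVRs without overlap; genome too full")
    out.sort()
    return out


def generate(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout
    n_pops = len(cfg.populations)
    n_samples = n_pops * cfg.n_per_population
    pop_of_sample = np.repeat(np.arange(n_pops), cfg.n_per_population)
    samples = [
        Sample(f"S{i:03d}", cfg.populations[pop_of_sample[i]], cfg.groups[pop_of_sample[i]])
        for i in range(n_samples)
    ]

    # --- true CNVRs, flags and per-population carrier frequencies ----------
    cnvrs = _place_cnvrs(rng, cfg)
    n_cnvr = len(cnvrs)
    cnvr_type = np.where(
        rng.random(n_cnvr) < cfg.deletion_fraction, DELETION, INSERTION
    )
    taggable = rng.random(n_cnvr) < cfg.fraction_taggable
    selected = rng.random(n_cnvr) < cfg.fraction_selected
    base_freq = rng.beta(cfg.carrier_freq_alpha, cfg.carrier_freq_beta, size=n_cnvr)
    base_freq = np.clip(base_freq, 0.01, 0.9)
    # two-level Balding-Nichols: ancestral -> group -> population
    unique_groups = list(dict.fromkeys(cfg.groups))
    group_of_pop = [unique_groups.index(g) for g in cfg.groups]
    pop_freq = np.empty((n_cnvr, n_pops))
    for i in range(n_cnvr):
        g_freq = [_beta_bn(rng, base_freq[i], cfg.group_divergence) for _ in unique_groups]
        for p in range(n_pops):
            pop_freq[i, p] = _beta_bn(rng, g_freq[group_of_pop[p]], cfg.population_divergence)
    pop_freq = np.clip(pop_freq, 0.0, 0.95)

    # --- founder-mosaic haplotype scaffold ---------------------------------
    K = cfg.founders_per_block
    blocks = {
        chrom: math.ceil(layout.length_of(chrom) / cfg.block_size)
        for chrom in cfg.chromosomes
    }
    # founder frequencies: ancestral Dirichlet -> group -> population
    founder_freq: dict[tuple[str, int], np.ndarray] = {}  # (chrom, block) -> (n_pops, K)
    for chrom in cfg.chromosomes:
        for b in range(blocks[chrom]):
            base = rng.dirichlet(np.ones(K))
            g_freqs = [_dirichlet_bn(rng, base, cfg.group_divergence) for _ in unique_groups]
            founder_freq[(chrom, b)] = np.stack(
                [
                    _dirichlet_bn(rng, g_freqs[group_of_pop[p]], cfg.population_divergence)
                    for p in range(n_pops)
                ]
            )

    # anchor blocks for taggable CNVRs: one designated founder per anchor,
    # its frequency pinned to the per-chromosome tag frequency h with
    # 1 - (1 - h)^2 = configured carrier frequency
    tag_anchor: dict[int, tuple[str, int, int]] = {}
    used_blocks: set[tuple[str, int]] = set()
    for i in range(n_cnvr):
        if not taggable[i]:
            continue
        # anchor = available block with maximal overlap with the tag window,
        # so the tagging stage sees enough of the anchor's SNPs
        w_start = max(0, cnvrs[i].start - cfg.tag_window_flank)
        w_end = min(layout.length_of(cnvrs[i].chrom), cnvrs[i].end + cfg.tag_window_flank)
        candidates = []
        for b in range(w_start // cfg.block_size, (w_end - 1) // cfg.block_size + 1):
            if (cnvrs[i].chrom, b) in used_blocks:
                continue
            ovl = min(w_end, (b + 1) * cfg.block_size) - max(w_start, b * cfg.block_size)
            candidates.append((ovl, b))
        if not candidates:
            taggable[i] = False  # anchor collision: demote to recurrent
            continue
        b = max(candidates)[1]
        key = (cnvrs[i].chrom, b)
        used_blocks.add(key)
        founder = int(rng.integers(0, K))
        tag_anchor[i] = (cnvrs[i].chrom, b, founder)
        freqs = founder_freq[key].copy()
        for p in range(n_pops):
            h = 1.0 - math.sqrt(1.0 - pop_freq[i, p])
            others = np.delete(freqs[p], founder)
            others = others / others.sum() * (1.0 - h) if others.sum() > 0 else others
            row = np.insert(others, founder, h)
            freqs[p] = row
        founder_freq[key] = freqs

    # chromosome founder assignment per block: (2 * n_samples,) founder ids
    n_chrom = 2 * n_samples
    pop_of_chrom = np.repeat(pop_of_sample, 2)
    founder_assign: dict[tuple[str, int], np.ndarray] = {}
    for key, freqs in sorted(founder_freq.items()):
        assign = np.empty(n_chrom, dtype=np.int8)
        for p in range(n_pops):
            mask = pop_of_chrom == p
            assign[mask] = rng.choice(K, size=int(mask.sum()), p=freqs[p])
        founder_assign[key] = assign

    # --- copy states --------------------------------------------------------
    copies = np.full((n_cnvr, n_samples), 2, dtype=np.int64)
    tag_dosage: dict[int, np.ndarray] = {}
    for i in range(n_cnvr):
        sign = -1 if cnvr_type[i] == DELETION else +1
        if taggable[i]:
            chrom, b, founder = tag_anchor[i]
            assign = founder_assign[(chrom, b)]
            dosage = (
                (assign[0::2] == founder).astype(int)
                + (assign[1::2] == founder).astype(int)
            )
            tag_dosage[i] = dosage.copy()
        else:
            dosage = np.empty(n_samples, dtype=int)
            for p in range(n_pops):
                mask = pop_of_sample == p
                h = 1.0 - math.sqrt(1.0 - pop_freq[i, p])
                dosage[mask] = rng.binomial(2, h, size=int(mask.sum()))
        copies[i] = np.clip(2 + sign * dosage, 0, None)

    # --- phased SNPs --------------------------------------------------------
    snps: list[SnpRecord] = []
    for chrom in cfg.chromosomes:
        length = layout.length_of(chrom)
        for k, pos in enumerate(range(cfg.snp_spacing, length, cfg.snp_spacing)):
            b = pos // cfg.block_size
            owner = k % K  # derived allele private to one founder
            assign = founder_assign[(chrom, b)]
            alleles = (assign == owner).astype(np.int8)
            geno = alleles.reshape(n_samples, 2)
            missing = rng.random(n_samples) < cfg.snp_missing_rate
            snps.append(
                SnpRecord(
                    chrom=chrom, pos=pos, ref="A", alt="G",
                    genotypes=geno.copy(), missing=missing,
                    id=f"{chrom}_{pos + 1}",
                )
            )

    # --- selection scores ---------------------------------------------------
    hot_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chromosomes}
    for i in range(n_cnvr):
        if selected[i]:
            iv = cnvrs[i]
            hot_spans[iv.chrom].append(
                (max(0, iv.start - cfg.selection_flank), iv.end + cfg.selection_flank)
            )
    # scores scaled so P(score > 3) = background_sig_rate exactly:
    # score = 3 * log(p) / log(background_sig_rate), p ~ Uniform(0, 1)
    scores: list[SelectionScore] = []
    extra_rate = (cfg.selection_enrichment_ratio - 1.0) * cfg.background_sig_rate
    scale = 3.0 / math.log(cfg.background_sig_rate)
    for rec in snps:
        p_val = max(float(rng.random()), 1e-300)
        in_hot = any(s <= rec.pos < e for s, e in hot_spans[rec.chrom])
        if in_hot and rng.random() < extra_rate:
            p_val = max(float(rng.random()) * cfg.background_sig_rate, 1e-300)
        scores.append(
            SelectionScore(rec.chrom, rec.pos_1based, scale * math.log(p_val))
        )

    # --- caller call sets ---------------------------------------------------
    outlier_idx = rng.choice(n_samples, size=cfg.n_outlier_samples, replace=False)
    outlier_ids = sorted(samples[i].id for i in outlier_idx)
    is_outlier = np.zeros(n_samples, dtype=bool)
    is_outlier[outlier_idx] = True

    def jitter_interval(iv: GenomicInterval) -> GenomicInterval:
        if cfg.caller_a_jitter_sd <= 0:
            return iv
        length = layout.length_of(iv.chrom)
        s = int(round(iv.start + rng.normal(0, cfg.caller_a_jitter_sd)))
        e = int(round(iv.end + rng.normal(0, cfg.caller_a_jitter_sd)))
        s = max(0, min(s, length - 2))
        e = max(s + 1, min(e, length))
        return GenomicInterval(iv.chrom, s, e)

    def noisy_copy(c: int):
        frac = max(0.0, c + float(rng.normal(0, cfg.caller_a_frac_noise_sd)))
        return int(round(frac)), frac

    def random_fp_call(sample_id: str, caller: str, scale: float = 1.0) -> CnvCall:
        L = max(100, int(rng.lognormal(math.log(cfg.cnvr_length_median * scale),
                                       cfg.cnvr_length_sigma)))
        chrom_lengths = np.asarray(layout.lengths, dtype=np.int64)
        L = min(L, int(chrom_lengths.max()) - 1)
        valid = np.maximum(chrom_lengths - L + 1, 0)
        ci = int(rng.choice(len(chrom_lengths), p=valid / valid.sum()))
        start = int(rng.integers(0, valid[ci]))
        c = int(rng.choice([1, 3]))
        cn, frac = noisy_copy(c)
        return CnvCall(sample_id, GenomicInterval(cfg.chromosomes[ci], start, start + L),
                       cn, frac, caller)

    calls_a: list[CnvCall] = []
    for i in range(n_cnvr):
        for s in np.flatnonzero(copies[i] != 2):
            cn, frac = noisy_copy(int(copies[i, s]))
            calls_a.append(
                CnvCall(samples[s].id, jitter_interval(cnvrs[i]), cn, frac, "callerA")
            )
    for s in range(n_samples):
        mult = cfg.outlier_fp_multiplier if is_outlier[s] else 1.0
        n_fp = rng.poisson(cfg.fp_rate * n_cnvr * mult)
        for _ in range(n_fp):
            calls_a.append(random_fp_call(samples[s].id, "callerA"))

    # caller B: coarse regions = true CNVRs merged within merge_distance, padded
    coarse: list[tuple[GenomicInterval, list[int]]] = []
    for i, iv in enumerate(cnvrs):
        if coarse and coarse[-1][0].chrom == iv.chrom and \
                iv.start - coarse[-1][0].end <= cfg.caller_b_merge_distance:
            prev, members = coarse.pop()
            coarse.append((GenomicInterval(iv.chrom, prev.start, max(prev.end, iv.end)),
                           members + [i]))
        else:
            coarse.append((iv, [i]))
    padded = []
    for iv, members in coarse:
        length = layout.length_of(iv.chrom)
        padded.append(
            (GenomicInterval(iv.chrom, max(0, iv.start - cfg.caller_b_pad),
                             min(length, iv.end + cfg.caller_b_pad)), members)
        )
    calls_b: list[CnvCall] = []
    for iv, members in padded:
        member_copies = copies[members]  # len(members) x n_samples
        for s in range(n_samples):
            carried = np.flatnonzero(member_copies[:, s] != 2)
            if carried.size == 0:
                continue
            # the member deviating most from reference dominates the read-depth signal
            j = carried[np.argmax(np.abs(member_copies[carried, s] - 2))]
            cn, frac = noisy_copy(int(member_copies[j, s]))
            calls_b.append(CnvCall(samples[s].id, iv, cn, frac, "callerB"))
    for s in range(n_samples):
        mult = cfg.outlier_fp_multiplier if is_outlier[s] else 1.0
        n_fp = rng.poisson(0.5 * cfg.fp_rate * len(padded) * mult)
        for _ in range(n_fp):
            calls_b.append(random_fp_call(samples[s].id, "callerB", scale=5.0))

    # --- known-region database ---------------------------------------------
    known: list[GenomicInterval] = []
    covered = rng.random(n_cnvr) < cfg.known_db_coverage
    for i in np.flatnonzero(covered):
        iv = cnvrs[i]
        length = layout.length_of(iv.chrom)
        pad_l, pad_r = rng.integers(0, 2000, size=2)
        known.append(GenomicInterval(iv.chrom, max(0, iv.start - int(pad_l)),
                                     min(length, iv.end + int(pad_r))))
    # decoys avoid true CNVRs so coverage stays at the configured rate
    true_spans = {c: [(iv.start, iv.end) for iv in cnvrs if iv.chrom == c]
                  for c in cfg.chromosomes}
    n_decoys = 0
    attempts = 0
    while n_decoys < cfg.n_known_decoys and attempts < 10000:
        attempts += 1
        fp = random_fp_call("_", "_")
        iv = fp.region
        if all(e <= iv.start or iv.end <= s for s, e in true_spans[iv.chrom]):
            known.append(iv)
            n_decoys += 1
    known.sort()

    truth = TruthSet(
        cnvrs=cnvrs, cnvr_type=cnvr_type, copies=copies,
        taggable=taggable, selected=selected,
        tag_anchor=tag_anchor, tag_dosage=tag_dosage, pop_carrier_freq=pop_freq,
    )
    return SyntheticCohort(
        config=cfg, layout=layout, samples=samples, truth=truth,
        calls_a=calls_a, calls_b=calls_b, snps=snps, scores=scores,
        known_regions=known, outlier_samples=outlier_ids,
    )
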