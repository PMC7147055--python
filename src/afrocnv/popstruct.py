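"""CNV-based population structure: encoding, PCA/IBS and Weir-Cockerham F_ST.

Multi-allelic CNV genotypes are recoded as ordered allele pairs so that
standard genotype machinery applies: copies 0 -> (1,1), 1 -> (1,2),
2 -> (2,2), 3 -> (2,3), 4 -> (3,3), up to (4,4) at six or more copies —
alleles are assumed to be as equally distributed between the two chromosomes
as possible.

F_ST is restricted to bi-allelic deletion loci (copies in {0, 1, 2}) because
only there is the phase of the encoding known: the deletion-allele dosage of
a sample with c copies is exactly 2 - c.  The per-locus estimator is
Weir & Cockerham's theta; the global value is the ratio of summed variance
components (not the mean of ratios).  Negative estimates are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .core_io import REFERENCE_COPY, ValidationError


def encode_alleles(copy_number: int) -> tuple[int, int]:
    """Ordered allele-pair encoding of an integer copy number (capped at 6)."""
    if copy_number < 0:
        raise ValidationError("copy number must be non-negative")
    c = min(copy_number, 6)
    return (1 + c // 2, 1 + (c + 1) // 2)


def decode_alleles(pair: tuple[int, int]) -> int:
    """Inverse of :func:`encode_alleles` (up to the 6-copy cap)."""
    a1, a2 = pair
    return (a1 - 1) + (a2 - 1)


def pca(copy_matrix: pd.DataFrame, k: int = 10):
    """PCA of the column-centered sample x locus copy-number matrix.

    ``copy_matrix`` is CNVR x sample (as written by the consensus stage);
    zero-variance loci are dropped.  Returns ``(coordinates, explained)``
    where ``coordinates`` is a sample x PC DataFrame.
    """
    mat = copy_matrix.T.to_numpy(dtype=float)  # samples x loci
    n_samples = mat.shape[0]
    if n_samples < 2:
        raise ValidationError("pca needs >= 2 samples")
    keep = mat.std(axis=0) > 0
    mat = mat[:, keep]
    max_k = min(n_samples - 1, mat.shape[1])
    if k > max_k:
        import warnings

        warnings.warn(f"pca: k={k} exceeds rank, reduced to {max_k}")
        k = max_k
    model = _SkPCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(mat - mat.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=copy_matrix.columns, columns=cols),
        model.explained_variance_ratio_,
    )


def ibs_distance_matrix(copy_matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - mean identity-by-state over the allele-pair encoding.

    IBS between two samples at a locus is the size of the multiset
    intersection of their allele pairs (0, 1 or 2) divided by 2.
    """
    samples = list(copy_matrix.columns)
    enc = np.array(
        [[encode_alleles(int(c)) for c in copy_matrix[s]] for s in samples]
    )  # samples x loci x 2
    # per-sample, per-locus allele-value counts (alleles are 1..4)
    counts = np.stack(
        [(enc == v).sum(axis=2) for v in (1, 2, 3, 4)], axis=2
    )  # samples x loci x 4
    n = len(samples)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.minimum(counts[i], counts[j]).sum(axis=1)
            ibs = shared.mean() / 2.0
            dist[i, j] = dist[j, i] = 1.0 - ibs
    return pd.DataFrame(dist, index=samples, columns=samples)


def ibs_mds(copy_matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of the IBS distance matrix."""
    d = ibs_distance_matrix(copy_matrix).to_numpy()
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0))
    return pd.DataFrame(
        coords, index=copy_matrix.columns, columns=[f"C{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST on bi-allelic deletions
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    per_locus: pd.Series  # theta per locus, NaN where undefined
    global_fst: float  # ratio of summed variance components
    z_scores: pd.Series
    high_flags: pd.Series  # theta > mean + k*SD

    @property
    def high_fst_loci(self) -> list[str]:
        return list(self.high_flags.index[self.high_flags])


def _wc_components(dosages: np.ndarray, pops: np.ndarray):
    """Weir-Cockerham (1984) variance components (a, b, c) for one bi-allelic
    locus from per-sample alternate-allele dosages (0/1/2) and population
    labels.  Returns NaN components for monomorphic loci."""
    labels = np.unique(pops)
    r = len(labels)
    if r < 2:
        raise ValidationError("F_ST needs >= 2 populations")
    n_i = np.array([(pops == l).sum() for l in labels], dtype=float)
    p_i = np.array([dosages[pops == l].mean() / 2.0 for l in labels])
    h_i = np.array([(dosages[pops == l] == 1).mean() for l in labels])
    n_bar = n_i.mean()
    n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
    p_bar = (n_i * p_i).sum() / n_i.sum()
    if p_bar == 0 or p_bar == 1:
        return float("nan"), float("nan"), float("nan")
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / n_i.sum()
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return float(a), float(b), float(c)


def fst_deletions(copy_matrix: pd.DataFrame, populations: dict[str, str],
                  high_k: float = 3.0) -> FstResult:
    """Weir-Cockerham F_ST across populations on bi-allelic deletion loci.

    ``copy_matrix`` is CNVR x sample integer copies; only loci whose states
    are a subset of {0, 1, 2} with at least one deletion allele are used
    (deletion-allele dosage = 2 - copies).  Per-locus estimates may be
    negative.  Monomorphic loci are excluded from the global sums.  The high
    flag marks loci above mean + ``high_k`` * SD of defined per-locus values.
    """
    samples = list(copy_matrix.columns)
    pops = np.array([populations[s] for s in samples])
    if len(np.unique(pops)) < 2:
        raise ValidationError("F_ST needs >= 2 populations")
    per_locus = {}
    sum_a = sum_abc = 0.0
    for locus, row in copy_matrix.iterrows():
        states = row.to_numpy(dtype=float)
        if not np.isin(states, [0, 1, 2]).all() or (states == 2).all():
            continue  # not a bi-allelic deletion locus
        dosage = 2.0 - states  # deletion-allele dosage
        a, b, c = _wc_components(dosage, pops)
        if np.isnan(a):
            per_locus[locus] = float("nan")
            continue
        per_locus[locus] = a / (a + b + c) if (a + b + c) != 0 else float("nan")
        sum_a += a
        sum_abc += a + b + c
    per_locus = pd.Series(per_locus, dtype=float)
    defined = per_locus.dropna()
    global_fst = sum_a / sum_abc if sum_abc != 0 else float("nan")
    mean, sd = defined.mean(), defined.std(ddof=1)
    z = (per_locus - mean) / sd if sd and sd > 0 else per_locus * float("nan")
    flags = per_locus > (mean + high_k * sd) if sd and sd > 0 else per_locus > mean
    return FstResult(per_locus, float(global_fst), z, flags.fillna(False))


def pairwise_fst(copy_matrix: pd.DataFrame, populations: dict[str, str]) -> pd.DataFrame:
    """Population x population global F_ST matrix (zero diagonal)."""
    labels = sorted(set(populations.values()))
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, p in enumerate(labels):
        for q in labels[i + 1:]:
            keep = [s for s in copy_matrix.columns if populations[s] in (p, q)]
            res = fst_deletions(copy_matrix[keep], {s: populations[s] for s in keep})
            mat.loc[p, q] = mat.loc[q, p] = res.global_fst
    return mat


def high_fst_cnvrs(per_locus: pd.Series, k: float = 3.0) -> list[str]:
    """Loci whose F_ST exceeds mean + k * SD of the defined per-locus values."""
    defined = per_locus.dropna()
    if len(defined) < 10:
        raise ValidationError("high_fst_cnvrs needs >= 10 defined per-locus values")
    mean, sd = defined.mean(), defined.std(ddof=1)
    return list(defined.index[defined > mean + k * sd])
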