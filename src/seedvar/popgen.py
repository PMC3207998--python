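"""Population differentiation (F_ST) analysis of seed-site SNPs.

F_ST measures the proportion of allele-frequency variance attributable to
population subdivision; elevated values flag loci under locally varying
(positive) selection.  The per-SNP estimator is the multi-population
Weir-Cockerham theta computed from per-group allele counts, with observed
heterozygosity taken under Hardy-Weinberg proportions (the inputs are allele
frequencies, not genotypes).  Negative estimates, which arise for weakly
differentiated loci, are clamped to 0.

Downstream, the F_ST distribution is Box-Cox transformed towards normality
(profile-likelihood grid search for lambda), the seed-site (MRESS/CNM) and
background 3'UTR SNP groups are compared with an unpaired two-sided t-test,
outliers are flagged at ``mean + k*SD`` on the transformed scale, and the two
groups are summarised over 10 equal-width F_ST bins with the background
down-sampled to the seed-site group's size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FstRecord",
    "GroupFrequencies",
    "fst_weir_cockerham",
    "boxcox_fit",
    "compare_groups",
    "fst_outliers",
    "bin_counts",
]


@dataclass(frozen=True)
class FstRecord:
    """Per-SNP F_ST with seed-site membership and its transformed value."""

    rsid: str
    fst: float
    is_mre: bool
    transformed: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst <= 1.0:
            raise ValueError(f"{self.rsid}: F_ST must lie in [0, 1], got {self.fst}")


@dataclass(frozen=True)
class GroupFrequencies:
    """Per-group allele data for one SNP: group -> (alt count, allele total)."""

    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        groups = [g for g, (_, n) in self.counts.items() if n > 0]
        if len(groups) < 2:
            raise ValueError("need at least 2 groups with nonzero sample size")
        for g, (c, n) in self.counts.items():
            if not 0 <= c <= n:
                raise ValueError(f"group {g}: count {c} outside [0, {n}]")


def _theta_components(p: np.ndarray, n_ind: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) for one bi-allelic locus.

    ``p`` are per-group allele frequencies, ``n_ind`` per-group diploid
    sample sizes.  Heterozygosity is taken as 2p(1-p) (HWE), appropriate for
    allele-frequency input.
    """
    r = p.size
    nbar = n_ind.mean()
    nc = (r * nbar - (n_ind**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_ind * p).sum() / (r * nbar)
    s2 = (n_ind * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    h = 2.0 * p * (1.0 - p)
    hbar = (n_ind * h).sum() / (r * nbar)
    if nbar <= 1:
        raise ValueError("Weir-Cockerham estimator needs more than one diploid per group")
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def fst_weir_cockerham(freqs: GroupFrequencies) -> float:
    """Multi-population Weir-Cockerham theta for one SNP (clamped to [0, 1]).

    Monomorphic loci (same fixed allele everywhere) return 0.
    """
    items = [(c, n) for c, n in freqs.counts.values() if n > 0]
    counts = np.array([c for c, _ in items], dtype=float)
    totals = np.array([n for _, n in items], dtype=float)
    p = counts / totals
    a, b, c = _theta_components(p, totals / 2.0)
    denom = a + b + c
    if denom == 0.0:  # monomorphic across all groups
        return 0.0
    return float(min(1.0, max(0.0, a / denom)))


def fst_many(
    alt_counts: np.ndarray, allele_totals: np.ndarray, clamp: bool = True
) -> np.ndarray:
    """Vectorised Weir-Cockerham theta over SNPs.

    ``alt_counts`` and ``allele_totals`` have shape (n_snps, n_groups).
    """
    alt_counts = np.asarray(alt_counts, dtype=float)
    totals = np.asarray(allele_totals, dtype=float)
    r = alt_counts.shape[1]
    n = totals / 2.0  # diploid individuals
    p = alt_counts / totals
    nbar = n.mean(axis=1)
    nc = (r * nbar - (n**2).sum(axis=1) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=1) / (r * nbar)
    s2 = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n * 2.0 * p * (1.0 - p)).sum(axis=1) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0.0, a / denom, 0.0)
    return np.clip(theta, 0.0, 1.0) if clamp else theta


def boxcox_fit(
    values: Sequence[float],
    eps: float = 1e-6,
    grid: tuple[float, float, float] = (-3.0, 3.0, 0.01),
) -> tuple[float, np.ndarray]:
    """Box-Cox transform with lambda chosen by profile-likelihood grid search.

    Zeros are offset by ``eps`` before transforming; negative values raise.
    The transform is ``(x**lam - 1)/lam`` (``ln x`` at lambda = 0).
    """
    x = np.asarray(values, dtype=float).copy()
    if np.any(x < 0):
        raise ValueError("Box-Cox requires non-negative input")
    x[x == 0.0] = eps
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, x) for l in lams])
    lam = float(lams[int(np.argmax(llf))])
    transformed = np.log(x) if lam == 0.0 else (x**lam - 1.0) / lam
    return lam, transformed


def compare_groups(mre: Sequence[float], other: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-sided Student's t-test between transformed F_ST groups."""
    mre = np.asarray(mre, dtype=float)
    other = np.asarray(other, dtype=float)
    if mre.size < 2 or other.size < 2:
        raise ValueError("each group needs at least 2 values")
    if mre.std(ddof=1) == 0.0 and other.std(ddof=1) == 0.0:
        raise ValueError("zero variance in both groups: t undefined")
    t, p = stats.ttest_ind(mre, other, equal_var=True)
    return float(t), float(p)


def fst_outliers(
    records: Sequence[FstRecord],
    k: float = 2.0,
    two_sided: bool = False,
    scale: str = "transformed",
) -> list[FstRecord]:
    """Records at least ``k`` SDs above the mean of the input distribution.

    The cut is applied on the transformed scale by default (``scale="raw"``
    uses the raw F_ST values); ``two_sided=True`` also returns the lower
    tail.  The mean/SD are those of the records passed in, so pass the
    seed-site (MRESS/CNM) subset to mirror an outlier scan within that group.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if scale == "transformed":
        vals = np.array([r.transformed for r in records], dtype=float)
        if np.isnan(vals).any():
            raise ValueError("records lack transformed values; run boxcox_fit first")
    elif scale == "raw":
        vals = np.array([r.fst for r in records], dtype=float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    mu, sd = vals.mean(), vals.std(ddof=1)
    hi = mu + k * sd
    lo = mu - k * sd
    out = []
    for rec, v in zip(records, vals):
        if v >= hi or (two_sided and v <= lo):
            out.append(rec)
    return out


def bin_counts(
    mre_values: Sequence[float],
    other_values: Sequence[float],
    nbins: int = 10,
    rng_seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin counts of both groups over equal-width F_ST bins on [0, 1].

    The comparison group is down-sampled without replacement to the
    seed-site group's size with a seeded RNG; the final bin is right-closed
    so an F_ST of exactly 1.0 lands in the last bin.  Returns
    (bin_edges, mre_counts, other_counts).
    """
    mre = np.asarray(mre_values, dtype=float)
    other = np.asarray(other_values, dtype=float)
    for arr in (mre, other):
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("F_ST values must lie in [0, 1]")
    if other.size > mre.size:
        rng = np.random.default_rng(rng_seed)
        other = rng.choice(other, size=mre.size, replace=False)
    edges = np.linspace(0.0, 1.0, nbins + 1)
    mre_counts, _ = np.histogram(mre, bins=edges)
    other_counts, _ = np.histogram(other, bins=edges)
    return edges, mre_counts, other_counts
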