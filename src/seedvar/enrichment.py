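"""GWAS-catalog intersection with seed-site SNP sets via LD proxies.

A GWAS tag SNP is rarely the functional variant; any SNP in strong LD
(r^2 > 0.8) with it is an equally good candidate.  This module expands each
catalog SNP into its LD proxy set, counts how many site-disrupting (MRESS)
and site-creating (CNM) SNPs those proxy sets capture, and calibrates that
observed overlap against a resampling null: repeatedly draw the same number
of SNPs from a MAF-filtered universe, expand LD identically, and count hits.
Significance is reported both as an upper normal-tail probability from the
replicate mean/SD and as an add-one empirical permutation p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import SnpRecord, fold_maf

__all__ = [
    "GwasCatalog",
    "LdTable",
    "OverlapSummary",
    "NullDistribution",
    "TailProbability",
    "expand_ld",
    "merge_catalog_loci",
    "observed_overlap",
    "resample_null",
    "tail_probability",
    "load_gwas_catalog",
    "load_ld_table",
]

GWAS_P_THRESHOLD = 1e-5


@dataclass(frozen=True)
class GwasCatalog:
    """Reported GWAS associations past the genome-wide suggestive threshold."""

    records: pd.DataFrame  # columns: rsid, trait, p_value, pmid
    p_threshold: float = GWAS_P_THRESHOLD

    @property
    def snps(self) -> list[str]:
        return list(pd.unique(self.records["rsid"]))

    def __len__(self) -> int:
        return len(self.records)


def load_gwas_catalog(path, p_threshold: float = GWAS_P_THRESHOLD) -> GwasCatalog:
    """Load a GWAS catalog TSV and apply the significance threshold."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "trait": str})
    df["p_value"] = df["p_value"].astype(float)
    df = df[df["p_value"] < p_threshold].reset_index(drop=True)
    return GwasCatalog(records=df, p_threshold=p_threshold)


class LdTable:
    """Symmetric pairwise r^2 lookup with per-SNP neighbour lists."""

    def __init__(self, pairs: Optional[Iterable[tuple[str, str, float]]] = None):
        self._neighbours: dict[str, dict[str, float]] = {}
        if pairs:
            for a, b, r2 in pairs:
                self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r^2 must be in [0, 1], got {r2}")
        if a == b:
            return
        self._neighbours.setdefault(a, {})[b] = r2
        self._neighbours.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._neighbours.get(a, {}).get(b, 0.0)

    def neighbours(self, snp: str, r2_min: float) -> set[str]:
        """SNPs with r^2 strictly above ``r2_min`` (self excluded)."""
        return {t for t, r in self._neighbours.get(snp, {}).items() if r > r2_min}

    def __len__(self) -> int:
        return sum(len(v) for v in self._neighbours.values()) // 2


def load_ld_table(path) -> LdTable:
    df = pd.read_csv(path, sep="\t", dtype={"snpA": str, "snpB": str})
    return LdTable(zip(df["snpA"], df["snpB"], df["r2"].astype(float)))


def expand_ld(snps: Iterable[str], ld: LdTable, r2_min: float = 0.8) -> dict[str, set[str]]:
    """Proxy set of each SNP: itself plus direct neighbours with r^2 > r2_min.

    No transitive closure: only pairs listed in the LD table count.  SNPs
    absent from the table map to themselves alone.
    """
    return {s: {s} | ld.neighbours(s, r2_min) for s in snps}


def merge_catalog_loci(catalog: GwasCatalog, ld: LdTable, r2_min: float = 0.8) -> int:
    """Number of distinct loci among catalog SNPs after merging LD-linked ones.

    Loci are connected components of the graph on catalog SNPs with edges
    where r^2 > r2_min.
    """
    import networkx as nx

    snps = catalog.snps
    g = nx.Graph()
    g.add_nodes_from(snps)
    snp_set = set(snps)
    for s in snps:
        for t in ld.neighbours(s, r2_min):
            if t in snp_set:
                g.add_edge(s, t)
    return nx.number_connected_components(g)


@dataclass(frozen=True)
class OverlapSummary:
    """Unique MRESS/CNM SNPs captured by the catalog's LD proxy sets."""

    n_mress: int
    n_cnm: int
    n_total: int
    hits: tuple = ()  # (catalog_snp, proxy_snp, label) provenance rows


def observed_overlap(
    catalog: GwasCatalog,
    ld: LdTable,
    mress_set: Iterable[str],
    cnm_set: Iterable[str],
    r2_min: float = 0.8,
) -> OverlapSummary:
    """Count unique MRESS and CNM SNPs found in any catalog proxy set.

    A catalog SNP that is itself a member counts (every proxy set contains
    the SNP itself).  A SNP in both input sets is counted once in each class
    count but once in the total.
    """
    mress_set, cnm_set = set(mress_set), set(cnm_set)
    proxies = expand_ld(catalog.snps, ld, r2_min)
    found_mress: set[str] = set()
    found_cnm: set[str] = set()
    hits = []
    for cat_snp, pset in proxies.items():
        for p in pset:
            if p in mress_set:
                found_mress.add(p)
                hits.append((cat_snp, p, "MRESS"))
            if p in cnm_set:
                found_cnm.add(p)
                hits.append((cat_snp, p, "CNM"))
    return OverlapSummary(
        n_mress=len(found_mress),
        n_cnm=len(found_cnm),
        n_total=len(found_mress | found_cnm),
        hits=tuple(hits),
    )


@dataclass(frozen=True)
class NullDistribution:
    """Resampled overlap counts with their summary statistics."""

    replicate_counts: np.ndarray
    mean: float
    sd: float
    reps: int
    n_draw: int
    rng_seed: Optional[int] = None

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, n_draw: int, rng_seed: Optional[int] = None
    ) -> "NullDistribution":
        counts = np.asarray(counts, dtype=int)
        return cls(
            replicate_counts=counts,
            mean=float(counts.mean()),
            sd=float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
            reps=int(counts.size),
            n_draw=n_draw,
            rng_seed=rng_seed,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mean": self.mean,
                    "sd": self.sd,
                    "reps": self.reps,
                    "n_draw": self.n_draw,
                    "rng_seed": self.rng_seed,
                    "replicate_counts": self.replicate_counts.tolist(),
                },
                fh,
            )


def resample_null(
    universe: Sequence[SnpRecord] | Sequence[str],
    mress_cnm_set: Iterable[str],
    ld: Optional[LdTable],
    n_draw: int,
    reps: int = 1000,
    maf_min: float = 0.01,
    rng_seed: Optional[int] = None,
    r2_min: float = 0.8,
) -> NullDistribution:
    """Resampling null for the catalog/seed-site overlap count.

    Each replicate draws ``n_draw`` SNPs without replacement from the
    MAF-filtered universe (folded MAF over the maximum across populations
    must reach ``maf_min``; SNPs without frequency data are excluded),
    expands each draw through the LD table, and counts the unique members of
    ``mress_cnm_set`` captured.  Deterministic given ``rng_seed``.

    The universe may also be given as plain rsid strings, in which case no
    MAF filter is applied (the caller has already filtered).
    """
    if universe and isinstance(universe[0], SnpRecord):
        eligible = [
            s.rsid
            for s in universe
            if (m := s.max_folded_maf()) is not None and m >= maf_min
        ]
    else:
        eligible = list(universe)
    if len(eligible) < n_draw:
        raise ValueError(
            f"universe too small after MAF filter: need {n_draw}, have {len(eligible)}"
        )
    target = set(mress_cnm_set)
    rng = np.random.default_rng(rng_seed)
    eligible_arr = np.asarray(eligible, dtype=object)
    counts = np.empty(reps, dtype=int)

    if ld is None or len(ld) == 0:
        member = np.fromiter((s in target for s in eligible), dtype=bool, count=len(eligible))
        for r in range(reps):
            idx = rng.choice(len(eligible), size=n_draw, replace=False)
            counts[r] = int(member[idx].sum())
    else:
        proxy_cache = {s: ({s} | ld.neighbours(s, r2_min)) & target for s in eligible}
        for r in range(reps):
            idx = rng.choice(len(eligible), size=n_draw, replace=False)
            found: set[str] = set()
            for s in eligible_arr[idx]:
                found |= proxy_cache[s]
            counts[r] = len(found)
    return NullDistribution.from_counts(counts, n_draw=n_draw, rng_seed=rng_seed)


@dataclass(frozen=True)
class TailProbability:
    z: Optional[float]
    p_normal: Optional[float]
    p_empirical: float


def tail_probability(null: NullDistribution, observed: int) -> TailProbability:
    """Upper-tail probability of the observed overlap under the null.

    ``p_normal`` is the standard-normal upper tail at
    z = (observed - mean)/sd (undefined when sd = 0); ``p_empirical`` is the
    add-one permutation estimate (1 + #{replicates >= observed})/(reps + 1).
    """
    p_emp = float(
        (1 + int((null.replicate_counts >= observed).sum())) / (null.reps + 1)
    )
    if null.sd == 0:
        return TailProbability(z=None, p_normal=None, p_empirical=p_emp)
    z = (observed - null.mean) / null.sd
    return TailProbability(z=z, p_normal=float(stats.norm.sf(z)), p_empirical=p_emp)
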