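"""Rarefaction, alpha diversity with rarefaction averaging and Monte-Carlo
pairwise tests, non-phylogenetic beta diversity, and consensus distance
matrices (element-wise averages over repeated rarefactions).

Conventions follow the QIIME-1 lineage of tools: Shannon is reported in
bits (log base 2), Equitability is Shannon / log2(observed OTUs), and Chao1
defaults to the bias-corrected form S + F1(F1-1) / (2(F2+1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal
from skbio.diversity import alpha as skbio_alpha

from .io import CountTable

ALPHA_METRICS = ("shannon", "simpson", "equitability", "chao1",
                 "observed_otus")
BETA_METRICS = ("bray_curtis", "jaccard_binary", "canberra", "euclidean")


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with provenance."""

    sample_ids: list[str]
    values: np.ndarray
    metric_name: str = ""
    provenance: str | tuple = "direct"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def filter(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)],
                              self.metric_name, self.provenance)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metric_name: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(s) for s in df.index], df.to_numpy(), metric_name)


@dataclass
class AlphaResult:
    """Per-sample alpha-diversity values averaged over rarefactions."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str
    depth: int
    n_rarefactions: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids,
                         name=self.metric)


# ---------------------------------------------------------------------------
# rarefaction


def rarefy(table: CountTable, depth: int,
           seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (reported via
    the returned table's sample set); draws are multivariate hypergeometric.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    depths = table.sample_depths()
    keep = depths >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rows = []
    for i in np.flatnonzero(keep):
        rows.append(rng.multivariate_hypergeometric(
            table.counts[i].astype(np.int64), depth))
    return CountTable([s for s, k in zip(table.sample_ids, keep) if k],
                      list(table.otu_ids),
                      np.asarray(rows, dtype=np.int64),
                      dict(table.taxonomy))


# ---------------------------------------------------------------------------
# alpha diversity


def _alpha_one(counts: np.ndarray, metric: str,
               chao1_bias_corrected: bool = True) -> float:
    counts = counts[counts > 0]
    if counts.size == 0:
        return np.nan
    if metric == "shannon":
        return float(skbio_alpha.shannon(counts, base=2))
    if metric == "simpson":
        p = counts / counts.sum()
        return float(1.0 - np.sum(p * p))
    if metric == "equitability":
        s = len(counts)
        if s == 1:
            return 1.0
        return float(skbio_alpha.shannon(counts, base=2) / np.log2(s))
    if metric == "chao1":
        return float(skbio_alpha.chao1(counts,
                                       bias_corrected=chao1_bias_corrected))
    if metric == "observed_otus":
        return float(len(counts))
    raise ValueError(f"unknown alpha metric {metric!r}")


def alpha_diversity(table: CountTable, metric: str, depth: int,
                    n_rarefactions: int = 10, seed: int = 0,
                    chao1_bias_corrected: bool = True) -> AlphaResult:
    """Compute ``metric`` on each of ``n_rarefactions`` rarefied tables and
    average per sample; samples below ``depth`` are dropped."""
    if metric not in ALPHA_METRICS:
        raise ValueError(f"metric must be one of {ALPHA_METRICS}")
    rng = np.random.default_rng(seed)
    acc: dict[str, list[float]] = {}
    for _ in range(n_rarefactions):
        rt = rarefy(table, depth, rng)
        for sid, row in zip(rt.sample_ids, rt.counts):
            acc.setdefault(sid, []).append(
                _alpha_one(row, metric, chao1_bias_corrected))
    sample_ids = [s for s in table.sample_ids if s in acc]
    values = np.array([np.mean(acc[s]) for s in sample_ids])
    return AlphaResult(sample_ids, values, metric, depth, n_rarefactions)


def _perm_t_test(x: np.ndarray, y: np.ndarray, n_perm: int,
                 rng: np.random.Generator,
                 exhaustive_limit: int = 100_000) -> tuple[float, float]:
    """Two-sided permutation test on the Welch t statistic.

    Enumerates all label assignments when their number is below
    ``exhaustive_limit`` (p is then an exact proportion), otherwise draws
    ``n_perm`` random shuffles and reports (1 + hits) / (1 + n_perm).
    """

    def tstat(a: np.ndarray, b: np.ndarray) -> float:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / len(a) + vb / len(b))
        if se == 0:
            return 0.0
        return (a.mean() - b.mean()) / se

    obs = abs(tstat(x, y))
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    from math import comb
    n_distinct = comb(n, nx)
    if n_distinct <= exhaustive_limit:
        hits = 0
        for idx in combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if abs(tstat(pooled[mask], pooled[~mask])) >= obs - 1e-12:
                hits += 1
        return obs, hits / n_distinct
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(tstat(perm[:nx], perm[nx:])) >= obs - 1e-12:
            hits += 1
    return obs, (1 + hits) / (1 + n_perm)


def compare_alpha(result: AlphaResult, groups: pd.Series | dict,
                  n_perm: int = 999, seed: int = 0) -> dict:
    """Pairwise Monte-Carlo permutation t tests between groups with
    Bonferroni correction, plus an omnibus Kruskal-Wallis test."""
    rng = np.random.default_rng(seed)
    groups = pd.Series(groups)
    labels = groups.loc[result.sample_ids]
    values = pd.Series(result.values, index=result.sample_ids)
    names = sorted(labels.dropna().unique())
    sets = {g: values[labels == g].to_numpy() for g in names}
    usable = [g for g in names if len(sets[g]) >= 2]
    pairs = list(combinations(names, 2))
    n_pairs = len(pairs)
    rows = []
    for ga, gb in pairs:
        if ga not in usable or gb not in usable:
            rows.append((ga, gb, np.nan, np.nan, np.nan, True))
            continue
        t, p = _perm_t_test(sets[ga], sets[gb], n_perm, rng)
        rows.append((ga, gb, t, p, min(1.0, p * n_pairs), False))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p",
                                           "p_bonf", "skipped"])
    if len(usable) >= 2:
        h, p_kw = kruskal(*[sets[g] for g in usable])
    else:
        h, p_kw = np.nan, np.nan
    return {"pairwise": pairwise, "kruskal_h": float(h),
            "kruskal_p": float(p_kw)}


# ---------------------------------------------------------------------------
# beta diversity

_SCIPY_METRIC = {"bray_curtis": "braycurtis", "canberra": "canberra",
                 "euclidean": "euclidean"}


def beta_diversity(table: CountTable, metric: str = "bray_curtis"
                   ) -> DistanceMatrix:
    """Pairwise dissimilarity on counts (Bray-Curtis, binary Jaccard,
    Canberra, or Euclidean)."""
    if metric not in BETA_METRICS:
        raise ValueError(f"metric must be one of {BETA_METRICS}")
    depths = table.sample_depths()
    if (depths == 0).any():
        bad = table.sample_ids[int(np.argmax(depths == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    x = table.counts.astype(float)
    if metric == "jaccard_binary":
        condensed = pdist(x > 0, metric="jaccard")
    else:
        condensed = pdist(x, metric=_SCIPY_METRIC[metric])
    return DistanceMatrix(list(table.sample_ids), squareform(condensed),
                          metric, "direct")


def consensus_distance(table: CountTable, metric: str, depth: int,
                       n_rarefactions: int = 100, seed: int = 0
                       ) -> DistanceMatrix:
    """Element-wise mean of beta-diversity matrices over repeated
    rarefactions; the unit of the distinguishability analyses."""
    if n_rarefactions < 1:
        raise ValueError("n_rarefactions must be >= 1")
    rng = np.random.default_rng(seed)
    acc = None
    ids = None
    for _ in range(n_rarefactions):
        dm = beta_diversity(rarefy(table, depth, rng), metric)
        if acc is None:
            acc, ids = dm.values.copy(), dm.sample_ids
        else:
            if dm.sample_ids != ids:
                raise RuntimeError("rarefactions retained different samples")
            acc += dm.values
    return DistanceMatrix(ids, acc / n_rarefactions, metric,
                          (depth, n_rarefactions, seed))
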