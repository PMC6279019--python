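"""Distinguishability tests on distance matrices: rank-based ANOSIM (with
exact enumeration for small designs), multi-term sequential-SS PERMANOVA,
an adapted BioEnv permutation test for single metadata variables, and the
subsampling / group-ablation ledgers used to probe imbalanced designs.

All permutation p-values use the (1 + hits) / (1 + permutations)
convention, so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sympy.utilities.iterables import multiset_permutations

from .diversity import DistanceMatrix


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    group_sizes: dict[str, int]
    exact: bool = False


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # per-term df, SS, R2, pseudo-F, p (+ residual/total)
    n_permutations: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class BioEnvResult:
    rho: float
    p: dict[str, float]
    n_shuffles: int


# ---------------------------------------------------------------------------
# ANOSIM


def _anosim_r(rank_sq: np.ndarray, within: np.ndarray) -> float:
    n = rank_sq.shape[0]
    iu = np.triu_indices(n, 1)
    w = within[iu]
    rw = rank_sq[iu][w].mean()
    rb = rank_sq[iu][~w].mean()
    return (rb - rw) / (n * (n - 1) / 4.0)


def anosim(dm: DistanceMatrix, groups: pd.Series | dict,
           n_perm: int = 9999, seed: int = 0,
           method: str = "auto") -> AnosimResult:
    """Analysis of similarities on a labelled distance matrix.

    R contrasts mean between-group vs within-group distance ranks (average
    ranks on ties), normalized by n(n-1)/4.  ``method='exact'`` enumerates
    every distinct assignment of the group labels (p is then the exact
    proportion of assignments with R >= observed, the observed assignment
    included); ``'permutation'`` shuffles labels ``n_perm`` times;
    ``'auto'`` picks exact when at most ``n_perm`` distinct assignments
    exist.
    """
    groups = pd.Series(groups)
    labels = groups.loc[dm.sample_ids].to_numpy()
    sizes = pd.Series(labels).value_counts().to_dict()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    for g, c in sizes.items():
        if c < 2:
            raise ValueError(
                f"group {g!r} has a single member; remove or merge it")
    condensed = dm.condensed()
    ranks = rankdata(condensed)  # average ranks on ties
    n = dm.n
    rank_sq = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    rank_sq[iu] = ranks
    rank_sq = rank_sq + rank_sq.T

    codes = pd.factorize(labels)[0]
    obs = _anosim_r(rank_sq, codes[:, None] == codes[None, :])

    from math import factorial
    counts = np.bincount(codes)
    n_distinct = factorial(n)
    for c in counts:
        n_distinct //= factorial(c)
    exact = method == "exact" or (method == "auto" and n_distinct <= n_perm)

    if exact:
        hits = total = 0
        for perm in multiset_permutations(list(codes)):
            pc = np.asarray(perm)
            r = _anosim_r(rank_sq, pc[:, None] == pc[None, :])
            if r >= obs - 1e-12:
                hits += 1
            total += 1
        return AnosimResult(obs, hits / total, total, sizes, exact=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        pc = rng.permutation(codes)
        if _anosim_r(rank_sq, pc[:, None] == pc[None, :]) >= obs - 1e-12:
            hits += 1
    return AnosimResult(obs, (1 + hits) / (1 + n_perm), n_perm, sizes)


def anosim_subsampled(dm: DistanceMatrix, groups: pd.Series | dict,
                      subset_size: int, n_reps: int = 10,
                      n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """ANOSIM after down-sampling every group larger than ``subset_size``
    to ``subset_size`` members, repeated ``n_reps`` times; R and p are
    averaged across repetitions (evens out extreme class imbalance)."""
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    groups = pd.Series(groups)
    labels = groups.loc[dm.sample_ids]
    if (labels.value_counts() >= 2).sum() < 2:
        raise ValueError("need at least two groups with >= 2 members")
    rng = np.random.default_rng(seed)
    rs, ps = [], []
    sizes: dict[str, int] = {}
    for _ in range(n_reps):
        keep: list[str] = []
        for g, members in labels.groupby(labels).groups.items():
            members = list(members)
            if len(members) > subset_size:
                members = list(rng.choice(members, subset_size,
                                          replace=False))
            keep += members
        keep = [s for s in dm.sample_ids if s in set(keep)]
        res = anosim(dm.filter(keep), groups, n_perm=n_perm,
                     seed=int(rng.integers(2**31)), method="permutation")
        rs.append(res.R)
        ps.append(res.p)
        sizes = res.group_sizes
    return AnosimResult(float(np.mean(rs)), float(np.mean(ps)),
                        n_perm, sizes)


def anosim_ablation(dm: DistanceMatrix, groups: pd.Series | dict,
                    n_perm: int = 999, seed: int = 0
                    ) -> dict[tuple[str, ...], AnosimResult]:
    """ANOSIM ledger over group subsets: all groups, each single group
    removed, and each pair of groups alone; keyed by the retained set."""
    groups = pd.Series(groups)
    labels = groups.loc[dm.sample_ids]
    names = sorted(labels.dropna().unique())
    if len(names) < 3:
        raise ValueError("ablation requires at least three groups")
    configs: list[tuple[str, ...]] = [tuple(names)]
    configs += [tuple(g for g in names if g != drop) for drop in names]
    configs += list(combinations(names, 2))
    rng = np.random.default_rng(seed)
    ledger: dict[tuple[str, ...], AnosimResult] = {}
    for retained in configs:
        if len(retained) < 2:
            continue
        keep = [s for s in dm.sample_ids if labels.loc[s] in retained]
        ledger[retained] = anosim(dm.filter(keep), groups, n_perm=n_perm,
                                  seed=int(rng.integers(2**31)),
                                  method="permutation")
    return ledger


def ablation_to_frame(ledger: dict[tuple[str, ...], AnosimResult]
                      ) -> pd.DataFrame:
    rows = [("+".join(k), v.R, v.p, v.n_permutations)
            for k, v in ledger.items()]
    return pd.DataFrame(rows, columns=["retained_groups", "R", "p",
                                       "n_perm"])


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(values: np.ndarray) -> np.ndarray:
    a = -0.5 * values ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design_blocks(metadata: pd.DataFrame, terms: list[str]
                   ) -> list[tuple[str, np.ndarray]]:
    blocks = []
    for t in terms:
        col = metadata[t]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)[:, None]
        else:
            x = pd.get_dummies(col.astype(str), drop_first=True,
                               dtype=float).to_numpy()
        blocks.append((t, x))
    return blocks


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def permanova(dm: DistanceMatrix | list[DistanceMatrix],
              metadata: pd.DataFrame,
              terms: list[str] = ("ethnicity", "age", "sex", "bmi"),
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (Type-I) sums of
    squares in the listed term order, e.g. ``dm ~ ethnicity + age + sex +
    bmi``.

    Partitions the Gower-centred inner-product matrix; significance by
    permutation of sample rows.  Passing a list of (rarefied) distance
    matrices averages each term's statistics across them.
    """
    terms = list(terms)
    if isinstance(dm, list):
        results = [permanova(d, metadata, terms, n_perm,
                             seed=seed + i) for i, d in enumerate(dm)]
        avg = sum(r.table for r in results) / len(results)
        avg["df"] = results[0].table["df"]
        return PermanovaResult(avg, n_perm)

    md = metadata.loc[dm.sample_ids]
    g = _gower_center(dm.values)
    n = dm.n
    blocks = _design_blocks(md, terms)
    x = np.ones((n, 1))
    hats, dfs = [], []
    prev_rank = 1
    for name, blk in blocks:
        x = np.hstack([x, blk])
        h, rank = _hat(x)
        hats.append(h)
        dfs.append(rank - prev_rank)
        prev_rank = rank
    ss_total = float(np.trace(g))
    h0 = np.ones((n, n)) / n

    def term_ss(gm: np.ndarray) -> np.ndarray:
        tr = [float(np.sum(h * gm)) for h in hats]
        prev = float(np.sum(h0 * gm))
        out = []
        for t in tr:
            out.append(t - prev)
            prev = t
        return np.asarray(out)

    ss = term_ss(g)
    df = np.asarray(dfs, dtype=float)
    df_resid = n - prev_rank
    ss_resid = ss_total - float(np.sum(hats[-1] * g))
    with np.errstate(invalid="ignore", divide="ignore"):
        f_obs = (ss / df) / (ss_resid / df_resid)
    f_obs[df == 0] = np.nan

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssp = term_ss(gp)
        ss_resid_p = ss_total - float(np.sum(hats[-1] * gp))
        with np.errstate(invalid="ignore", divide="ignore"):
            fp = (ssp / df) / (ss_resid_p / df_resid)
        hits += fp >= f_obs - 1e-12
    pvals = (1 + hits) / (1 + n_perm)
    pvals[df == 0] = np.nan

    rows = []
    for i, t in enumerate(terms):
        rows.append((t, df[i], ss[i], ss[i] / ss_total, f_obs[i], pvals[i]))
    rows.append(("Residual", float(df_resid), ss_resid,
                 ss_resid / ss_total, np.nan, np.nan))
    rows.append(("Total", float(n - 1), ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "R2",
                                        "pseudo_F", "p"]).set_index("term")
    return PermanovaResult(table, n_perm)


# ---------------------------------------------------------------------------
# adapted BioEnv


def _encode_metadata(md: pd.DataFrame, variables: list[str]
                     ) -> dict[str, np.ndarray]:
    """Continuous -> centred/scaled column; categorical -> full-rank dummy
    block (reference level dropped), one encoded block per variable."""
    blocks = {}
    for v in variables:
        col = md[v]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            sd = x.std()
            blocks[v] = ((x - x.mean()) / sd if sd > 0
                         else np.zeros_like(x))[:, None]
        else:
            blocks[v] = pd.get_dummies(col.astype(str), drop_first=True,
                                       dtype=float).to_numpy()
    return blocks


def _meta_rho(dm_cond: np.ndarray, blocks: dict[str, np.ndarray]) -> float:
    enc = np.hstack([blocks[v] for v in blocks])
    from scipy.spatial.distance import pdist
    meta_cond = pdist(enc, metric="euclidean")
    return float(spearmanr(dm_cond, meta_cond).statistic)


def bioenv_adapted(dm: DistanceMatrix, metadata: pd.DataFrame,
                   variables: list[str] = ("ethnicity", "age", "sex", "bmi"),
                   target: str | None = None, n_shuffles: int = 1000,
                   seed: int = 0) -> BioEnvResult:
    """Correlation between community distances and the Euclidean distances
    over all encoded metadata variables, with a per-variable permutation
    test: each variable's significance is how often the all-variable
    correlation under random shuffles of that variable alone reaches the
    observed correlation.

    With ``target`` given only that variable is tested; otherwise every
    variable in ``variables`` is tested in turn.
    """
    variables = list(variables)
    if target is not None and target not in variables:
        raise ValueError("target must be one of the supplied variables")
    md = metadata.loc[dm.sample_ids]
    blocks = _encode_metadata(md, variables)
    dm_cond = dm.condensed()
    rho = _meta_rho(dm_cond, blocks)
    rng = np.random.default_rng(seed)
    todo = [target] if target is not None else variables
    pvals: dict[str, float] = {}
    for v in todo:
        col = md[v]
        if col.nunique(dropna=False) <= 1:
            import warnings
            warnings.warn(f"variable {v!r} is constant; p set to 1")
            pvals[v] = 1.0
            continue
        hits = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(len(md))
            shuffled = dict(blocks)
            shuffled[v] = blocks[v][perm]
            if _meta_rho(dm_cond, shuffled) >= rho - 1e-12:
                hits += 1
        pvals[v] = (1 + hits) / (1 + n_shuffles)
    return BioEnvResult(rho, pvals, n_shuffles)
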