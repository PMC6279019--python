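"""Community-structure statistics: intra-/inter-group beta-diversity
contrasts (all-pairs and per-individual-mean modes, the latter guarding
against pseudo-inflation of pair counts), ubiquity sets with
abundance/ubiquity (A/U) stability statistics and robust regressions, and
family-level co-occurrence clustering with an enrichment test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import kruskal, mannwhitneyu, spearmanr

from .diversity import DistanceMatrix
from .io import CountTable, TaxonTable


@dataclass
class DistancePartition:
    """Distances binned into per-group intra sets and per-pair inter sets."""

    intra: dict[str, np.ndarray]
    inter: dict[tuple[str, str], np.ndarray]
    mode: str  # all_pairs | per_individual_mean
    flagged_groups: list[str] = field(default_factory=list)


@dataclass
class UbiquitySummary:
    per_otu: pd.DataFrame        # group, otu, ubiquity, mean_abundance, au
    ubiquitous: dict[str, set]   # group -> OTUs at/above the threshold
    regressions: pd.DataFrame    # group, slope, intercept, r2, p, p_adj
    mean_au: dict[str, float]
    threshold: float


@dataclass
class CooccurrenceClusters:
    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame    # Bonferroni mask (True = significant)
    clusters: list[set]
    cluster_associated: dict[str, set]
    enrichment: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# distance partitions


def partition_distances(dm: DistanceMatrix, groups: pd.Series | dict,
                        mode: str = "all_pairs") -> DistancePartition:
    """Organize pairwise distances by group membership.

    ``all_pairs`` bins every condensed distance into its (group, group)
    cell; ``per_individual_mean`` gives each individual one value per
    comparison group — its mean distance to that group (self excluded) —
    so large groups cannot pseudo-inflate the comparison.
    """
    if mode not in ("all_pairs", "per_individual_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = pd.Series(groups).loc[dm.sample_ids].to_numpy()
    names = sorted(pd.unique(labels))
    vals = dm.values
    n = dm.n
    intra: dict[str, list] = {g: [] for g in names}
    inter: dict[tuple[str, str], list] = {
        p: [] for p in combinations(names, 2)}
    if mode == "all_pairs":
        for i, j in combinations(range(n), 2):
            gi, gj = labels[i], labels[j]
            if gi == gj:
                intra[gi].append(vals[i, j])
            else:
                inter[tuple(sorted((gi, gj)))].append(vals[i, j])
    else:
        for i in range(n):
            for g in names:
                mask = labels == g
                mask = mask.copy()
                mask[i] = False
                if not mask.any():
                    continue
                m = vals[i, mask].mean()
                if labels[i] == g:
                    intra[g].append(m)
                else:
                    inter[tuple(sorted((labels[i], g)))].append(m)
    flagged = [g for g in names if len(intra[g]) == 0]
    return DistancePartition(
        {g: np.asarray(v) for g, v in intra.items()},
        {p: np.asarray(v) for p, v in inter.items()},
        mode, flagged)


def compare_distance_sets(partition: DistancePartition) -> dict:
    """Kruskal-Wallis across intra-group sets plus Bonferroni-corrected
    Mann-Whitney U tests for every intra-intra pair and every
    intra-vs-inter contrast."""
    intra = {g: v for g, v in partition.intra.items() if len(v) > 0}
    names = sorted(intra)
    if len(names) >= 2:
        h, p_kw = kruskal(*[intra[g] for g in names])
    else:
        h, p_kw = np.nan, np.nan
    contrasts = []
    for ga, gb in combinations(names, 2):
        contrasts.append((f"intra:{ga}", f"intra:{gb}",
                          intra[ga], intra[gb]))
    for g in names:
        pooled_inter = [v for pair, v in partition.inter.items()
                        if g in pair and len(v) > 0]
        if pooled_inter:
            contrasts.append((f"intra:{g}", f"inter:{g}",
                              intra[g], np.concatenate(pooled_inter)))
    n_tests = len(contrasts)
    rows = []
    for name_a, name_b, a, b in contrasts:
        if len(a) == 0 or len(b) == 0:
            continue
        u, p = mannwhitneyu(a, b, alternative="two-sided")
        rows.append((name_a, name_b, float(u), float(p),
                     min(1.0, p * n_tests),
                     float(np.mean(a)), float(np.mean(b))))
    pairwise = pd.DataFrame(rows, columns=["set_a", "set_b", "U", "p",
                                           "p_bonf", "mean_a", "mean_b"])
    return {"kruskal_h": float(h), "kruskal_p": float(p_kw),
            "pairwise": pairwise}


# ---------------------------------------------------------------------------
# ubiquity / stability


def ubiquitous_otus(table: CountTable, groups: pd.Series | dict,
                    threshold: float = 0.5,
                    abundance_over: str = "all") -> UbiquitySummary:
    """Per-group ubiquitous OTU sets and abundance/ubiquity stability.

    For each group: ubiquity = fraction of the group's samples with a
    nonzero count; mean relative abundance is over all samples of the
    group (zeros included) or over possessors only
    (``abundance_over='possessors'``); A/U = mean abundance / ubiquity.
    Within each group's qualifying set, log10(mean abundance) is regressed
    on ubiquity (OLS with HC3 robust standard errors), Bonferroni-adjusted
    over groups.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    labels = pd.Series(groups).loc[table.sample_ids]
    rel = table.relative_abundance()
    names = sorted(labels.dropna().unique())
    per_otu_rows = []
    ubiq_sets: dict[str, set] = {}
    reg_rows = []
    mean_au: dict[str, float] = {}
    for g in names:
        mask = (labels == g).to_numpy()
        sub = rel[mask]
        ubiq = (sub > 0).mean(axis=0)
        if abundance_over == "possessors":
            with np.errstate(invalid="ignore"):
                mean_ab = np.where((sub > 0).sum(axis=0) > 0,
                                   sub.sum(axis=0)
                                   / np.maximum((sub > 0).sum(axis=0), 1),
                                   0.0)
        else:
            mean_ab = sub.mean(axis=0)
        qualify = ubiq >= threshold
        ubiq_sets[g] = {o for o, q in zip(table.otu_ids, qualify) if q}
        with np.errstate(divide="ignore", invalid="ignore"):
            au = np.where(ubiq > 0, mean_ab / ubiq, np.nan)
        for j in np.flatnonzero(qualify):
            per_otu_rows.append((g, table.otu_ids[j], ubiq[j],
                                 mean_ab[j], au[j]))
        if qualify.sum() >= 3 and (mean_ab[qualify] > 0).all():
            y = np.log10(mean_ab[qualify])
            x = sm.add_constant(ubiq[qualify])
            fit = sm.OLS(y, x).fit(cov_type="HC3")
            slope_p = fit.pvalues[1] if len(fit.pvalues) > 1 else np.nan
            reg_rows.append((g, fit.params[1], fit.params[0],
                             fit.rsquared, slope_p,
                             min(1.0, slope_p * len(names))))
            mean_au[g] = float(np.nanmean(au[qualify]))
        elif qualify.sum() > 0:
            mean_au[g] = float(np.nanmean(au[qualify]))
    per_otu = pd.DataFrame(per_otu_rows, columns=["group", "otu", "ubiquity",
                                                  "mean_abundance", "au"])
    regressions = pd.DataFrame(reg_rows, columns=["group", "slope",
                                                  "intercept", "r2", "p",
                                                  "p_adj"])
    return UbiquitySummary(per_otu, ubiq_sets, regressions, mean_au,
                           threshold)


# ---------------------------------------------------------------------------
# co-occurrence


def cooccurrence_clusters(family_table: TaxonTable,
                          external_assoc_p: dict[str, float] | None = None,
                          alpha: float = 0.05,
                          rho_threshold: float = 0.3,
                          min_links: int = 3) -> CooccurrenceClusters:
    """Family co-occurrence structure from masked Spearman correlations.

    Pairwise Spearman correlations between family relative abundances are
    Bonferroni-corrected over all pairs and masked at ``alpha``; clusters
    are connected components (>= 2 members) of the graph of significant
    positive edges with rho >= ``rho_threshold``; non-member families with
    at least ``min_links`` significant positive links into one cluster are
    flagged cluster-associated.  When per-family external association
    p-values are supplied, cluster membership is tested for enrichment of
    small p-values by a one-sided Mann-Whitney U.
    """
    df = family_table.to_frame()
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"excluding constant families: {constant[:5]}...")
        df = df.drop(columns=constant)
    fams = list(df.columns)
    k = len(fams)
    if k < 3:
        raise ValueError("need at least three non-constant families")
    rho_mat, p_mat = spearmanr(df.to_numpy())
    rho = pd.DataFrame(rho_mat, index=fams, columns=fams)
    pv = pd.DataFrame(p_mat, index=fams, columns=fams)
    n_pairs = k * (k - 1) // 2
    p_corr = np.minimum(pv * n_pairs, 1.0)
    np.fill_diagonal(p_corr.values, 0.0)
    significant = p_corr <= alpha
    np.fill_diagonal(significant.values, False)

    g = nx.Graph()
    g.add_nodes_from(fams)
    for i, j in combinations(range(k), 2):
        if significant.iloc[i, j] and rho.iloc[i, j] >= rho_threshold:
            g.add_edge(fams[i], fams[j])
    clusters = [set(c) for c in nx.connected_components(g) if len(c) >= 2]
    clusters.sort(key=len, reverse=True)

    cluster_associated: dict[str, set] = {}
    for ci, cl in enumerate(clusters):
        for f in fams:
            if f in cl:
                continue
            links = sum(1 for m in cl
                        if significant.loc[f, m] and rho.loc[f, m] > 0)
            if links >= min_links:
                cluster_associated.setdefault(f, set()).add(ci)

    enrich_rows = []
    if external_assoc_p:
        for ci, cl in enumerate(clusters):
            members = [external_assoc_p[f] for f in cl
                       if f in external_assoc_p]
            others = [external_assoc_p[f] for f in fams
                      if f not in cl and f in external_assoc_p]
            if len(members) >= 2 and len(others) >= 2:
                u, p = mannwhitneyu(members, others, alternative="less")
                enrich_rows.append((ci, len(members), float(u), float(p)))
    enrichment = pd.DataFrame(enrich_rows, columns=["cluster", "n_members",
                                                    "U", "p"])
    return CooccurrenceClusters(rho, pv, significant, clusters,
                                cluster_associated, enrichment,
                                excluded=constant)
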