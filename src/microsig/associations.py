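"""Per-taxon group-association screening and its replication machinery:
Kruskal-Wallis screens with FDR/Bonferroni correction, cross-cohort
replication overlap with a label-permutation null, taxonomic-redundancy
collapsing, pairwise Mann-Whitney shifts with direction and replication
flags, covariate regressions on abundance and presence, presence-phenotype
tests, and imbalance-aware one-vs-all random-forest classifiers with
resampling applied strictly inside the cross-validation training folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, mannwhitneyu, rankdata, fisher_exact
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .diversity import rarefy
from .io import COLLAPSE_RANKS, CountTable, TaxonTable, collapse_taxonomy

# ---------------------------------------------------------------------------
# vectorized Kruskal-Wallis (tie-corrected), reusing ranks across label
# permutations: under a label shuffle the per-taxon ranks do not change,
# only the group sums do, which makes 1,000-permutation nulls cheap.


def _rank_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column average ranks and tie-correction factors."""
    n, t = values.shape
    ranks = np.empty_like(values, dtype=float)
    ties = np.empty(t)
    for j in range(t):
        ranks[:, j] = rankdata(values[:, j])
        _, counts = np.unique(values[:, j], return_counts=True)
        ties[j] = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return ranks, ties


def _kw_from_ranks(ranks: np.ndarray, ties: np.ndarray,
                   codes: np.ndarray, n_groups: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """H statistics and chi-square p-values for every column at once."""
    n = ranks.shape[0]
    indicator = np.zeros((n_groups, n))
    indicator[codes, np.arange(n)] = 1.0
    sizes = indicator.sum(axis=1)
    group_sums = indicator @ ranks  # (k, t)
    h = 12.0 / (n * (n + 1)) * (group_sums ** 2 / sizes[:, None]).sum(axis=0) \
        - 3.0 * (n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(ties > 0, h / ties, 0.0)
    h = np.maximum(h, 0.0)
    p = np.where(ties > 0, chi2.sf(h, n_groups - 1), 1.0)
    return h, p


def kruskal_wallis_exact(*samples: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with an exact permutation p-value.

    Enumerates every distinct assignment of the group labels to the pooled
    observations; p is the proportion of assignments (observed included)
    with H >= the observed H.  Intended for small designs where the
    chi-square approximation is unreliable.
    """
    from sympy.utilities.iterables import multiset_permutations
    samples = [np.asarray(s, dtype=float) for s in samples]
    values = np.concatenate(samples)[:, None]
    codes = np.concatenate([np.full(len(s), i)
                            for i, s in enumerate(samples)])
    ranks, ties = _rank_matrix(values)
    k = len(samples)
    h_obs = _kw_from_ranks(ranks, ties, codes, k)[0][0]
    hits = total = 0
    for perm in multiset_permutations(list(codes)):
        h = _kw_from_ranks(ranks, ties, np.asarray(perm), k)[0][0]
        if h >= h_obs - 1e-12:
            hits += 1
        total += 1
    return float(h_obs), hits / total


@dataclass
class ReplicationResult:
    significant_a: dict[str, set]
    significant_b: dict[str, set]
    overlap: dict[str, int]          # per rank + "combined"
    alpha: float
    fisher: pd.DataFrame | None = None
    null_overlap: dict[str, np.ndarray] | None = None
    permutation_p: dict[str, float] | None = None
    n_permutations: int = 0


# ---------------------------------------------------------------------------
# per-taxon screens


def kruskal_by_group(taxon_table: TaxonTable, groups: pd.Series | dict
                     ) -> pd.DataFrame:
    """Kruskal-Wallis group-association screen for every taxon of a
    collapsed table.

    Returns one record per taxon with tie-corrected H, p, BH-FDR and
    Bonferroni p (both corrected within this table, i.e. within the
    taxonomic rank), per-group mean relative abundance and ubiquity,
    sorted by p.  All-tied taxa get H = 0, p = 1 and a flag.
    """
    labels = pd.Series(groups).loc[taxon_table.sample_ids]
    codes, names = pd.factorize(labels)
    if len(names) < 2 or pd.Series(codes).value_counts().min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    values = taxon_table.values
    ranks, ties = _rank_matrix(values)
    h, p = _kw_from_ranks(ranks, ties, codes, len(names))
    rec = pd.DataFrame({
        "taxon": taxon_table.taxon_labels,
        "rank": taxon_table.rank,
        "H": h, "p": p,
        "degenerate": ties <= 0,
    })
    rec["p_fdr"] = multipletests(rec["p"], method="fdr_bh")[1]
    rec["p_bonf"] = np.minimum(rec["p"] * len(rec), 1.0)
    for gi, g in enumerate(names):
        mask = codes == gi
        rec[f"mean_{g}"] = values[mask].mean(axis=0)
        rec[f"ubiq_{g}"] = (values[mask] > 0).mean(axis=0)
    return rec.sort_values("p", kind="stable").reset_index(drop=True)


def associate_all_ranks(table: CountTable, groups: pd.Series | dict,
                        ranks: tuple[str, ...] = COLLAPSE_RANKS
                        ) -> pd.DataFrame:
    """Run the Kruskal-Wallis screen at every collapse rank (correction is
    applied within each rank) and concatenate the records."""
    parts = [kruskal_by_group(collapse_taxonomy(table, r), groups)
             for r in ranks]
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# replication


def _sig_sets(records: pd.DataFrame, alpha: float) -> dict[str, set]:
    out: dict[str, set] = {}
    for r, sub in records.groupby("rank"):
        out[r] = set(sub.loc[sub["p_fdr"] < alpha, "taxon"])
    return out


def replication_overlap(records_a: pd.DataFrame, records_b: pd.DataFrame,
                        alpha: float = 0.05) -> ReplicationResult:
    """Cross-cohort overlap of FDR-significant taxa with a Fisher test
    against a 5%-of-significant-taxa chance expectation (per cohort)."""
    sig_a = _sig_sets(records_a, alpha)
    sig_b = _sig_sets(records_b, alpha)
    ranks = sorted(set(sig_a) | set(sig_b))
    overlap = {r: len(sig_a.get(r, set()) & sig_b.get(r, set()))
               for r in ranks}
    overlap["combined"] = sum(overlap[r] for r in ranks)
    n_a = sum(len(s) for s in sig_a.values())
    n_b = sum(len(s) for s in sig_b.values())
    fisher = None
    if n_a > 0 and n_b > 0:
        rows = []
        for label, n_sig in (("cohort_a", n_a), ("cohort_b", n_b)):
            expected = int(round(0.05 * n_sig))
            tab = [[overlap["combined"], max(n_sig - overlap["combined"], 0)],
                   [expected, max(n_sig - expected, 0)]]
            odds, p = fisher_exact(tab, alternative="greater")
            rows.append((label, n_sig, overlap["combined"], expected,
                         odds, p))
        fisher = pd.DataFrame(rows, columns=["cohort", "n_significant",
                                             "observed_overlap",
                                             "expected_overlap",
                                             "odds_ratio", "p"])
    return ReplicationResult(sig_a, sig_b, overlap, alpha, fisher=fisher)


def overlap_permutation_null(tables_a: list[TaxonTable],
                             groups_a: pd.Series | dict,
                             tables_b: list[TaxonTable],
                             groups_b: pd.Series | dict,
                             alpha: float = 0.05, n_perm: int = 1000,
                             seed: int = 0) -> ReplicationResult:
    """Permutation null for the cross-cohort replication overlap.

    Group labels are shuffled independently in both cohorts, the full
    per-rank Kruskal-Wallis + BH-FDR screen is recomputed, and the overlap
    of significant identically-labelled taxa is recorded; the reported p
    is (1 + #{null overlap >= observed}) / (1 + n_perm), per rank and for
    all ranks combined.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def prep(tables, groups):
        prepped = []
        for t in tables:
            labels = pd.Series(groups).loc[t.sample_ids]
            codes, names = pd.factorize(labels)
            ranks, ties = _rank_matrix(t.values)
            prepped.append((t, codes, len(names), ranks, ties))
        return prepped

    prep_a, prep_b = prep(tables_a, groups_a), prep(tables_b, groups_b)

    def sig_sets(prepped, permute=False):
        out: dict[str, set] = {}
        for t, codes, k, ranks, ties in prepped:
            c = rng.permutation(codes) if permute else codes
            _, p = _kw_from_ranks(ranks, ties, c, k)
            p_fdr = multipletests(p, method="fdr_bh")[1]
            out.setdefault(t.rank, set()).update(
                np.asarray(t.taxon_labels)[p_fdr < alpha])
        return out

    obs_a, obs_b = sig_sets(prep_a), sig_sets(prep_b)
    rank_names = sorted(set(obs_a) | set(obs_b))
    observed = {r: len(obs_a.get(r, set()) & obs_b.get(r, set()))
                for r in rank_names}
    observed["combined"] = sum(observed[r] for r in rank_names)

    null = {r: np.zeros(n_perm, dtype=int) for r in observed}
    for i in range(n_perm):
        na, nb = sig_sets(prep_a, True), sig_sets(prep_b, True)
        tot = 0
        for r in rank_names:
            o = len(na.get(r, set()) & nb.get(r, set()))
            null[r][i] = o
            tot += o
        null["combined"][i] = tot
    pvals = {r: (1 + int((null[r] >= observed[r]).sum())) / (1 + n_perm)
             for r in observed}
    return ReplicationResult(obs_a, obs_b, observed, alpha,
                             null_overlap=null, permutation_p=pvals,
                             n_permutations=n_perm)


# ---------------------------------------------------------------------------
# taxonomic redundancy


def collapse_redundant_taxa(significant: pd.DataFrame,
                            family_table: TaxonTable,
                            genus_table: TaxonTable,
                            groups: pd.Series | dict,
                            threshold: float = 0.82) -> pd.DataFrame:
    """Collapse (family, child genus) pairs whose abundances are nearly
    identical into one representative taxon.

    A pair is redundant when the genus carries at least ``threshold`` of
    the family's mean relative abundance in every group; the classified
    genus is kept, or the family when the genus is unclassified.  Input is
    the table of significant records (columns ``rank`` and ``taxon``);
    output adds ``kept`` and ``redundant_with`` columns.
    """
    labels = pd.Series(groups)
    fam_df = family_table.to_frame()
    gen_df = genus_table.to_frame()
    fam_labels = labels.loc[family_table.sample_ids]
    names = sorted(fam_labels.dropna().unique())

    sig_fams = set(significant.loc[significant["rank"] == "family", "taxon"])
    sig_gens = set(significant.loc[significant["rank"] == "genus", "taxon"])
    kept = {t: True for t in set(significant["taxon"])}
    partner: dict[str, str] = {}
    for fam in sig_fams:
        children = [g for g in sig_gens if g.startswith(fam)]
        for gen in children:
            ratios = []
            for grp in names:
                mask = (fam_labels == grp).to_numpy()
                fmean = fam_df.loc[mask, fam].mean()
                gmean = gen_df.loc[mask, gen].mean() if gen in gen_df else 0.0
                ratios.append(gmean / fmean if fmean > 0 else 1.0)
            if min(ratios) >= threshold:
                unclassified = gen.rsplit(";", 1)[-1].strip() in (
                    "g__", "g__Unclassified")
                if unclassified:
                    kept[gen] = False
                    partner[gen] = fam
                else:
                    kept[fam] = False
                    partner[fam] = gen
    out = significant.copy()
    out["kept"] = out["taxon"].map(kept).fillna(True)
    out["redundant_with"] = out["taxon"].map(partner)
    return out


# ---------------------------------------------------------------------------
# pairwise shifts


def pairwise_group_shifts(taxon_table: TaxonTable, groups: pd.Series | dict,
                          taxa: list[str] | None = None,
                          cohort: str = "") -> pd.DataFrame:
    """Mann-Whitney U between every pair of groups for each taxon, on all
    individuals (zeros included), Bonferroni-corrected within each taxon
    for the number of pairs; reports both the abundance direction and the
    ubiquity direction of group_b relative to group_a."""
    labels = pd.Series(groups).loc[taxon_table.sample_ids]
    names = sorted(labels.dropna().unique())
    pairs = list(combinations(names, 2))
    df = taxon_table.to_frame()
    taxa = list(taxa) if taxa is not None else list(df.columns)
    rows = []
    for taxon in taxa:
        vals = df[taxon]
        for ga, gb in pairs:
            a = vals[(labels == ga).to_numpy()].to_numpy()
            b = vals[(labels == gb).to_numpy()].to_numpy()
            u, p = mannwhitneyu(a, b, alternative="two-sided")
            rows.append((cohort, taxon, ga, gb, float(u), float(p),
                         min(1.0, p * len(pairs)),
                         "up" if b.mean() > a.mean() else "down",
                         "up" if (b > 0).mean() > (a > 0).mean() else "down",
                         float(a.mean()), float(b.mean())))
    return pd.DataFrame(rows, columns=["cohort", "taxon", "group_a",
                                       "group_b", "U", "p", "p_bonf",
                                       "direction", "ubiquity_direction",
                                       "mean_a", "mean_b"])


def replicated_shifts(shifts_a: pd.DataFrame, shifts_b: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Merge two cohorts' pairwise shifts and flag contrasts that are
    Bonferroni-significant in both with the same abundance direction."""
    key = ["taxon", "group_a", "group_b"]
    merged = shifts_a.merge(shifts_b, on=key, suffixes=("_a", "_b"))
    merged["replicated"] = ((merged["p_bonf_a"] < alpha)
                            & (merged["p_bonf_b"] < alpha)
                            & (merged["direction_a"]
                               == merged["direction_b"]))
    return merged


# ---------------------------------------------------------------------------
# covariate regressions


def _ethnicity_dummies(labels: pd.Series) -> pd.DataFrame:
    """Full-rank dummy coding with the largest group as reference."""
    ref = labels.value_counts().idxmax()
    cats = [ref] + sorted(c for c in labels.unique() if c != ref)
    coded = pd.Categorical(labels, categories=cats)
    return pd.get_dummies(coded, drop_first=True, dtype=float,
                          prefix="eth")


def abundance_regressions(taxon_table: TaxonTable, metadata: pd.DataFrame,
                          group_col: str = "ethnicity",
                          min_possessors: int = 10) -> pd.DataFrame:
    """Per-taxon linear (log10 abundance among possessors) and logistic
    (presence/absence, all individuals) regressions on ethnicity, with and
    without age/sex/BMI covariates.

    Overall-model significance is the F test (linear) or likelihood-ratio
    test (logistic) against the intercept-only model; Bonferroni correction
    is over the number of taxa fitted per model family.
    """
    md = metadata.loc[taxon_table.sample_ids]
    eth = _ethnicity_dummies(md[group_col].astype(str))
    covs = pd.DataFrame({
        "age": pd.to_numeric(md["age"], errors="coerce"),
        "bmi": pd.to_numeric(md["bmi"], errors="coerce"),
        "sex_female": (md["sex"].astype(str) == "female").astype(float),
    }, index=md.index)
    eth.index = md.index
    df = taxon_table.to_frame()
    rows = []
    for taxon in df.columns:
        vals = df[taxon]
        present = vals > 0
        rec = {"taxon": taxon, "rank": taxon_table.rank,
               "n_possessors": int(present.sum())}
        # linear model among possessors
        if present.sum() >= min_possessors and present.sum() > eth.shape[1] + 4:
            y = np.log10(vals[present])
            x1 = sm.add_constant(eth.loc[present.to_numpy()])
            x2 = sm.add_constant(
                pd.concat([eth, covs], axis=1).loc[present.to_numpy()])
            try:
                f1 = sm.OLS(y.to_numpy(), x1.to_numpy()).fit()
                f2 = sm.OLS(y.to_numpy(), x2.to_numpy()).fit()
                rec.update(lin_p=f1.f_pvalue, lin_r2=f1.rsquared,
                           lin_cov_p=f2.f_pvalue, lin_cov_r2=f2.rsquared)
                names2 = list(x2.columns)
                for term, cols in (("ethnicity",
                                    [c for c in names2 if c.startswith("eth_")]),
                                   ("age", ["age"]), ("bmi", ["bmi"]),
                                   ("sex", ["sex_female"])):
                    contrast = np.zeros((len(cols), len(names2)))
                    for r_i, c in enumerate(cols):
                        contrast[r_i, names2.index(c)] = 1.0
                    rec[f"lin_p_{term}"] = float(f2.f_test(contrast).pvalue)
            except Exception:
                rec.update(lin_p=np.nan)
        else:
            rec.update(lin_p=np.nan, lin_skipped=True)
        # logistic model on all individuals
        if 0 < present.sum() < len(vals):
            x1 = sm.add_constant(eth)
            x2 = sm.add_constant(pd.concat([eth, covs], axis=1))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    l1 = sm.Logit(present.astype(float).to_numpy(),
                                  x1.to_numpy()).fit(disp=0, maxiter=200)
                    l2 = sm.Logit(present.astype(float).to_numpy(),
                                  x2.to_numpy()).fit(disp=0, maxiter=200)
                rec.update(log_p=l1.llr_pvalue, log_cov_p=l2.llr_pvalue)
            except Exception:
                rec.update(log_p=np.nan)
        else:
            rec.update(log_p=np.nan, log_skipped=True)
        rows.append(rec)
    out = pd.DataFrame(rows)
    for col in ("lin_p", "log_p", "lin_cov_p", "log_cov_p"):
        if col in out:
            n_fit = out[col].notna().sum()
            out[col + "_bonf"] = np.minimum(out[col] * max(n_fit, 1), 1.0)
    return out


def presence_phenotype_test(presence: pd.Series, phenotype: pd.Series,
                            groups: pd.Series | None = None) -> pd.DataFrame:
    """One-tailed Mann-Whitney U test that possessors of a taxon have
    LOWER phenotype values (e.g. BMI), overall and within each group."""
    presence = presence.astype(bool)
    idx = presence.index
    phen = pd.to_numeric(phenotype.loc[idx], errors="coerce")
    rows = []

    def one(name, mask):
        pos = phen[mask & presence].dropna()
        neg = phen[mask & ~presence].dropna()
        if len(pos) == 0 or len(neg) == 0:
            rows.append((name, len(pos), len(neg), np.nan, np.nan, True))
            return
        if phen[mask].nunique() <= 1:
            rows.append((name, len(pos), len(neg), np.nan, 1.0, True))
            return
        u, p = mannwhitneyu(pos, neg, alternative="less")
        rows.append((name, len(pos), len(neg), float(u), float(p), False))

    one("overall", pd.Series(True, index=idx))
    if groups is not None:
        labels = pd.Series(groups).loc[idx]
        for g in sorted(labels.dropna().unique()):
            one(g, labels == g)
    return pd.DataFrame(rows, columns=["subset", "n_with", "n_without",
                                       "U", "p", "skipped"])


# ---------------------------------------------------------------------------
# one-vs-all random forests


@dataclass
class RFReport:
    target: str
    sampling: str
    auc: float
    fold_aucs: list[float]
    mean_roc: tuple[np.ndarray, np.ndarray]  # (fpr grid, mean tpr)
    sensitivity: float
    specificity: float
    precision: float
    oob_error: float
    importances: pd.Series  # percent of max


def prepare_genus_features(table: CountTable, groups: pd.Series | dict,
                           depth: int = 10000, seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix for the classifiers: rarefy to ``depth``, collapse
    to genus (deepest classified rank as fallback), drop taxa present in
    fewer than floor(rarest-group-size / 2) samples, close to relative
    abundance, arcsin-sqrt transform."""
    rt = rarefy(table, depth, seed)
    genus = collapse_taxonomy(rt, "genus")
    labels = pd.Series(groups).loc[genus.sample_ids]
    min_group = int(labels.value_counts().min())
    min_present = min_group // 2
    present_counts = (genus.values > 0).sum(axis=0)
    keep = present_counts >= min_present
    rel = genus.values[:, keep]
    rel = rel / np.maximum(rel.sum(axis=1, keepdims=True), 1e-12)
    x = np.arcsin(np.sqrt(np.clip(rel, 0.0, 1.0)))
    cols = [t for t, k in zip(genus.taxon_labels, keep) if k]
    return pd.DataFrame(x, index=genus.sample_ids, columns=cols), labels


def smote_resample(x: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator, k: int = 5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE with majority downsampling: the minority class is doubled via
    k-nearest-neighbour interpolation and the majority class is randomly
    downsampled to the new minority size (balanced output)."""
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[np.argmin(counts)]
    x_min = x[y == minority]
    n_min = len(x_min)
    k_eff = min(k, n_min - 1)
    if k_eff < 1:
        # too few minority points to interpolate; fall back to duplication
        synth = x_min[rng.integers(0, n_min, size=n_min)]
    else:
        d = np.linalg.norm(x_min[:, None, :] - x_min[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1)[:, :k_eff]
        base_idx = rng.integers(0, n_min, size=n_min)
        nb_idx = nn[base_idx, rng.integers(0, k_eff, size=n_min)]
        u = rng.random(n_min)[:, None]
        synth = x_min[base_idx] + u * (x_min[nb_idx] - x_min[base_idx])
    new_min_x = np.vstack([x_min, synth])
    target = len(new_min_x)
    x_maj = x[y != minority]
    if len(x_maj) > target:
        sel = rng.choice(len(x_maj), target, replace=False)
        x_maj = x_maj[sel]
    xr = np.vstack([new_min_x, x_maj])
    yr = np.concatenate([np.full(len(new_min_x), minority),
                         np.full(len(x_maj),
                                 classes[classes != minority][0])])
    return xr, yr


def downsample_resample(x: np.ndarray, y: np.ndarray,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Randomly downsample the majority class to the minority size."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, n_min, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    return x[keep], y[keep]


def rf_one_vs_all(features: pd.DataFrame, labels: pd.Series,
                  target: str, sampling: str = "smote", k: int = 10,
                  seed: int = 0, n_estimators: int = 200) -> RFReport:
    """One-vs-all random-forest classification of ``target`` vs the rest.

    Stratified k-fold cross-validation with resampling (SMOTE or
    downsampling) applied ONLY to the training folds; evaluation is on the
    untouched held-out fold.  ROC curves are averaged on a common FPR
    grid; the final model is refit on the resampled full data set and its
    out-of-bag error reported; feature importances are scaled to percent
    of the maximum.
    """
    if sampling not in ("smote", "down"):
        raise ValueError("sampling must be 'smote' or 'down'")
    y = (labels.loc[features.index] == target).astype(int).to_numpy()
    x = features.to_numpy()
    n_target = int(y.sum())
    if n_target < 2:
        raise ValueError(f"target group {target!r} has fewer than 2 samples")
    k_eff = min(k, n_target)
    if k_eff < k:
        warnings.warn(f"reducing folds to {k_eff} (target group size)")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    fpr_grid = np.linspace(0, 1, 101)
    tprs, aucs = [], []
    tp = fp = tn = fn = 0
    for train, test in skf.split(x, y):
        xt, yt = x[train], y[train]
        if sampling == "smote":
            xt, yt = smote_resample(xt, yt, rng)
        else:
            xt, yt = downsample_resample(xt, yt, rng)
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31)))
        clf.fit(xt, yt)
        pos = list(clf.classes_).index(1)
        prob = clf.predict_proba(x[test])[:, pos]
        if len(np.unique(y[test])) == 2:
            aucs.append(roc_auc_score(y[test], prob))
            f, t, _ = roc_curve(y[test], prob)
            tprs.append(np.interp(fpr_grid, f, t))
        pred = (prob >= 0.5).astype(int)
        tp += int(((pred == 1) & (y[test] == 1)).sum())
        fp += int(((pred == 1) & (y[test] == 0)).sum())
        tn += int(((pred == 0) & (y[test] == 0)).sum())
        fn += int(((pred == 0) & (y[test] == 1)).sum())
    mean_tpr = np.mean(tprs, axis=0) if tprs else np.full_like(fpr_grid,
                                                               np.nan)
    # final model on the resampled full data for OOB error and importances
    if sampling == "smote":
        xf, yf = smote_resample(x, y, rng)
    else:
        xf, yf = downsample_resample(x, y, rng)
    final = RandomForestClassifier(n_estimators=n_estimators,
                                   oob_score=True,
                                   random_state=int(rng.integers(2**31)))
    final.fit(xf, yf)
    imp = final.feature_importances_
    imp_pct = pd.Series(100.0 * imp / imp.max() if imp.max() > 0 else imp,
                        index=features.columns).sort_values(ascending=False)
    return RFReport(
        target=target, sampling=sampling,
        auc=float(np.mean(aucs)) if aucs else np.nan,
        fold_aucs=[float(a) for a in aucs],
        mean_roc=(fpr_grid, mean_tpr),
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        precision=tp / (tp + fp) if tp + fp else np.nan,
        oob_error=float(1.0 - final.oob_score_),
        importances=imp_pct)


def rf_all_groups(features: pd.DataFrame, labels: pd.Series,
                  sampling: str = "smote", k: int = 10, seed: int = 0,
                  n_estimators: int = 200) -> dict[str, RFReport]:
    """One-vs-all report for every group label."""
    return {g: rf_one_vs_all(features, labels, g, sampling, k,
                             seed=seed + i, n_estimators=n_estimators)
            for i, g in enumerate(sorted(labels.dropna().unique()))}
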