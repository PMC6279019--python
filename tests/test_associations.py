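"""Per-taxon screens, replication overlap, redundancy collapsing, pairwise
shifts, covariate regressions, presence-phenotype tests, and the
imbalance-aware random forests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal

import microsig as ms
from microsig.associations import _kw_from_ranks, _rank_matrix


def _taxon_table(values, labels=None, rank="genus"):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    labels = labels or [f"t{j}" for j in range(values.shape[1])]
    return ms.TaxonTable([f"s{i}" for i in range(values.shape[0])],
                         labels, values, rank)


class TestKruskalScreen:
    def test_matches_scipy_per_taxon(self, null_cohort):
        table, md = null_cohort
        gen = ms.collapse_taxonomy(table, "genus")
        rec = ms.kruskal_by_group(gen, md["ethnicity"]).set_index("taxon")
        df = gen.to_frame()
        labels = md["ethnicity"]
        for taxon in list(df.columns)[:25]:
            sets = [df.loc[(labels == g).to_numpy(), taxon]
                    for g in sorted(labels.unique())]
            if df[taxon].nunique() <= 1:
                assert rec.loc[taxon, "p"] == 1.0
                continue
            h, p = kruskal(*sets)
            assert rec.loc[taxon, "H"] == pytest.approx(h, abs=1e-9)
            assert rec.loc[taxon, "p"] == pytest.approx(p, abs=1e-9)

    def test_constant_taxon_degenerate(self):
        vals = np.column_stack([np.full(8, 0.5), np.full(8, 0.5)])
        t = ms.TaxonTable([f"s{i}" for i in range(8)], ["c", "c2"], vals,
                          "genus")
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=t.sample_ids)
        rec = ms.kruskal_by_group(t, groups)
        assert (rec["H"] == 0).all()
        assert (rec["p"] == 1.0).all()
        assert rec["degenerate"].all()

    def test_exact_enumeration_matches_brute_force(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        h, p = ms.kruskal_wallis_exact(a, b)
        # independent oracle: scipy H over all 20 assignments
        pooled = np.array(a + b)
        h_obs = kruskal(a, b).statistic
        hits = total = 0
        for idx in itertools.combinations(range(6), 3):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(6) if i not in idx]]
            if kruskal(ga, gb).statistic >= h_obs - 1e-12:
                hits += 1
            total += 1
        assert h == pytest.approx(h_obs, abs=1e-9)
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_bh_fdr_order_invariance(self, null_cohort):
        table, md = null_cohort
        gen = ms.collapse_taxonomy(table, "genus")
        rec = ms.kruskal_by_group(gen, md["ethnicity"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(gen.taxon_labels))
        shuffled = ms.TaxonTable(gen.sample_ids,
                                 [gen.taxon_labels[i] for i in perm],
                                 gen.values[:, perm], gen.rank)
        rec2 = ms.kruskal_by_group(shuffled, md["ethnicity"])
        merged = rec.set_index("taxon")["p_fdr"]
        merged2 = rec2.set_index("taxon")["p_fdr"]
        assert np.allclose(merged.sort_index(), merged2.sort_index())


class TestReplication:
    def _records(self, taxa, sig_taxa, rank="genus"):
        p = np.where(np.isin(taxa, list(sig_taxa)), 1e-6, 0.9)
        return pd.DataFrame({"taxon": taxa, "rank": rank, "H": 1.0,
                             "p": p, "p_fdr": p,
                             "p_bonf": np.minimum(p * len(taxa), 1)})

    def test_constructed_overlap_counts(self):
        universe = np.array([f"g{i}" for i in range(500)])
        sig_a = set(universe[:130])
        sig_b = set(universe[105:150])  # 25 shared with sig_a
        rec_a = self._records(universe, sig_a)
        rec_b = self._records(universe, sig_b)
        res = ms.replication_overlap(rec_a, rec_b)
        assert res.overlap["genus"] == 25
        assert res.overlap["combined"] == 25
        assert res.fisher is not None
        assert (res.fisher["p"] < 0.05).all()

    def test_identical_and_disjoint(self):
        universe = np.array([f"g{i}" for i in range(50)])
        rec = self._records(universe, set(universe[:10]))
        same = ms.replication_overlap(rec, rec)
        assert same.overlap["combined"] == 10
        other = self._records(universe, set(universe[20:30]))
        none = ms.replication_overlap(rec, other)
        assert none.overlap["combined"] == 0

    def test_permutation_null_detects_planted_overlap(self):
        shared = [ms.PlantedEffect(f"f__Family{i:02d}", "B",
                                   fold_change=6.0) for i in range(4)]
        ca = ms.SimulationConfig(seed=31, n_samples_per_group={"A": 40,
                                                               "B": 40},
                                 n_otus=60, depth_range=(3000, 3000))
        cb = ms.SimulationConfig(seed=32, n_samples_per_group={"A": 40,
                                                               "B": 40},
                                 n_otus=60, depth_range=(3000, 3000))
        (ta, ma), (tb, mb) = ms.generate_paired_cohorts(ca, cb, shared)
        fam_a = ms.collapse_taxonomy(ta, "family")
        fam_b = ms.collapse_taxonomy(tb, "family")
        res = ms.overlap_permutation_null([fam_a], ma["ethnicity"],
                                          [fam_b], mb["ethnicity"],
                                          n_perm=99, seed=0)
        assert res.overlap["family"] >= 4
        assert res.permutation_p["family"] == pytest.approx(1 / 100)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            ms.overlap_permutation_null([], {}, [], {}, n_perm=0)


class TestRedundancy:
    def _tables(self, fam_vals, gen_vals, fam_labels, gen_labels):
        n = fam_vals.shape[0]
        ids = [f"s{i}" for i in range(n)]
        fam = ms.TaxonTable(ids, fam_labels,
                            fam_vals / fam_vals.sum(1, keepdims=True),
                            "family")
        gen = ms.TaxonTable(ids, gen_labels,
                            gen_vals / gen_vals.sum(1, keepdims=True),
                            "genus")
        return fam, gen

    def test_redundant_classified_genus_kept(self):
        fam_labels = ["f__X", "f__Other"]
        gen_labels = ["f__X; g__A", "f__Other; g__Z"]
        fam_vals = np.array([[4.0, 6.0]] * 6)
        gen_vals = np.array([[4.0, 6.0]] * 6)
        fam, gen = self._tables(fam_vals, gen_vals, fam_labels, gen_labels)
        sig = pd.DataFrame({"rank": ["family", "genus"],
                            "taxon": ["f__X", "f__X; g__A"]})
        groups = pd.Series(["G1"] * 3 + ["G2"] * 3, index=fam.sample_ids)
        out = ms.collapse_redundant_taxa(sig, fam, gen, groups)
        kept = out.set_index("taxon")["kept"]
        assert kept["f__X; g__A"] and not kept["f__X"]

    def test_unclassified_genus_drops_to_family(self):
        fam_labels = ["f__X", "f__Other"]
        gen_labels = ["f__X; g__Unclassified", "f__Other; g__Z"]
        fam_vals = np.array([[4.0, 6.0]] * 6)
        gen_vals = np.array([[3.9, 6.1]] * 6)  # 97.5% of the family
        fam, gen = self._tables(fam_vals, gen_vals, fam_labels, gen_labels)
        sig = pd.DataFrame({"rank": ["family", "genus"],
                            "taxon": ["f__X", "f__X; g__Unclassified"]})
        groups = pd.Series(["G1"] * 3 + ["G2"] * 3, index=fam.sample_ids)
        out = ms.collapse_redundant_taxa(sig, fam, gen, groups)
        kept = out.set_index("taxon")["kept"]
        assert kept["f__X"] and not kept["f__X; g__Unclassified"]

    def test_split_family_keeps_both(self):
        fam_labels = ["f__X", "f__Other"]
        gen_labels = ["f__X; g__A", "f__X; g__B", "f__Other; g__Z"]
        fam_vals = np.array([[10.0, 10.0]] * 6)
        gen_vals = np.array([[6.0, 4.0, 10.0]] * 6)  # 60%/40% split
        fam, gen = self._tables(fam_vals, gen_vals, fam_labels, gen_labels)
        sig = pd.DataFrame({"rank": ["family", "genus", "genus"],
                            "taxon": ["f__X", "f__X; g__A", "f__X; g__B"]})
        groups = pd.Series(["G1"] * 3 + ["G2"] * 3, index=fam.sample_ids)
        out = ms.collapse_redundant_taxa(sig, fam, gen, groups)
        assert out["kept"].all()


class TestPairwiseShifts:
    def test_six_tests_per_taxon(self):
        rng = np.random.default_rng(0)
        t = _taxon_table(rng.uniform(size=(40, 3)) + 0.1)
        groups = pd.Series(sum([[g] * 10 for g in "ABCD"], []),
                           index=t.sample_ids)
        shifts = ms.pairwise_group_shifts(t, groups)
        assert len(shifts) == 3 * 6
        for _, row in shifts.iterrows():
            assert row["p_bonf"] == pytest.approx(min(1.0, row["p"] * 6))

    def test_planted_reduction_replicates_with_direction(self):
        shared = [ms.PlantedEffect("f__Family01", "B", fold_change=8.0)]
        cfgs = [ms.SimulationConfig(seed=s,
                                    n_samples_per_group={"A": 30, "B": 30,
                                                         "C": 30, "D": 30},
                                    n_otus=60, depth_range=(4000, 4000))
                for s in (41, 42)]
        (ta, ma), (tb, mb) = ms.generate_paired_cohorts(*cfgs, shared)
        shifts = []
        for t, m, name in ((ta, ma, "a"), (tb, mb, "b")):
            fam = ms.collapse_taxonomy(t, "family")
            taxa = [c for c in fam.taxon_labels if "f__Family01" in c]
            shifts.append(ms.pairwise_group_shifts(fam, m["ethnicity"],
                                                   taxa=taxa, cohort=name))
        merged = ms.replicated_shifts(*shifts)
        b_rows = merged[(merged["group_a"] == "B")
                        | (merged["group_b"] == "B")]
        assert len(b_rows) == 3
        assert b_rows["replicated"].all()
        # group B is elevated: direction "up" when B is group_b
        for _, row in b_rows.iterrows():
            expect = "up" if row["group_b"] == "B" else "down"
            assert row["direction_a"] == expect


class TestRegressions:
    def _metadata(self, n, rng):
        return pd.DataFrame({
            "ethnicity": rng.choice(["A", "B", "C"], n, p=[0.6, 0.25,
                                                           0.15]),
            "sex": rng.choice(["male", "female"], n),
            "age": rng.uniform(18, 55, n),
            "bmi": rng.normal(25, 4, n),
        }, index=[f"s{i}" for i in range(n)])

    def test_exact_bmi_relation_recovered(self):
        rng = np.random.default_rng(1)
        n = 120
        md = self._metadata(n, rng)
        ab = 10 ** (-3 + 0.05 * md["bmi"].to_numpy())
        vals = np.column_stack([ab, 1.0 - ab])
        t = ms.TaxonTable(list(md.index), ["target", "rest"], vals,
                          "genus")
        out = ms.abundance_regressions(t, md).set_index("taxon")
        assert out.loc["target", "lin_p_bmi"] < 1e-12
        assert out.loc["target", "lin_cov_r2"] == pytest.approx(1.0,
                                                                abs=1e-9)

    def test_absent_and_saturated_taxa_skipped(self):
        rng = np.random.default_rng(2)
        n = 60
        md = self._metadata(n, rng)
        everywhere = np.full(n, 0.5)
        vals = np.column_stack([everywhere, 0.5 - 0.001 * rng.random(n),
                                0.001 * rng.random(n) + 1e-6])
        t = ms.TaxonTable(list(md.index), ["all", "most", "filler"],
                          vals / vals.sum(1, keepdims=True), "genus")
        out = ms.abundance_regressions(t, md).set_index("taxon")
        # present in every sample: logistic fit is degenerate
        assert np.isnan(out.loc["all", "log_p"])

    def test_null_presence_not_significant_on_average(self):
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(20):
            n = 80
            md = self._metadata(n, rng)
            present = rng.random(n) < 0.6
            ab = np.where(present, rng.uniform(0.01, 0.2, n), 0.0)
            vals = np.column_stack([ab, 1.0 - ab])
            t = ms.TaxonTable(list(md.index), ["t", "rest"], vals, "genus")
            out = ms.abundance_regressions(t, md).set_index("taxon")
            pvals.append(out.loc["t", "log_p"])
        pvals = np.array([p for p in pvals if np.isfinite(p)])
        assert (pvals < 0.05).mean() < 0.25


class TestPresencePhenotype:
    def test_shifted_phenotype_detected(self):
        rng = np.random.default_rng(4)
        n = 200
        presence = pd.Series([True] * 100 + [False] * 100,
                             index=[f"s{i}" for i in range(n)])
        phen = pd.Series(np.concatenate([rng.normal(23, 3, 100),
                                         rng.normal(25, 3, 100)]),
                         index=presence.index)
        res = ms.presence_phenotype_test(presence, phen)
        assert res.iloc[0]["p"] < 0.001

    def test_null_centred_near_half(self):
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(40):
            presence = pd.Series(rng.random(60) < 0.5,
                                 index=[f"s{i}" for i in range(60)])
            if presence.all() or not presence.any():
                continue
            phen = pd.Series(rng.normal(25, 4, 60), index=presence.index)
            ps.append(ms.presence_phenotype_test(presence,
                                                 phen).iloc[0]["p"])
        assert abs(np.mean(ps) - 0.5) < 0.15

    def test_everyone_possessing_is_skipped(self):
        presence = pd.Series([True] * 10,
                             index=[f"s{i}" for i in range(10)])
        phen = pd.Series(np.arange(10.0), index=presence.index)
        res = ms.presence_phenotype_test(presence, phen)
        assert res.iloc[0]["skipped"]

    def test_per_group_subsets(self):
        rng = np.random.default_rng(6)
        n = 120
        idx = [f"s{i}" for i in range(n)]
        presence = pd.Series(rng.random(n) < 0.5, index=idx)
        phen = pd.Series(rng.normal(25, 4, n), index=idx)
        groups = pd.Series(["A"] * 60 + ["B"] * 60, index=idx)
        res = ms.presence_phenotype_test(presence, phen, groups)
        assert set(res["subset"]) == {"overall", "A", "B"}


class TestRandomForest:
    def test_presence_filter_threshold(self):
        # rarest group 13 -> floor(13/2) = 6; a genus in 5 samples is
        # dropped, one in 6 samples is kept
        rng = np.random.default_rng(7)
        n = 13 + 30
        depth = 500
        base = rng.integers(20, 60, size=(n, 6))
        rare5 = np.zeros((n, 1), dtype=int)
        rare5[:5] = 40
        rare6 = np.zeros((n, 1), dtype=int)
        rare6[:6] = 40
        counts = np.hstack([base, rare5, rare6])
        # equalize depths so rarefaction at the common depth is identity
        filler = depth * 2 - counts.sum(axis=1)
        counts = np.hstack([counts, filler[:, None]])
        tax = {}
        for j in range(6):
            tax[f"O{j}"] = (f"k__B; p__P; c__C; o__O; f__F{j}; "
                            f"g__G{j}; s__")
        tax["R5"] = "k__B; p__P; c__C; o__O; f__R; g__Rare5; s__"
        tax["R6"] = "k__B; p__P; c__C; o__O; f__R; g__Rare6; s__"
        tax["FIL"] = "k__B; p__P; c__C; o__O; f__Z; g__Fill; s__"
        ids = [f"O{j}" for j in range(6)] + ["R5", "R6", "FIL"]
        t = ms.CountTable([f"s{i}" for i in range(n)], ids, counts, tax)
        groups = pd.Series(["A"] * 13 + ["B"] * 30, index=t.sample_ids)
        feats, _ = ms.prepare_genus_features(t, groups, depth=depth * 2,
                                             seed=0)
        kept = " ".join(feats.columns)
        assert "g__Rare6" in kept
        assert "g__Rare5" not in kept

    def test_separable_feature_gives_perfect_auc(self):
        rng = np.random.default_rng(8)
        n = 60
        y = pd.Series(["T"] * 15 + ["R"] * 45,
                      index=[f"s{i}" for i in range(n)])
        x = rng.normal(size=(n, 5))
        x[:15, 0] += 10.0  # disjoint support on feature 0
        feats = pd.DataFrame(x, index=y.index,
                             columns=[f"f{j}" for j in range(5)])
        rep = ms.rf_one_vs_all(feats, y, "T", sampling="down", k=5,
                               seed=0, n_estimators=100)
        assert rep.auc == pytest.approx(1.0)
        assert rep.importances.index[0] == "f0"

    def test_smote_interpolates_within_minority_hull(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.uniform(0, 1, (10, 3)),
                       rng.uniform(5, 6, (40, 3))])
        y = np.array([1] * 10 + [0] * 40)
        xr, yr = ms.smote_resample(x, y, np.random.default_rng(0))
        assert (yr == 1).sum() == 20
        assert (yr == 0).sum() == 20
        new_min = xr[yr == 1]
        assert new_min.min() >= 0.0 and new_min.max() <= 1.0

    def test_downsample_balances(self):
        x = np.arange(50, dtype=float)[:, None]
        y = np.array([1] * 10 + [0] * 40)
        xr, yr = ms.downsample_resample(x, y, np.random.default_rng(0))
        assert (yr == 1).sum() == (yr == 0).sum() == 10
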