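"""Per-variant Weir-Cockerham (1984) FST between population pairs with
chromosome-wide and genome-wide percentile ranking and outlier flags.

The estimator is the two-allele ratio-of-variance-components form
theta = a / (a + b + c) computed from genotype counts (observed
heterozygosity included), matching the per-site behaviour of the standard
VCF tooling; negative estimates are reported as computed, never clipped.
Percentiles use strict "higher than" counting: the fraction of background
variants with strictly higher FST determines the rank, so ties do not
count against the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .simulate import VariantPanel


@dataclass
class AlleleFrequencyTable:
    """Per-variant alt-allele frequency, MAF and call count for one
    population (or globally)."""

    table: pd.DataFrame  # id, alt_freq, maf, n_called, excluded_maf


def allele_frequencies(panel: VariantPanel, population: str | None = None,
                       maf_min: float = 0.01) -> AlleleFrequencyTable:
    """Alt-allele frequencies from dosages (missing excluded); variants
    with MAF below ``maf_min`` get the exclusion flag."""
    if population is None:
        mask = np.ones(len(panel.sample_ids), dtype=bool)
    else:
        mask = panel.population_samples(population)
    g = panel.genotypes[:, mask].astype(float)
    called = g >= 0
    n_called = called.sum(axis=1)
    alt = np.where(called, g, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    maf = np.minimum(freq, 1.0 - freq)
    out = pd.DataFrame({
        "id": panel.variants["id"].to_numpy(),
        "alt_freq": freq, "maf": maf, "n_called": n_called.astype(int),
        "excluded_maf": (maf < maf_min) | np.isnan(maf),
    })
    return AlleleFrequencyTable(out)


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham a, b, c variance components for one variant across
    r populations (vectorized over variants).

    ``n``: called diploids per population (r, v); ``p``: alt frequency
    (r, v); ``h``: observed heterozygote frequency (r, v).
    """
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    nc = (nsum - (n ** 2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / nsum
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4.0) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst(panel: VariantPanel, pop_a: str, pop_b: str,
                       maf_min: float = 0.01) -> pd.DataFrame:
    """Per-variant Weir-Cockerham FST between two populations.

    Variants monomorphic across both populations, with < 2 called diploids
    in either population, or below the global ``maf_min`` are flagged
    ``skip`` with a NaN estimate.  FST(A, B) = FST(B, A) exactly.
    """
    masks = [panel.population_samples(p) for p in (pop_a, pop_b)]
    n_list, p_list, h_list = [], [], []
    for m in masks:
        g = panel.genotypes[:, m].astype(float)
        called = g >= 0
        n = called.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, g, 0.0).sum(axis=1) / (2.0 * n)
            h = np.where(called, g == 1, False).sum(axis=1) / n
        n_list.append(n)
        p_list.append(p)
        h_list.append(h)
    n = np.vstack(n_list)
    p = np.vstack(p_list)
    h = np.vstack(h_list)
    skip = (n < 2).any(axis=0)
    global_maf = allele_frequencies(panel, maf_min=maf_min).table
    skip |= global_maf["excluded_maf"].to_numpy()
    mono = np.isclose(p, p[0:1, :]).all(axis=0) & \
        ((np.isclose(p[0], 0.0) | np.isclose(p[0], 1.0)))
    skip |= mono
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, c = _wc_components(np.where(n > 0, n, np.nan), p, h)
        denom = a + b + c
        fst = np.where(np.abs(denom) > 0, a / denom, np.nan)
    fst = np.where(skip, np.nan, fst)
    return pd.DataFrame({
        "id": panel.variants["id"].to_numpy(),
        "chrom": panel.variants["chrom"].to_numpy(),
        "pop_a": pop_a, "pop_b": pop_b,
        "fst": fst, "skip": skip,
        "a": np.where(skip, np.nan, a),
        "abc": np.where(skip, np.nan, denom),
    })


def weighted_fst(records: pd.DataFrame) -> float:
    """Multi-locus weighted estimate: sum of a components over sum of
    (a + b + c) across variants (the standard low-bias aggregate; the
    plain mean of per-variant ratios is biased downward)."""
    ok = records.loc[~records["skip"]]
    return float(ok["a"].sum() / ok["abc"].sum())


def pairwise_fst(panel: VariantPanel,
                 pairs: list[tuple[str, str]] | None = None,
                 exclude_pairs: list[tuple[str, str]] | None = None,
                 maf_min: float = 0.01) -> pd.DataFrame:
    """FST for every population pair (minus an exclusion list)."""
    pops = sorted(panel.populations.unique())
    if pairs is None:
        pairs = list(combinations(pops, 2))
    excluded = {tuple(sorted(p)) for p in (exclude_pairs or [])}
    frames = [weir_cockerham_fst(panel, a, b, maf_min)
              for a, b in pairs if tuple(sorted((a, b))) not in excluded]
    return pd.concat(frames, ignore_index=True)


def fst_percentiles(target_records: pd.DataFrame,
                    background_records: pd.DataFrame,
                    low_confidence_n: int = 20) -> pd.DataFrame:
    """Rank target variants' FST against same-chromosome and genome-wide
    backgrounds, per population pair.

    percentile = 100 * (1 - higher / total) with strict "higher than"
    counting; flags mark estimates at or above the 95th and 99th
    genome-wide and chromosome percentiles (both backgrounds must agree),
    and backgrounds smaller than ``low_confidence_n`` variants are flagged.
    """
    bg = background_records.loc[~background_records["skip"]
                                & background_records["fst"].notna()]
    rows = []
    for _, rec in target_records.iterrows():
        if rec.get("skip", False) or pd.isna(rec["fst"]):
            continue
        pair_bg = bg[(bg["pop_a"] == rec["pop_a"])
                     & (bg["pop_b"] == rec["pop_b"])]
        chrom_bg = pair_bg[pair_bg["chrom"] == rec["chrom"]]
        out = {"id": rec["id"], "chrom": rec["chrom"],
               "pop_a": rec["pop_a"], "pop_b": rec["pop_b"],
               "fst": rec["fst"]}
        for name, sub in (("genome", pair_bg), ("chrom", chrom_bg)):
            total = len(sub)
            if total == 0:
                raise ValueError(
                    f"empty {name} background for {rec['id']} "
                    f"({rec['pop_a']} vs {rec['pop_b']})")
            higher = int((sub["fst"].to_numpy() > rec["fst"]).sum())
            out[f"{name}_higher"] = higher
            out[f"{name}_total"] = total
            out[f"{name}_percentile"] = 100.0 * (1.0 - higher / total)
            out[f"{name}_low_confidence"] = total < low_confidence_n
        out["above_95"] = (out["genome_percentile"] >= 95.0
                           and out["chrom_percentile"] >= 95.0)
        out["above_99"] = (out["genome_percentile"] >= 99.0
                           and out["chrom_percentile"] >= 99.0)
        rows.append(out)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF + population map input


def read_popmap(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df.iloc[:, 1].to_numpy(),
                     index=df.iloc[:, 0].to_numpy(), name="population")


def read_vcf(path, popmap: pd.Series) -> VariantPanel:
    """Read GT fields from a VCF into a VariantPanel (requires cyvcf2)."""
    from cyvcf2 import VCF
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3=missing
        gt[gt == 3] = -1
        rows.append(gt)
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                             "ref": refs, "alt": alts})
    missing = [s for s in sample_ids if s not in popmap.index]
    if missing:
        raise ValueError(f"samples missing from population map: "
                         f"{missing[:5]}")
    return VariantPanel(variants, np.vstack(rows), sample_ids,
                        popmap.loc[sample_ids])
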