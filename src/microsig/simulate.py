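"""Synthetic cohort and variant-panel generation.

Emulates the statistical structure of US-population 16S gut cohorts so the
whole pipeline is testable without any download: compositional counts with
variable sequencing depth and overdispersion (Dirichlet-multinomial), severe
four-level group imbalance with one ~90% majority class, sex/age/BMI
covariates drawn inside the QC window, per-(sample, taxon) zero inflation
emulating carriage differences, planted multiplicative taxon effects shared
or not between paired cohorts, a block of co-occurring families driven by a
latent factor, and population-structured allele frequencies under the
Balding-Nichols model with a tunable differentiation parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable

#: group sizes mirroring the four-level, ~90%-majority imbalance of a large
#: US crowd-sourced gut cohort (Caucasian 1237, Asian-Pacific Islander 88,
#: Hispanic 37, African American 13)
DEFAULT_GROUP_SIZES = {
    "Caucasian": 1237,
    "Asian-Pacific Islander": 88,
    "Hispanic": 37,
    "African American": 13,
}


@dataclass
class PlantedEffect:
    """A group-specific effect planted on one taxon.

    ``taxon_id`` is matched as a substring of OTU lineage strings (e.g.
    ``"f__Christensenellaceae"``).  ``fold_change`` acts multiplicatively on
    the expected relative abundance of matching OTUs in ``affected_group``
    before compositional closure; ``presence_shift`` is added to the
    carriage probability.  ``fold_change=1, presence_shift=0`` is a null.
    """

    taxon_id: str
    affected_group: str
    fold_change: float = 1.0
    presence_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if not -1.0 <= self.presence_shift <= 1.0:
            raise ValueError("presence_shift must lie in [-1, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_otus: int = 200
    depth_range: tuple[int, int] = (1000, 10000)
    base_abundance_logmean_sd: tuple[float, float] = (0.0, 1.5)
    planted_taxa: list[PlantedEffect] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    cooccurrence_block: tuple[int, float] = (0, 0.0)
    zero_inflation: float = 0.3
    overdispersion: float = 200.0
    n_families: int = 25
    unclassified_genus_fraction: float = 0.2
    #: taxonomy is drawn from its own seed so paired cohorts share the
    #: same lineage strings (as real cohorts share a reference taxonomy)
    taxonomy_seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_otus <= 0:
            raise ValueError("n_otus must be positive")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range min must be >= 1 and <= max")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must lie in [0, 1)")
        for g, n in self.n_samples_per_group.items():
            if n <= 0:
                raise ValueError(f"non-positive group size for {g!r}")


@dataclass
class VariantPanelConfig:
    seed: int = 0
    n_variants: int = 2000
    n_populations: int = 2
    samples_per_population: int = 100
    differentiation: float = 0.10
    n_outlier_variants: int = 0
    outlier_differentiation: float = 0.5
    n_chromosomes: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.differentiation < 1.0:
            raise ValueError("differentiation must lie in [0, 1)")
        if self.samples_per_population < 2:
            raise ValueError("need >= 2 diploids per population")
        if (self.n_outlier_variants > 0
                and self.outlier_differentiation <= self.differentiation):
            raise ValueError(
                "outlier_differentiation must exceed differentiation")


# ---------------------------------------------------------------------------


def _make_taxonomy(config: SimulationConfig
                   ) -> tuple[list[str], dict[str, str]]:
    """Random 7-rank lineages: OTUs nested in genera nested in families.

    Drawn from ``taxonomy_seed`` (not the cohort seed) so cohorts built
    with the same taxonomy settings share lineage strings.
    """
    rng = np.random.default_rng(config.taxonomy_seed)
    n_fam = max(1, config.n_families)
    otu_ids = [f"OTU_{i:04d}" for i in range(config.n_otus)]
    taxonomy = {}
    fam_of_otu = rng.integers(0, n_fam, size=config.n_otus)
    # every family gets at least one OTU so planted family ids resolve
    k = min(n_fam, config.n_otus)
    fam_of_otu[:k] = np.arange(k)
    phylum_of_fam = rng.integers(0, max(2, n_fam // 5), size=n_fam)
    for i, otu in enumerate(otu_ids):
        fam = fam_of_otu[i]
        phy = phylum_of_fam[fam]
        genus = (f"g__Genus{i:04d}"
                 if rng.random() > config.unclassified_genus_fraction
                 else "g__")
        taxonomy[otu] = (
            f"k__Bacteria; p__Phylum{phy:02d}; c__Class{phy:02d}; "
            f"o__Order{fam:02d}; f__Family{fam:02d}; {genus}; s__"
        )
    return otu_ids, taxonomy


def _match_otus(taxon_id: str, otu_ids: list[str],
                taxonomy: dict[str, str]) -> np.ndarray:
    mask = np.array([taxon_id in taxonomy[o] or taxon_id == o
                     for o in otu_ids])
    if not mask.any():
        raise ValueError(f"planted taxon id {taxon_id!r} matches no OTU")
    return mask


def generate_cohort(config: SimulationConfig
                    ) -> tuple[CountTable, pd.DataFrame]:
    """Generate one cohort: a CountTable plus per-sample metadata.

    Counts per sample are Dirichlet-multinomial around a log-normal base
    composition modified by the sample's group (planted effects) and
    covariates, with per-(sample, taxon) zero inflation applied before
    renormalization; read depth is uniform on ``depth_range``.  The same
    seed yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    otu_ids, taxonomy = _make_taxonomy(config)
    base = rng.lognormal(*config.base_abundance_logmean_sd,
                         size=config.n_otus)
    base /= base.sum()

    groups, sample_ids = [], []
    for g, n in config.n_samples_per_group.items():
        groups += [g] * n
        sample_ids += [f"{g.replace(' ', '')[:4]}.{k:04d}"
                       for k in range(n)]
    n = len(sample_ids)

    sex = np.where(rng.random(n) < 0.5, "female", "male")
    age = rng.uniform(18, 55, size=n)
    bmi = np.clip(rng.normal(25, 4, size=n), 10.01, 59.99)

    effect_masks = [( _match_otus(e.taxon_id, otu_ids, taxonomy), e)
                    for e in config.planted_taxa]
    seen: dict[str, set[int]] = {}
    for mask, e in effect_masks:
        hits = seen.setdefault(e.affected_group, set())
        new = set(np.flatnonzero(mask))
        if hits & new and len(config.planted_taxa) > 1:
            overlap_effects = [x for m, x in effect_masks
                               if x.affected_group == e.affected_group
                               and set(np.flatnonzero(m)) & new and x is not e]
            if overlap_effects:
                raise ValueError(
                    f"conflicting planted effects on the same taxon for "
                    f"group {e.affected_group!r}")
        hits |= new

    cov_values = {"age": (age - age.mean()) / max(age.std(), 1e-9),
                  "bmi": (bmi - bmi.mean()) / max(bmi.std(), 1e-9),
                  "sex": (sex == "female").astype(float) - 0.5}

    n_block, block_rho = config.cooccurrence_block
    block_fams = [f"f__Family{j:02d}" for j in range(n_block)]
    block_masks = [np.array([f in taxonomy[o] for o in otu_ids])
                   for f in block_fams]

    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1,
                          size=n)
    counts = np.zeros((n, config.n_otus), dtype=np.int64)
    carriage = 1.0 - config.zero_inflation
    for i in range(n):
        expected = base.copy()
        carry_p = np.full(config.n_otus, carriage)
        for mask, e in effect_masks:
            if groups[i] == e.affected_group:
                expected[mask] *= e.fold_change
                carry_p[mask] = np.clip(carry_p[mask] + e.presence_shift,
                                        0.0, 1.0)
        for cov, beta in config.covariate_effects.items():
            if not effect_masks:
                continue
            x = cov_values[cov][i]
            for mask, _ in effect_masks:
                expected[mask] *= np.exp(beta * x)
        if n_block and block_rho > 0:
            # shared latent log-normal factor drives the block families
            latent = rng.normal(0.0, 1.0)
            for m in block_masks:
                eps = rng.normal(0.0, 1.0)
                z = (np.sqrt(block_rho) * latent
                     + np.sqrt(1 - block_rho) * eps)
                expected[m] *= np.exp(z)
        present = rng.random(config.n_otus) < carry_p
        expected = expected * present
        if expected.sum() == 0:
            expected = base.copy()
        expected /= expected.sum()
        alpha = expected * config.overdispersion
        # Dirichlet-multinomial: composition jitter then multinomial draw
        pos = alpha > 0
        comp = np.zeros(config.n_otus)
        comp[pos] = rng.dirichlet(alpha[pos])
        counts[i] = rng.multinomial(depths[i], comp)

    table = CountTable(sample_ids, otu_ids, counts, taxonomy)
    metadata = pd.DataFrame({
        "ethnicity": groups, "sex": sex, "age": np.round(age, 1),
        "bmi": np.round(bmi, 2), "body_site": "fecal", "country": "USA",
    }, index=pd.Index(sample_ids, name="sample_id"))
    return table, metadata


def generate_paired_cohorts(
        config_a: SimulationConfig, config_b: SimulationConfig,
        shared_taxa: list[PlantedEffect] | None = None,
        ) -> tuple[tuple[CountTable, pd.DataFrame],
                   tuple[CountTable, pd.DataFrame]]:
    """Two independent cohorts carrying the same planted effects on the
    same taxonomy strings (the cross-cohort replication design).

    Cohort-specific effects already present in each config are kept;
    ``shared_taxa`` are appended to both.  Base profiles and noise are
    independent whenever the two seeds differ.
    """
    shared = list(shared_taxa or [])
    cfg_a = dataclasses.replace(config_a,
                                planted_taxa=list(config_a.planted_taxa) + shared)
    cfg_b = dataclasses.replace(config_b,
                                planted_taxa=list(config_b.planted_taxa) + shared)
    return generate_cohort(cfg_a), generate_cohort(cfg_b)


# ---------------------------------------------------------------------------
# variant panels


@dataclass
class VariantPanel:
    """Population-labelled diploid genotypes (alt-dosage, -1 = missing)."""

    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    genotypes: np.ndarray   # (n_variants, n_samples) in {0,1,2,-1}
    sample_ids: list[str]
    populations: pd.Series  # sample_id -> population label

    def population_samples(self, pop: str) -> np.ndarray:
        mask = (self.populations.loc[self.sample_ids] == pop).to_numpy()
        if not mask.any():
            raise KeyError(f"population {pop!r} not in panel")
        return mask


def generate_variant_panel(config: VariantPanelConfig) -> VariantPanel:
    """Balding-Nichols panel: per-population allele frequencies beta-drawn
    around a shared ancestral frequency; diploid genotypes binomial.

    The last ``n_outlier_variants`` variants use ``outlier_differentiation``
    and carry ``_OUT`` in their ids.
    """
    rng = np.random.default_rng(config.seed)
    n_var = config.n_variants
    n_pop = config.n_populations
    n_per = config.samples_per_population
    is_outlier = np.zeros(n_var, dtype=bool)
    if config.n_outlier_variants:
        is_outlier[-config.n_outlier_variants:] = True

    anc = rng.uniform(0.05, 0.95, size=n_var)
    # mid-range ancestral frequency for constructed outliers so their
    # opposite-tail placement yields maximal differentiation
    anc[is_outlier] = rng.uniform(0.4, 0.6, size=int(is_outlier.sum()))
    genotypes = np.zeros((n_var, n_pop * n_per), dtype=np.int8)
    pop_labels = []
    for k in range(n_pop):
        pop_labels += [f"POP{k + 1}"] * n_per
    for v in range(n_var):
        for k in range(n_pop):
            if is_outlier[v]:
                # deterministic opposite-tail placement so constructed
                # outliers separate cleanly from the background
                f_out = config.outlier_differentiation
                d = np.sqrt(f_out * anc[v] * (1 - anc[v]))
                sign = 1.0 if k % 2 == 0 else -1.0
                p = float(np.clip(anc[v] + sign * d, 0.02, 0.98))
            elif config.differentiation == 0.0:
                p = anc[v]
            else:
                F = config.differentiation
                a = anc[v] * (1 - F) / F
                b = (1 - anc[v]) * (1 - F) / F
                p = rng.beta(a, b)
            sl = slice(k * n_per, (k + 1) * n_per)
            genotypes[v, sl] = rng.binomial(2, p, size=n_per)

    chrom = (np.arange(n_var) % config.n_chromosomes) + 1
    ids = [f"rs{v:06d}_OUT" if is_outlier[v] else f"rs{v:06d}"
           for v in range(n_var)]
    variants = pd.DataFrame({
        "id": ids, "chrom": [f"chr{c}" for c in chrom],
        "pos": np.arange(1, n_var + 1) * 100, "ref": "A", "alt": "G",
    })
    sample_ids = [f"S{j:04d}" for j in range(n_pop * n_per)]
    pops = pd.Series(pop_labels, index=sample_ids, name="population")
    return VariantPanel(variants, genotypes, sample_ids, pops)


def write_vcf(panel: VariantPanel, vcf_path, popmap_path=None) -> None:
    """Write a minimal GT-only VCF plus an optional two-column population map."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(panel.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for v in range(len(panel.variants)):
            row = panel.variants.iloc[v]
            gts = "\t".join(gt_map[int(g)] for g in panel.genotypes[v])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{gts}\n")
    if popmap_path is not None:
        panel.populations.rename_axis("sample_id").to_frame().to_csv(
            popmap_path, sep="\t")
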