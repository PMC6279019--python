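"""Core containers and I/O: OTU tables, sample metadata, quality control,
taxonomy collapse, and metadata-factor structure tests.

The pipeline starts at a sample-by-OTU count table with 7-rank taxonomy
strings (``k__...; p__...; ...; g__...``) and a per-sample metadata table.
Supported on-disk dialects are the classic tab-delimited OTU table
(QIIME-1 style: OTU ids as rows, samples as columns, optional leading
``# Constructed from biom file`` comment, final ``taxonomy`` column) and
read-only BIOM-JSON (v1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: canonical metadata columns; anything else is treated as a free factor
METADATA_COLUMNS = ("ethnicity", "sex", "age", "bmi", "body_site", "country")


@dataclass
class CountTable:
    """Integer sample x OTU count matrix with per-OTU taxonomy strings."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # (n_samples, n_otus) non-negative integers
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            s, o = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[s]!r}, "
                f"OTU {self.otu_ids[o]!r}"
            )
        for otu in self.otu_ids:
            self.taxonomy.setdefault(otu, "")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def select_samples(self, keep: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(list(keep), list(self.otu_ids),
                          self.counts[idx, :], dict(self.taxonomy))

    def select_otus(self, keep: list[str]) -> "CountTable":
        idx = [self.otu_ids.index(o) for o in keep]
        return CountTable(list(self.sample_ids), list(keep),
                          self.counts[:, idx],
                          {o: self.taxonomy[o] for o in keep})

    def relative_abundance(self) -> np.ndarray:
        depths = self.sample_depths().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / depths[:, None]
        rel[depths == 0, :] = 0.0
        return rel


@dataclass
class TaxonTable:
    """Relative-abundance matrix collapsed at one taxonomic rank.

    Rows are samples and sum to 1 (all-zero samples stay all-zero); labels
    are lineage strings truncated at ``rank``, with unclassified taxa kept
    distinct within their parent lineage.
    """

    sample_ids: list[str]
    taxon_labels: list[str]
    values: np.ndarray  # (n_samples, n_taxa) relative abundances
    rank: str
    counts: np.ndarray | None = None  # pre-closure collapsed counts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("negative relative abundance")
        sums = self.values.sum(axis=1)
        bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0))
        if bad.any():
            raise ValueError(
                f"rows do not close to 1: samples {np.flatnonzero(bad)[:5]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.taxon_labels)


@dataclass
class QCConfig:
    """Sample/OTU quality-control thresholds.

    Defaults match the standard adult-gut QC window: BMI in (10, 60),
    age in [18, 55], fecal samples from the accepted countries, at least
    10 reads per OTU and 1,000 reads per sample.
    """

    bmi_min: float = 10.0
    bmi_max: float = 60.0
    age_min: float = 18.0
    age_max: float = 55.0
    required_site: str = "fecal"
    accepted_countries: tuple[str, ...] = ("USA",)
    #: None accepts any non-missing ethnicity label
    known_ethnicities: tuple[str, ...] | None = (
        "African American", "Asian-Pacific Islander", "Caucasian", "Hispanic",
    )
    min_otu_total: int = 10
    min_sample_depth: int = 1000

    def __post_init__(self) -> None:
        if self.bmi_min >= self.bmi_max or self.age_min >= self.age_max:
            raise ValueError("min must be below max for BMI and age ranges")


@dataclass
class QCReport:
    """Per-step attrition record; the audit surface of ``apply_qc``."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    # (step name, n removed, n remaining)
    otus_removed: int = 0

    def add(self, name: str, removed: int, remaining: int) -> None:
        self.steps.append((name, removed, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "removed", "remaining"])


# ---------------------------------------------------------------------------
# readers / writers


def write_count_table(table: CountTable, path) -> None:
    """Write the classic tab-delimited OTU table (samples as columns)."""
    with open(path, "w") as fh:
        fh.write("# Constructed from biom file\n")
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for j, otu in enumerate(table.otu_ids):
            row = "\t".join(str(int(c)) for c in table.counts[:, j])
            fh.write(f"{otu}\t{row}\t{table.taxonomy.get(otu, '')}\n")


def read_count_table(path, format: str = "classic_tsv") -> CountTable:
    """Read an OTU table in the named dialect (``classic_tsv``/``biom_json``)."""
    if format == "classic_tsv":
        return _read_classic_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_classic_tsv(path) -> CountTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    # skip leading comment lines but keep the '#OTU ID' header
    while lines and lines[0].startswith("#") and not lines[0].startswith("#OTU ID"):
        lines.pop(0)
    if not lines:
        raise ValueError(f"{path}: empty OTU table")
    header = lines[0].split("\t")
    has_taxonomy = header[-1].strip().lower() == "taxonomy"
    if not has_taxonomy:
        warnings.warn(f"{path}: no taxonomy column; lineages left empty")
    sample_ids = header[1:-1] if has_taxonomy else header[1:]
    otu_ids, taxonomy, rows = [], {}, []
    for ln in lines[1:]:
        parts = ln.split("\t")
        otu = parts[0]
        vals = parts[1:-1] if has_taxonomy else parts[1:]
        if len(vals) != len(sample_ids):
            raise ValueError(f"{path}: row {otu!r} has {len(vals)} values, "
                             f"expected {len(sample_ids)}")
        for sid, v in zip(sample_ids, vals):
            if float(v) < 0:
                raise ValueError(
                    f"{path}: negative count at sample {sid!r}, OTU {otu!r}")
        otu_ids.append(otu)
        taxonomy[otu] = parts[-1].strip() if has_taxonomy else ""
        rows.append([int(round(float(v))) for v in vals])
    counts = np.asarray(rows, dtype=np.int64).T  # samples x OTUs
    return CountTable(sample_ids, otu_ids, counts, taxonomy)


def _read_biom_json(path) -> CountTable:
    with open(path) as fh:
        obj = json.load(fh)
    otu_ids = [r["id"] for r in obj["rows"]]
    sample_ids = [c["id"] for c in obj["columns"]]
    taxonomy = {}
    for r in obj["rows"]:
        md = r.get("metadata") or {}
        tax = md.get("taxonomy", "")
        if isinstance(tax, list):
            tax = "; ".join(tax)
        taxonomy[r["id"]] = tax
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if obj.get("matrix_type") == "dense":
        mat[:] = np.asarray(obj["data"])
    else:
        for i, j, v in obj["data"]:
            mat[int(i), int(j)] = v
    return CountTable(sample_ids, otu_ids, mat.T.astype(np.int64), taxonomy)


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata TSV keyed by sample id (``#SampleID`` header accepted)."""
    md = pd.read_csv(path, sep="\t", dtype={0: str})
    first = md.columns[0]
    if first.lstrip("#").replace(" ", "").lower() in ("sampleid", "sample_id"):
        md = md.rename(columns={first: "sample_id"})
    return md.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "#SampleID"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# quality control


def apply_qc(table: CountTable, metadata: pd.DataFrame,
             config: QCConfig | None = None
             ) -> tuple[CountTable, pd.DataFrame, QCReport]:
    """Apply the sample and OTU quality-control filters in a fixed order.

    Sample filters: BMI range -> age present/range -> appears in the count
    table -> known ethnicity -> fecal body site -> known sex -> accepted
    country; community filters: OTUs with < ``min_otu_total`` reads, then
    samples with < ``min_sample_depth`` reads.  Each sample is attributed
    to the first step at which it fails, so the report's per-step removal
    counts sum to the total attrition.
    """
    cfg = config or QCConfig()
    report = QCReport()
    md = metadata.copy()

    def _drop(mask: pd.Series, name: str) -> None:
        nonlocal md
        removed = int(mask.sum())
        md = md.loc[~mask]
        report.add(name, removed, len(md))

    bmi = pd.to_numeric(md.get("bmi"), errors="coerce")
    _drop(bmi > cfg.bmi_max, "bmi_above_max")
    bmi = pd.to_numeric(md.get("bmi"), errors="coerce")
    _drop(bmi < cfg.bmi_min, "bmi_below_min")
    age = pd.to_numeric(md.get("age"), errors="coerce")
    _drop(age.isna(), "age_missing")
    age = pd.to_numeric(md.get("age"), errors="coerce")
    _drop(age > cfg.age_max, "age_above_max")
    age = pd.to_numeric(md.get("age"), errors="coerce")
    _drop(age < cfg.age_min, "age_below_min")
    _drop(~md.index.isin(table.sample_ids), "not_in_table")
    eth = md.get("ethnicity")
    if cfg.known_ethnicities is None:
        _drop(eth.isna() | eth.astype(str).str.lower().isin(
            ["other", "unknown", ""]), "unknown_ethnicity")
    else:
        _drop(~eth.isin(cfg.known_ethnicities), "unknown_ethnicity")
    _drop(md.get("body_site").ne(cfg.required_site), "not_required_site")
    _drop(~md.get("sex").isin(["male", "female"]), "unknown_sex")
    _drop(~md.get("country").isin(cfg.accepted_countries), "country")

    if len(md) == 0:
        raise ValueError("all samples removed by quality control")

    sub = table.select_samples(list(md.index))
    otu_totals = sub.counts.sum(axis=0)
    keep_otus = [o for o, t in zip(sub.otu_ids, otu_totals)
                 if t >= cfg.min_otu_total]
    report.otus_removed = sub.n_otus - len(keep_otus)
    sub = sub.select_otus(keep_otus)
    depths = sub.sample_depths()
    keep_samples = [s for s, d in zip(sub.sample_ids, depths)
                    if d >= cfg.min_sample_depth]
    report.add("sample_depth", sub.n_samples - len(keep_samples),
               len(keep_samples))
    if not keep_samples:
        raise ValueError("all samples removed by quality control")
    sub = sub.select_samples(keep_samples)
    md = md.loc[keep_samples]
    return sub, md, report


# ---------------------------------------------------------------------------
# taxonomy collapse

COLLAPSE_RANKS = ("phylum", "class", "order", "family", "genus")


def parse_lineage(tax_string: str) -> list[str]:
    """Split a 7-rank greengenes-style string into per-rank fields."""
    fields = ["" for _ in RANKS]
    if not tax_string:
        return fields
    for part in tax_string.split(";"):
        part = part.strip()
        for i, pref in enumerate(RANK_PREFIXES):
            if part.startswith(pref):
                fields[i] = part
                break
    return fields


def _collapse_label(tax_string: str, rank_idx: int) -> str:
    fields = parse_lineage(tax_string)
    if not any(fields):
        return "Unassigned"
    out = []
    last_classified = -1
    for i in range(rank_idx + 1):
        f = fields[i]
        if f and f not in RANK_PREFIXES:
            last_classified = i
    for i in range(rank_idx + 1):
        f = fields[i]
        if i <= last_classified:
            out.append(f if f else RANK_PREFIXES[i])
        else:
            out.append(RANK_PREFIXES[i] + "Unclassified")
    return "; ".join(out)


def collapse_taxonomy(table: CountTable, rank: str) -> TaxonTable:
    """Sum OTUs sharing the lineage prefix through ``rank`` and close rows
    to relative abundance.

    OTUs unclassified at ``rank`` are kept distinct within their deepest
    classified parent (e.g. an OTU with ``g__`` under ``f__X`` collapses to
    ``...; f__X; g__Unclassified``), so collapsing at genus then summing
    within families is consistent with collapsing at family.
    """
    if rank not in COLLAPSE_RANKS:
        raise ValueError(f"rank must be one of {COLLAPSE_RANKS}, got {rank!r}")
    rank_idx = RANKS.index(rank)
    labels: list[str] = []
    label_index: dict[str, int] = {}
    cols = np.empty(table.n_otus, dtype=np.int64)
    for j, otu in enumerate(table.otu_ids):
        lab = _collapse_label(table.taxonomy.get(otu, ""), rank_idx)
        if lab not in label_index:
            label_index[lab] = len(labels)
            labels.append(lab)
        cols[j] = label_index[lab]
    collapsed = np.zeros((table.n_samples, len(labels)), dtype=np.int64)
    np.add.at(collapsed.T, cols, table.counts.T)
    depths = collapsed.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = collapsed / depths[:, None]
    rel[depths == 0, :] = 0.0
    return TaxonTable(list(table.sample_ids), labels, rel, rank,
                      counts=collapsed)


# ---------------------------------------------------------------------------
# metadata factor structure


def compare_factor_proportions(metadata: pd.DataFrame, factor: str,
                               group_col: str = "ethnicity",
                               groups: list[str] | None = None
                               ) -> pd.DataFrame:
    """Two-proportion Z tests of a categorical factor between group pairs.

    For every level of ``factor`` and every pair of groups, tests whether
    the proportion of samples at that level differs between the groups;
    p-values are Bonferroni-corrected within the factor for the number of
    pairwise group comparisons.
    """
    md = metadata.dropna(subset=[factor, group_col])
    if groups is None:
        groups = sorted(md[group_col].unique())
    levels = sorted(md[factor].astype(str).unique())
    pairs = list(combinations(groups, 2))
    rows = []
    for level in levels:
        for ga, gb in pairs:
            a = md.loc[md[group_col] == ga, factor].astype(str)
            b = md.loc[md[group_col] == gb, factor].astype(str)
            na, nb = len(a), len(b)
            if na == 0 or nb == 0:
                rows.append((level, ga, gb, np.nan, np.nan, np.nan, True))
                continue
            xa, xb = int((a == level).sum()), int((b == level).sum())
            if xa + xb == 0 or xa + xb == na + nb:
                z, p = 0.0, 1.0
            else:
                z, p = proportions_ztest([xa, xb], [na, nb])
            rows.append((level, ga, gb, z, p, min(1.0, p * len(pairs)), False))
    return pd.DataFrame(rows, columns=["level", "group_a", "group_b",
                                       "z", "p", "p_bonf", "skipped"])
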