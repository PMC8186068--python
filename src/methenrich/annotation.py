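"""CpG-to-gene annotation model for Illumina-style methylation arrays.

A methylation array measures methylation at individual CpG dinucleotides,
each identified by a probe id and a single 1-based genomic basepair.  The
manifest annotates each probe with zero or more genes (a probe falling in a
region where genes overlap is annotated to several genes, one line per
transcript) together with a genomic-feature label per transcript (TSS1500,
TSS200, 5'UTR, 1stExon, Body, 3'UTR, ExonBnd).

This module parses such tables, collapses transcript-level entries to unique
gene links, and derives the two quantities that drive bias correction
downstream:

* the multi-gene weight ``w = 1/k`` of a CpG annotated to ``k`` genes, and
* the *equivalent CpG count* ``N_j`` of gene ``j`` — the sum of the weights
  of its CpGs, i.e. the integer probe count discounted for probes shared
  with other genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Canonical genomic-feature labels used by Illumina manifests.  Other labels
#: are accepted (annotation dialects vary) but trigger a warning when used in
#: :func:`restrict_by_feature`.
FEATURE_LABELS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "ExonBnd")

#: Default column-name mapping for annotation files written by this package.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "cpg_id": "cpg_id",
    "chrom": "chrom",
    "pos": "pos",
    "genes": "genes",
    "features": "features",
}

#: Column mapping matching CSV exports of the Illumina manifest annotation
#: packages (450K / EPIC).
ILLUMINA_COLUMNS: Mapping[str, str] = {
    "cpg_id": "Name",
    "chrom": "chr",
    "pos": "pos",
    "genes": "UCSC_RefGene_Name",
    "features": "UCSC_RefGene_Group",
}


@dataclass(frozen=True)
class CpGSite:
    """A single measured CpG with its (deduplicated) gene links.

    ``gene_links`` maps gene id to the frozenset of feature labels under
    which the gene was listed for this CpG; it is empty for unannotated
    probes.
    """

    cpg_id: str
    chrom: str
    pos: int
    gene_links: Mapping[str, frozenset] = field(default_factory=dict)

    @property
    def genes(self) -> tuple:
        return tuple(self.gene_links)


class AnnotationTable:
    """The CpG universe: every probe on the array plus its gene links.

    Internally two data frames are held:

    ``sites``
        one row per CpG — columns ``cpg_id``, ``chrom``, ``pos``.
    ``links``
        one row per (CpG, gene) pair — columns ``cpg_id``, ``gene``,
        ``features`` (a frozenset of labels).  A gene appears at most once
        per CpG.
    """

    def __init__(self, sites: pd.DataFrame, links: pd.DataFrame, *, validate: bool = True):
        sites = sites.reset_index(drop=True)
        links = links.reset_index(drop=True)
        if validate:
            missing = {"cpg_id", "chrom", "pos"} - set(sites.columns)
            if missing:
                raise FormatError(f"sites frame missing columns: {sorted(missing)}")
            missing = {"cpg_id", "gene", "features"} - set(links.columns)
            if missing:
                raise FormatError(f"links frame missing columns: {sorted(missing)}")
            if sites["cpg_id"].duplicated().any():
                dups = sites.loc[sites["cpg_id"].duplicated(), "cpg_id"].head().tolist()
                raise ValidationError(f"duplicate cpg_id values, e.g. {dups}")
            if (sites["pos"] < 1).any():
                raise ValidationError("CpG positions must be 1-based (>= 1)")
            if links.duplicated(subset=["cpg_id", "gene"]).any():
                raise ValidationError("a gene may be linked to a CpG at most once")
            unknown = set(links["cpg_id"]) - set(sites["cpg_id"])
            if unknown:
                raise ValidationError(f"links refer to unknown CpGs, e.g. {sorted(unknown)[:5]}")
        self.sites = sites
        self.links = links
        self._cpg_index = pd.Index(sites["cpg_id"])
        self._pos_cache: dict | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_cpgs(self) -> int:
        return len(self.sites)

    @property
    def cpg_ids(self) -> pd.Index:
        return self._cpg_index

    @property
    def genes(self) -> pd.Index:
        return pd.Index(np.sort(self.links["gene"].unique()))

    def site(self, cpg_id: str) -> CpGSite:
        i = self._cpg_index.get_loc(cpg_id)
        row = self.sites.iloc[i]
        sub = self.links[self.links["cpg_id"] == cpg_id]
        gl = {g: fs for g, fs in zip(sub["gene"], sub["features"])}
        return CpGSite(row["cpg_id"], row["chrom"], int(row["pos"]), gl)

    def positions_by_chrom(self) -> dict:
        """``chrom -> (sorted 1-based positions, cpg ids in that order)``; cached."""
        if self._pos_cache is None:
            cache = {}
            for chrom, sub in self.sites.groupby("chrom", sort=False):
                order = np.argsort(sub["pos"].to_numpy(), kind="stable")
                cache[str(chrom)] = (
                    sub["pos"].to_numpy()[order],
                    sub["cpg_id"].to_numpy()[order],
                )
            self._pos_cache = cache
        return self._pos_cache


def _split_field(value) -> list:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value).strip()
    if not text:
        return []
    return text.split(";")


def load_annotation(
    path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> AnnotationTable:
    """Read a manifest-like CSV/TSV into an :class:`AnnotationTable`.

    ``columns`` maps the logical names (cpg_id, chrom, pos, genes, features)
    to the file's column headers, so real Illumina manifest exports and
    synthetic files share this one reader.  ``sep`` defaults to tab for
    ``.tsv``/``.txt`` files and comma otherwise.

    Transcript-level duplicates are collapsed: a gene listed several times
    for one CpG becomes a single link whose feature set is the union of the
    listed labels.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise FormatError(f"annotation file {path} missing required columns: {missing}")

    cpg_ids = df[colmap["cpg_id"]]
    if cpg_ids.duplicated().any():
        dups = cpg_ids[cpg_ids.duplicated()].head().tolist()
        raise ValidationError(f"duplicate cpg_id in {path}: {dups}")
    try:
        pos = df[colmap["pos"]].astype(float).astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer position in {path}: {exc}") from exc

    link_rows = []
    for cpg, genes_s, feats_s in zip(cpg_ids, df[colmap["genes"]], df[colmap["features"]]):
        genes = _split_field(genes_s)
        feats = _split_field(feats_s)
        if not genes:
            continue
        if feats and len(feats) != len(genes):
            raise ValidationError(
                f"CpG {cpg}: {len(genes)} genes but {len(feats)} feature labels"
            )
        if not feats:
            feats = [""] * len(genes)
        merged: dict[str, set] = {}
        for g, f in zip(genes, feats):
            merged.setdefault(g, set())
            if f:
                merged[g].add(f)
        for g, fs in merged.items():
            link_rows.append((cpg, g, frozenset(fs)))

    sites = pd.DataFrame(
        {"cpg_id": cpg_ids, "chrom": df[colmap["chrom"]], "pos": pos}
    )
    links = pd.DataFrame(link_rows, columns=["cpg_id", "gene", "features"])
    return AnnotationTable(sites, links)


def write_annotation(annot: AnnotationTable, path, sep: str = ",") -> None:
    """Write the table back in the default column layout (inverse of
    :func:`load_annotation` with default columns)."""
    gene_strs = {}
    feat_strs = {}
    for cpg, sub in annot.links.groupby("cpg_id", sort=False):
        gene_strs[cpg] = ";".join(sub["gene"])
        feat_strs[cpg] = ";".join(
            ";".join(sorted(fs)) if fs else "" for fs in sub["features"]
        )
    out = annot.sites.copy()
    out["genes"] = out["cpg_id"].map(gene_strs).fillna("")
    out["features"] = out["cpg_id"].map(feat_strs).fillna("")
    out.to_csv(path, sep=sep, index=False)


def compute_weights(annot: AnnotationTable) -> pd.Series:
    """Multi-gene weight per annotated CpG: ``w = 1 / (#genes linked)``.

    Unannotated CpGs are absent from the returned series.
    """
    k = annot.links.groupby("cpg_id", sort=False).size()
    return (1.0 / k).rename("w")


class GeneIndex:
    """Per-gene equivalent CpG counts and the weighted CpG lists behind them.

    Also carries flat numpy views of the link table (``link_cpg``,
    ``link_gene``, ``link_w`` — parallel arrays of CpG row index, gene row
    index and weight) which the enrichment engine uses for vectorised
    scoring.
    """

    def __init__(self, annot: AnnotationTable, weights: pd.Series):
        links = annot.links
        self.cpg_index = annot.cpg_ids
        self.genes = pd.Index(np.sort(links["gene"].unique()))
        self.link_cpg = self.cpg_index.get_indexer(links["cpg_id"]).astype(np.int64)
        self.link_gene = self.genes.get_indexer(links["gene"]).astype(np.int64)
        self.link_w = weights.reindex(links["cpg_id"]).to_numpy(dtype=float)
        L = len(self.genes)
        self.equiv_counts = np.bincount(self.link_gene, weights=self.link_w, minlength=L)
        self.raw_counts = np.bincount(self.link_gene, minlength=L)
        self.n_annotated_cpgs = int(pd.unique(links["cpg_id"]).size)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def equivalent_counts(self) -> pd.Series:
        """``N_j`` per gene, as a series indexed by gene id."""
        return pd.Series(self.equiv_counts, index=self.genes, name="N")

    @property
    def raw_cpg_counts(self) -> pd.Series:
        """Integer probe count per gene (multi-gene probes counted fully)."""
        return pd.Series(self.raw_counts, index=self.genes, name="n_cpgs")

    def gene_cpgs(self, gene: str) -> pd.DataFrame:
        """The (cpg_id, w) list for one gene."""
        j = self.genes.get_loc(gene)
        mask = self.link_gene == j
        return pd.DataFrame(
            {"cpg_id": self.cpg_index[self.link_cpg[mask]], "w": self.link_w[mask]}
        )


def build_gene_index(annot: AnnotationTable, weights: pd.Series | None = None) -> GeneIndex:
    """Build the gene universe with equivalent CpG counts ``N_j = Σ_i w_ij``."""
    if weights is None:
        weights = compute_weights(annot)
    return GeneIndex(annot, weights)


def restrict_by_feature(annot: AnnotationTable, features: Iterable[str]) -> AnnotationTable:
    """Keep only gene links carrying at least one of the given feature labels.

    CpGs whose links are all removed become unannotated but stay in the
    table.  Weights and the gene index must be recomputed from the returned
    table — a CpG that loses links gains weight on those it keeps.
    """
    features = set(features)
    if not features:
        raise ValueError("features must be a non-empty set of labels")
    present: set = set()
    for fs in annot.links["features"]:
        present |= fs
    unknown = features - present
    if unknown:
        warnings.warn(
            f"feature labels not present in the annotation: {sorted(unknown)}",
            stacklevel=2,
        )
    keep = annot.links["features"].map(lambda fs: bool(fs & features))
    return AnnotationTable(annot.sites, annot.links[keep], validate=False)


def composition_summary(annot: AnnotationTable) -> dict:
    """Array-composition diagnostics: probe-number and multi-gene structure.

    Returns CpGs-per-gene summaries (raw integer counts), the fraction of
    CpGs annotated to at least one gene, and the fraction of gene-annotated
    CpGs linked to two or more genes.  All values are 0/NaN-flagged for an
    empty table.
    """
    n_cpgs = annot.n_cpgs
    if n_cpgs == 0 or annot.links.empty:
        return {
            "n_cpgs": n_cpgs,
            "n_genes": 0,
            "frac_annotated": 0.0 if n_cpgs else float("nan"),
            "frac_multi_gene": float("nan"),
            "cpgs_per_gene_min": float("nan"),
            "cpgs_per_gene_median": float("nan"),
            "cpgs_per_gene_max": float("nan"),
            "cpgs_per_gene_mode": float("nan"),
        }
    per_gene = annot.links.groupby("gene", sort=False).size().to_numpy()
    genes_per_cpg = annot.links.groupby("cpg_id", sort=False).size()
    n_annot = len(genes_per_cpg)
    values, counts = np.unique(per_gene, return_counts=True)
    return {
        "n_cpgs": n_cpgs,
        "n_genes": len(per_gene),
        "frac_annotated": n_annot / n_cpgs,
        "frac_multi_gene": float((genes_per_cpg >= 2).sum()) / n_annot,
        "cpgs_per_gene_min": int(per_gene.min()),
        "cpgs_per_gene_median": float(np.median(per_gene)),
        "cpgs_per_gene_max": int(per_gene.max()),
        "cpgs_per_gene_mode": int(values[np.argmax(counts)]),
    }
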