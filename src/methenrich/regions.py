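"""Gene set testing for differentially methylated regions (DMRs).

Region finders (DMRcate, bumphunter, ...) output genomic intervals rather
than probes.  The region route here filters the DMR list, overlaps the
surviving intervals with the array's CpG positions to recover the set of
probes underlying the regions, and hands that set to the probe-level
engine — so the region test inherits the probe-number and multi-gene bias
corrections unchanged.

Coordinates are stored 0-based half-open (BED convention).  A CpG at
1-based basepair ``p`` lies in region ``[start, end)`` iff
``start <= p - 1 < end``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .enrich import SignificantSet, test_gene_sets
from .errors import FormatError, ValidationError
from .genesets import GeneSetCollection


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open, with optional DMR metadata."""

    chrom: str
    start: int
    end: int
    no_cpgs: Optional[int] = None
    mean_delta_beta: Optional[float] = None

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("region chromosome must be non-empty")
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end} has start >= end"
            )


class RegionSet:
    """An ordered collection of regions; duplicates are allowed but flagged."""

    def __init__(self, regions):
        self.regions = list(regions)
        seen = set()
        dups = 0
        for r in self.regions:
            key = (r.chrom, r.start, r.end)
            if key in seen:
                dups += 1
            seen.add(key)
        if dups:
            warnings.warn(f"region set contains {dups} duplicate intervals", stacklevel=2)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "no_cpgs": [r.no_cpgs for r in self.regions],
                "mean_delta_beta": [r.mean_delta_beta for r in self.regions],
            }
        )


def load_regions(path, dialect: str = "BED", one_based: bool = True) -> RegionSet:
    """Read DMRs from a BED file or a named-column CSV.

    BED is 0-based half-open with at least 3 columns and no header.  CSV
    must carry ``chrom``/``start``/``end`` columns (``no_cpgs`` and
    ``mean_delta_beta`` are picked up when present); its coordinates are
    taken as 1-based inclusive by default — the common DMR-caller
    convention — and converted on load (``one_based=False`` for half-open
    input).
    """
    regions = []
    if dialect == "BED":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: BED line has < 3 columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
                try:
                    regions.append(Region(fields[0], start, end))
                except ValidationError as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    elif dialect == "CSV":
        df = pd.read_csv(path)
        required = {"chrom", "start", "end"} - set(df.columns)
        if required:
            raise FormatError(f"{path}: missing columns {sorted(required)}")
        shift = 1 if one_based else 0
        for i, row in df.iterrows():
            kwargs = {}
            if "no_cpgs" in df.columns and pd.notna(row["no_cpgs"]):
                kwargs["no_cpgs"] = int(row["no_cpgs"])
            if "mean_delta_beta" in df.columns and pd.notna(row["mean_delta_beta"]):
                kwargs["mean_delta_beta"] = float(row["mean_delta_beta"])
            try:
                regions.append(
                    Region(str(row["chrom"]), int(row["start"]) - shift,
                           int(row["end"]), **kwargs)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from exc
    else:
        raise ValueError(f"unknown region dialect {dialect!r}; use 'BED' or 'CSV'")
    return RegionSet(regions)


def filter_regions(
    regions: RegionSet,
    min_cpgs: Optional[int] = 3,
    min_abs_delta_beta: Optional[float] = 0.1,
) -> RegionSet:
    """Keep regions with ``no_cpgs >= min_cpgs`` and ``|mean Δβ| >=
    min_abs_delta_beta`` (both bounds inclusive — removal is for strictly
    smaller values).  Pass ``None`` to disable either threshold; with both
    disabled this is the identity.
    """
    kept = []
    for r in regions:
        if min_cpgs is not None:
            if r.no_cpgs is None:
                raise ValidationError(
                    f"region {r.chrom}:{r.start}-{r.end} lacks no_cpgs but the "
                    "CpG-count filter is active"
                )
            if r.no_cpgs < min_cpgs:
                continue
        if min_abs_delta_beta is not None:
            if r.mean_delta_beta is None:
                raise ValidationError(
                    f"region {r.chrom}:{r.start}-{r.end} lacks mean_delta_beta but "
                    "the effect-size filter is active"
                )
            if abs(r.mean_delta_beta) < min_abs_delta_beta:
                continue
        kept.append(r)
    return RegionSet(kept)


def regions_to_cpgs(regions: RegionSet, annot: AnnotationTable) -> SignificantSet:
    """The deduplicated union of array CpGs whose basepair falls in any region."""
    by_chrom = annot.positions_by_chrom()
    hits: set = set()
    for r in regions:
        entry = by_chrom.get(r.chrom)
        if entry is None:
            continue
        pos, ids = entry
        # CpG pos is 1-based; region is 0-based half-open
        lo = np.searchsorted(pos, r.start + 1, side="left")
        hi = np.searchsorted(pos, r.end, side="right")
        hits.update(ids[lo:hi])
    if not hits:
        raise ValueError(
            "no array CpGs underlie the supplied regions; check coordinate "
            "conventions and chromosome naming"
        )
    return SignificantSet(hits)


def goregion(
    regions: RegionSet,
    annot: AnnotationTable,
    sets: GeneSetCollection,
    method: str = "GOmeth",
    span: float = 0.5,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Region-level gene set test: overlap DMRs with CpGs, then delegate.

    Identical by construction to running the probe-level test on
    ``regions_to_cpgs(regions, annot)``.  Filtering is the caller's choice
    (see :func:`filter_regions`); none is applied here.
    """
    if len(regions) == 0:
        raise ValueError("region set is empty")
    sig = regions_to_cpgs(regions, annot)
    return test_gene_sets(sig, annot, sets, method=method, span=span, adjust=adjust)
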