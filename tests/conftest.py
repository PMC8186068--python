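"""Shared fixtures: tiny hand-built annotations and a small synthetic dataset."""

import pandas as pd
import pytest

from methenrich import AnnotationTable, GeneSetCollection, SyntheticConfig, generate_dataset


def make_annotation(rows):
    """Build an AnnotationTable from (cpg_id, chrom, pos, links) tuples,
    where links is a list of (gene, feature) pairs (feature may be "")."""
    sites = pd.DataFrame(
        [(c, ch, p) for c, ch, p, _ in rows], columns=["cpg_id", "chrom", "pos"]
    )
    link_rows = []
    for c, _, _, links in rows:
        merged = {}
        for g, f in links:
            merged.setdefault(g, set())
            if f:
                merged[g].add(f)
        for g, fs in merged.items():
            link_rows.append((c, g, frozenset(fs)))
    links = pd.DataFrame(link_rows, columns=["cpg_id", "gene", "features"])
    return AnnotationTable(sites, links)


@pytest.fixture
def fig2_annot():
    """Two genes: gene1 with 3 CpGs, gene2 with 8, one CpG shared.

    Equivalent counts are N1 = 2.5 and N2 = 7.5 over 10 distinct CpGs.
    """
    rows = [
        ("cg01", "chr1", 100, [("GENE1", "Body")]),
        ("cg02", "chr1", 200, [("GENE1", "Body")]),
        ("cg03", "chr1", 300, [("GENE1", "Body"), ("GENE2", "TSS200")]),
        *[
            (f"cg{i:02d}", "chr1", 100 * i, [("GENE2", "Body")])
            for i in range(4, 11)
        ],
    ]
    return make_annotation(rows)


@pytest.fixture
def shared22_annot():
    """One CpG annotated to a cluster of 22 genes (protocadherin-like), plus
    30 background genes with 5 exclusive CpGs each; each cluster gene also
    has 3 exclusive CpGs."""
    rows = [("cgSHARED", "chr5", 1000, [(f"PC{k:02d}", "Body") for k in range(22)])]
    pos = 2000
    for k in range(22):
        for i in range(3):
            rows.append((f"cgPC{k:02d}_{i}", "chr5", pos, [(f"PC{k:02d}", "Body")]))
            pos += 100
    for b in range(30):
        for i in range(5):
            rows.append((f"cgBG{b:02d}_{i}", "chr6", 100 * (5 * b + i + 1),
                         [(f"BG{b:02d}", "Body")]))
    return make_annotation(rows)


@pytest.fixture
def shared22_sets():
    """The 22-gene cluster as one set, plus two background sets."""
    return GeneSetCollection.from_dict(
        {
            "CLUSTER": [f"PC{k:02d}" for k in range(22)],
            "BGSET1": [f"BG{b:02d}" for b in range(15)],
            "BGSET2": [f"BG{b:02d}" for b in range(15, 30)],
        }
    )


@pytest.fixture(scope="session")
def small_synth():
    """A 300-gene synthetic dataset with default composition."""
    cfg = SyntheticConfig(n_genes=300, n_sets=30, seed=11)
    return generate_dataset(cfg)
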