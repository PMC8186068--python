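"""Synthetic arrays, gene sets and null experiments.

The generator emulates the composition features of Illumina methylation
arrays that drive the biases the tests correct:

* a heavy-tailed CpGs-per-gene distribution (default: negative binomial
  with median raw count ≈ 20, minimum 1, tail into the hundreds);
* a configurable fraction of gene-annotated CpGs shared between two
  adjacent genes (default 9%), with genes that co-occur in the same
  synthetic gene set preferentially placed next to each other so that
  shared CpGs tend to connect functionally related genes — the mechanism
  behind multi-gene false positives;
* a fraction of probes annotated to no gene at all (default 30%).

Everything is a pure function of (config, seed): the same inputs always
yield byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationTable
from .enrich import GenesetTester, SignificantSet
from .genesets import GeneSet, GeneSetCollection

_FEATURES = np.array(["Body", "TSS1500", "TSS200", "5'UTR", "1stExon", "3'UTR", "ExonBnd"])
_FEATURE_P = np.array([0.45, 0.13, 0.10, 0.12, 0.05, 0.10, 0.05])

_N_CHROMS = 20


@dataclass(frozen=True)
class CountDistribution:
    """A small distribution spec for integer counts.

    Families: ``nbinom`` (params ``r``, ``mean``, optional ``min``),
    ``uniform`` (``low``, ``high`` inclusive), ``fixed`` (``values`` cycled
    in order).
    """

    family: str
    params: Mapping

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "nbinom":
            r, mean = p["r"], p["mean"]
            prob = r / (r + mean)
            draws = rng.negative_binomial(r, prob, size)
            return np.maximum(draws, p.get("min", 1)).astype(np.int64)
        if self.family == "uniform":
            return rng.integers(p["low"], p["high"] + 1, size).astype(np.int64)
        if self.family == "fixed":
            values = np.asarray(p["values"], dtype=np.int64)
            return np.resize(values, size)
        raise ValueError(f"unknown count distribution family {self.family!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; ``seed`` fully determines every output."""

    n_genes: int = 10_000
    cpgs_per_gene: CountDistribution = field(
        default_factory=lambda: CountDistribution("nbinom", {"r": 1.2, "mean": 27.0, "min": 1})
    )
    multi_gene_fraction: float = 0.09
    unannotated_fraction: float = 0.30
    n_sets: int = 300
    set_size: CountDistribution = field(
        default_factory=lambda: CountDistribution("uniform", {"low": 10, "high": 500})
    )
    cluster_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.multi_gene_fraction < 1:
            raise ValueError("multi_gene_fraction must lie in [0, 1)")
        if not 0 <= self.unannotated_fraction < 1:
            raise ValueError("unannotated_fraction must lie in [0, 1)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _gene_names(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n)])


def generate_gene_sets(cfg: SyntheticConfig) -> GeneSetCollection:
    """Synthetic gene set collection; shares the config seed with
    :func:`generate_annotation` so the two are mutually consistent."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    names = _gene_names(cfg.n_genes)
    sizes = np.minimum(cfg.set_size.sample(rng, cfg.n_sets), cfg.n_genes)
    sets = []
    for k in range(cfg.n_sets):
        members = rng.choice(cfg.n_genes, size=sizes[k], replace=False)
        sets.append(GeneSet(f"SET{k:04d}", f"synthetic set {k}", tuple(names[np.sort(members)])))
    return GeneSetCollection(sets)


def generate_annotation(cfg: SyntheticConfig) -> AnnotationTable:
    """Generate a synthetic array annotation.

    Genes are laid out contiguously along synthetic chromosomes, ordered so
    that members of the same gene set cluster with probability
    ``cluster_prob``.  A fraction of gene-annotated CpGs is merged with a
    CpG of the next gene in the layout (one probe, two gene links), and a
    further block of probes carries no gene annotation.
    """
    sets = generate_gene_sets(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    G = cfg.n_genes
    names = _gene_names(G)

    counts = cfg.cpgs_per_gene.sample(rng, G)

    # placement order: cluster same-set genes so shared CpGs connect them
    primary = np.full(G, -1, dtype=np.int64)
    name_pos = {n: i for i, n in enumerate(names)}
    for k, s in enumerate(sets.sets()):
        idx = np.array([name_pos[g] for g in s.genes], dtype=np.int64)
        fresh = idx[primary[idx] < 0]
        primary[fresh] = k
    key = np.where(
        (rng.random(G) < cfg.cluster_prob) & (primary >= 0),
        primary,
        cfg.n_sets + rng.integers(0, G, G),
    )
    perm = rng.permutation(G)  # random tie-break within equal keys
    order = perm[np.argsort(key[perm], kind="stable")]
    c = counts[order]

    # chromosome blocks over the placement order; few genes -> few chromosomes
    n_chroms = max(1, min(_N_CHROMS, G // 25)) if G >= 25 else 1
    bounds = np.linspace(0, G, n_chroms + 1).astype(np.int64)
    chrom_of = np.empty(G, dtype=np.int64)
    for ci in range(n_chroms):
        chrom_of[bounds[ci]:bounds[ci + 1]] = ci
    last_in_chrom = np.zeros(G, dtype=bool)
    last_in_chrom[bounds[1:] - 1] = True

    # shared (merged) CpGs between adjacent gene pairs: m'/(sum(c)-m') ~ f
    f = cfg.multi_gene_fraction
    total = int(c.sum())
    m = int(round(f / (1.0 + f) * total))
    s = np.zeros(G, dtype=np.int64)  # s[j]: CpGs shared between gene j and j+1
    if m > 0 and G > 1:
        cap = np.minimum(c, np.roll(c, -1))
        cap[last_in_chrom] = 0
        if cap.sum() == 0:
            raise ValueError("multi_gene_fraction infeasible for this layout")
        raw = rng.multinomial(m, cap / cap.sum())
        prev = 0
        for j in range(G):  # left-to-right feasibility pass
            if last_in_chrom[j]:
                s[j] = 0
                prev = 0
                continue
            s[j] = max(0, min(raw[j], c[j] - prev, c[j + 1 if j + 1 < G else j]))
            prev = s[j]

    h = c - np.concatenate([[0], s[:-1]])  # CpGs hosted (positioned) per gene
    h[bounds[:-1]] = c[bounds[:-1]]  # chrom-first genes receive no carry-over
    H = int(h.sum())

    # positions: small within-gene gaps, larger gaps between genes, per chrom
    host_gene = np.repeat(np.arange(G), h)
    gaps = rng.integers(20, 300, H)
    first_of_gene = np.zeros(H, dtype=bool)
    starts = np.cumsum(h) - h
    first_of_gene[starts[h > 0]] = True
    gaps[first_of_gene] += 2000
    pos = np.empty(H, dtype=np.int64)
    chrom_ids = np.empty(H, dtype=np.int64)
    for ci in range(n_chroms):
        sel = (chrom_of[host_gene] == ci)
        pos[sel] = np.cumsum(gaps[sel])
        chrom_ids[sel] = ci

    # links: every hosted CpG links its host gene; the last s[j] hosted CpGs
    # of gene j additionally link gene j+1
    link_rows = [np.arange(H)]
    link_genes = [host_gene]
    if s.sum() > 0:
        ends = np.cumsum(h) - 1
        off = np.arange(s.sum()) - np.repeat(np.cumsum(s) - s, s)
        donor_rows = np.repeat(ends, s) - off
        link_rows.append(donor_rows)
        link_genes.append(np.repeat(np.arange(G) + 1, s))
    link_row = np.concatenate(link_rows)
    link_gene_placed = np.concatenate(link_genes)

    # unannotated probes, interleaved on the same chromosomes
    u = cfg.unannotated_fraction
    n_un = int(round(H * u / (1.0 - u)))
    chrom_max = np.zeros(n_chroms, dtype=np.int64)
    for ci in range(n_chroms):
        sel = chrom_ids == ci
        if sel.any():
            chrom_max[ci] = pos[sel].max()
    un_chrom = rng.integers(0, n_chroms, n_un)
    un_pos = np.empty(n_un, dtype=np.int64)
    for ci in range(n_chroms):
        sel = un_chrom == ci
        need = int(sel.sum())
        if need == 0:
            continue
        taken = set(pos[chrom_ids == ci].tolist())
        out = np.empty(need, dtype=np.int64)
        got = 0
        while got < need:
            cand = rng.integers(1, max(chrom_max[ci], 1) + 200 * (need + 1), need - got)
            for v in np.unique(cand):
                if v not in taken and got < need:
                    taken.add(v)
                    out[got] = v
                    got += 1
        un_pos[sel] = out

    n_cpgs = H + n_un
    cpg_ids = np.array([f"cg{i:08d}" for i in range(n_cpgs)])
    chrom_names = np.array([f"chr{ci + 1}" for ci in range(n_chroms)])
    sites = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "chrom": np.concatenate([chrom_names[chrom_ids], chrom_names[un_chrom]]),
            "pos": np.concatenate([pos, un_pos]),
        }
    )
    feats = rng.choice(_FEATURES, size=len(link_row), p=_FEATURE_P)
    links = pd.DataFrame(
        {
            "cpg_id": cpg_ids[link_row],
            "gene": names[order[link_gene_placed]],
            "features": [frozenset((fx,)) for fx in feats],
        }
    )
    return AnnotationTable(sites, links)


def generate_dataset(cfg: SyntheticConfig):
    """Convenience: ``(annotation, gene_sets)`` from one config."""
    return generate_annotation(cfg), generate_gene_sets(cfg)


def sample_null_cpgs(annot: AnnotationTable, n_sig: int, seed: int) -> SignificantSet:
    """Uniform sample of CpGs (annotated or not) without replacement."""
    if n_sig > annot.n_cpgs:
        raise ValueError(f"n_sig={n_sig} exceeds the {annot.n_cpgs} CpGs on the array")
    rng = np.random.default_rng(seed)
    ids = rng.choice(annot.cpg_ids.to_numpy(), size=n_sig, replace=False)
    return SignificantSet(ids)


def simulate_null_two_group(
    annot: AnnotationTable,
    n_per_group: int,
    top_n: int,
    seed: int,
    sd_sigma: float = 0.25,
) -> SignificantSet:
    """Null two-group comparison: rank CpGs by |t| with no true group effect.

    Per-CpG values for ``2 * n_per_group`` samples are drawn from one shared
    normal model (CpG-specific mean ~ N(0,1), CpG-specific standard
    deviation lognormal with log-scale ``sd_sigma``); samples are split into
    two arbitrary groups, a two-sample pooled t-statistic is computed per
    CpG, and the ``top_n`` CpGs by |t| are returned as the "significant"
    set.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    if top_n > annot.n_cpgs:
        raise ValueError(f"top_n={top_n} exceeds the {annot.n_cpgs} CpGs on the array")
    rng = np.random.default_rng(seed)
    P = annot.n_cpgs
    mu = rng.normal(0.0, 1.0, P)
    sd = rng.lognormal(0.0, sd_sigma, P)
    data = rng.normal(mu, sd, size=(2 * n_per_group, P))
    g1, g2 = data[:n_per_group], data[n_per_group:]
    n = n_per_group
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    pooled = ((n - 1) * v1 + (n - 1) * v2) / (2 * n - 2)
    t = (g1.mean(axis=0) - g2.mean(axis=0)) / np.sqrt(pooled * (2.0 / n))
    top = np.argsort(-np.abs(t), kind="stable")[:top_n]
    return SignificantSet(annot.cpg_ids.to_numpy()[top])


@dataclass
class TypeIErrorResult:
    """Per-replicate fractions and per-(size, method) summaries."""

    replicates: pd.DataFrame
    summary: pd.DataFrame


def type1_error_experiment(
    annot: AnnotationTable,
    sets: GeneSetCollection,
    sizes: Sequence[int] = (50, 100, 500, 1000, 5000, 10_000),
    reps: int = 100,
    alpha: float = 0.05,
    methods: Sequence[str] = ("HGT", "HGT-mod", "GOmeth"),
    seed: int = 0,
    span: float = 0.5,
) -> TypeIErrorResult:
    """Null experiment: random CpG sets designated significant, repeatedly.

    For each set size and replicate a uniform random CpG sample is tested
    with every requested method against the same gene sets, and the
    fraction of sets reaching ``p < alpha`` is recorded.  A well-calibrated
    test keeps that fraction at or below ``alpha``.
    """
    tester = GenesetTester(annot, sets, span=span)
    master = np.random.default_rng(seed)
    draw_seeds = master.integers(0, 2**31 - 1, size=(len(sizes), reps))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for si, size in enumerate(sizes):
            for rep in range(reps):
                sig = sample_null_cpgs(annot, size, int(draw_seeds[si, rep]))
                for method in methods:
                    res = tester.test(sig, method=method)
                    frac = float((res["p"].to_numpy() < alpha).mean())
                    rows.append((size, rep, method, frac))
    replicates = pd.DataFrame(rows, columns=["size", "rep", "method", "frac_significant"])
    summary = (
        replicates.groupby(["size", "method"])["frac_significant"]
        .agg(
            mean="mean",
            median="median",
            q10=lambda v: float(np.quantile(v, 0.10)),
            q90=lambda v: float(np.quantile(v, 0.90)),
        )
        .reset_index()
    )
    return TypeIErrorResult(replicates, summary)
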