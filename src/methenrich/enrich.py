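"""Bias-aware over-representation testing of gene sets from significant CpGs.

The engine implements three test variants on a shared scaffold:

``HGT``
    the naive central hypergeometric test: a gene is "differentially
    methylated" if any of its CpGs is significant, and every such gene
    counts fully toward the overlap with each gene set.
``HGT-mod``
    corrects *probe-number bias* only: the overlap stays an integer gene
    count, but each set's draw odds come from a probability weighting
    function (PWF) — the smoothed empirical probability that a gene is
    called differentially methylated as a function of its raw CpG count —
    and the p-value comes from Wallenius' noncentral hypergeometric
    distribution.
``GOmeth``
    additionally corrects *multi-gene bias*: CpGs annotated to several
    genes contribute fractional weights, genes are scored
    ``S_j = min(Σ significant weights, 1)``, the overlap statistic is
    ``ES_g = Σ_{j∈g} S_j`` floored to an integer, and the PWF is estimated
    against equivalent CpG counts ``N_j``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import convolve
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationTable, GeneIndex, build_gene_index
from .genesets import GeneSetCollection
from .wallenius import wallenius_upper_tail_many

METHODS = ("HGT", "HGT-mod", "GOmeth")

#: Cap applied to a set's odds when the out-of-set PWF mean is zero
#: (degenerate; effectively impossible on real arrays).
ODDS_CAP = 1e6

RESULT_COLUMNS = [
    "set_id", "set_name", "J", "n_sig_genes", "ES", "odds", "p", "p_adj", "method",
]


@dataclass(frozen=True)
class SignificantSet:
    """The set ``A`` of CpGs designated differentially methylated.

    Members absent from the annotation (or unannotated) are permitted; they
    simply contribute to no gene.
    """

    cpg_ids: frozenset

    def __init__(self, cpg_ids: Iterable[str]):
        object.__setattr__(self, "cpg_ids", frozenset(cpg_ids))

    def __len__(self) -> int:
        return len(self.cpg_ids)

    @classmethod
    def from_file(cls, path) -> "SignificantSet":
        """One CpG id per line; blank lines ignored."""
        with open(path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        return cls(ids)

    @classmethod
    def from_ranked(
        cls,
        table,
        top: int,
        id_col: str | None = None,
        rank_col: str | None = None,
        ascending: bool = True,
    ) -> "SignificantSet":
        """Take the ``top`` most highly ranked CpGs from a statistics table.

        ``table`` is a data frame or a TSV/CSV path.  By default the first
        column holds CpG ids and the second the ranking statistic, sorted
        ascending (p-value convention); pass ``ascending=False`` for
        statistics where large means significant.
        """
        if not isinstance(table, pd.DataFrame):
            sep = "\t" if str(table).endswith((".tsv", ".txt")) else ","
            table = pd.read_csv(table, sep=sep)
        id_col = id_col or table.columns[0]
        rank_col = rank_col or table.columns[1]
        if top > len(table):
            raise ValueError(f"top={top} exceeds table length {len(table)}")
        order = table.sort_values(rank_col, ascending=ascending, kind="mergesort")
        return cls(order[id_col].head(top))


def _as_cpg_ids(sig) -> frozenset:
    return sig.cpg_ids if isinstance(sig, SignificantSet) else frozenset(sig)


def compute_gene_scores(sig, index: GeneIndex) -> pd.Series:
    """Differential methylation score ``S_j = min(Σ_{i∈A} w_ij, 1)`` per gene.

    Every gene in the universe is retained; genes with no significant CpG
    score 0.  Significant CpGs unknown to the index are ignored here (the
    engine reports their count separately).
    """
    ids = _as_cpg_ids(sig)
    if not ids:
        warnings.warn("empty significant set: all gene scores are zero", stacklevel=2)
    codes = index.cpg_index.get_indexer(list(ids))
    flag = np.zeros(len(index.cpg_index), dtype=bool)
    flag[codes[codes >= 0]] = True
    hit = flag[index.link_cpg]
    s = np.bincount(index.link_gene[hit], weights=index.link_w[hit], minlength=len(index))
    return pd.Series(np.minimum(s, 1.0), index=index.genes, name="S")


def _tricube_kernel(half: int) -> np.ndarray:
    u = np.arange(-half, half + 1) / (half + 1)
    return (1.0 - np.abs(u) ** 3) ** 3


def _tricube_smooth(dm: np.ndarray, span: float, den: np.ndarray | None = None) -> np.ndarray:
    """Centered tricube moving average with edge truncation + renormalisation.

    Window width is ``2*floor(span*L/2) + 1``; at the edges the window is
    truncated and the kernel weights renormalised over the surviving part,
    so a constant input is reproduced exactly.
    """
    L = len(dm)
    half = int(span * L) // 2
    if half == 0:
        return dm.astype(float)
    k = _tricube_kernel(half)
    num = convolve(dm.astype(float), k, mode="same")
    if den is None:
        den = convolve(np.ones(L), k, mode="same")
    return np.clip(num / den, 0.0, 1.0)


def estimate_pwf(
    scores: pd.Series,
    index: GeneIndex,
    span: float = 0.5,
    bias_counts: str = "equivalent",
) -> pd.DataFrame:
    """Probability weighting function: P(gene is differentially methylated)
    as a smooth function of its CpG count.

    Genes are ordered by ``N_j`` (``bias_counts="equivalent"``) or by raw
    integer CpG count (``"raw"``), ties broken by gene id, and the binary
    indicator ``dm = (S > 0)`` is smoothed with a tricube moving average.
    Returns a frame (gene_id, N, dm, pwf) in that order.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if bias_counts not in ("equivalent", "raw"):
        raise ValueError("bias_counts must be 'equivalent' or 'raw'")
    if len(index) == 0:
        raise ValueError("empty gene universe")
    counts = index.equiv_counts if bias_counts == "equivalent" else index.raw_counts
    # index.genes is sorted, so a stable sort on counts yields (N, gene_id) order
    order = np.argsort(counts, kind="stable")
    dm = (scores.reindex(index.genes).to_numpy() > 0).astype(float)
    pwf = _tricube_smooth(dm[order], span)
    return pd.DataFrame(
        {
            "gene_id": index.genes[order],
            "N": counts[order],
            "dm": dm[order].astype(int),
            "pwf": pwf,
        }
    )


def compute_odds(pwf_table: pd.DataFrame, gene_set: Iterable[str]) -> float:
    """Wallenius odds for one set: mean PWF inside / mean PWF outside.

    Both means are taken over the array universe only.
    """
    members = pwf_table["gene_id"].isin(set(gene_set)).to_numpy()
    if not members.any():
        raise ValueError("gene set has no genes in the array universe")
    if members.all():
        raise ValueError("gene set covers the whole universe; odds undefined")
    pwf = pwf_table["pwf"].to_numpy()
    mean_in = pwf[members].mean()
    mean_out = pwf[~members].mean()
    if mean_out == 0:
        warnings.warn("out-of-set PWF mean is zero; capping odds", stacklevel=2)
        return ODDS_CAP
    return float(mean_in / mean_out)


def enrichment_statistic(scores: pd.Series, gene_set: Iterable[str]) -> float:
    """Weighted overlap ``ES_g = Σ_{j ∈ g ∩ universe} S_j``."""
    members = scores.index.intersection(pd.Index(set(gene_set)))
    return float(scores.loc[members].sum())


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Holm adjustment, monotone and capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "Holm": "holm"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}; use 'BH' or 'Holm'")
    if p.size == 0:
        return p
    return multipletests(p, method=key)[1]


class GenesetTester:
    """Precomputed state for testing one gene set collection against one
    annotation, so repeated calls (null simulations) stay cheap.

    Construction intersects every set with the array's gene universe, drops
    untestable sets (empty intersection, or covering the whole universe)
    with a warning, and caches the membership matrix, both gene orderings
    and the smoother denominators.
    """

    def __init__(
        self,
        annot: AnnotationTable,
        sets: GeneSetCollection,
        span: float = 0.5,
        index: GeneIndex | None = None,
    ):
        if len(sets) == 0:
            raise ValueError("gene set collection is empty")
        if not 0 < span <= 1:
            raise ValueError("span must lie in (0, 1]")
        self.index = index if index is not None else build_gene_index(annot)
        U = len(self.index)
        if U < 2:
            raise ValueError(f"gene universe has {U} genes; need at least 2")
        self.span = span
        gene_pos = {g: i for i, g in enumerate(self.index.genes)}

        ids, names, rows = [], [], []
        dropped = []
        for s in sets.sets():
            member_idx = np.array(
                sorted(gene_pos[g] for g in s.genes if g in gene_pos), dtype=np.int64
            )
            if member_idx.size == 0 or member_idx.size == U:
                dropped.append(s.set_id)
                continue
            ids.append(s.set_id)
            names.append(s.name)
            rows.append(member_idx)
        if dropped:
            warnings.warn(
                f"{len(dropped)} gene sets untestable against this universe "
                f"(empty or full intersection), e.g. {dropped[:3]}",
                stacklevel=2,
            )
        if not ids:
            raise ValueError("no gene set intersects the array universe")
        self.set_ids = np.array(ids)
        self.set_names = np.array(names)
        self.membership = np.zeros((len(ids), U))
        for r, idx in enumerate(rows):
            self.membership[r, idx] = 1.0
        self.J = self.membership.sum(axis=1).astype(np.int64)

        self._orders = {
            "equivalent": np.argsort(self.index.equiv_counts, kind="stable"),
            "raw": np.argsort(self.index.raw_counts, kind="stable"),
        }
        L = U
        half = int(span * L) // 2
        self._den = (
            convolve(np.ones(L), _tricube_kernel(half), mode="same") if half else None
        )

    @property
    def universe_size(self) -> int:
        return len(self.index)

    def _pwf(self, dm: np.ndarray, bias_counts: str) -> np.ndarray:
        """PWF evaluated in universe gene order (scattered back)."""
        order = self._orders[bias_counts]
        smoothed = _tricube_smooth(dm[order].astype(float), self.span, self._den)
        out = np.empty_like(smoothed)
        out[order] = smoothed
        return out

    def test(self, sig, method: str = "GOmeth", adjust: str = "BH") -> pd.DataFrame:
        """Run one variant over all testable sets for one significant-CpG set.

        Returns a frame with columns ``set_id, set_name, J, n_sig_genes, ES,
        odds, p, p_adj, method`` sorted by p (ties broken by set id).
        """
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        ids = _as_cpg_ids(sig)
        if not ids:
            raise ValueError("significant CpG set is empty")
        scores = compute_gene_scores(ids, self.index)
        s = scores.to_numpy()
        dm = s > 0
        n_sig = int(dm.sum())
        if n_sig == 0:
            warnings.warn(
                "no significant CpG maps to any gene; all p-values are 1", stacklevel=2
            )

        U = self.universe_size
        counts_in_set = self.membership @ dm.astype(float)  # integer overlap per set
        if method == "GOmeth":
            es = self.membership @ np.minimum(s, 1.0)
            # tiny epsilon so sums of reciprocal weights that should be
            # integral (e.g. 3 x 1/3) are not floored a unit too low
            x = np.floor(es + 1e-9).astype(np.int64)
            odds = self._set_odds(dm, "equivalent")
        elif method == "HGT-mod":
            es = counts_in_set
            x = counts_in_set.astype(np.int64)
            odds = self._set_odds(dm, "raw")
        else:  # HGT
            es = counts_in_set
            x = counts_in_set.astype(np.int64)
            odds = np.ones(len(self.J))

        p = wallenius_upper_tail_many(x, self.J, U - self.J, n_sig, odds)
        out = pd.DataFrame(
            {
                "set_id": self.set_ids,
                "set_name": self.set_names,
                "J": self.J,
                "n_sig_genes": n_sig,
                "ES": es,
                "odds": odds,
                "p": p,
                "p_adj": adjust_pvalues(p, adjust),
                "method": method,
            }
        )
        out = out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
        return out[RESULT_COLUMNS]

    def _set_odds(self, dm: np.ndarray, bias_counts: str) -> np.ndarray:
        pwf = self._pwf(dm.astype(float), bias_counts)
        in_sum = self.membership @ pwf
        total = pwf.sum()
        mean_in = in_sum / self.J
        out_count = self.universe_size - self.J
        mean_out = (total - in_sum) / out_count
        odds = np.full(len(self.J), ODDS_CAP)
        ok = mean_out > 0
        if not ok.all():
            warnings.warn("out-of-set PWF mean is zero for some sets; capping odds",
                          stacklevel=2)
        odds[ok] = mean_in[ok] / mean_out[ok]
        return odds


def test_gene_sets(
    sig,
    annot: AnnotationTable,
    sets: GeneSetCollection,
    method: str = "GOmeth",
    span: float = 0.5,
    adjust: str = "BH",
) -> pd.DataFrame:
    """One-shot interface: build the tester and run one method.

    For repeated testing against the same annotation and collection, build
    a :class:`GenesetTester` once and call ``.test`` directly.
    """
    return GenesetTester(annot, sets, span=span).test(sig, method=method, adjust=adjust)


def write_results(results: pd.DataFrame, path) -> None:
    """Write an enrichment result frame as TSV."""
    results.to_csv(path, sep="\t", index=False)
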