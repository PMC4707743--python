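"""Co-expressed modules of lincRNAs and coding genes.

Weighted-correlation-network analysis in the WGCNA tradition: an unsigned
adjacency |cor|^beta (soft threshold, default beta = 18), topological
overlap, average-linkage clustering of 1 - TOM, and a deterministic
dynamic cut producing modules of at least ``min_module_size`` genes.
Module labels are letters 'A', 'B', ... in decreasing module size; genes
in no module are 'unassigned'.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .exprstats import bh_adjust

log = logging.getLogger(__name__)


def expression_filter(
    norm_counts: pd.DataFrame,
    min_count: float = 5.0,
    min_samples: int = 3,
    var_quantile: float = 0.25,
) -> list[str]:
    """Keep expressed, variable genes for network construction.

    A gene survives when its normalized count exceeds ``min_count`` in at
    least ``min_samples`` libraries AND the variance of its log2(x+1)
    values reaches the ``var_quantile`` quantile of that variance
    distribution (default: keep the top 75%).  Ties at the quantile are
    kept.
    """
    expressed = (norm_counts > min_count).sum(axis=1) >= min_samples
    logvar = np.log2(norm_counts + 1.0).var(axis=1, ddof=1)
    cut = logvar.quantile(var_quantile)
    keep = expressed & (logvar >= cut)
    return list(norm_counts.index[keep])


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded co-expression adjacency, zero diagonal."""

    gene_ids: list[str]
    a: np.ndarray
    beta: int

    def __post_init__(self):
        assert np.allclose(self.a, self.a.T)
        assert np.all((self.a >= 0) & (self.a <= 1 + 1e-12))
        assert np.all(np.diag(self.a) == 0)

    @property
    def connectivity(self) -> np.ndarray:
        return self.a.sum(axis=1)


def adjacency(
    logmat: pd.DataFrame, beta: int = 18, signed: bool = False
) -> AdjacencyMatrix:
    """a_ij = |pearson(x_i, x_j)|^beta (unsigned) with zero diagonal.

    The signed variant uses ((1 + cor)/2)^beta.  Constant gene rows make
    the correlation undefined and raise, naming the gene.
    """
    if logmat.shape[1] < 3:
        raise ValueError("need >= 3 libraries")
    sd = logmat.std(axis=1, ddof=1)
    bad = list(logmat.index[sd == 0])
    if bad:
        raise ValueError(f"constant expression row(s): {bad[:5]}")
    r = np.corrcoef(logmat.to_numpy())
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(list(logmat.index), a, beta)


@dataclass
class TomMatrix:
    """Topological overlap: direct adjacency plus shared-neighbour strength."""

    gene_ids: list[str]
    t: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.t


def tom(adj: AdjacencyMatrix) -> TomMatrix:
    """Standard unsigned topological overlap matrix.

    t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal (the sum excludes u in {i, j}, which holds automatically for a
    zero-diagonal adjacency), t_ii = 1.
    """
    a = adj.a
    k = adj.connectivity
    shared = a @ a  # zero diagonal => u != i, j contribute only
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    assert np.all(denom > 0)
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return TomMatrix(adj.gene_ids, t)


@dataclass
class ModuleAssignment:
    """Gene -> module letter ('unassigned' for genes outside any module)."""

    labels: pd.Series  # index gene ids
    sizes: pd.Series  # per-module gene count, decreasing

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def cluster_modules(
    tom_matrix: TomMatrix, min_module_size: int = 30
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a dynamic height cut.

    The dendrogram is cut at the merge height that maximises the number of
    clusters holding at least ``min_module_size`` genes; among heights
    achieving that maximum the lowest (deepest) cut is taken, so modules
    are tight cores and loosely attached genes stay out.  Clusters below
    the size floor fall into 'unassigned'.  Deterministic given the TOM.
    """
    n = len(tom_matrix.gene_ids)
    labels = pd.Series("unassigned", index=tom_matrix.gene_ids, dtype=object)
    if n < min_module_size:
        log.warning("fewer genes (%d) than min_module_size (%d)", n,
                    min_module_size)
        return ModuleAssignment(labels, pd.Series(dtype=int))
    if n == 1:  # a single gene cannot be clustered but can satisfy min=1
        labels.iloc[0] = "A"
        return ModuleAssignment(labels, pd.Series({"A": 1}, dtype=int))
    d = tom_matrix.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    z = average(squareform(d, checks=False))
    heights = np.unique(z[:, 2])
    best_cut, best_count = None, 0
    for h in heights:  # ascending: first hit at each count = deepest cut
        cl = fcluster(z, t=h - 1e-12, criterion="distance")
        sizes = np.bincount(cl)
        count = int((sizes >= min_module_size).sum())
        if count > best_count:
            best_count, best_cut = count, cl
    if best_cut is None or best_count == 0:
        return ModuleAssignment(labels, pd.Series(dtype=int))
    cl = best_cut
    cluster_ids, cluster_sizes = np.unique(cl, return_counts=True)
    keep = [(int(s), int(c)) for c, s in zip(cluster_ids, cluster_sizes)
            if s >= min_module_size]
    # letters by decreasing size; ties by first member's gene id
    order = sorted(
        keep,
        key=lambda sc: (-sc[0],
                        tom_matrix.gene_ids[int(np.nonzero(cl == sc[1])[0][0])]),
    )
    letters = _module_letters(len(order))
    sizes_out = {}
    for letter, (size, cid) in zip(letters, order):
        labels.iloc[np.nonzero(cl == cid)[0]] = letter
        sizes_out[letter] = size
    return ModuleAssignment(labels, pd.Series(sizes_out, dtype=int))


def _module_letters(n: int) -> list[str]:
    """'A'..'Z', then 'AA', 'AB', ..."""
    out = []
    for i in range(n):
        name = ""
        i_ = i
        while True:
            name = string.ascii_uppercase[i_ % 26] + name
            i_ = i_ // 26 - 1
            if i_ < 0:
                break
        out.append(name)
    return out


def module_profiles(
    assignment: ModuleAssignment,
    norm_counts: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Per-module, per-stage median expression profile.

    Entry (m, s) is the median over module-m genes of the mean normalized
    count across the libraries of stage s.  Empty modules are excluded;
    'unassigned' is not a module.
    """
    stage_of = design["stage"]
    stage_means = norm_counts.T.groupby(stage_of, sort=False).mean().T
    stage_means = stage_means[list(dict.fromkeys(design["stage"]))]
    rows = {}
    for module in assignment.sizes.index:
        genes = assignment.members(module)
        if genes:
            rows[module] = stage_means.loc[genes].median(axis=0)
    return pd.DataFrame(rows).T


def term_enrichment(
    module_genes: set[str],
    background_genes: set[str],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of annotation terms in a module.

    ``annotation`` has columns (gene_id, term).  Terms annotating no
    background gene are skipped.  BH adjustment runs across all tested
    terms; rows are flagged enriched when p_adj < alpha.
    """
    if not module_genes <= background_genes:
        raise ValueError("module genes must be a subset of the background")
    if annotation.empty:
        raise ValueError("empty annotation")
    ann = annotation[annotation["gene_id"].isin(background_genes)]
    n_bg = len(background_genes)
    n_mod = len(module_genes)
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        term_genes = set(sub["gene_id"])
        k = len(term_genes & module_genes)
        big_k = len(term_genes)
        table = [[k, n_mod - k],
                 [big_k - k, n_bg - n_mod - (big_k - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"term": term, "module_with_term": k,
                     "module_size": n_mod, "background_with_term": big_k,
                     "background_size": n_bg, "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p"])
        df["enriched"] = df["p_adj"] < alpha
    return df
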