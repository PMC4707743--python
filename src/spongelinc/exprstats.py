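"""Expression statistics for the staged developmental design.

Covers median-of-ratios size factors, log2 normalization, sample PCA,
per-stage negative-binomial Wald tests against the non-reproductive
baseline, Benjamini-Hochberg correction, the lincRNA/neighbour expression
independence filter, Jaccard clustering of per-stage upregulated sets, and
the in-situ-hybridization candidate filter.

The DE engine is a per-gene NB GLM with a single two-level group factor:
gene-wise dispersion by method of moments on normalized counts (no
shrinkage), group means fitted by Newton iterations with size-factor
offsets, and a Wald z = log2FC / SE referred to the standard normal.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .genomecontext import NeighborPair

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Raw counts (genes x libraries) plus the stage/replicate design."""

    counts: pd.DataFrame  # rows genes, columns libraries, ints >= 0
    design: pd.DataFrame  # index library, columns: stage, replicate
    size_factors: pd.Series | None = None

    def __post_init__(self):
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("count columns and design libraries differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if "stage" not in self.design.columns:
            raise ValueError("design lacks a 'stage' column")

    @property
    def stages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.design["stage"]:
            seen.setdefault(s, None)
        return list(seen)

    def libraries_of(self, stage: str) -> list[str]:
        return list(self.design.index[self.design["stage"] == stage])

    def to_tsv(self, counts_path: str | Path, design_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.design.to_csv(design_path, sep="\t", index_label="library")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, design_path: str | Path
                 ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id",
                             comment="#")
        design = pd.read_csv(design_path, sep="\t", index_col="library",
                             comment="#")
        return cls(counts=counts, design=design)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each library j: factor_j = median over genes g (restricted to genes
    positive in every library) of count_gj / geometric-mean_g.  Falls back,
    with a warning, to the per-library positive subset when no gene is
    positive everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[0] == 0:
        raise ValueError("empty count matrix")
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    all_pos = np.isfinite(logmat).all(axis=1)
    factors = np.empty(mat.shape[1])
    if all_pos.any():
        loggeo = logmat[all_pos].mean(axis=1)
        factors = np.exp(np.median(logmat[all_pos] - loggeo[:, None], axis=0))
    else:
        log.warning("no gene positive in all libraries; "
                    "using per-library positive subsets for size factors")
        loggeo = np.where(np.isfinite(logmat), logmat, np.nan)
        loggeo = np.nanmean(loggeo, axis=1)
        for j in range(mat.shape[1]):
            ok = np.isfinite(logmat[:, j]) & np.isfinite(loggeo)
            if not ok.any():
                raise ValueError(f"library {counts.columns[j]} has no counts")
            factors[j] = np.exp(np.median(logmat[ok, j] - loggeo[ok]))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), elementwise."""
    return np.log2(counts.div(factors, axis=1) + 1.0)


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Size-factor normalized counts (count / size_factor)."""
    return counts.div(factors, axis=1)


def pca_samples(
    logmat: pd.DataFrame, top_n: int = 500
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of libraries on the top_n most variable genes.

    Genes are ranked by variance across libraries; libraries are projected
    on centred principal components.  Sign convention: in each component
    the loading of largest magnitude is made positive.  Returns (library
    coordinates, explained variance fractions).
    """
    if logmat.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    if top_n > logmat.shape[0]:
        log.warning("top_n=%d exceeds gene count %d; using all genes",
                    top_n, logmat.shape[0])
        top_n = logmat.shape[0]
    var = logmat.var(axis=1, ddof=1)
    keep = var.sort_values(ascending=False, kind="stable").index[:top_n]
    x = logmat.loc[keep].to_numpy().T  # libraries x genes
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    for k in range(coords.shape[1]):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=logmat.columns, columns=cols),
            pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# Negative-binomial Wald test
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    """One gene, one stage-vs-baseline Wald test."""

    gene_id: str
    stage: str
    log2_fold_change: float
    se: float
    wald_z: float
    p: float
    p_adj: float = math.nan
    upregulated: bool = False
    all_zero: bool = False


def _moment_dispersion(norm_groups: Sequence[np.ndarray]) -> float:
    """Pooled within-group method-of-moments NB dispersion, floored."""
    num, den = 0.0, 0
    for q in norm_groups:
        if len(q) < 2:
            continue
        m = q.mean()
        if m <= 0:
            continue
        v = q.var(ddof=1)
        num += (len(q) - 1) * (v - m) / (m * m)
        den += len(q) - 1
    alpha = num / den if den else 0.0
    return max(alpha, DISPERSION_FLOOR)


def _fit_group_mean(k: np.ndarray, sf: np.ndarray, alpha: float
                    ) -> tuple[float, float]:
    """MLE of the normalized group mean q (mu_j = sf_j q) and its Fisher info.

    Newton iterations on beta = log q.  All-zero groups use a half-count
    pseudo-mean so the log fold change stays finite.
    """
    total = k.sum()
    if total == 0:
        q = 0.5 / sf.sum()
        mu = sf * q
        info = (mu / (1.0 + alpha * mu)).sum()
        return q, info
    beta = math.log(total / sf.sum())
    for _ in range(50):
        mu = sf * math.exp(beta)
        w = mu / (1.0 + alpha * mu)
        score = ((k - mu) / (1.0 + alpha * mu)).sum()
        info = w.sum()
        step = score / info
        beta += step
        if abs(step) < 1e-10:
            break
    q = math.exp(beta)
    mu = sf * q
    info = (mu / (1.0 + alpha * mu)).sum()
    return q, info


def nb_wald_test(
    counts_test: np.ndarray,
    sf_test: np.ndarray,
    counts_ref: np.ndarray,
    sf_ref: np.ndarray,
    gene_id: str = "",
    stage: str = "",
) -> DEResult:
    """Wald test of test-group vs reference-group mean under an NB model.

    Dispersion is a pooled within-group moment estimate on normalized
    counts (floor 1e-8); the log2 fold change is the ratio of fitted group
    means; SE comes from the per-group Fisher information, inflated by the
    small-sample factor kappa = t_{nu,0.975} / z_{0.975} with
    nu = n1 + n2 - 2, which compensates the sampling noise of the plug-in
    dispersion so the normal-referenced Wald test stays calibrated at small
    replicate numbers.  The two-sided p uses the normal reference.  An
    all-zero gene returns p = 1, lfc = 0, flagged.
    """
    counts_test = np.asarray(counts_test, dtype=float)
    counts_ref = np.asarray(counts_ref, dtype=float)
    sf_test = np.asarray(sf_test, dtype=float)
    sf_ref = np.asarray(sf_ref, dtype=float)
    if len(counts_test) < 2 or len(counts_ref) < 2:
        raise ValueError("need >= 2 libraries per group")
    if counts_test.sum() == 0 and counts_ref.sum() == 0:
        return DEResult(gene_id, stage, 0.0, math.nan, 0.0, 1.0,
                        all_zero=True)
    alpha = _moment_dispersion(
        [counts_test / sf_test, counts_ref / sf_ref]
    )
    q_t, info_t = _fit_group_mean(counts_test, sf_test, alpha)
    q_r, info_r = _fit_group_mean(counts_ref, sf_ref, alpha)
    lfc = math.log2(q_t / q_r)
    nu = len(counts_test) + len(counts_ref) - 2
    kappa = stats.t.ppf(0.975, nu) / stats.norm.ppf(0.975)
    se_ln = math.sqrt(1.0 / info_t + 1.0 / info_r) * kappa
    se = se_ln / math.log(2.0)
    z = lfc / se
    p = 2.0 * stats.norm.sf(abs(z))
    return DEResult(gene_id, stage, lfc, se, z, min(p, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    cm: CountMatrix,
    baseline: str | None = None,
    alpha_de: float = 0.1,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-stage-vs-baseline Wald tests for every gene, BH within stage.

    ``baseline`` defaults to the first stage of the design (the
    non-reproductive condition).  BH adjustment is applied across genes
    separately for each stage contrast; ``upregulated`` means
    p_adj < alpha_de and log2FC > 0.
    """
    stages = cm.stages
    if baseline is None:
        baseline = stages[0]
    if baseline not in stages:
        raise ValueError(f"baseline stage {baseline!r} not in design")
    factors = cm.size_factors if cm.size_factors is not None \
        else size_factors(cm.counts)
    gene_ids = list(genes) if genes is not None else list(cm.counts.index)
    ref_libs = cm.libraries_of(baseline)
    sf_ref = factors[ref_libs].to_numpy()
    ref_counts = cm.counts.loc[gene_ids, ref_libs].to_numpy()
    rows = []
    for stage in stages:
        if stage == baseline:
            continue
        libs = cm.libraries_of(stage)
        sf_t = factors[libs].to_numpy()
        test_counts = cm.counts.loc[gene_ids, libs].to_numpy()
        results = [
            nb_wald_test(test_counts[i], sf_t, ref_counts[i], sf_ref,
                         gene_id=g, stage=stage)
            for i, g in enumerate(gene_ids)
        ]
        padj = bh_adjust([r.p for r in results])
        for r, pa in zip(results, padj):
            r.p_adj = float(pa)
            r.upregulated = bool(pa < alpha_de and r.log2_fold_change > 0)
            rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage sets, overlap clustering, ISH candidates
# ---------------------------------------------------------------------------


@dataclass
class StageSetSummary:
    stage: str
    upregulated: set[str]
    unique_to_stage: int
    shared_with_all: int


def stage_upregulated_sets(de: pd.DataFrame) -> list[StageSetSummary]:
    """Per-stage upregulated gene sets with unique/shared-across-all tallies."""
    stages = list(dict.fromkeys(de["stage"]))
    sets = {
        s: set(de.loc[(de["stage"] == s) & de["upregulated"], "gene_id"])
        for s in stages
    }
    inter: set[str] = set.intersection(*sets.values()) if sets else set()
    out = []
    for s in stages:
        others = set().union(*(sets[t] for t in stages if t != s)) \
            if len(stages) > 1 else set()
        out.append(StageSetSummary(
            stage=s, upregulated=sets[s],
            unique_to_stage=len(sets[s] - others),
            shared_with_all=len(inter),
        ))
    return out


def de_overlap_clustering(
    sets: Mapping[str, set[str]]
) -> tuple[pd.DataFrame, np.ndarray, str]:
    """Jaccard distances between per-stage upregulated sets, plus dendrogram.

    d(S, T) = 1 - |S ∩ T| / |S ∪ T| (0 when both sets are empty).  Stages
    are ordered by name before average-linkage clustering so the leaf order
    is deterministic.  Returns (distance matrix, scipy linkage, newick).
    """
    stages = sorted(sets)
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    n = len(stages)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = sets[stages[i]], sets[stages[j]]
        union = len(a | b)
        dij = 0.0 if union == 0 else 1.0 - len(a & b) / union
        d[i, j] = d[j, i] = dij
    z = average(squareform(d, checks=False))
    dist = pd.DataFrame(d, index=stages, columns=stages)
    return dist, z, linkage_to_newick(z, stages)


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def ish_candidates(
    norm_counts: pd.DataFrame,
    design: pd.DataFrame,
    min_count: float = 40.0,
    min_fold: float = 20.0,
) -> list[str]:
    """Genes promising for in-situ hybridization probing.

    A gene passes when its maximum normalized count over libraries reaches
    ``min_count`` and the ratio of its highest to lowest stage mean, with a
    pseudocount of 1, reaches ``min_fold``.
    """
    stage_of = design["stage"]
    stage_means = norm_counts.T.groupby(stage_of).mean().T
    max_lib = norm_counts.max(axis=1)
    fold = (stage_means.max(axis=1) + 1.0) / (stage_means.min(axis=1) + 1.0)
    ok = (max_lib >= min_count) & (fold >= min_fold)
    return list(norm_counts.index[ok])


# ---------------------------------------------------------------------------
# Independence filter
# ---------------------------------------------------------------------------


def spearman_rho_p(
    x: np.ndarray, y: np.ndarray, method: str = "t"
) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    method 't' uses the t-approximation; 'exact' enumerates all rank
    permutations (intended for n <= 9).  Average ranks resolve ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in profile")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: Spearman rho undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    elif method == "exact":
        count = 0
        total = 0
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c ** 2).sum())
        for perm in itertools.permutations(range(n)):
            ry_p = ry[list(perm)]
            r = float(np.dot(rx_c, ry_p - ry_p.mean())
                      / (denom * math.sqrt(((ry_p - ry_p.mean()) ** 2).sum())))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, min(p, 1.0)


def independence_filter(
    pairs: Sequence[NeighborPair],
    profiles: pd.DataFrame,
    rho_cut: float = 0.6,
    alpha: float = 0.05,
    method: str = "t",
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Drop lincRNAs co-expressed with a nearest coding neighbour.

    ``profiles`` holds per-gene expression rows over a common library set
    (one row per gene id appearing in the pairs).  Spearman rho and p are
    computed per pair over all libraries; BH adjustment is joint across all
    tested pairs; a lincRNA is discarded when any of its (at most two)
    pairs shows rho >= rho_cut with adjusted p < alpha.  Pairs with a
    constant profile are skipped and logged.

    Returns (independent linc ids, discarded linc ids, per-pair table).
    """
    tested, skipped = [], 0
    for pair in pairs:
        if pair.linc_gene_id not in profiles.index or \
                pair.neighbor_gene_id not in profiles.index:
            skipped += 1
            continue
        x = profiles.loc[pair.linc_gene_id].to_numpy()
        y = profiles.loc[pair.neighbor_gene_id].to_numpy()
        try:
            rho, p = spearman_rho_p(x, y, method=method)
        except ValueError:
            skipped += 1
            continue
        tested.append((pair, rho, p))
    if skipped:
        log.warning("independence filter skipped %d pairs "
                    "(constant or missing profiles)", skipped)
    if tested:
        padj = bh_adjust([p for _, _, p in tested])
    else:
        padj = np.array([])
    rows = []
    correlated: set[str] = set()
    for (pair, rho, p), pa in zip(tested, padj):
        pair.rho, pair.p_adj = rho, float(pa)
        flag = rho >= rho_cut and pa < alpha
        if flag:
            correlated.add(pair.linc_gene_id)
        rows.append({
            "linc_gene_id": pair.linc_gene_id,
            "neighbor_gene_id": pair.neighbor_gene_id,
            "side": pair.side, "distance": pair.distance,
            "rho": rho, "p": p, "p_adj": float(pa), "correlated": flag,
        })
    all_lincs = list(dict.fromkeys(p.linc_gene_id for p in pairs))
    independent = [g for g in all_lincs if g not in correlated]
    return independent, sorted(correlated), pd.DataFrame(rows)
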