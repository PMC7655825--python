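"""Thresholding, scoring and differential-expression procedures.

These are the calling procedures applied after counting and linking:

- ``bimodal_threshold``: a two-component Gaussian-mixture fit followed by a
  valley search in the histogram between the two component means — used for
  well occupancy, live-stain species gates and the malignancy cut.
- ``dead_cell_filter``: a single-Gaussian 5th-percentile floor on live-stain
  intensity.
- ``impute_expression`` / ``malignancy_score``: factor-model (theta, beta)
  imputation, log2(expected counts/10,000 + 1), and the Chr7-minus-Chr10
  average-expression score that flags glioblastoma aneuploidy (Chr7 gain,
  Chr10 loss).
- ``metafeatures`` / ``cluster_cells_by_metafeatures``: hierarchical
  grouping of the 16 imaging features into size / shape / staining-intensity
  meta-features (k=3) and a k=2 cut of cells on those meta-features.
- ``differential_expression``: cell- and depth-matched subsampling followed
  by per-gene two-sided Mann-Whitney U tests with Benjamini-Hochberg
  correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import mannwhitneyu, norm
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FactorModel",
    "MalignancyCall",
    "bimodal_threshold",
    "dead_cell_filter",
    "impute_expression",
    "malignancy_score",
    "metafeatures",
    "cluster_cells_by_metafeatures",
    "differential_expression",
]

logger = logging.getLogger(__name__)


@dataclass
class FactorModel:
    """Nonnegative factor model: cell weights theta (cells x K) and gene
    weights beta (genes x K)."""

    theta: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.theta.ndim != 2 or self.beta.ndim != 2:
            raise ValueError("theta and beta must be 2-D")
        if self.theta.shape[1] != self.beta.shape[1]:
            raise ValueError(
                f"theta and beta must share K: {self.theta.shape} vs {self.beta.shape}"
            )
        if (self.theta < 0).any() or (self.beta < 0).any():
            raise ValueError("factor weights must be nonnegative")


@dataclass
class MalignancyCall:
    scores: np.ndarray  # per-cell malignancy score
    threshold: float
    labels: np.ndarray  # boolean, True = malignant


def bimodal_threshold(values: np.ndarray, bins: int = 50) -> float:
    """Threshold separating the two modes of a bimodal distribution.

    A two-component Gaussian mixture is fit by EM (quantile initialization,
    tolerance 1e-6, up to 500 iterations); the threshold is the center of
    the least-populated histogram bin strictly between the two component
    means. Raises when the fit is degenerate (means within one bin width).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 values for a bimodal fit")
    init = np.quantile(x, [0.25, 0.75]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        means_init=init,
        max_iter=500,
        tol=1e-6,
        random_state=0,
        reg_covar=1e-10 * max(x.var(), 1e-30),
    ).fit(x.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    m_lo, m_hi = gm.means_.ravel()[order]
    s_lo, s_hi = np.sqrt(gm.covariances_.ravel()[order])
    counts, edges = np.histogram(x, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2
    bin_width = edges[1] - edges[0]
    # Ashman's D < 2 means the two fitted components do not produce a
    # bimodal density; also reject means closer than one histogram bin
    ashman_d = np.sqrt(2.0) * (m_hi - m_lo) / np.sqrt(s_lo**2 + s_hi**2)
    if m_hi - m_lo < bin_width or ashman_d < 2.0:
        raise ValueError(
            f"degenerate mixture fit: component means {m_lo:.4g} and {m_hi:.4g} "
            f"do not separate two modes (Ashman D = {ashman_d:.2f}, "
            f"bin width {bin_width:.4g})"
        )
    between = np.flatnonzero((centers > m_lo) & (centers < m_hi))
    if between.size == 0:
        raise ValueError("no histogram bins between the component means")
    b3 = between[np.argmin(counts[between])]
    return float(centers[b3])


def dead_cell_filter(intensities: np.ndarray) -> np.ndarray:
    """Keep/drop flags from a single-Gaussian 5th-percentile floor.

    A Gaussian is fit to the live-stain intensities and cells below its 5th
    percentile (mu - 1.645 sigma) are dropped (False).
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 20:
        raise ValueError("need at least 20 cells to fit the intensity Gaussian")
    mu, sigma = norm.fit(x)
    threshold = mu + norm.ppf(0.05) * sigma
    return x >= threshold


def impute_expression(model: FactorModel) -> np.ndarray:
    """Factor-model imputed expression: log2((theta @ beta.T) / 10000 + 1)."""
    expected = model.theta @ model.beta.T
    if (expected < 0).any():
        raise ValueError("expected counts must be nonnegative")
    return np.log2(expected / 10000.0 + 1.0)


def malignancy_score(
    imputed: np.ndarray | pd.DataFrame,
    chr7_genes: list[str] | np.ndarray,
    chr10_genes: list[str] | np.ndarray,
    bins: int = 50,
) -> MalignancyCall:
    """Chr7-minus-Chr10 mean imputed expression with a double-Gaussian cut.

    The score of a cell is its mean imputed (log2) expression over Chr7
    genes minus the mean over Chr10 genes; Chr7 gain with Chr10 loss — the
    canonical glioblastoma aneuploidy — shifts the score up. The threshold
    between the non-malignant and malignant modes comes from
    ``bimodal_threshold`` and cells strictly above it are labeled malignant.
    """
    if len(chr7_genes) == 0 or len(chr10_genes) == 0:
        raise ValueError("both chromosome gene sets must be non-empty")
    if isinstance(imputed, pd.DataFrame):
        chr7 = imputed.loc[:, list(chr7_genes)].to_numpy()
        chr10 = imputed.loc[:, list(chr10_genes)].to_numpy()
    else:
        chr7 = np.asarray(imputed)[:, np.asarray(chr7_genes, dtype=int)]
        chr10 = np.asarray(imputed)[:, np.asarray(chr10_genes, dtype=int)]
    scores = chr7.mean(axis=1) - chr10.mean(axis=1)
    threshold = bimodal_threshold(scores, bins=bins)
    return MalignancyCall(scores=scores, threshold=threshold, labels=scores > threshold)


def metafeatures(
    features: pd.DataFrame,
    k: int = 3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Group z-scored imaging features into meta-features.

    Features are z-normalized and hierarchically clustered (average linkage,
    correlation distance); the dendrogram is cut at ``k`` clusters and each
    meta-feature is the mean of its member features' z-scores. Constant
    features are dropped with a warning. Returns (cells x k meta-feature
    table, feature -> cluster id mapping).
    """
    if len(features) < 3:
        raise ValueError("need at least 3 cells")
    X = features.astype(float)
    constant = X.columns[X.std(ddof=0) == 0]
    if len(constant):
        logger.warning("dropping constant features: %s", list(constant))
        X = X.drop(columns=constant)
    Z = (X - X.mean()) / X.std(ddof=0)
    linkage = sch.linkage(Z.to_numpy().T, method="average", metric="correlation")
    assignments = sch.fcluster(linkage, t=k, criterion="maxclust")
    mapping = dict(zip(Z.columns, (int(a) for a in assignments)))
    meta = pd.DataFrame(
        {
            f"meta_{c}": Z.loc[:, [f for f, a in mapping.items() if a == c]].mean(axis=1)
            for c in sorted(set(assignments))
        },
        index=features.index,
    )
    return meta, mapping


def cluster_cells_by_metafeatures(meta: pd.DataFrame, k: int = 2) -> np.ndarray:
    """Cut a hierarchical clustering of cells on their meta-features.

    Average linkage with correlation distance, dendrogram cut at ``k``
    clusters; returned labels are arbitrary cluster ids (1-based).
    """
    if len(meta) < 2:
        raise ValueError("need at least 2 cells to cluster")
    linkage = sch.linkage(meta.to_numpy(float), method="average", metric="correlation")
    return sch.fcluster(linkage, t=k, criterion="maxclust")


def _thin_counts(counts: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial thinning of molecule counts at the given retention rate."""
    if rate >= 1.0:
        return counts
    return rng.binomial(counts.astype(np.int64), rate)


def differential_expression(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    seed: int,
    *,
    fdr_method: str = "fdr_bh",
    size_factors_a: np.ndarray | None = None,
    size_factors_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Subsampled, depth-matched Mann-Whitney differential expression.

    Procedure: (1) the larger group's cells are randomly subsampled to the
    smaller group's size; (2) the deeper group's molecules are binomially
    thinned per cell so the two groups match in mean molecules per cell;
    (3) counts are normalized — by default per-cell size factors scaling
    each cell to the pooled mean depth; externally computed size factors may
    be supplied instead; (4) each gene is tested with a two-sided
    Mann-Whitney U (normal approximation with tie correction); (5) p-values
    are Benjamini-Hochberg adjusted. Genes with all-zero counts in both
    groups get NA statistics.

    Returns a table with columns gene, U, p, FDR, direction (sign of the
    mean normalized difference, A minus B).
    """
    if len(counts_a) < 10 or len(counts_b) < 10:
        raise ValueError("both groups need at least 10 cells")
    if list(counts_a.columns) != list(counts_b.columns):
        raise ValueError("groups must share the same gene columns")
    rng = np.random.default_rng(seed)

    A = counts_a.to_numpy(np.int64)
    B = counts_b.to_numpy(np.int64)
    n = min(len(A), len(B))
    if len(A) > n:
        A = A[rng.choice(len(A), size=n, replace=False)]
    if len(B) > n:
        B = B[rng.choice(len(B), size=n, replace=False)]

    mean_a, mean_b = A.sum(1).mean(), B.sum(1).mean()
    if mean_a > mean_b and mean_a > 0:
        A = _thin_counts(A, mean_b / mean_a, rng)
    elif mean_b > mean_a and mean_b > 0:
        B = _thin_counts(B, mean_a / mean_b, rng)

    pooled_mean = np.concatenate([A.sum(1), B.sum(1)]).mean()

    def normalize(X: np.ndarray, sf: np.ndarray | None) -> np.ndarray:
        if sf is None:
            depth = X.sum(1).astype(float)
            sf = np.where(depth > 0, depth / pooled_mean, 1.0)
        return X / np.asarray(sf, dtype=float)[:, None]

    An = normalize(A, size_factors_a)
    Bn = normalize(B, size_factors_b)

    genes = list(counts_a.columns)
    u_stats = np.full(len(genes), np.nan)
    pvals = np.full(len(genes), np.nan)
    direction = np.zeros(len(genes))
    testable = []
    for j in range(len(genes)):
        if A[:, j].sum() == 0 and B[:, j].sum() == 0:
            continue
        res = mannwhitneyu(An[:, j], Bn[:, j], alternative="two-sided", method="asymptotic")
        u_stats[j] = res.statistic
        pvals[j] = res.pvalue
        direction[j] = np.sign(An[:, j].mean() - Bn[:, j].mean())
        testable.append(j)
    fdr = np.full(len(genes), np.nan)
    if testable:
        fdr[testable] = multipletests(pvals[testable], method=fdr_method)[1]
    return pd.DataFrame(
        {"gene": genes, "U": u_stats, "p": pvals, "FDR": fdr, "direction": direction}
    )
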