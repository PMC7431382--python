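"""Bulk microglial RNA-seq analysis: CPM filtering, expression-module
discovery by k-means, marker-based purity scoring, PCA, and a simple
gene-wise negative-binomial exact test for paired comparisons.

The clustering space is the per-sample z-score of log2(CPM + 1) with
Euclidean distance — the field-standard transform for expression heatmaps.
Module labels are assigned mechanically: each module is named after the
sample group in which its centroid is maximal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "CountsMatrix",
    "ExpressionMatrix",
    "ModuleAssignment",
    "MarkerPanel",
    "DEFAULT_MARKER_PANEL",
    "PurityProfile",
    "DEResult",
    "cpm",
    "log2_cpm",
    "filter_expressed",
    "zscore_rows",
    "kmeans_modules",
    "select_k_elbow",
    "purity",
    "pca_scores",
    "nb_exact_test",
    "read_counts_tsv",
    "read_metadata_csv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class CountsMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``counts``: DataFrame, genes as rows, samples as columns, integer values.
    ``meta``: DataFrame indexed by sample id; must cover every sample column.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame):
        if counts.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(counts.columns) - set(meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        self.counts = counts
        self.meta = meta.loc[counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountsMatrix":
        return CountsMatrix(self.counts.loc[genes], self.meta)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values on a named scale."""

    values: pd.DataFrame
    scale: str  # "CPM", "TPM", "log2CPM", "zscore"
    meta: pd.DataFrame | None = None


@dataclass
class ModuleAssignment:
    """A partition of genes into k expression modules."""

    labels: pd.Series  # gene -> module label
    k: int
    centroids: pd.DataFrame  # module x sample centroid means (z-units)
    wcss: float  # within-cluster sum of squares at this k

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_in(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].to_list()


@dataclass(frozen=True)
class MarkerPanel:
    """Cell-type marker genes used for the purity score."""

    markers: dict[str, tuple[str, ...]]
    reference_type: str = "microglia"

    def __post_init__(self) -> None:
        all_genes = [g for v in self.markers.values() for g in v]
        if len(set(all_genes)) != len(all_genes):
            raise ValueError("marker genes must be distinct across cell types")
        if self.reference_type not in self.markers:
            raise ValueError("reference cell type missing from panel")

    @property
    def genes(self) -> list[str]:
        return [g for v in self.markers.values() for g in v]


#: five cell types x five markers used to score sorted-microglia purity
DEFAULT_MARKER_PANEL = MarkerPanel(
    {
        "neurons": ("Dcx", "Npas4", "Npy", "Reln", "Tubb3"),
        "oligodendrocytes": ("Mag", "Mbp", "Mog", "Ppapdc1a", "Sox10"),
        "astrocytes": ("Aqp4", "Gfap", "Gdpd2", "Plcd4", "Slc7a2"),
        "endothelial": ("Emcn", "Ocln", "Pecam1", "Slc16a4", "Tek"),
        "microglia": ("C1qa", "Csf1r", "Cx3cr1", "Fcrls", "Hexb"),
    }
)


@dataclass
class PurityProfile:
    """Per-sample cell-type fractions (sum to 1 where defined)."""

    fractions: pd.DataFrame  # samples x cell types
    undefined_samples: list[str] = field(default_factory=list)
    scale_note: str = "TPM"


@dataclass
class DEResult:
    """Per-gene differential-expression table from the exact test."""

    table: pd.DataFrame  # columns: log2_fc, pvalue, significant
    alpha: float
    dispersion: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def cpm(counts: CountsMatrix) -> ExpressionMatrix:
    """Counts per million: c_gs / L_s * 1e6; every column sums to 1e6."""
    lib = counts.library_sizes
    zero = lib.index[lib == 0].to_list()
    if zero:
        raise ValueError(f"zero library size for samples: {zero}")
    values = counts.counts.div(lib, axis=1) * 1e6
    return ExpressionMatrix(values, "CPM", counts.meta)


def log2_cpm(counts: CountsMatrix) -> ExpressionMatrix:
    values = np.log2(cpm(counts).values + 1.0)
    return ExpressionMatrix(values, "log2CPM", counts.meta)


def filter_expressed(
    counts: CountsMatrix, min_cpm: float = 2.0, min_samples: int = 3
) -> tuple[CountsMatrix, int]:
    """Retain genes with CPM >= ``min_cpm`` in at least ``min_samples``
    samples, preserving gene order.  Returns the filtered matrix and the
    retained gene count."""
    if min_cpm <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be positive")
    if counts.counts.empty:
        raise ValueError("empty counts matrix")
    expr = cpm(counts).values
    keep = (expr >= min_cpm).sum(axis=1) >= min_samples
    filtered = counts.subset_genes(counts.genes[keep])
    return filtered, int(keep.sum())


def zscore_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise z-score; constant rows map to all-zero with a warning."""
    v = expr.values
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant rows mapped to zero z-scores",
            stacklevel=2,
        )
    sd_safe = sd.where(~constant, 1.0)
    z = v.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[constant] = 0.0
    return ExpressionMatrix(z, "zscore", expr.meta)


# ---------------------------------------------------------------------------
# module discovery
# ---------------------------------------------------------------------------

def kmeans_modules(
    expr: ExpressionMatrix,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 25,
) -> ModuleAssignment:
    """Partition genes into k modules by k-means on row z-scores.

    Each module is labeled by the sample group in which its centroid mean is
    maximal (group labels from the attached metadata; sample ids otherwise).
    Ties in group labels are disambiguated with a numeric suffix.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > expr.values.shape[0]:
        raise ValueError("k exceeds the number of genes")
    x = expr.values.to_numpy()
    if np.allclose(x, x[0]):
        warnings.warn("all rows identical: single effective cluster", stacklevel=2)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x)

    centroids = pd.DataFrame(km.cluster_centers_, columns=expr.values.columns)
    if expr.meta is not None and "group" in expr.meta.columns:
        group_means = centroids.T.groupby(expr.meta["group"]).mean().T
    else:
        group_means = centroids
    names: list[str] = []
    for i in range(k):
        base = str(group_means.iloc[i].idxmax())
        name = base
        suffix = 2
        while name in names:
            name = f"{base}#{suffix}"
            suffix += 1
        names.append(name)
    labels = pd.Series([names[c] for c in raw], index=expr.values.index, name="module")
    centroids.index = pd.Index(names, name="module")
    return ModuleAssignment(labels, k, centroids, float(km.inertia_))


def wcss_by_k(
    expr: ExpressionMatrix,
    k_range=range(2, 9),
    seed: int = 0,
    n_restarts: int = 25,
) -> dict[int, float]:
    """Within-cluster sum of squares over a k scan, for elbow plots."""
    out: dict[int, float] = {}
    x = expr.values.to_numpy()
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(x)
        out[k] = float(km.inertia_)
    return out


def select_k_elbow(wcss: dict[int, float]) -> int:
    """Elbow rule: the k maximizing the second difference of WCSS.

    Requires at least three k values, so the curvature is defined for the
    interior points.  A flat (linear) profile ties at zero curvature and is
    broken toward the smallest k with a warning.
    """
    ks = sorted(wcss)
    if len(ks) < 3:
        raise ValueError("need WCSS at three or more k values")
    curvature = {
        ks[i]: wcss[ks[i - 1]] - 2.0 * wcss[ks[i]] + wcss[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    best = max(curvature, key=lambda k: (curvature[k], -k))
    top = max(curvature.values())
    ties = [k for k, c in curvature.items() if np.isclose(c, top, atol=1e-12)]
    if len(ties) > 1:
        warnings.warn("flat WCSS curvature: tie broken to smallest k", stacklevel=2)
        best = min(ties)
    return best


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------

def purity(
    expr_tpm: ExpressionMatrix, panel: MarkerPanel = DEFAULT_MARKER_PANEL
) -> PurityProfile:
    """Within-panel purity: for each sample, the fraction of total panel TPM
    contributed by each cell type's markers.

    Missing panel genes score as 0 with a warning.  Samples with zero total
    panel TPM are flagged as undefined rather than silently set to 0.
    The statistic is a within-panel ratio and therefore invariant to any
    common per-sample scale, so CPM is an exact surrogate when transcript
    lengths (hence true TPM) are unavailable.
    """
    values = expr_tpm.values
    missing = [g for g in panel.genes if g not in values.index]
    if missing:
        warnings.warn(f"panel genes missing from matrix (scored 0): {missing}", stacklevel=2)
    per_type = {}
    for cell_type, genes in panel.markers.items():
        present = [g for g in genes if g in values.index]
        per_type[cell_type] = (
            values.loc[present].sum(axis=0) if present else pd.Series(0.0, index=values.columns)
        )
    sums = pd.DataFrame(per_type)
    total = sums.sum(axis=1)
    undefined = total.index[total == 0].to_list()
    fractions = sums.div(total.where(total > 0), axis=0)
    return PurityProfile(fractions, undefined, scale_note=expr_tpm.scale)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_scores(expr: ExpressionMatrix, n_components: int = 2):
    """Per-sample PCA scores (samples as observations, genes as features).

    Returns ``(scores, explained_variance_ratio)`` with components ordered
    by explained variance.
    """
    n_samples = expr.values.shape[1]
    if n_components > n_samples:
        raise ValueError("n_components exceeds the number of samples")
    if expr.values.shape[0] < n_components:
        raise ValueError("fewer genes than components")
    x = expr.values.to_numpy().T
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=expr.values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------

def _common_dispersion(a: np.ndarray, b: np.ndarray) -> float:
    """Method-of-moments common dispersion across genes, pooling both groups.

    For each gene and group, phi_hat = (s^2 - m) / m^2; the common value is
    the mean of the finite per-gene estimates, floored at a small epsilon so
    the exact test remains defined.
    """
    ests = []
    for g in (a, b):
        m = g.mean(axis=1)
        v = g.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v - m) / m**2
        ests.append(phi[np.isfinite(phi) & (m > 0)])
    pooled = np.concatenate(ests)
    if pooled.size == 0:
        return 1e-8
    return float(max(np.mean(pooled), 1e-8))


def nb_exact_test(
    counts: CountsMatrix,
    group_a,
    group_b,
    alpha: float = 0.05,
    dispersion: float | None = None,
) -> DEResult:
    """Gene-wise two-sided exact NB test between two sample groups.

    Counts are normalized to a common library size by total counts.  Under a
    common dispersion phi (method-of-moments across genes unless supplied),
    the group sums are NB with mean n*mu and dispersion phi/n; conditioning
    on the total, the p-value sums the probabilities of all splits at most as
    likely as the observed one (the minimum-likelihood two-sided convention).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two samples per group")
    lib = counts.library_sizes
    for s in group_a + group_b:
        if lib[s] == 0:
            raise ValueError(f"all-zero library for sample {s}")
    ref = lib[group_a + group_b].mean()
    pseudo = counts.counts[group_a + group_b].mul(ref / lib[group_a + group_b], axis=1)
    a = np.rint(pseudo[group_a].to_numpy())
    b = np.rint(pseudo[group_b].to_numpy())
    na, nb = a.shape[1], b.shape[1]
    phi = _common_dispersion(a, b) if dispersion is None else float(dispersion)

    sum_a = a.sum(axis=1)
    sum_b = b.sum(axis=1)
    total = sum_a + sum_b
    mu = total / (na + nb)  # per-sample null mean

    pvals = np.ones(len(mu))
    for i, (sa, s, m) in enumerate(zip(sum_a, total, mu)):
        if s == 0:
            continue
        pvals[i] = _exact_conditional_p(int(sa), int(s), m, phi, na, nb)
    with np.errstate(divide="ignore"):
        log_fc = np.log2((sum_a / na + 0.5) / (sum_b / nb + 0.5))
    table = pd.DataFrame(
        {"log2_fc": log_fc, "pvalue": pvals, "significant": pvals < alpha},
        index=counts.genes,
    )
    return DEResult(table, alpha, phi)


def _exact_conditional_p(sum_a: int, total: int, mu: float, phi: float, na: int, nb: int) -> float:
    """P-value of the observed group-A sum conditional on the two-group total."""
    x = np.arange(total + 1)
    size_a, size_b = na / phi, nb / phi
    la = stats.nbinom.logpmf(x, size_a, size_a / (size_a + na * mu))
    lb = stats.nbinom.logpmf(total - x, size_b, size_b / (size_b + nb * mu))
    joint = la + lb
    joint -= joint.max()
    prob = np.exp(joint)
    prob /= prob.sum()
    p_obs = prob[sum_a]
    return float(min(prob[prob <= p_obs * (1 + 1e-12)].sum(), 1.0))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts_tsv(counts_path, meta_path) -> CountsMatrix:
    """Counts TSV (first column gene id, header = sample ids) + metadata CSV
    keyed by sample id."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, index_col=0)
    return CountsMatrix(counts, meta)


def read_metadata_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
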