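"""Cross-modality Spearman correlation surface.

Pairwise rank correlations over per-cell feature tables mixing
neurophysiology (input resistance, action-potential kinetics, sEPSC
properties) and morphology (microglial branch counts, spine and
spine-interaction densities).  Missing values are handled by pairwise
deletion, so each pair uses its own n; ties receive average ranks and
two-sided p-values come from the t-approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationSurface", "spearman_matrix", "export_surface", "read_surface"]

MIN_PAIRS = 3


@dataclass
class CorrelationSurface:
    """Symmetric rho / p-value / n-per-pair matrices over named features."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    n: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.pvalue < self.alpha

    def apply_bonferroni(self) -> "CorrelationSurface":
        """Bonferroni-adjusted copy (off-diagonal upper-triangle test count)."""
        k = len(self.rho)
        n_tests = k * (k - 1) // 2
        adj = (self.pvalue * n_tests).clip(upper=1.0)
        np.fill_diagonal(adj.values, 0.0)
        return CorrelationSurface(self.rho.copy(), adj, self.n.copy(), self.alpha)


def spearman_matrix(
    features: pd.DataFrame, min_pairs: int = MIN_PAIRS, alpha: float = 0.05
) -> CorrelationSurface:
    """Pairwise Spearman rho over the numeric columns of a feature table.

    Rows are cells, columns are features; non-numeric columns are ignored.
    For each feature pair only complete observations enter (pairwise
    deletion); pairs with fewer than ``min_pairs`` complete rows, and pairs
    involving a constant feature, are flagged NaN with a warning.
    """
    numeric = features.select_dtypes(include=[np.number])
    if numeric.columns.duplicated().any():
        raise ValueError("duplicate feature names")
    cols = numeric.columns
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    n_mat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(n_mat, numeric.notna().sum().to_numpy())
    flagged = []
    for i in range(k):
        for j in range(i + 1, k):
            pair = numeric.iloc[:, [i, j]].dropna()
            n = len(pair)
            n_mat[i, j] = n_mat[j, i] = n
            if n < min_pairs:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                flagged.append((cols[i], cols[j], "too few complete pairs"))
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                flagged.append((cols[i], cols[j], "constant feature"))
                continue
            r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    if flagged:
        warnings.warn(f"{len(flagged)} feature pairs undefined: {flagged[:5]}", stacklevel=2)
    return CorrelationSurface(
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
        pd.DataFrame(n_mat, index=cols, columns=cols),
        alpha,
    )


def export_surface(
    surface: CorrelationSurface, out_dir, heatmap: bool = False
) -> dict[str, Path]:
    """Write rho/p/n CSVs (and optionally a color-map PNG, red = +1 to
    green = -1, significant cells starred)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("rho", surface.rho), ("pvalue", surface.pvalue), ("n", surface.n)):
        path = out_dir / f"spearman_{name}.csv"
        frame.to_csv(path)
        paths[name] = path
    if heatmap:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.5 * len(surface.rho),) * 2)
        im = ax.imshow(surface.rho.to_numpy(), cmap="RdYlGn_r", vmin=-1, vmax=1)
        ax.set_xticks(range(len(surface.rho)), surface.rho.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(surface.rho)), surface.rho.index, fontsize=6)
        sig = surface.significant.to_numpy()
        for i in range(len(surface.rho)):
            for j in range(len(surface.rho)):
                if i != j and sig[i, j]:
                    ax.text(j, i, "*", ha="center", va="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="Spearman rho")
        fig.tight_layout()
        path = out_dir / "spearman_heatmap.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths["heatmap"] = path
    return paths


def read_surface(out_dir) -> CorrelationSurface:
    """Round-trip reader for :func:`export_surface` CSV output."""
    out_dir = Path(out_dir)
    return CorrelationSurface(
        pd.read_csv(out_dir / "spearman_rho.csv", index_col=0),
        pd.read_csv(out_dir / "spearman_pvalue.csv", index_col=0),
        pd.read_csv(out_dir / "spearman_n.csv", index_col=0),
    )
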