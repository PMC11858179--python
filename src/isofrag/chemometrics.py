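"""NIPALS PCA and diagnostic-fragment ranking for MS/MS spectral matrices.

The multivariate workflow is: TIC-normalise each spectrum, align into a
samples x m/z matrix, mean-centre the columns, and extract principal
components with NIPALS (Nonlinear estimation by Iterative PArtial Least
Squares).  NIPALS pulls components one at a time by alternating
score/loading regressions with deflation, which is the natural fit for
short-and-wide spectral matrices (few samples, many m/z variables).

No variance scaling is applied — centring only.  This is load-bearing:
with unscaled columns a variable's loading magnitude tracks its intensity
variation, so loading magnitude is proportional to fragment-ion abundance,
and aligned loading vectors flag consecutive-fragmentation series (a parent
ion and its sequential neutral-loss products co-vary across samples).

Sign convention: each loading vector is flipped so its largest-magnitude
element is positive (NIPALS signs are otherwise arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import AlignedMatrix

__all__ = [
    "mean_center",
    "PcaModel",
    "nipals_pca",
    "pca_from_matrix",
    "DiagnosticReport",
    "rank_diagnostics",
    "restrict_range",
]


def mean_center(matrix: AlignedMatrix) -> tuple[AlignedMatrix, np.ndarray]:
    """Subtract column means; returns the centred matrix and the means
    (kept for reconstruction).  A single-row matrix is an error: centring
    would annihilate it."""
    if matrix.n_samples < 2:
        raise ValueError("mean-centring needs at least 2 samples")
    means = matrix.X.mean(axis=0)
    centred = AlignedMatrix(
        matrix.variable_mzs.copy(),
        matrix.X - means,
        list(matrix.metas),
        matrix.tic_normalized,
    )
    return centred, means


@dataclass
class PcaModel:
    """Scores, unit-norm loadings, and explained variance of a PCA fit."""

    n_components: int
    scores: np.ndarray  # (n_samples, k)
    loadings: np.ndarray  # (n_variables, k)
    explained_variance_pct: np.ndarray  # (k,)
    variable_mzs: np.ndarray
    column_means: np.ndarray
    #: component indices extracted beyond the matrix rank (zero variance)
    degenerate_components: tuple[int, ...] = ()

    def reconstruct(self) -> np.ndarray:
        """scores @ loadings.T + column_means."""
        return self.scores @ self.loadings.T + self.column_means


def nipals_pca(
    X: np.ndarray,
    n_components: int,
    tol: float = 1e-9,
    max_iter: int = 500,
    variable_mzs: np.ndarray | None = None,
    column_means: np.ndarray | None = None,
) -> PcaModel:
    """NIPALS PCA of an already-centred matrix.

    Per component: seed the score vector t with the highest-variance
    column, then iterate p = X't/t't, p <- p/||p||, t = Xp until the
    relative change of t falls below ``tol``; deflate X <- X - t p'.
    Explained variance per component is ||t||^2 over the total centred sum
    of squares, in percent.

    Raises on non-convergence (naming the component) and on an all-zero
    matrix.  Components requested beyond the matrix rank come back with
    zero scores/loadings and are listed in ``degenerate_components``.
    """
    X = np.array(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)={min(n - 1, p)}"
        )
    if tol <= 0:
        raise ValueError("tol must be > 0")
    total_ss = float((X**2).sum())
    if total_ss == 0:
        raise ValueError("matrix has no variance (all zeros after centring)")

    scores = np.zeros((n, n_components))
    loadings = np.zeros((p, n_components))
    explained = np.zeros(n_components)
    degenerate: list[int] = []

    work = X.copy()
    for k in range(n_components):
        col_ss = (work**2).sum(axis=0)
        residual_ss = float(col_ss.sum())
        if residual_ss <= 1e-12 * total_ss:
            degenerate.append(k)
            continue
        t = work[:, int(np.argmax(col_ss))].copy()
        if float(t @ t) == 0.0:
            # seed column is zero but residual variance remains elsewhere
            t = work[:, int(np.argmax((work != 0).any(axis=0)))].copy()
        pvec = np.zeros(p)
        for _ in range(max_iter):
            pvec = work.T @ t / float(t @ t)
            norm_p = float(np.linalg.norm(pvec))
            if norm_p == 0.0:
                raise RuntimeError(f"NIPALS collapsed on component {k + 1}")
            pvec /= norm_p
            t_new = work @ pvec
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        else:
            raise RuntimeError(
                f"NIPALS did not converge for component {k + 1} "
                f"within {max_iter} iterations"
            )
        # sign convention: largest-|loading| element positive
        imax = int(np.argmax(np.abs(pvec)))
        if pvec[imax] < 0:
            pvec = -pvec
            t = -t
        work -= np.outer(t, pvec)
        scores[:, k] = t
        loadings[:, k] = pvec
        explained[k] = 100.0 * float(t @ t) / total_ss

    if variable_mzs is None:
        variable_mzs = np.arange(p, dtype=float)
    if column_means is None:
        column_means = np.zeros(p)
    return PcaModel(
        n_components=n_components,
        scores=scores,
        loadings=loadings,
        explained_variance_pct=explained,
        variable_mzs=np.asarray(variable_mzs, dtype=float),
        column_means=np.asarray(column_means, dtype=float),
        degenerate_components=tuple(degenerate),
    )


def pca_from_matrix(
    matrix: AlignedMatrix,
    n_components: int = 2,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> PcaModel:
    """Centre an aligned matrix and run NIPALS in one step."""
    centred, means = mean_center(matrix)
    return nipals_pca(
        centred.X,
        n_components,
        tol=tol,
        max_iter=max_iter,
        variable_mzs=matrix.variable_mzs,
        column_means=means,
    )


def restrict_range(matrix: AlignedMatrix, lo: float, hi: float) -> AlignedMatrix:
    """Keep only variables with lo <= m/z <= hi.  Rows are NOT
    re-normalised: TIC normalisation refers to the full spectrum acquired,
    not to the analysed window."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    keep = (matrix.variable_mzs >= lo) & (matrix.variable_mzs <= hi)
    if not keep.any():
        raise ValueError(f"no variables in m/z range [{lo}, {hi}]")
    return AlignedMatrix(
        matrix.variable_mzs[keep],
        matrix.X[:, keep],
        list(matrix.metas),
        matrix.tic_normalized,
    )


@dataclass
class DiagnosticReport:
    """Per-group ranking of candidate diagnostic m/z variables.

    ``tables`` maps each group label to a DataFrame with columns
    (mz, loading_magnitude, specificity, score) sorted by score descending;
    ``correlation`` is the pairwise cosine similarity of the variables'
    loading-plane vectors, whose near-unity blocks flag consecutive
    fragmentation series.
    """

    tables: dict[str, pd.DataFrame]
    correlation: pd.DataFrame

    def top(self, group: str, k: int) -> pd.DataFrame:
        return self.tables[group].head(k)


def rank_diagnostics(
    model: PcaModel, group_labels: Sequence[str]
) -> DiagnosticReport:
    """Rank variables by how specifically they point at each sample group
    in component space.

    Each group's direction is its mean score vector (normalised); each
    variable's specificity is the cosine between its loading-plane vector
    and that direction (in [-1, 1]); the ranking score is
    specificity x loading magnitude, so abundant *and* group-aligned
    fragments rank first.  Ties break deterministically by ascending m/z.
    """
    labels = list(group_labels)
    if len(labels) != model.scores.shape[0]:
        raise ValueError("one group label per sample is required")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if model.n_components < 2:
        raise ValueError("need a model with at least 2 components")

    L = model.loadings  # (p, k)
    mags = np.linalg.norm(L, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(mags[:, None] > 0, L / np.where(mags[:, None] == 0, 1, mags[:, None]), 0.0)

    tables: dict[str, pd.DataFrame] = {}
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        if not idx:
            raise ValueError(f"group {g!r} has no samples")
        centre = model.scores[idx].mean(axis=0)
        norm_c = np.linalg.norm(centre)
        if norm_c == 0:
            raise ValueError(f"group {g!r} has a zero mean score vector")
        centre = centre / norm_c
        specificity = dirs @ centre
        score = specificity * mags
        df = pd.DataFrame(
            {
                "mz": model.variable_mzs,
                "loading_magnitude": mags,
                "specificity": specificity,
                "score": score,
            }
        ).sort_values(["score", "mz"], ascending=[False, True], kind="stable")
        tables[g] = df.reset_index(drop=True)

    # pairwise cosine similarity of loading-plane vectors
    cos = dirs @ dirs.T
    names = [f"{m:.4f}" for m in model.variable_mzs]
    correlation = pd.DataFrame(cos, index=names, columns=names)
    return DiagnosticReport(tables=tables, correlation=correlation)
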