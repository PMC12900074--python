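"""Rigid superposition and principal component analysis of Cα coordinates.

Frames are Kabsch-aligned to a state-specific reference to remove overall
translation and rotation, then the flattened Cα coordinate matrix (n frames ×
3N) is mean-centered and decomposed by PCA.  Explained-variance ratios (EVRs)
quantify each collective mode's contribution; PC1–PC2 projections visualize the
sampled conformational landscape and the coverage of a selected representative
subset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.decomposition import PCA


@dataclass
class AlignmentResult:
    """Optimal proper rotation/translation and the residual RMSD (Å).

    The aligned mobile coordinates are ``mobile @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass
class PCAResult:
    components: np.ndarray    # (k, 3N) orthonormal rows
    evr: np.ndarray           # explained-variance ratios, non-increasing
    projections: np.ndarray   # (n, k)
    mean: np.ndarray          # (3N,)


def kabsch_align(mobile: np.ndarray, reference: np.ndarray) -> tuple[AlignmentResult, np.ndarray]:
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Returns the alignment (proper rotation — reflections are excluded by the
    determinant correction inside the SVD solver) and the aligned coordinates.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3) with equal N")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("alignment needs at least 3 points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = reference.mean(axis=0) - mobile.mean(axis=0) @ R.T
    aligned = mobile @ R.T + t
    rmsd = float(np.sqrt(((aligned - reference) ** 2).sum(axis=1).mean()))
    return AlignmentResult(rotation=R, translation=t, rmsd=rmsd), aligned


def align_frames(coord_matrix: np.ndarray, reference_row: np.ndarray) -> np.ndarray:
    """Kabsch-align every flattened-Cα row of (n, 3N) onto a reference row."""
    ref = np.asarray(reference_row, dtype=float).reshape(-1, 3)
    out = np.empty_like(coord_matrix, dtype=float)
    for i, row in enumerate(coord_matrix):
        _, aligned = kabsch_align(row.reshape(-1, 3), ref)
        out[i] = aligned.ravel()
    return out


def run_pca(coord_matrix: np.ndarray, n_components: int = 2) -> PCAResult:
    """PCA of mean-centered coordinate rows with a deterministic sign convention.

    Covariance uses the (n−1) denominator; EVR is eigenvalue over total
    variance.  Each component's sign is fixed so its largest-magnitude loading
    is positive, making projections reproducible across runs and libraries.
    """
    X = np.asarray(coord_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (n ≥ 2) × 3N coordinate matrix")
    max_k = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_k:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_k}")
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(X)
    comps = pca.components_.copy()
    for j in range(comps.shape[0]):
        lead = np.argmax(np.abs(comps[j]))
        if comps[j, lead] < 0:
            comps[j] = -comps[j]
            proj[:, j] = -proj[:, j]
    return PCAResult(components=comps, evr=pca.explained_variance_ratio_.copy(),
                     projections=proj, mean=pca.mean_.copy())


def project_selection(pca: PCAResult, selected, out_csv=None, out_plot=None) -> pd.DataFrame:
    """PC1–PC2 coordinates of every frame with the selected subset flagged.

    Optionally writes a CSV (frame, pc1, pc2, selected) and a scatter plot with
    the representatives highlighted.
    """
    n = pca.projections.shape[0]
    selected = np.asarray(selected, dtype=int)
    if selected.size and (selected.min() < 0 or selected.max() >= n):
        raise IndexError("selected frame index out of range")
    flag = np.zeros(n, dtype=bool)
    flag[selected] = True
    df = pd.DataFrame({
        "frame": np.arange(n),
        "pc1": pca.projections[:, 0],
        "pc2": pca.projections[:, 1] if pca.projections.shape[1] > 1 else 0.0,
        "selected": flag,
    })
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_plot is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(df.pc1[~flag], df.pc2[~flag], s=12, c="0.7", label="ensemble")
        ax.scatter(df.pc1[flag], df.pc2[flag], marker="^", s=40, c="crimson",
                   label="selected")
        ax.set_xlabel(f"PC1 ({pca.evr[0] * 100:.1f}% EVR)")
        if len(pca.evr) > 1:
            ax.set_ylabel(f"PC2 ({pca.evr[1] * 100:.1f}% EVR)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out_plot)
        plt.close(fig)
    return df
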