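"""Generalized Procrustes Analysis and shape statistics.

GPA superimposes landmark configurations by translating each to a common
centroid, scaling to unit centroid size and rotating (proper rotations only)
to minimise the summed squared distance to an iteratively refined consensus.
Shape variation in the superimposed coordinates is summarised by PCA of
their covariance matrix, and classifier effects are tested with a
Goodall-style Procrustes ANOVA in which sums of squares of Procrustes
distances are divided by degrees of freedom multiplied by the shape-space
dimension (2k - 4 for k two-dimensional landmarks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from equilunge.landmarks import LandmarkConfiguration


def _as_stack(dataset) -> np.ndarray:
    """Coerce a dataset (configurations or array) to an (n, k, 2) float stack."""
    if isinstance(dataset, np.ndarray):
        stack = np.asarray(dataset, dtype=float)
        if stack.ndim == 2:
            stack = stack[None]
    else:
        stack = np.stack([
            c.points if isinstance(c, LandmarkConfiguration) else np.asarray(c, float)
            for c in dataset
        ])
    if stack.ndim != 3 or stack.shape[-1] != 2:
        raise ValueError(f"expected (n, k, 2) landmark stack, got shape {stack.shape}")
    return stack


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise ValueError("all landmarks coincident: centroid size is zero")
    return cs


def _center_scale(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each configuration at the origin and scale to unit centroid size."""
    centered = stack - stack.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(centered**2, axis=(1, 2)))
    if np.any(sizes == 0.0):
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / sizes[:, None, None], sizes


def _rotate_to(stack: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimally rotate each centered configuration onto ``reference``.

    Proper 2-D rotations only; the optimal angle has the closed form
    theta = atan2(sum(x_i ^ r_i), sum(x_i . r_i)) which we vectorise over
    the whole stack.
    """
    dots = np.einsum("nkd,kd->n", stack, reference)
    crosses = np.einsum("nk,k->n", stack[:, :, 1], reference[:, 0]) - np.einsum(
        "nk,k->n", stack[:, :, 0], reference[:, 1]
    )
    theta = np.arctan2(crosses, dots)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.empty((len(stack), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = -s
    rot[:, 1, 0] = s
    rot[:, 1, 1] = c
    return np.einsum("nkd,nde->nke", stack, rot)


@dataclass
class ProcrustesFit:
    """Result of a Generalized Procrustes superimposition."""

    consensus: np.ndarray          # (k, 2) mean shape, centered, unit size
    aligned: np.ndarray            # (n, k, 2) superimposed coordinates
    centroid_sizes: np.ndarray     # (n,) sizes before scaling
    n_iterations: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]


def align_pair(reference, target) -> tuple[np.ndarray, float]:
    """Partial Procrustes superimposition of ``target`` onto ``reference``.

    Both configurations are centered and scaled to unit centroid size; the
    target is then rotated (proper rotation) to minimise the summed squared
    landmark distance. Returns the aligned target and the minimised root
    distance (the partial Procrustes distance).
    """
    ref = _as_stack([reference])[0]
    tgt = _as_stack([target])[0]
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must have the same landmark count")
    ref_u = (ref - ref.mean(axis=0)) / centroid_size(ref)
    tgt_u = (tgt - tgt.mean(axis=0)) / centroid_size(tgt)
    aligned = _rotate_to(tgt_u[None], ref_u)[0]
    return aligned, float(np.sqrt(np.sum((aligned - ref_u) ** 2)))


def gpa(dataset, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesFit:
    """Generalized Procrustes Analysis of a landmark dataset.

    Iterates rotate-to-consensus / recompute-consensus until the consensus
    displacement falls below ``tol`` (root summed squared coordinate change).
    Centroid sizes are recorded before scaling. A fit that has not reached
    ``tol`` within ``max_iter`` iterations is returned with
    ``converged=False``.
    """
    stack = _as_stack(dataset)
    if stack.shape[0] < 2:
        raise ValueError("GPA needs at least two configurations")
    unit, sizes = _center_scale(stack)
    consensus = unit[0].copy()
    aligned = unit
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        aligned = _rotate_to(unit, consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        shift = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    # canonical orientation: first-to-last landmark chord of the consensus
    # along +x, so the fit is invariant to the input frames
    v = consensus[-1] - consensus[0]
    if np.hypot(*v) > 0:
        theta = -np.arctan2(v[1], v[0])
        c, s = np.cos(theta), np.sin(theta)
        consensus = consensus @ np.array([[c, s], [-s, c]])
    aligned = _rotate_to(unit, consensus)
    if not converged:
        warnings.warn(f"GPA did not converge within {max_iter} iterations", stacklevel=2)
    return ProcrustesFit(
        consensus=consensus,
        aligned=aligned,
        centroid_sizes=sizes,
        n_iterations=n_iter,
        converged=converged,
    )


def shape_dimension(k: int, d: int = 2) -> int:
    """Dimension of shape space for k landmarks in d dimensions.

    d*k coordinates minus d translations, d(d-1)/2 rotations and 1 scale:
    30 two-dimensional landmarks span a 56-dimensional shape space.
    """
    if k < 3 or d not in (2, 3):
        raise ValueError("need k >= 3 landmarks and d in {2, 3}")
    return d * k - d - d * (d - 1) // 2 - 1


@dataclass
class PcaResult:
    """PCA of superimposed Procrustes coordinates."""

    eigenvalues: np.ndarray     # descending, nonzero components only
    pct_variance: np.ndarray    # percentages, sum to 100
    cum_pct: np.ndarray
    scores: np.ndarray          # (n, m)
    vectors: np.ndarray         # (m, 2k) orthonormal rows
    total_variance: float
    mean: np.ndarray            # (2k,) flattened mean of the aligned data
    coordinates: np.ndarray     # (n, 2k) tangent-space coordinates decomposed

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(self.eigenvalues))],
                "eigenvalue": self.eigenvalues,
                "pct_variance": self.pct_variance,
                "cum_pct": self.cum_pct,
            }
        )


def pca(fit: ProcrustesFit) -> PcaResult:
    """PCA of the covariance matrix of superimposed coordinates.

    The centered coordinates are first projected orthogonally into the
    tangent space at the consensus (removing the radial direction of the
    pre-shape sphere, a second-order curvature artifact), so the nonzero
    spectrum spans at most the shape-space dimension 2k - 4. Eigenvalues
    are sample variances along orthonormal deformation directions (n - 1
    denominator); percentages are eigenvalue shares of the total variance
    (the trace). Each vector's sign is fixed so its largest-magnitude
    loading is positive; ``mean + scores @ vectors`` reproduces the
    decomposed tangent coordinates exactly.
    """
    n = fit.n_specimens
    if n < 3:
        raise ValueError("PCA needs at least three specimens")
    X = fit.aligned.reshape(n, -1)
    mean = X.mean(axis=0)
    centered = X - mean
    radial = fit.consensus.reshape(-1)
    radial = radial / np.linalg.norm(radial)
    centered = centered - np.outer(centered @ radial, radial)
    total_variance = float(np.sum(centered**2) / (n - 1))
    if total_variance == 0.0:
        raise ValueError("zero total shape variance")
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = svals**2 / (n - 1)
    keep = eigenvalues > eigenvalues[0] * 1e-12
    eigenvalues = eigenvalues[keep]
    vectors = vt[keep]
    # deterministic sign: largest-magnitude loading positive
    flip = np.sign(vectors[np.arange(len(vectors)), np.argmax(np.abs(vectors), axis=1)])
    vectors = vectors * flip[:, None]
    scores = centered @ vectors.T
    pct = eigenvalues / total_variance * 100.0
    return PcaResult(
        eigenvalues=eigenvalues,
        pct_variance=pct,
        cum_pct=np.cumsum(pct),
        scores=scores,
        vectors=vectors,
        total_variance=total_variance,
        mean=mean,
        coordinates=mean + centered,
    )


def eigenvalue_variance_stats(
    eigenvalues: Sequence[float], total_variance: float, n_variables: int
) -> tuple[float, float, float]:
    """Dispersion of an eigenvalue spectrum, raw and in scaled variants.

    Returns ``(raw, by_total, standardized)`` where ``raw`` is the
    population variance of the eigenvalue sequence, ``by_total`` divides by
    the squared total variance, and ``standardized`` further multiplies by
    the variable count. Several scalings of this index circulate in
    morphometric software; these are the conventions implemented here.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    raw = float(np.var(eig))
    if total_variance == 0.0:
        return raw, 0.0, 0.0
    by_total = raw / total_variance**2
    return raw, by_total, by_total * n_variables


@dataclass
class AnovaRow:
    """One effect row of a Procrustes (or centroid-size) ANOVA table."""

    effect: str
    SS: float
    MS: float
    df: int
    F: float
    p: float
    SS_residual: float = np.nan
    MS_residual: float = np.nan
    df_residual: int = 0
    p_method: str = "parametric"


def _group_indices(labels: Sequence) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    # deterministic group order: sorted by string form (A<B<C<D, 0<1)
    uniq = sorted(set(labels.tolist()), key=str)
    codes = np.array([uniq.index(l) for l in labels.tolist()])
    return codes, uniq


def _goodall_ss(X: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    grand = X.mean(axis=0)
    ss_effect = 0.0
    ss_resid = 0.0
    for g in range(n_groups):
        Xg = X[codes == g]
        if len(Xg) == 0:
            raise ValueError(f"classifier group {g} has no specimens")
        mg = Xg.mean(axis=0)
        ss_effect += len(Xg) * float(np.sum((mg - grand) ** 2))
        ss_resid += float(np.sum((Xg - mg) ** 2))
    return ss_effect, ss_resid


def procrustes_anova_shape(
    fit: ProcrustesFit,
    classifier_labels: Sequence,
    effect: str = "classifier",
    p_method: str = "parametric",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AnovaRow:
    """Goodall-style Procrustes ANOVA of shape against one classifier.

    The between-group sum of squares is the size-weighted squared Procrustes
    distance of group mean shapes from the grand mean over superimposed
    coordinates; degrees of freedom are multiplied by the shape-space
    dimension m = 2k - 4. The p-value is parametric (F distribution with
    (g-1)m and (n-g)m df) by default, or a permutation tail with labels
    shuffled under a fixed seed.
    """
    codes, uniq = _group_indices(classifier_labels)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need at least two classifier groups")
    X = fit.aligned.reshape(fit.n_specimens, -1)
    if len(codes) != len(X):
        raise ValueError("labels must align one-to-one with specimens")
    m = shape_dimension(fit.n_landmarks, 2)
    ss_effect, ss_resid = _goodall_ss(X, codes, n_groups)
    df_effect = (n_groups - 1) * m
    df_resid = (len(X) - n_groups) * m
    ms_effect = ss_effect / df_effect
    if ss_resid == 0.0:
        warnings.warn("zero residual SS: p reported at boundary", stacklevel=2)
        F = np.inf
        p = 0.0
    else:
        ms_resid = ss_resid / df_resid
        F = ms_effect / ms_resid
        if p_method == "parametric":
            p = float(stats.f.sf(F, df_effect, df_resid))
        elif p_method == "permutation":
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(codes)
                ss_e, ss_r = _goodall_ss(X, perm, n_groups)
                if ss_e / df_effect >= F * (ss_r / df_resid):
                    count += 1
            p = (count + 1) / (n_permutations + 1)
        else:
            raise ValueError(f"unknown p_method {p_method!r}")
    return AnovaRow(
        effect=effect,
        SS=ss_effect,
        MS=ms_effect,
        df=df_effect,
        F=float(F),
        p=float(p),
        SS_residual=ss_resid,
        MS_residual=ss_resid / df_resid if df_resid else np.nan,
        df_residual=df_resid,
        p_method=p_method,
    )


def anova_centroid_size(
    sizes: Sequence[float], classifier_labels: Sequence, effect: str = "classifier"
) -> AnovaRow:
    """One-way ANOVA of centroid size against one classifier."""
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be positive")
    codes, uniq = _group_indices(classifier_labels)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need at least two classifier groups")
    grand = sizes.mean()
    ss_effect = sum(
        np.sum(codes == g) * (sizes[codes == g].mean() - grand) ** 2 for g in range(n_groups)
    )
    ss_resid = sum(
        float(np.sum((sizes[codes == g] - sizes[codes == g].mean()) ** 2))
        for g in range(n_groups)
    )
    df_effect = n_groups - 1
    df_resid = len(sizes) - n_groups
    ms_effect = ss_effect / df_effect
    if ss_resid == 0.0:
        warnings.warn("zero within-group variance: p reported at boundary", stacklevel=2)
        return AnovaRow(effect, float(ss_effect), float(ms_effect), df_effect, np.inf, 0.0,
                        0.0, 0.0, df_resid)
    ms_resid = ss_resid / df_resid
    F = ms_effect / ms_resid
    p = float(stats.f.sf(F, df_effect, df_resid))
    return AnovaRow(
        effect=effect,
        SS=float(ss_effect),
        MS=float(ms_effect),
        df=df_effect,
        F=float(F),
        p=p,
        SS_residual=ss_resid,
        MS_residual=ms_resid,
        df_residual=df_resid,
    )


def consensus_by_class(fit: ProcrustesFit, classifier_labels: Sequence) -> dict:
    """Per-class mean shapes of the aligned coordinates, keyed by label."""
    codes, uniq = _group_indices(classifier_labels)
    out = {}
    for g, label in enumerate(uniq):
        members = fit.aligned[codes == g]
        if len(members) == 0:
            raise ValueError(f"class {label!r} is empty")
        out[label] = members.mean(axis=0)
    return out


@dataclass
class ConfidenceEllipse:
    """Gaussian confidence ellipse for a 2-D score cloud."""

    center: np.ndarray
    semi_axes: np.ndarray   # descending
    orientation: float      # radians, major axis vs +x
    probability: float = 0.9

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        pts = np.atleast_2d(points) - self.center
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        return (local[:, 0] / self.semi_axes[0]) ** 2 + (
            local[:, 1] / self.semi_axes[1]
        ) ** 2 <= 1.0

    def boundary(self, n: int = 200) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        xy = np.column_stack([self.semi_axes[0] * np.cos(t), self.semi_axes[1] * np.sin(t)])
        rot = np.array([[c, -s], [s, c]])
        return xy @ rot.T + self.center


def confidence_ellipse(scores_2d: np.ndarray, probability: float = 0.9) -> ConfidenceEllipse:
    """Confidence ellipse of a 2-D Gaussian fitted to PC scores.

    The squared Mahalanobis radius equals the chi-square quantile with 2 df
    at ``probability``, so the ellipse covers that fraction of the
    generating Gaussian.
    """
    pts = np.asarray(scores_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional score points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 0:
        raise ValueError("singular score covariance: ellipse undefined")
    r2 = stats.chi2.ppf(probability, df=2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    semi_axes = np.sqrt(eigvals * r2)
    major = eigvecs[:, 0]
    orientation = float(np.arctan2(major[1], major[0]))
    return ConfidenceEllipse(center, semi_axes, orientation, probability)
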