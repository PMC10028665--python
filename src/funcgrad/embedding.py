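"""Diffusion-map gradients and Procrustes alignment.

The sparsified connectome is turned into a cosine-similarity affinity
matrix; diffusion embedding of the degree-normalised Markov operator built
from that affinity yields the functional gradients — continuous axes of
connectome organisation ordered by the variance they explain. Individual
embeddings are aligned to a group template by orthogonal Procrustes
rotation so gradient axes are comparable across scans.

:class:`DiffusionGradients` and :class:`ProcrustesAlignment` are
scikit-learn-style estimators; :func:`diffusion_embedding` and
:func:`procrustes_align` are thin functional wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import cosine_similarity

from .connectome import ConnectivityMatrix

__all__ = [
    "EmbeddingConfig",
    "GradientEmbedding",
    "cosine_affinity",
    "DiffusionGradients",
    "ProcrustesAlignment",
    "diffusion_embedding",
    "variance_explained",
    "procrustes_align",
]


@dataclass
class EmbeddingConfig:
    """Free parameters of the diffusion operator.

    alpha
        Anisotropic-diffusion exponent in [0, 1]; 0.5 (Fokker-Planck
        normalisation) is the common default for connectome gradients.
    diffusion_time
        t = 0 selects the multiscale scaling lambda / (1 - lambda);
        t > 0 scales eigenvectors by lambda ** t.
    n_components
        Number of non-trivial gradients retained (G >= 2).
    """

    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.diffusion_time < 0:
            raise ValueError("diffusion_time must be non-negative")
        if self.n_components < 2:
            raise ValueError("need at least 2 gradient components")


@dataclass
class GradientEmbedding:
    """N x G node coordinates in gradient space with spectra attached."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    variance_ratios: np.ndarray
    alignment: str = "unaligned"
    node_ids: list[str] | None = None
    procrustes_residual: float | None = None
    config: EmbeddingConfig | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_ratios = np.asarray(self.variance_ratios, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValueError("embedding must be N x G with G >= 2")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")
        if np.any(self.variance_ratios < -1e-12) or np.any(self.variance_ratios > 1 + 1e-12):
            raise ValueError("variance ratios must lie in [0, 1]")
        if self.alignment not in ("unaligned", "procrustes_aligned"):
            raise ValueError(f"unknown alignment state {self.alignment!r}")
        if self.node_ids is None:
            self.node_ids = [f"n{i + 1:04d}" for i in range(self.coords.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.coords.shape[1]


def cosine_affinity(cm: ConnectivityMatrix) -> np.ndarray:
    """Cosine-similarity affinity between the columns of a sparsified matrix.

    A[i, j] is the cosine of the angle between connectivity profiles
    (columns) i and j; negative similarities are clipped to 0 so the
    subsequent Markov operator is non-negative, and the diagonal is 1.
    """
    if cm.sparsity != "column_thresholded":
        raise ValueError("cosine affinity expects a column-thresholded matrix")
    values = cm.values
    norms = np.linalg.norm(values, axis=0)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        names = [cm.node_ids[i] for i in dead]
        raise ValueError(f"all-zero connectivity profiles for nodes: {names}")
    a = cosine_similarity(values.T)
    a = np.clip((a + a.T) / 2.0, 0.0, None)
    np.fill_diagonal(a, 1.0)
    return a


def _validate_affinity(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("affinity must be symmetric (tolerance 1e-12)")
    if np.any(a < 0):
        raise ValueError("affinity must be non-negative")
    n_comp, _ = connected_components(a > 0, directed=False)
    if n_comp != 1:
        raise ValueError(
            f"affinity graph has {n_comp} connected components; diffusion "
            "embedding requires a single component"
        )
    return a


def variance_explained(eigenvalues: np.ndarray) -> np.ndarray:
    """Share of each retained non-trivial eigenvalue in their total.

    ratio_i = lambda_i / sum_j lambda_j; the ratios are non-increasing and
    sum to 1 over the retained set.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.ndim != 1 or lam.size == 0:
        raise ValueError("eigenvalues must be a non-empty 1-D array")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be in descending order")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    total = lam.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero; variance shares undefined")
    return lam / total


class DiffusionGradients(BaseEstimator):
    """Diffusion-map embedding of a symmetric non-negative affinity matrix.

    The affinity is degree-normalised with exponent ``alpha``
    (W = D^-alpha A D^-alpha), row-normalised to a Markov operator, and
    eigendecomposed. The trivial stationary eigenvector (eigenvalue 1) is
    dropped; the remaining right eigenvectors, scaled by
    lambda / (1 - lambda) (``diffusion_time = 0``) or lambda ** t, are the
    gradients. Each gradient is oriented so its largest-magnitude loading
    is positive, making repeated runs identical.

    Attributes (after :meth:`fit`)
    ------------------------------
    gradients_ : (N, n_components) node coordinates.
    eigenvalues_ : non-trivial eigenvalues, descending.
    variance_explained_ratio_ : eigenvalue shares over the retained set.
    trivial_eigenvalue_ : the dropped eigenvalue (1 up to round-off).
    """

    def __init__(self, n_components: int = 10, alpha: float = 0.5, diffusion_time: float = 0.0):
        self.n_components = n_components
        self.alpha = alpha
        self.diffusion_time = diffusion_time

    def fit(self, X: np.ndarray, y=None) -> "DiffusionGradients":
        config = EmbeddingConfig(
            alpha=self.alpha,
            diffusion_time=self.diffusion_time,
            n_components=self.n_components,
        )
        a = _validate_affinity(X)
        n = a.shape[0]
        if n < self.n_components + 1:
            raise ValueError(
                f"affinity of size {n} cannot yield {self.n_components} "
                "non-trivial gradients"
            )
        degree = a.sum(axis=1)
        w = a / np.outer(degree**config.alpha, degree**config.alpha)
        d2 = w.sum(axis=1)
        # symmetric conjugate of the Markov operator P = D2^-1 W:
        # M = D2^-1/2 W D2^-1/2 shares P's eigenvalues; right eigenvectors
        # of P are D2^-1/2 times M's orthonormal eigenvectors.
        inv_sqrt = 1.0 / np.sqrt(d2)
        m = w * np.outer(inv_sqrt, inv_sqrt)
        m = (m + m.T) / 2.0
        lams, vecs = eigh(m, subset_by_index=(n - self.n_components - 1, n - 1))
        order = np.argsort(lams)[::-1]
        lams = lams[order]
        vecs = vecs[:, order]
        psi = vecs * inv_sqrt[:, None]
        # normalise so the trivial eigenvector is the constant 1-vector
        psi = psi / psi[:, [0]]
        self.trivial_eigenvalue_ = float(lams[0])
        lam_rest = lams[1:]
        if config.diffusion_time == 0:
            scale = lam_rest / (1.0 - lam_rest)
        else:
            scale = lam_rest**config.diffusion_time
        coords = psi[:, 1:] * scale
        # deterministic sign: largest-|loading| entry of each gradient positive
        flip = coords[np.abs(coords).argmax(axis=0), np.arange(coords.shape[1])] < 0
        coords[:, flip] *= -1.0
        self.gradients_ = coords
        self.eigenvalues_ = lam_rest
        self.variance_explained_ratio_ = variance_explained(np.clip(lam_rest, 0, None))
        self.n_features_in_ = n
        self.config_ = config
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).gradients_


def diffusion_embedding(
    affinity: np.ndarray,
    config: EmbeddingConfig | None = None,
    node_ids: list[str] | None = None,
) -> GradientEmbedding:
    """Functional wrapper around :class:`DiffusionGradients`."""
    config = config or EmbeddingConfig()
    est = DiffusionGradients(
        n_components=config.n_components,
        alpha=config.alpha,
        diffusion_time=config.diffusion_time,
    ).fit(affinity)
    return GradientEmbedding(
        coords=est.gradients_,
        eigenvalues=est.eigenvalues_,
        variance_ratios=est.variance_explained_ratio_,
        node_ids=node_ids,
        config=config,
    )


class ProcrustesAlignment(BaseEstimator, TransformerMixin):
    """Orthogonal Procrustes alignment to a fixed template embedding.

    :meth:`fit` stores the template; :meth:`transform` centres a source
    embedding, finds the orthogonal matrix (rotation or reflection, no
    scaling) minimising the Frobenius distance to the centred template,
    and re-attaches the template's column means. The residual Frobenius
    distance of the last transform is stored in ``residual_``.
    """

    def __init__(self):
        pass

    def fit(self, X: np.ndarray, y=None) -> "ProcrustesAlignment":
        template = np.asarray(X, dtype=float)
        if template.ndim != 2:
            raise ValueError("template must be an N x G matrix")
        self.template_mean_ = template.mean(axis=0)
        self.template_centered_ = template - self.template_mean_
        self.n_features_in_ = template.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        source = np.asarray(X, dtype=float)
        if source.shape != self.template_centered_.shape:
            raise ValueError(
                f"source shape {source.shape} does not match template shape "
                f"{self.template_centered_.shape}"
            )
        centered = source - source.mean(axis=0)
        rotation, _ = orthogonal_procrustes(centered, self.template_centered_)
        aligned = centered @ rotation + self.template_mean_
        self.rotation_ = rotation
        self.residual_ = float(
            np.linalg.norm(centered @ rotation - self.template_centered_)
        )
        return aligned


def procrustes_align(source: GradientEmbedding, template: GradientEmbedding) -> GradientEmbedding:
    """Align a source embedding to a template; returns a new embedding with
    alignment state ``procrustes_aligned`` and the residual distance."""
    if source.coords.shape != template.coords.shape:
        raise ValueError(
            f"source {source.coords.shape} and template {template.coords.shape} "
            "dimensions differ"
        )
    est = ProcrustesAlignment().fit(template.coords)
    aligned = est.transform(source.coords)
    return GradientEmbedding(
        coords=aligned,
        eigenvalues=source.eigenvalues,
        variance_ratios=source.variance_ratios,
        alignment="procrustes_aligned",
        node_ids=source.node_ids,
        procrustes_residual=est.residual_,
        config=source.config,
    )
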