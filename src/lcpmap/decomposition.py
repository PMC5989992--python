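"""Economical SVD of fingerprint matrices and component-score projection.

With far more fiber elements than subjects (``p >> n``), the cohort matrix
``X`` is decomposed as ``X = U S V^T`` using the thin (economical) SVD, which
never forms the ``p x p`` Gram matrix. The rows of ``Z = U S`` (equivalently
``X V``) are the subjects' component scores and the columns of ``V`` are the
principal axes in fiber space.

No column centering is applied by default: decomposing the raw matrix keeps
the shared mean fingerprint inside the span of the leading axes, so a
truncated reconstruction recovers it. A ``center`` flag exists for comparing
against conventional (centered) PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Decomposition",
    "economical_svd",
    "component_scores",
    "variance_explained",
    "components_for_fraction",
    "reconstruct",
    "save_decomposition",
    "load_decomposition",
]

# relative threshold below which trailing singular values are treated as
# numerically zero and truncated
_RANK_RTOL = 1e-10


@dataclass
class Decomposition:
    """Thin SVD of a training fingerprint matrix.

    ``U`` is ``n x r`` and ``V`` is ``p x r``, both with orthonormal columns;
    ``S`` holds the ``r`` retained singular values in non-increasing order.
    ``column_means`` is zero unless the matrix was centered before
    decomposition, and is added back on reconstruction.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    training_subject_ids: np.ndarray
    column_means: np.ndarray | None = None

    @property
    def r(self) -> int:
        return len(self.S)

    @property
    def scores(self) -> np.ndarray:
        """Training component scores ``Z = U S``."""
        return self.U * self.S


def economical_svd(
    X: np.ndarray,
    subject_ids: np.ndarray | None = None,
    center: bool = False,
) -> Decomposition:
    """Thin SVD ``X = U S V^T`` with deterministic sign and rank truncation.

    Sign ambiguity is removed by forcing each principal axis's
    largest-magnitude entry positive, so repeated runs are bit-identical.
    Singular values below ``1e-10 * S_max`` are truncated (numerical rank).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("X must be an n x p matrix with n >= 2, p >= 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if subject_ids is None:
        subject_ids = np.arange(X.shape[0])
    means = None
    if center:
        means = X.mean(axis=0)
        X = X - means
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S[0] > 0:
        keep = S > _RANK_RTOL * S[0]
        U, S, Vt = U[:, keep], S[keep], Vt[keep]
    V = Vt.T
    # deterministic sign: largest-|entry| of each axis made positive
    pivot = np.abs(V).argmax(axis=0)
    signs = np.sign(V[pivot, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    U = U * signs
    return Decomposition(U, S, V, np.asarray(subject_ids), column_means=means)


def component_scores(d: Decomposition, X_new: np.ndarray) -> np.ndarray:
    """Project new fingerprints onto the principal axes: ``Z_new = X_new V``.

    For the training rows this reproduces ``U S`` exactly (the algebraic
    identity ``X V = U S V^T V = U S``).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != d.V.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, decomposition expects {d.V.shape[0]}"
        )
    if d.column_means is not None:
        X_new = X_new - d.column_means
    return X_new @ d.V


def variance_explained(d: Decomposition) -> np.ndarray:
    """Cumulative fraction of variance carried by the leading components.

    Component ``j`` carries ``S_j^2 / sum(S^2)``; the returned curve is
    non-decreasing with final value 1.
    """
    s2 = d.S**2
    total = s2.sum()
    if total == 0:
        raise ValueError("all singular values are zero")
    return np.cumsum(s2) / total


def components_for_fraction(d: Decomposition, fraction: float) -> int:
    """Smallest component count whose cumulative variance reaches ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    curve = variance_explained(d)
    return int(np.searchsorted(curve, fraction - 1e-12) + 1)


def reconstruct(d: Decomposition, k: int | None = None) -> np.ndarray:
    """Rank-``k`` approximation of the training matrix (all components if None).

    By the Eckart-Young theorem the Frobenius error equals the tail energy
    ``sqrt(sum_{j>k} S_j^2)``; it is non-increasing in ``k``.
    """
    if k is None:
        k = d.r
    if not 1 <= k <= d.r:
        raise ValueError(f"k must be in [1, {d.r}], got {k}")
    X = (d.U[:, :k] * d.S[:k]) @ d.V[:, :k].T
    if d.column_means is not None:
        X = X + d.column_means
    return X


def save_decomposition(d: Decomposition, path) -> None:
    """Persist a decomposition under ``/decomposition`` in an HDF5 container.

    Appends to (or creates) the file, so it can live alongside the
    fingerprint datasets.
    """
    import h5py

    with h5py.File(path, "a") as f:
        if "decomposition" in f:
            del f["decomposition"]
        g = f.create_group("decomposition")
        g.create_dataset("U", data=d.U)
        g.create_dataset("S", data=d.S)
        g.create_dataset("V", data=d.V)
        g.create_dataset(
            "training_subject_ids",
            data=np.asarray([str(s) for s in d.training_subject_ids], dtype=object),
            dtype=h5py.string_dtype(),
        )
        if d.column_means is not None:
            g.create_dataset("column_means", data=d.column_means)


def load_decomposition(path) -> Decomposition:
    """Read a decomposition stored by :func:`save_decomposition`."""
    import h5py

    with h5py.File(path, "r") as f:
        if "decomposition" not in f:
            raise ValueError("container has no 'decomposition' group")
        g = f["decomposition"]
        ids = np.asarray([s.decode() if isinstance(s, bytes) else str(s)
                          for s in g["training_subject_ids"][()]], dtype=object)
        means = g["column_means"][()] if "column_means" in g else None
        return Decomposition(g["U"][()], g["S"][()], g["V"][()], ids,
                             column_means=means)
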