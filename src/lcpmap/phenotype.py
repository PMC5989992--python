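"""Local connectome phenotype (LCP) maps: back-projection and prediction.

A fitted sparse component regression lives in component space; projecting
its truncated coefficients back through the principal axes,

    w_hat = V beta_star,

yields a fiber-wise weight map — the *local connectome phenotype* — that
assigns each fiber element its contribution to the prediction of one subject
attribute. Held-out prediction is then a plain dot product
``y_hat_i = x_i . w_hat`` (no ICV, no intercept: continuous predictions are
scored by correlation, which is location/scale invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import Decomposition, component_scores
from .regression import SparseModel
from .store import ElementMap

__all__ = [
    "LCPMap",
    "VoxelMap",
    "build_phenotype_map",
    "predict_from_map",
    "predict_binary",
    "project_to_voxels",
    "phenotype_correlation_matrix",
    "save_phenotype_map",
    "load_phenotype_map",
    "save_voxel_map_nifti",
]


@dataclass
class LCPMap:
    """A fiber-wise phenotype weight map for one response.

    ``weights`` has one entry per fingerprint element (dimensionless
    regression weight); ``fold_id`` is ``"full"`` for full-sample maps or the
    fold label of a cross-validation training split.
    """

    weights: np.ndarray
    response_name: str = ""
    fold_id: str = "full"
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("phenotype map contains non-finite weights")

    @property
    def p(self) -> int:
        return len(self.weights)


@dataclass
class VoxelMap:
    """Phenotype weights averaged per voxel on a 3-D grid."""

    values: np.ndarray
    dims: tuple[int, int, int]
    background: float = 0.0


def build_phenotype_map(
    d: Decomposition,
    beta_star: np.ndarray,
    response_name: str = "",
    fold_id: str = "full",
) -> LCPMap:
    """Back-project truncated coefficients into fiber space: ``w = V beta_star``."""
    beta_star = np.asarray(beta_star, dtype=float).ravel()
    if len(beta_star) != d.r:
        raise ValueError(
            f"beta_star has length {len(beta_star)}, decomposition rank is {d.r}"
        )
    return LCPMap(d.V @ beta_star, response_name=response_name, fold_id=fold_id)


def predict_from_map(lcp: LCPMap, X_new: np.ndarray) -> np.ndarray:
    """Score subjects against a phenotype map: ``y_hat_i = x_i . w``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != lcp.p:
        raise ValueError(
            f"fingerprints have {X_new.shape[1]} elements, map has {lcp.p}"
        )
    return X_new @ lcp.weights


def predict_binary(
    m: SparseModel,
    d: Decomposition,
    X_new: np.ndarray,
    icv_new: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and probabilities from a fitted logistic model.

    Probability is the inverse logit of ``intercept + z . beta +
    beta_icv * icv`` with ``z`` the component scores of the new fingerprints.
    A probability of exactly 0.5 is labeled class 1.
    """
    if m.family != "logistic":
        raise ValueError("predict_binary requires a logistic-family model")
    Z_new = component_scores(d, X_new)
    icv_new = np.asarray(icv_new, dtype=float).ravel()
    eta = m.intercept + Z_new @ m.beta + m.beta_icv * icv_new
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (prob >= 0.5).astype(int), prob


def project_to_voxels(
    lcp: LCPMap, em: ElementMap, dims: tuple[int, int, int] | None = None,
    background: float = 0.0,
) -> VoxelMap:
    """Average fiber weights within each voxel onto a 3-D grid.

    Voxels containing several fiber populations get the mean of their
    members' weights; voxels with no fibers get ``background``.
    """
    if len(em) != lcp.p:
        raise ValueError(f"element map covers {len(em)} elements, map has {lcp.p}")
    if dims is None:
        dims = em.dims
    if dims is None:
        raise ValueError("volume dims required (not recorded in element map)")
    dims = tuple(int(x) for x in dims)
    for arr, d in zip((em.i, em.j, em.k), dims):
        if len(arr) and (arr.min() < 0 or arr.max() >= d):
            raise ValueError("element coordinates outside volume dims")
    total = np.zeros(dims)
    count = np.zeros(dims)
    np.add.at(total, (em.i, em.j, em.k), lcp.weights)
    np.add.at(count, (em.i, em.j, em.k), 1.0)
    values = np.full(dims, float(background))
    filled = count > 0
    values[filled] = total[filled] / count[filled]
    return VoxelMap(values, dims, background=background)


def phenotype_correlation_matrix(maps: list[LCPMap]) -> np.ndarray:
    """Pairwise Pearson correlations between phenotype maps.

    Quantifies how specific each phenotype's anatomical weighting is: maps
    for unrelated attributes should decorrelate.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    lengths = {m.p for m in maps}
    if len(lengths) != 1:
        raise ValueError("maps have mismatched lengths")
    W = np.stack([m.weights for m in maps])
    if np.any(W.std(axis=1) == 0):
        raise ValueError("constant phenotype map has no defined correlation")
    C = np.corrcoef(W)
    np.fill_diagonal(C, 1.0)
    return C


def save_phenotype_map(lcp: LCPMap, path) -> None:
    """Store a phenotype map under ``/phenotypes/<response>`` in a container."""
    import h5py

    name = lcp.response_name or "unnamed"
    with h5py.File(path, "a") as f:
        g = f.require_group("phenotypes")
        if name in g:
            del g[name]
        ds = g.create_dataset(name, data=lcp.weights)
        ds.attrs["fold_id"] = lcp.fold_id


def load_phenotype_map(path, response_name: str) -> LCPMap:
    """Read a phenotype map stored by :func:`save_phenotype_map`."""
    import h5py

    with h5py.File(path, "r") as f:
        if "phenotypes" not in f or response_name not in f["phenotypes"]:
            raise ValueError(f"container has no phenotype map {response_name!r}")
        ds = f["phenotypes"][response_name]
        return LCPMap(ds[()], response_name=response_name,
                      fold_id=str(ds.attrs.get("fold_id", "full")))


def save_voxel_map_nifti(vm: VoxelMap, path, affine: np.ndarray | None = None) -> None:
    """Export a voxel map as NIfTI-1 (float32, identity affine by default)."""
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(vm.values.astype(np.float32), affine), str(path))
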