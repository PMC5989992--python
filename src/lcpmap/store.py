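"""Data model and I/O for fingerprint matrices, element maps, and attribute tables.

A *local connectome fingerprint* is a per-subject vector of fiber-wise
diffusion-density estimates, sampled along atlas-defined axonal directions in
white-matter voxels. A cohort of fingerprints is an ``n x p`` matrix ``X``
(subjects by fiber elements). Because the density units are arbitrary, each
fingerprint is scaled to unit sample variance before analysis.

Containers round-trip losslessly through HDF5 (or TSV for tiny fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "FingerprintMatrix",
    "ElementMap",
    "AttributeTable",
    "scale_to_unit_variance",
    "save_fingerprints",
    "load_fingerprints",
    "prepare_binary_response",
    "align_and_drop_missing",
]


@dataclass
class FingerprintMatrix:
    """An ``n x p`` matrix of per-subject fingerprints with subject labels.

    Parameters
    ----------
    values
        Real matrix, one row per subject, one column per fiber element.
    subject_ids
        Unique subject labels, length ``n``.
    """

    values: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("fingerprint values must be a 2-D matrix")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.subject_ids)} subject IDs for {self.values.shape[0]} rows"
            )
        if len(set(self.subject_ids.tolist())) != len(self.subject_ids):
            raise ValueError("subject IDs must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, index: np.ndarray) -> "FingerprintMatrix":
        """Row subset by positional index, preserving order."""
        return FingerprintMatrix(self.values[index], self.subject_ids[index])


@dataclass
class ElementMap:
    """Feature index -> (voxel coordinate, fiber-direction index) lookup.

    Voxel coordinates are 0-based indices in atlas space; ``direction`` tells
    which fiber population within the voxel the element samples. The axis
    order of the original sampling (left-posterior-superior) is metadata only.
    """

    i: np.ndarray
    j: np.ndarray
    k: np.ndarray
    direction: np.ndarray
    dims: tuple[int, int, int] | None = None
    axis_order: str = "LPS"

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        self.direction = np.asarray(self.direction, dtype=np.int64)
        lengths = {len(self.i), len(self.j), len(self.k), len(self.direction)}
        if len(lengths) != 1:
            raise ValueError("element map columns have mismatched lengths")
        coords = np.stack([self.i, self.j, self.k, self.direction], axis=1)
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("(voxel, direction) pairs must be unique")
        if self.dims is not None:
            dims = tuple(int(d) for d in self.dims)
            if len(dims) != 3:
                raise ValueError("dims must be a 3-tuple")
            self.dims = dims
            for arr, d in zip((self.i, self.j, self.k), dims):
                if len(arr) and (arr.min() < 0 or arr.max() >= d):
                    raise ValueError("voxel coordinates outside stated dims")
        elif len(self.i) and min(self.i.min(), self.j.min(), self.k.min()) < 0:
            raise ValueError("voxel coordinates must be non-negative")

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class AttributeTable:
    """Subject attributes (responses) plus intracranial volume.

    ``table`` is indexed by subject ID and must contain an ``icv`` column
    (intracranial volume, mm^3, positive). ``kinds`` tags every response
    column as ``"continuous"`` or ``"categorical"``; missing values are
    permitted per column and handled downstream by complete-case deletion.
    """

    table: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "icv" not in self.table.columns:
            raise ValueError("attribute table requires an 'icv' column")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate subject IDs in attribute table")
        icv = self.table["icv"].to_numpy(dtype=float)
        if np.nanmin(icv) <= 0:
            raise ValueError("ICV must be positive")
        for name, kind in self.kinds.items():
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"unknown column kind {kind!r} for {name!r}")
            if name not in self.table.columns:
                raise ValueError(f"kinds references missing column {name!r}")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    @property
    def icv(self) -> np.ndarray:
        return self.table["icv"].to_numpy(dtype=float)

    def column(self, name: str) -> pd.Series:
        return self.table[name]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path: str | Path, kinds: dict[str, str] | None = None) -> "AttributeTable":
        df = pd.read_csv(path, index_col="subject_id")
        df.index = df.index.astype(str)
        if kinds is None:
            kinds = {
                c: ("continuous" if pd.api.types.is_numeric_dtype(df[c]) else "categorical")
                for c in df.columns
                if c != "icv"
            }
        return cls(df, kinds)


def scale_to_unit_variance(fp: FingerprintMatrix) -> FingerprintMatrix:
    """Scale every fingerprint row to unit sample variance.

    Density estimates carry arbitrary units, so each subject's vector is
    rescaled so its sample variance (ddof=1 across elements) equals 1. The
    row direction is preserved (each row is a positive multiple of the
    original). Idempotent.
    """
    sd = fp.values.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        raise ValueError(
            f"constant fingerprint row for subject {fp.subject_ids[bad[0]]!r}: "
            "variance is zero, cannot scale"
        )
    return FingerprintMatrix(fp.values / sd[:, None], fp.subject_ids)


def save_fingerprints(
    fp: FingerprintMatrix,
    em: ElementMap | None,
    path: str | Path,
    dtype: np.dtype | str | None = None,
) -> None:
    """Write a fingerprint container (HDF5 ``.h5``/``.hdf5``, else TSV).

    The matrix is stored under ``/fingerprints`` with ``/subject_ids`` and,
    when given, ``/element_map``. The stored dtype defaults to the matrix's
    own dtype so a save/load round-trip is bit-exact; pass ``dtype="float32"``
    to downcast large cohorts.
    """
    if em is not None and len(em) != fp.p:
        raise ValueError(f"element map length {len(em)} does not match p={fp.p}")
    path = Path(path)
    values = fp.values if dtype is None else fp.values.astype(dtype)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("fingerprints", data=values)
            f.create_dataset(
                "subject_ids",
                data=np.asarray([str(s) for s in fp.subject_ids], dtype=object),
                dtype=h5py.string_dtype(),
            )
            if em is not None:
                g = f.create_group("element_map")
                for name in ("i", "j", "k", "direction"):
                    g.create_dataset(name, data=getattr(em, name))
                if em.dims is not None:
                    g.attrs["dims"] = em.dims
                g.attrs["axis_order"] = em.axis_order
    else:
        df = pd.DataFrame(values, index=[str(s) for s in fp.subject_ids])
        # %.17g guarantees a bit-exact float64 round trip through text
        df.to_csv(path, sep="\t", index_label="subject_id", float_format="%.17g")
        if em is not None:
            em_df = pd.DataFrame(
                {"i": em.i, "j": em.j, "k": em.k, "direction": em.direction}
            )
            em_df.to_csv(Path(str(path) + ".elements.tsv"), sep="\t", index=False)


def load_fingerprints(path: str | Path) -> tuple[FingerprintMatrix, ElementMap | None]:
    """Read a container written by :func:`save_fingerprints`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "fingerprints" not in f:
                raise ValueError("container missing 'fingerprints' dataset")
            if "subject_ids" not in f:
                raise ValueError("container missing 'subject_ids' dataset")
            values = f["fingerprints"][()]
            ids = np.asarray([s.decode() if isinstance(s, bytes) else str(s)
                              for s in f["subject_ids"][()]], dtype=object)
            em = None
            if "element_map" in f:
                g = f["element_map"]
                dims = tuple(int(d) for d in g.attrs["dims"]) if "dims" in g.attrs else None
                em = ElementMap(
                    g["i"][()], g["j"][()], g["k"][()], g["direction"][()],
                    dims=dims, axis_order=str(g.attrs.get("axis_order", "LPS")),
                )
    else:
        df = pd.read_csv(path, sep="\t", index_col="subject_id",
                         float_precision="round_trip")
        values = df.to_numpy()
        ids = df.index.to_numpy(dtype=object)
        em_path = Path(str(path) + ".elements.tsv")
        em = None
        if em_path.exists():
            em_df = pd.read_csv(em_path, sep="\t")
            em = ElementMap(em_df["i"], em_df["j"], em_df["k"], em_df["direction"])
    fp = FingerprintMatrix(values, ids)
    if em is not None and len(em) != fp.p:
        raise ValueError(f"element map length {len(em)} does not match p={fp.p}")
    return fp, em


def prepare_binary_response(
    table: AttributeTable, column: str, min_class_count: int = 50
) -> tuple[pd.Series, np.ndarray, int]:
    """Binarize a categorical response, dropping rare categories.

    Keeps the two largest classes that each reach ``min_class_count``
    subjects and drops everyone else. The larger class is encoded 0 and the
    smaller 1; exact ties break lexicographically (first label -> 0).

    Returns ``(binary response indexed by subject, retained subject IDs,
    number of subjects dropped)``.
    """
    if table.kinds.get(column) != "categorical":
        raise ValueError(f"column {column!r} is not tagged categorical")
    col = table.column(column).dropna()
    counts = col.value_counts()
    eligible = counts[counts >= min_class_count]
    if len(eligible) < 2:
        raise ValueError(
            f"fewer than two classes of {column!r} reach min_class_count={min_class_count}"
        )
    # deterministic order: by descending size, then label
    order = sorted(eligible.index, key=lambda c: (-int(eligible[c]), str(c)))
    keep = order[:2]
    mask = col.isin(keep)
    retained = col[mask]
    y = (retained == keep[1]).astype(int)
    dropped = len(table.table) - int(mask.sum())
    return y, retained.index.to_numpy(dtype=object), dropped


def align_and_drop_missing(
    fp: FingerprintMatrix,
    table: AttributeTable,
    response,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Align fingerprints, ICV and a response by subject ID, complete-case.

    ``response`` is a pandas Series indexed by subject ID (for example a
    continuous column of the table, or the output of
    :func:`prepare_binary_response`). Subjects missing the response or ICV
    are excluded; row order follows the fingerprint matrix.

    Returns ``(X, icv, y, subject_ids)`` for the retained subjects.
    """
    response = pd.Series(response).dropna()
    icv = table.table["icv"].dropna()
    ok = set(response.index) & set(icv.index)
    keep = [idx for idx, sid in enumerate(fp.subject_ids) if sid in ok]
    if not keep:
        raise ValueError("no subjects shared between fingerprints and response")
    keep = np.asarray(keep)
    sids = fp.subject_ids[keep]
    X = fp.values[keep]
    return X, icv.loc[sids].to_numpy(dtype=float), response.loc[sids].to_numpy(dtype=float), sids
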