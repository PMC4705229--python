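"""Labeled multivariate datasets.

Readers for the MNIST-style IDX binary convention and delimited-text
tables, the first-come benchmark subset rule, per-feature min-max
scaling, and a synthetic Gaussian-cluster generator so that every
pipeline stage can be exercised without downloading external data.

All samples live in the unit hypercube [0, 1]^d; class identifiers are
integers kept in first-appearance order.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "IdxFormatError",
    "load_idx",
    "write_idx",
    "load_table",
    "build_subset",
    "make_synthetic",
    "fit_minmax",
    "apply_minmax",
]

_IDX_IMAGES_MAGIC = 2051
_IDX_LABELS_MAGIC = 2049


class IdxFormatError(ValueError):
    """Raised when an IDX file violates the binary convention."""


@dataclass
class Dataset:
    """An n x d matrix of real-valued samples in [0, 1] with integer labels.

    Attributes
    ----------
    samples:
        Array of shape (n, d), dtype float64, every entry in [0, 1].
    labels:
        Array of shape (n,), integer class identifiers.
    class_set:
        Distinct classes in first-appearance order.
    """

    samples: np.ndarray
    labels: np.ndarray
    class_set: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n, d) matrix")
        if self.labels.shape != (self.samples.shape[0],):
            raise ValueError("labels length must match number of samples")
        if not self.class_set:
            self.class_set = _first_appearance_order(self.labels)
        missing = set(self.labels.tolist()) - set(self.class_set)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in class_set")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_features(self) -> int:
        return self.samples.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.class_set}


def _first_appearance_order(labels: np.ndarray) -> tuple[int, ...]:
    seen: dict[int, None] = {}
    for lab in labels.tolist():
        seen.setdefault(int(lab), None)
    return tuple(seen)


def _read_idx_header(buf: bytes, expect_magic: int, path: str) -> tuple[int, tuple[int, ...], int]:
    """Return (n_records, trailing dims, header size) from an IDX buffer."""
    if len(buf) < 8:
        raise IdxFormatError(f"{path}: truncated IDX header")
    magic = struct.unpack(">i", buf[:4])[0]
    if magic != expect_magic:
        raise IdxFormatError(
            f"{path}: bad magic number {magic}, expected {expect_magic}"
        )
    n_dims = magic & 0xFF
    header = 4 + 4 * n_dims
    if len(buf) < header:
        raise IdxFormatError(f"{path}: truncated IDX dimension block")
    dims = struct.unpack(f">{n_dims}i", buf[4:header])
    return dims[0], tuple(dims[1:]), header


def load_idx(images_path: str, labels_path: str) -> Dataset:
    """Read an IDX image/label file pair into a Dataset.

    Images (magic 2051, u8 pixels, big-endian dims n x rows x cols) are
    flattened row-major and divided by 255 into [0, 1]; labels come from
    the companion file (magic 2049).
    """
    with open(images_path, "rb") as fh:
        img_buf = fh.read()
    with open(labels_path, "rb") as fh:
        lab_buf = fh.read()

    n_img, img_dims, img_header = _read_idx_header(img_buf, _IDX_IMAGES_MAGIC, str(images_path))
    n_lab, _, lab_header = _read_idx_header(lab_buf, _IDX_LABELS_MAGIC, str(labels_path))
    if n_img != n_lab:
        raise ValueError(
            f"record count mismatch: {n_img} images vs {n_lab} labels"
        )
    d = int(np.prod(img_dims)) if img_dims else 1
    expected = img_header + n_img * d
    if len(img_buf) < expected:
        raise IdxFormatError(f"{images_path}: truncated pixel data")
    if len(lab_buf) < lab_header + n_lab:
        raise IdxFormatError(f"{labels_path}: truncated label data")

    pixels = np.frombuffer(img_buf, dtype=np.uint8, count=n_img * d, offset=img_header)
    samples = pixels.reshape(n_img, d).astype(np.float64) / 255.0
    labels = np.frombuffer(lab_buf, dtype=np.uint8, count=n_lab, offset=lab_header).astype(np.int64)
    return Dataset(samples=samples, labels=labels)


def write_idx(dataset: Dataset, images_path: str, labels_path: str,
              image_shape: tuple[int, int] | None = None) -> None:
    """Write a Dataset back to an IDX image/label file pair.

    Pixel values are recovered as round(sample * 255); a dataset read with
    :func:`load_idx` therefore round-trips byte-identically.
    """
    n, d = dataset.samples.shape
    if image_shape is None:
        side = int(round(d ** 0.5))
        if side * side != d:
            raise ValueError("non-square feature count; pass image_shape explicitly")
        image_shape = (side, side)
    rows, cols = image_shape
    if rows * cols != d:
        raise ValueError("image_shape does not match feature count")
    pixels = np.rint(dataset.samples * 255.0).astype(np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">iiii", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(pixels.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">ii", _IDX_LABELS_MAGIC, n))
        fh.write(dataset.labels.astype(np.uint8).tobytes())


def load_table(path: str, label_col: int | str = -1, delimiter: str | None = None,
               header: bool = False) -> Dataset:
    """Read a delimited-text table: one sample per row, label in `label_col`.

    Features are NOT rescaled here; callers apply :func:`fit_minmax` /
    :func:`apply_minmax` with statistics from the training split.
    """
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None,
                     engine="python")
    if isinstance(label_col, str):
        labels = df[label_col].to_numpy()
        feats = df.drop(columns=[label_col]).to_numpy(dtype=np.float64)
    else:
        labels = df.iloc[:, label_col].to_numpy()
        feats = df.drop(columns=[df.columns[label_col]]).to_numpy(dtype=np.float64)
    return Dataset(samples=feats, labels=labels.astype(np.int64))


def build_subset(dataset: Dataset, allowed: list[int], max_per_class: int) -> Dataset:
    """First-come benchmark subset: traverse in original order, keeping up to
    `max_per_class` examples of each allowed class.
    """
    if max_per_class < 1:
        raise ValueError("max_per_class must be >= 1")
    allowed_order = list(dict.fromkeys(int(a) for a in allowed))
    present = set(dataset.class_set)
    kept_classes = []
    for a in allowed_order:
        if a not in present:
            warnings.warn(f"class {a} absent from dataset; dropped", stacklevel=2)
        else:
            kept_classes.append(a)
    counts = {c: 0 for c in kept_classes}
    idx = []
    for i, lab in enumerate(dataset.labels.tolist()):
        if lab in counts and counts[lab] < max_per_class:
            counts[lab] += 1
            idx.append(i)
    idx = np.asarray(idx, dtype=np.int64)
    sub_labels = dataset.labels[idx] if idx.size else np.empty(0, dtype=np.int64)
    class_set = tuple(c for c in _first_appearance_order(sub_labels))
    return Dataset(samples=dataset.samples[idx] if idx.size else
                   np.empty((0, dataset.n_features)),
                   labels=sub_labels, class_set=class_set or ())


def make_synthetic(k_classes: int, dim: int, n_per_class: int,
                   separation: float, noise_sd: float, seed: int) -> Dataset:
    """Generate Gaussian-cluster class data inside the unit hypercube.

    Class means sit on a regular simplex so every pair of means is exactly
    `separation` apart; samples are isotropic Gaussian around their mean
    with standard deviation `noise_sd`, then clipped into [0, 1]^dim.
    Deterministic for a fixed seed.
    """
    if k_classes < 2:
        raise ValueError("k_classes must be >= 2")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if dim < k_classes - 1:
        raise ValueError(
            f"cannot place {k_classes} equidistant means in {dim} dimensions"
        )
    # regular simplex: scaled unit-basis vectors are pairwise sqrt(2) apart,
    # so scale = separation / sqrt(2); k = dim + 1 adds the apex vertex.
    scale = separation / np.sqrt(2.0)
    basis = np.zeros((k_classes, dim))
    for c in range(min(k_classes, dim)):
        basis[c, c] = 1.0
    if k_classes > dim:
        centroid = basis[:dim].mean(axis=0)
        r2 = float(np.sum((basis[0] - centroid) ** 2))
        h = np.sqrt(max(1.0 - r2, 0.0))
        basis[dim] = centroid + h * np.ones(dim) / np.sqrt(dim)
    means = scale * basis
    means = means - means.mean(axis=0) + 0.5
    if means.min() < -1e-9 or means.max() > 1.0 + 1e-9:
        raise ValueError(
            f"separation {separation} places class means outside the unit cube"
        )
    rng = np.random.default_rng(seed)
    samples = np.empty((k_classes * n_per_class, dim))
    labels = np.empty(k_classes * n_per_class, dtype=np.int64)
    for c in range(k_classes):
        block = slice(c * n_per_class, (c + 1) * n_per_class)
        samples[block] = means[c] + noise_sd * rng.standard_normal((n_per_class, dim))
        labels[block] = c
    np.clip(samples, 0.0, 1.0, out=samples)
    # interleave classes so order-sensitive consumers see a mixed stream
    order = np.arange(k_classes * n_per_class).reshape(k_classes, n_per_class).T.ravel()
    return Dataset(samples=samples[order], labels=labels[order],
                   class_set=tuple(range(k_classes)))


def fit_minmax(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (low, span) statistics, computed on the training split only."""
    lo = samples.min(axis=0)
    span = samples.max(axis=0) - lo
    span[span == 0] = 1.0
    return lo, span


def apply_minmax(samples: np.ndarray, lo: np.ndarray, span: np.ndarray) -> np.ndarray:
    """Scale with training statistics and clip into [0, 1] (test values may
    exceed the training range)."""
    return np.clip((samples - lo) / span, 0.0, 1.0)
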