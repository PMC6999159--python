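"""Datasets: MNIST-style IDX files and a synthetic clustered generator.

The synthetic generator emulates the geometry that makes rate-coded digit
classification work: classes are unions of tight angular clusters of
non-negative, sparse, magnitude-insensitive vectors, with much larger
angular separation between classes than within a cluster. It produces
curricula for both the interleaved and the disjoint (class-sequential)
scenarios without any external download.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

IDX_IMAGES_MAGIC = 0x00000803
IDX_LABELS_MAGIC = 0x00000801


class IdxFormatError(ValueError):
    """Raised when an IDX file has a bad magic number or truncated payload."""


@dataclass
class Dataset:
    """Raw non-negative samples with integer class labels.

    ``samples`` is an (n, dim) float array; rows need not be normalized
    (rate coding normalizes at presentation time). ``class_order`` is the
    permutation in which classes are presented in the disjoint scenario.
    """

    samples: np.ndarray
    labels: np.ndarray
    class_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D array (n, dim)")
        if len(self.samples) != len(self.labels):
            raise ValueError("samples and labels length mismatch")
        if len(self.labels) and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if np.any(self.samples < 0):
            raise ValueError("samples must be non-negative")
        if not self.class_order:
            self.class_order = sorted(np.unique(self.labels).tolist())

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    @property
    def dim(self) -> int:
        return self.samples.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.samples[idx], self.labels[idx], list(self.class_order))

    def class_indices(self, cls: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cls)


# ---------------------------------------------------------------------------
# IDX reading/writing


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        head = fh.read(2)
    if head == b"\x1f\x8b":
        return gzip.open(path, "rb")
    return open(path, "rb")


def read_idx(path: str | Path) -> np.ndarray:
    """Read one IDX file (plain or gzipped) into a numpy array.

    Images (magic ``0x00000803``) come back as (n, rows, cols) uint8;
    labels (magic ``0x00000801``) as (n,) uint8.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        header = fh.read(4)
        if len(header) < 4:
            raise IdxFormatError(f"{path}: truncated header at offset 0")
        (magic,) = struct.unpack(">I", header)
        if magic == IDX_IMAGES_MAGIC:
            n_dims = 3
        elif magic == IDX_LABELS_MAGIC:
            n_dims = 1
        else:
            raise IdxFormatError(
                f"{path}: bad magic 0x{magic:08x} at offset 0 "
                f"(expected 0x{IDX_IMAGES_MAGIC:08x} images or "
                f"0x{IDX_LABELS_MAGIC:08x} labels)"
            )
        raw_dims = fh.read(4 * n_dims)
        if len(raw_dims) < 4 * n_dims:
            raise IdxFormatError(f"{path}: truncated dimension fields at offset 4")
        dims = struct.unpack(f">{n_dims}I", raw_dims)
        payload = fh.read()
    expected = int(np.prod(dims))
    if len(payload) < expected:
        raise IdxFormatError(
            f"{path}: truncated payload at offset {4 + 4 * n_dims + len(payload)} "
            f"(expected {expected} bytes, got {len(payload)})"
        )
    return np.frombuffer(payload[:expected], dtype=np.uint8).reshape(dims)


def load_idx_dataset(images_path: str | Path, labels_path: str | Path) -> Dataset:
    """Read an images/labels IDX pair into a flat-vector :class:`Dataset`."""
    images = read_idx(images_path)
    labels = read_idx(labels_path)
    if images.ndim != 3:
        raise IdxFormatError(f"{images_path}: not an images file")
    if labels.ndim != 1:
        raise IdxFormatError(f"{labels_path}: not a labels file")
    if len(images) != len(labels):
        raise IdxFormatError(
            f"image/label count mismatch: {len(images)} images vs "
            f"{len(labels)} labels"
        )
    flat = images.reshape(len(images), -1).astype(float)
    return Dataset(flat, labels.astype(int))


def write_idx_images(path: str | Path, images: np.ndarray) -> None:
    """Write a (n, rows, cols) uint8 array as an IDX images file."""
    images = np.ascontiguousarray(images, dtype=np.uint8)
    if images.ndim != 3:
        raise ValueError("images must be (n, rows, cols)")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", IDX_IMAGES_MAGIC, *images.shape))
        fh.write(images.tobytes())


def write_idx_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a (n,) array of small non-negative ints as an IDX labels file."""
    labels = np.ascontiguousarray(labels, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", IDX_LABELS_MAGIC, labels.size))
        fh.write(labels.tobytes())


def export_idx(dataset: Dataset, images_path: str | Path, labels_path: str | Path) -> None:
    """Export a dataset to the IDX layout (values quantized to 0..255).

    Samples are stored as n×dim×1 "images" so any IDX consumer can read
    them back; intensities are rescaled to the uint8 range, which is
    harmless for magnitude-insensitive data.
    """
    x = dataset.samples
    peak = x.max() if x.size else 1.0
    quant = np.round(x / peak * 255.0).astype(np.uint8)
    write_idx_images(images_path, quant.reshape(len(x), dataset.dim, 1))
    write_idx_labels(labels_path, dataset.labels)


# ---------------------------------------------------------------------------
# Synthetic clustered data


@dataclass
class SyntheticConfig:
    """Parameters of the clustered synthetic generator.

    ``intra_dot_min`` / ``inter_dot_max`` are realized-geometry targets:
    the mean within-cluster pairwise dot product must reach at least
    ``intra_dot_min`` and the mean between-class dot product must stay at
    or below ``inter_dot_max`` (all samples unit-normalized), else centers
    are redrawn.
    """

    dim: int = 64
    n_classes: int = 4
    clusters_per_class: int = 3
    samples_per_class: int = 60
    intra_dot_min: float = 0.95
    inter_dot_max: float = 0.65
    noise_sd: float = 0.02
    sparsity: float = 0.75
    core_fraction: float = 0.5
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.inter_dot_max < self.intra_dot_min <= 1):
            raise ValueError("need 0 < inter_dot_max < intra_dot_min <= 1")
        if self.dim < self.n_classes * self.clusters_per_class:
            raise ValueError("dim must be >= n_classes * clusters_per_class")
        if not (0 <= self.sparsity < 1):
            raise ValueError("sparsity must be in [0, 1)")
        if not (0 <= self.core_fraction < 1):
            raise ValueError("core_fraction must be in [0, 1)")


def _draw_centers(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Sparse non-negative unit centers with near-equal active components.

    Each center is supported on a "core" of channels shared by the whole
    dataset (like the central ink mass all digits share) plus a set of
    cluster-specific channels, with intensities drawn from a narrow band
    like the roughly uniform stroke intensity of a raster. The shared core
    makes a trained neuron angularly closer to a novel class than an
    untrained random-weight neuron is — the geometry that makes naive
    networks reuse and overwrite trained neurons — while the specific
    channels keep classes separable. Note that unit centers on a 16-channel
    support have components around 0.25, so the synaptic weight cap used
    with this data must sit above that (see the study configuration in the
    protocols module); otherwise the stabilized learning rule could not
    represent a cluster center as a weight vector.
    """
    n_centers = cfg.n_classes * cfg.clusters_per_class
    n_active = max(1, int(round((1.0 - cfg.sparsity) * cfg.dim)))
    n_core = min(int(round(cfg.core_fraction * n_active)), n_active - 1)
    n_spec = n_active - n_core

    channels = rng.permutation(cfg.dim)
    core_idx, free_idx = channels[:n_core], channels[n_core:]
    core_vals = rng.uniform(0.8, 1.0, size=n_core)

    centers = np.zeros((n_centers, cfg.dim))
    for c in centers:
        c[core_idx] = core_vals
        spec_idx = rng.choice(free_idx, size=n_spec, replace=False)
        c[spec_idx] = rng.uniform(0.8, 1.0, size=n_spec)
    norms = np.linalg.norm(centers, axis=1)
    return centers / norms[:, None]


def _realized_geometry(samples: np.ndarray, labels: np.ndarray,
                       cluster_ids: np.ndarray) -> tuple[float, float]:
    unit = samples / np.linalg.norm(samples, axis=1, keepdims=True)
    intra_means = []
    for cid in np.unique(cluster_ids):
        u = unit[cluster_ids == cid]
        n = len(u)
        if n < 2:
            continue
        s = u.sum(axis=0)
        intra_means.append((s @ s - n) / (n * (n - 1)))
    class_means = np.stack(
        [unit[labels == c].mean(axis=0) for c in np.unique(labels)]
    )
    gram = class_means @ class_means.T
    off = gram[~np.eye(len(gram), dtype=bool)]
    return float(np.mean(intra_means)), float(off.mean())


def generate_synthetic(cfg: SyntheticConfig) -> Dataset:
    """Generate an angularly clustered, class-sequential dataset.

    Cluster centers are sparse non-negative unit vectors; each sample is its
    center plus per-channel Gaussian noise, clipped at zero and
    L2-normalized. Centers are redrawn (up to ``cfg.max_retries``) until the
    realized intra-cluster / inter-class dot-product targets are met.
    Samples are emitted grouped by class in ascending class order.
    """
    rng = np.random.default_rng(cfg.seed)
    per_cluster = np.full(cfg.clusters_per_class, cfg.samples_per_class // cfg.clusters_per_class)
    per_cluster[: cfg.samples_per_class % cfg.clusters_per_class] += 1

    for _ in range(cfg.max_retries):
        centers = _draw_centers(cfg, rng)
        samples, labels, cluster_ids = [], [], []
        cid = 0
        for cls in range(cfg.n_classes):
            for k in range(cfg.clusters_per_class):
                n = per_cluster[k]
                base = centers[cls * cfg.clusters_per_class + k]
                noisy = base + rng.normal(0.0, cfg.noise_sd, size=(n, cfg.dim))
                np.clip(noisy, 0.0, None, out=noisy)
                noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
                samples.append(noisy)
                labels.extend([cls] * n)
                cluster_ids.extend([cid] * n)
                cid += 1
        x = np.vstack(samples)
        y = np.asarray(labels)
        cids = np.asarray(cluster_ids)
        intra, inter = _realized_geometry(x, y, cids)
        if intra >= cfg.intra_dot_min and inter <= cfg.inter_dot_max:
            return Dataset(x, y)
    raise ValueError(
        f"could not meet dot-product targets (intra >= {cfg.intra_dot_min}, "
        f"inter <= {cfg.inter_dot_max}) after {cfg.max_retries} retries"
    )


def split_train_test(
    dataset: Dataset, test_fraction: float, rng: np.random.Generator
) -> tuple[Dataset, Dataset]:
    """Per-class random split into train and test subsets."""
    train_idx, test_idx = [], []
    for cls in np.unique(dataset.labels):
        idx = dataset.class_indices(cls)
        idx = idx[rng.permutation(len(idx))]
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return (
        dataset.subset(np.concatenate(train_idx)),
        dataset.subset(np.concatenate(test_idx)),
    )
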