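"""Region kernels: one linear kernel per anatomical region.

Contrast images are masked, split by an integer-labelled atlas into
per-region feature blocks (samples x voxels), and each block is turned
into a linear kernel.  Before training, kernels are mean-centred in
feature space and trace-normalised so that regions with many voxels do
not dominate purely by dimensionality; both operations compute their
statistics from training rows only and apply them to all rows, which
keeps held-out samples untouched by test information.

The centring/normalisation order is centre-then-normalise: the trace of
the *centred* training kernel measures the region's effective scale, so
normalising after centring equalises regions irrespective of their mean
pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .glm import ContrastImage
from .synthetic import AtlasParcellation

__all__ = [
    "RegionFeatureBlock",
    "KernelSet",
    "sort_samples",
    "parcellate",
    "linear_kernel",
    "normalize_kernel",
    "center_kernel",
    "build_kernelset",
    "process_kernelset",
    "transform_block",
]


@dataclass
class RegionFeatureBlock:
    """All masked voxel values of one region, for every sample."""

    region_id: int
    data: np.ndarray                 # n_samples x n_voxels
    voxel_coords: np.ndarray         # n_voxels x 3 integer grid coordinates

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.voxel_coords):
            raise ValueError("column count must equal voxel coordinate count")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class KernelSet:
    """Ordered per-region kernel matrices over one shared sample set.

    ``sample_subjects``/``sample_conditions`` describe the row ordering
    shared by every kernel.  ``centered``/``normalized`` record what has
    been applied and ``training_rows`` which rows supplied the
    statistics.
    """

    region_ids: list[int]
    matrices: list[np.ndarray]
    sample_subjects: list[str]
    sample_conditions: list[str]
    centered: bool = False
    normalized: bool = False
    training_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.n_samples
        for rid, K in zip(self.region_ids, self.matrices):
            if K.shape != (n, n):
                raise ValueError(f"kernel for region {rid} has shape {K.shape}")
            if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
                raise ValueError(f"kernel for region {rid} is not symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_subjects)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def combined(self, weights: np.ndarray) -> np.ndarray:
        """Weighted sum over region kernels."""
        out = np.zeros_like(self.matrices[0])
        for w, K in zip(weights, self.matrices):
            if w != 0:
                out += w * K
        return out


def sort_samples(images: list[ContrastImage],
                 condition_order: tuple[str, ...] | list[str]) -> list[ContrastImage]:
    """Canonical sample ordering: subjects sorted by id, then the declared
    condition order.  All kernels and target vectors share this order."""
    cond_rank = {c: i for i, c in enumerate(condition_order)}
    return sorted(images, key=lambda im: (im.subject_id, cond_rank[im.condition]))


def parcellate(images: list[ContrastImage], atlas: AtlasParcellation,
               mask: np.ndarray) -> list[RegionFeatureBlock]:
    """Split masked image values into one feature block per atlas region.

    Regions left without any voxel by the mask are dropped with a
    warning.  Raises if the grids disagree or no region survives.
    """
    shape = atlas.label_volume.shape
    if mask.shape != shape or any(im.data.shape != shape for im in images):
        raise ValueError("images, atlas and mask must share one grid")
    stacked = np.stack([im.data for im in images])  # n x X x Y x Z
    if not np.isfinite(stacked[:, mask]).all():
        raise ValueError("images contain non-finite values inside the mask")
    blocks: list[RegionFeatureBlock] = []
    dropped: list[int] = []
    for rid in atlas.region_ids:
        sel = (atlas.label_volume == rid) & mask
        coords = np.argwhere(sel)
        if len(coords) == 0:
            dropped.append(rid)
            continue
        blocks.append(RegionFeatureBlock(region_id=rid,
                                         data=stacked[:, sel],
                                         voxel_coords=coords))
    if dropped:
        warnings.warn(f"regions removed entirely by the mask: {dropped}",
                      stacklevel=2)
    if not blocks:
        raise ValueError("mask removed every region")
    return blocks


def linear_kernel(block: RegionFeatureBlock) -> np.ndarray:
    """Gram matrix of the block: K[i, j] = <x_i, x_j> over region voxels."""
    if block.data.size == 0:
        raise ValueError("empty feature block")
    return block.data @ block.data.T


def center_kernel(K: np.ndarray, training_rows: np.ndarray) -> np.ndarray:
    """Subtract the feature-space mean of the TRAINING samples.

    K' = K - 1·m_row - m_rowᵀ·1 + m̄ where m_row is the mean over
    training columns and m̄ the training-block mean, so training rows
    and columns of K' sum to ~0 while test rows use training statistics
    only.
    """
    tr = np.asarray(training_rows)
    if tr.dtype == bool:
        tr = np.flatnonzero(tr)
    if len(tr) < 2:
        raise ValueError("centering needs at least two training rows")
    row_mean = K[:, tr].mean(axis=1)          # mean over training columns
    grand = K[np.ix_(tr, tr)].mean()
    return K - row_mean[:, None] - row_mean[None, :] + grand


def normalize_kernel(K: np.ndarray, training_rows: np.ndarray) -> np.ndarray:
    """Scale so the training submatrix has trace = n_train.

    Compensates for region size: a linear kernel's trace grows with the
    voxel count, so without this step large regions dominate the kernel
    combination.  The same factor is applied to all rows/columns.
    """
    tr = np.asarray(training_rows)
    if tr.dtype == bool:
        tr = np.flatnonzero(tr)
    trace = np.trace(K[np.ix_(tr, tr)])
    if trace <= 0:
        raise ValueError("nonpositive training trace; drop the region instead")
    return K * (len(tr) / trace)


def build_kernelset(blocks: list[RegionFeatureBlock],
                    sample_subjects: list[str],
                    sample_conditions: list[str]) -> KernelSet:
    """Raw (uncentred, unnormalised) linear kernels from feature blocks."""
    return KernelSet(region_ids=[b.region_id for b in blocks],
                     matrices=[linear_kernel(b) for b in blocks],
                     sample_subjects=list(sample_subjects),
                     sample_conditions=list(sample_conditions))


def process_kernelset(raw: KernelSet, training_rows: np.ndarray) -> KernelSet:
    """Centre then trace-normalise every kernel using training rows only.

    Regions whose centred training kernel has (near-)zero trace — zero
    variance over the training samples — are dropped with a warning,
    since they carry no pattern and break trace normalisation.
    """
    tr = np.asarray(training_rows)
    if tr.dtype == bool:
        tr = np.flatnonzero(tr)
    ids, mats, dropped = [], [], []
    for rid, K in zip(raw.region_ids, raw.matrices):
        Kc = center_kernel(K, tr)
        trace = np.trace(Kc[np.ix_(tr, tr)])
        if trace <= 1e-12 * max(1.0, np.abs(K).max()):
            dropped.append(rid)
            continue
        ids.append(rid)
        mats.append(Kc * (len(tr) / trace))
    if dropped:
        warnings.warn(f"regions with zero training variance dropped: {dropped}",
                      stacklevel=2)
    if not ids:
        raise ValueError("no region kernel survived processing")
    return KernelSet(region_ids=ids, matrices=mats,
                     sample_subjects=raw.sample_subjects,
                     sample_conditions=raw.sample_conditions,
                     centered=True, normalized=True, training_rows=tr)


def transform_block(block: RegionFeatureBlock,
                    training_rows: np.ndarray) -> np.ndarray:
    """Explicit feature-space counterpart of :func:`process_kernelset`.

    Returns features phi(x) = sqrt(c) * (x - mean_train(x)) whose Gram
    matrix equals the centred + normalised kernel; used for primal
    (voxel) weight computation and the kernel-trick consistency check.
    Returns None-equivalent scaling of zero for degenerate regions.
    """
    tr = np.asarray(training_rows)
    if tr.dtype == bool:
        tr = np.flatnonzero(tr)
    mean = block.data[tr].mean(axis=0)
    X = block.data - mean
    trace = float(np.sum(X[tr] ** 2))
    if trace <= 0:
        raise ValueError("zero training variance; region should have been dropped")
    return X * np.sqrt(len(tr) / trace)
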