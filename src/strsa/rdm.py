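"""Representational dissimilarity matrices (RDMs) and their constructions.

An RDM is a symmetric condition-by-condition matrix of pattern
dissimilarities with a zero diagonal.  This module provides the container
types plus every RDM construction used in the pipeline:

* ``euclidean_rdm`` — Euclidean distance between per-condition feature
  vectors (e.g. conv-layer activations, per-frame motion-energy vectors);
* ``binary_category_rdm`` — 0/1 distances from categorical labels
  (e.g. social vs nonsocial);
* ``rating_difference_rdm`` — absolute differences of scalar ratings
  (valence, arousal);
* ``similarity_inversion_rdm`` — 7 minus the rater-averaged pairwise
  similarity judgment on a 1–7 Likert scale (biological motion);
* ``correlation_distance_rdm`` — 1 minus Pearson correlation between
  multivoxel response patterns (fMRI ROI RDMs);
* ``conv_output_shape`` / ``extract_conv_features`` — geometry and linear
  map of a single convolutional layer, used to build low-level visual
  feature vectors from stimulus frames;
* ``motion_energy_vector`` — per-frame summed optic-flow magnitude.

``vectorize_rdm`` / ``devectorize_rdm`` convert between the square matrix
and its upper-triangle vector (row-major, diagonal excluded), the common
currency of all downstream RSA and regression stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RDM",
    "TimeResolvedRDM",
    "ROIPatterns",
    "ConvLayerSpec",
    "conv_output_shape",
    "extract_conv_features",
    "motion_energy_vector",
    "euclidean_rdm",
    "binary_category_rdm",
    "rating_difference_rdm",
    "similarity_inversion_rdm",
    "correlation_distance_rdm",
    "vectorize_rdm",
    "devectorize_rdm",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class RDM:
    """Symmetric condition x condition dissimilarity matrix, zero diagonal.

    Parameters
    ----------
    matrix : (n, n) array
        Dissimilarities.  Must be symmetric with a zero diagonal and
        finite entries.
    condition_ids : sequence, optional
        Condition identifiers; defaults to ``0..n-1``.
    meta : dict, optional
        Construction metadata (method, source).
    """

    matrix: np.ndarray
    condition_ids: Sequence[Any] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"RDM must be square, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("RDM entries must be finite")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-8):
            raise ValueError("RDM diagonal must be zero")
        # store exactly symmetric with exact zero diagonal
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        self.matrix = m
        if self.condition_ids is None:
            self.condition_ids = list(range(m.shape[0]))
        else:
            self.condition_ids = list(self.condition_ids)
            if len(self.condition_ids) != m.shape[0]:
                raise ValueError("condition_ids length must match matrix size")

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    def vector(self) -> np.ndarray:
        """Upper-triangle vector (row-major, diagonal excluded)."""
        return vectorize_rdm(self)


@dataclass
class TimeResolvedRDM:
    """A stack of RDMs over sliding time windows.

    ``dissimilarities`` has shape (n_windows, n, n); each slice satisfies
    the RDM invariants.  ``window_centers_ms`` gives the center time of
    each window relative to stimulus onset.
    """

    dissimilarities: np.ndarray
    window_centers_ms: np.ndarray
    condition_ids: Sequence[Any] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.dissimilarities, dtype=float)
        if d.ndim != 3 or d.shape[1] != d.shape[2]:
            raise ValueError(f"expected (windows, n, n) array, got {d.shape}")
        self.dissimilarities = d
        self.window_centers_ms = np.asarray(self.window_centers_ms, dtype=float)
        if self.window_centers_ms.shape[0] != d.shape[0]:
            raise ValueError("window_centers_ms length must match n_windows")
        if self.condition_ids is None:
            self.condition_ids = list(range(d.shape[1]))
        else:
            self.condition_ids = list(self.condition_ids)

    @property
    def n_windows(self) -> int:
        return self.dissimilarities.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.dissimilarities.shape[1]

    def window(self, i: int) -> RDM:
        return RDM(self.dissimilarities[i], self.condition_ids)

    def vectors(self) -> np.ndarray:
        """(n_windows, n*(n-1)/2) matrix of vectorized RDMs."""
        n = self.n_conditions
        iu = np.triu_indices(n, k=1)
        return self.dissimilarities[:, iu[0], iu[1]]


@dataclass
class ROIPatterns:
    """Multivoxel response patterns for one region of interest.

    ``patterns`` is voxels x conditions.  At least 2 voxels and 3
    conditions are required, and after centering no condition may have a
    constant (zero-variance) voxel vector, otherwise the correlation
    distance is undefined.
    """

    name: str
    patterns: np.ndarray
    condition_ids: Sequence[Any] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.patterns, dtype=float)
        if p.ndim != 2:
            raise ValueError("patterns must be 2-D (voxels x conditions)")
        if p.shape[0] < 2:
            raise ValueError("need at least 2 voxels")
        if p.shape[1] < 3:
            raise ValueError("need at least 3 conditions")
        self.patterns = p
        if self.condition_ids is None:
            self.condition_ids = list(range(p.shape[1]))
        else:
            self.condition_ids = list(self.condition_ids)


# ---------------------------------------------------------------------------
# Convolutional feature geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvLayerSpec:
    """Geometry of a single 2-D convolutional layer."""

    kernel: int
    stride: int = 1
    padding: int = 0
    n_kernels: int = 1

    def __post_init__(self) -> None:
        if self.kernel < 1:
            raise ValueError("kernel must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")


def conv_output_shape(input_h: int, input_w: int, spec: ConvLayerSpec) -> tuple[int, int, int]:
    """Output (height, width, n_kernels) of a conv layer.

    Uses the standard formula ``floor((in + 2*pad - kernel)/stride) + 1``
    per spatial axis.  For a 360 x 640 frame through an 11 x 11, stride-4,
    padding-2, 64-kernel first layer this gives (89, 159, 64).
    """
    out_h = (input_h + 2 * spec.padding - spec.kernel) // spec.stride + 1
    out_w = (input_w + 2 * spec.padding - spec.kernel) // spec.stride + 1
    if out_h < 1 or out_w < 1:
        raise ValueError(
            f"input {input_h}x{input_w} too small for kernel {spec.kernel} "
            f"with padding {spec.padding}"
        )
    return out_h, out_w, spec.n_kernels


def extract_conv_features(
    image: np.ndarray,
    spec: ConvLayerSpec,
    weights: np.ndarray,
    bias: np.ndarray | None = None,
    relu: bool = True,
) -> np.ndarray:
    """Flattened output of one convolutional layer applied to ``image``.

    Parameters
    ----------
    image : (H, W) or (C, H, W) array
        Input frame, already resized/normalized upstream.
    weights : (n_kernels, kernel, kernel) or (n_kernels, C, kernel, kernel)
        Kernel weights; any supplied weights are accepted (pretrained or
        random), only the layer geometry and linearity are fixed here.
    bias : (n_kernels,) array, optional
    relu : bool
        Apply a rectified-linear nonlinearity to the output (default, to
        match post-activation features).

    Returns
    -------
    1-D array of length out_h * out_w * n_kernels, ordered as
    (kernel, row, col) like a (n_kernels, out_h, out_w) stack flattened in
    C order.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3:
        raise ValueError("image must be (H, W) or (C, H, W)")
    w = np.asarray(weights, dtype=float)
    if w.ndim == 3:
        w = w[:, None]
    if w.shape != (spec.n_kernels, img.shape[0], spec.kernel, spec.kernel):
        raise ValueError(
            f"weights shape {w.shape} does not match spec "
            f"({spec.n_kernels} kernels of {img.shape[0]}x{spec.kernel}x{spec.kernel})"
        )
    c, h, wd = img.shape
    out_h, out_w, _ = conv_output_shape(h, wd, spec)
    padded = np.pad(img, ((0, 0), (spec.padding,) * 2, (spec.padding,) * 2))
    # (C, out_h, out_w, k, k) view of all kernel placements
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (spec.kernel, spec.kernel), axis=(1, 2)
    )[:, :: spec.stride, :: spec.stride]
    out = np.einsum("cijkl,nckl->nij", windows, w)
    if bias is not None:
        out = out + np.asarray(bias, dtype=float)[:, None, None]
    if relu:
        out = np.maximum(out, 0.0)
    assert out.shape == (spec.n_kernels, out_h, out_w)
    return out.ravel()


def motion_energy_vector(flow_fields: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Per-frame motion energy: the summed optic-flow magnitude.

    ``flow_fields`` is (n_frames, H, W, 2) (or a sequence of (H, W, 2)
    frames) of per-pixel flow vectors.  Element ``f`` of the output is the
    sum over pixels of the flow-vector magnitude at frame ``f`` —
    magnitudes, not componentwise sums, so opposing flows do not cancel.
    """
    frames = [np.asarray(f, dtype=float) for f in flow_fields]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    out = np.empty(len(frames))
    for i, f in enumerate(frames):
        if f.size == 0:
            raise ValueError(f"frame {i} is empty")
        if f.ndim != 3 or f.shape[-1] != 2:
            raise ValueError("each flow field must be (H, W, 2)")
        out[i] = np.sqrt((f**2).sum(axis=-1)).sum()
    return out


# ---------------------------------------------------------------------------
# RDM constructions
# ---------------------------------------------------------------------------

def _feature_matrix(features) -> tuple[np.ndarray, list]:
    """Coerce a feature table to (n_conditions, n_features) + ids."""
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.index)
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2:
        raise ValueError("features must be 2-D (conditions x features)")
    return arr, list(range(arr.shape[0]))


def euclidean_rdm(features, condition_ids: Sequence[Any] | None = None) -> RDM:
    """RDM of pairwise Euclidean distances between feature vectors.

    ``features`` is (n_conditions, n_features) (array or DataFrame indexed
    by condition id); all rows must have equal length, which the 2-D shape
    enforces.
    """
    x, ids = _feature_matrix(features)
    if condition_ids is not None:
        ids = list(condition_ids)
    sq = (x**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    d = np.sqrt(np.maximum(d2, 0.0))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return RDM(d, ids, meta={"method": "euclidean"})


def binary_category_rdm(labels: Sequence[Any], condition_ids=None) -> RDM:
    """0/1 RDM from categorical labels: 0 within category, 1 between."""
    labels = list(labels)
    if len(labels) == 0 or any(lab is None for lab in labels):
        raise ValueError("labels must be non-empty with no missing values")
    arr = np.asarray(labels, dtype=object)
    d = (arr[:, None] != arr[None, :]).astype(float)
    return RDM(d, condition_ids, meta={"method": "binary_category"})


def rating_difference_rdm(ratings: Sequence[float], condition_ids=None) -> RDM:
    """RDM of absolute rating differences, one scalar rating per condition."""
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 1:
        raise ValueError("ratings must be a 1-D vector, one per condition")
    if not np.all(np.isfinite(r)):
        raise ValueError("ratings must be finite")
    d = np.abs(r[:, None] - r[None, :])
    return RDM(d, condition_ids, meta={"method": "rating_difference"})


def similarity_inversion_rdm(
    judgments: pd.DataFrame,
    condition_ids: Sequence[Any] | None = None,
    scale_max: float = 7.0,
) -> RDM:
    """RDM from pairwise similarity judgments on a 1..scale_max scale.

    ``judgments`` is long-format with columns ``cond_i``, ``cond_j``,
    ``rater``, ``score`` (scores in [1, scale_max]; scale_max = identical).
    Dissimilarity = scale_max minus the across-rater mean judgment for the
    pair; the diagonal is forced to zero.
    """
    req = {"cond_i", "cond_j", "score"}
    if not req.issubset(judgments.columns):
        raise ValueError(f"judgments must have columns {sorted(req)}")
    scores = judgments["score"].to_numpy(dtype=float)
    if np.any(scores < 1.0) or np.any(scores > scale_max):
        raise ValueError(f"judgments must lie in [1, {scale_max}]")
    if condition_ids is None:
        condition_ids = sorted(
            set(judgments["cond_i"]).union(judgments["cond_j"]), key=str
        )
    idx = {c: k for k, c in enumerate(condition_ids)}
    n = len(condition_ids)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    for ci, cj, s in zip(judgments["cond_i"], judgments["cond_j"], scores):
        i, j = idx[ci], idx[cj]
        sums[i, j] += s
        counts[i, j] += 1
        if i != j:
            sums[j, i] += s
            counts[j, i] += 1
    offdiag = ~np.eye(n, dtype=bool)
    if np.any(counts[offdiag] == 0):
        raise ValueError("every condition pair needs at least one judgment")
    d = np.zeros((n, n))
    d[offdiag] = scale_max - sums[offdiag] / counts[offdiag]
    return RDM(d, condition_ids, meta={"method": "similarity_inversion"})


def correlation_distance_rdm(patterns: ROIPatterns) -> RDM:
    """1 - Pearson correlation between multivoxel condition patterns."""
    x = patterns.patterns  # voxels x conditions
    xc = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(xc, axis=0)
    if np.any(norms == 0):
        bad = [patterns.condition_ids[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(
            f"zero-variance pattern for condition(s) {bad}: correlation undefined"
        )
    r = (xc.T @ xc) / np.outer(norms, norms)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return RDM(d, patterns.condition_ids, meta={"method": "correlation_distance", "roi": patterns.name})


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------

def vectorize_rdm(rdm: RDM | np.ndarray) -> np.ndarray:
    """Upper-triangle vector of an RDM (row-major, diagonal excluded).

    Length is n(n-1)/2.  ``devectorize_rdm`` is the exact inverse.
    """
    m = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize_rdm(vec: np.ndarray, condition_ids=None) -> RDM:
    """Rebuild the symmetric zero-diagonal matrix from its vector form."""
    v = np.asarray(vec, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * v.size)) / 2))
    if n * (n - 1) // 2 != v.size:
        raise ValueError(f"vector length {v.size} is not n(n-1)/2 for integer n")
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    m = m + m.T
    return RDM(m, condition_ids)
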