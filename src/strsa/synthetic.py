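"""Synthetic designs, EEG epochs, and ROI RDM sets with known ground truth.

Every downstream stage of the pipeline (decoding, RSA, fusion, variance
partitioning, permutation statistics) is validated against data generated
here, where the representational geometry, its onset latency, and the
variance decomposition are known by construction.

The generator emulates the structure of a one-back touch-video EEG study:
75 conditions (39 social / 36 nonsocial), 15 blocks of 83 trials (75
presentations plus 4 catch events realised as inserted immediate-repeat
pairs, 1245 trials in total), 1.2-s epochs at 1000 Hz.  EEG epochs carry
condition-mean patterns whose pairwise geometry follows target RDMs,
switched on at specified latencies with a one-window linear ramp, riding
on spatially correlated AR(1) noise.  It is a geometry-level simulation:
no dipole/forward modelling, no volume conduction physics.

Seeding: one master seed; per-stage child seeds are derived
deterministically via :func:`numpy.random.SeedSequence.spawn`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .rdm import RDM, vectorize_rdm, devectorize_rdm

__all__ = [
    "DesignSpec",
    "TrialSequence",
    "Embedding",
    "LatentFeature",
    "GroundTruth",
    "SyntheticROISet",
    "generate_design",
    "embed_rdm",
    "generate_eeg_trials",
    "generate_roi_rdm_set",
]


# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the block design.

    Defaults reproduce the study design: 75 videos (39 social), 15 blocks,
    4 catch events per block -> 83 trials/block, 1245 in total.
    """

    n_videos: int = 75
    n_social: int = 39
    n_blocks: int = 15
    n_catch_events_per_block: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_videos", "n_social", "n_blocks", "n_catch_events_per_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_social > self.n_videos:
            raise ValueError("n_social cannot exceed n_videos")
        if self.n_catch_events_per_block > self.n_videos:
            raise ValueError(
                "cannot have more catch events per block than videos"
            )

    @property
    def trials_per_block(self) -> int:
        return self.n_videos + 2 * self.n_catch_events_per_block

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def category_labels(self) -> np.ndarray:
        """'social' for the first ``n_social`` condition ids, else 'nonsocial'."""
        return np.where(
            np.arange(self.n_videos) < self.n_social, "social", "nonsocial"
        )


@dataclass
class TrialSequence:
    """Ordered trials as (block, condition, is_catch) triples."""

    block: np.ndarray
    condition: np.ndarray
    is_catch: np.ndarray

    def __post_init__(self) -> None:
        self.block = np.asarray(self.block, dtype=int)
        self.condition = np.asarray(self.condition, dtype=int)
        self.is_catch = np.asarray(self.is_catch, dtype=bool)
        if not (len(self.block) == len(self.condition) == len(self.is_catch)):
            raise ValueError("field lengths must match")

    def __len__(self) -> int:
        return len(self.block)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"block": self.block, "condition": self.condition, "is_catch": self.is_catch}
        )


def generate_design(spec: DesignSpec) -> TrialSequence:
    """Generate the pseudo-random one-back trial sequence.

    Per block: every condition once in a shuffled order, plus
    ``n_catch_events_per_block`` catch events.  A catch event inserts two
    extra presentations of a (distinct, randomly chosen) condition
    immediately after that condition's scheduled trial, so each catch
    event is a pair of consecutive identical trials sharing the condition
    of its immediate predecessor — the repeat the one-back task asks
    participants to detect.  Catch trials are flagged and excluded from
    analysis.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    blocks, conds, catch = [], [], []
    for b in range(spec.n_blocks):
        order = rng.permutation(spec.n_videos)
        catch_conds = set(
            rng.choice(spec.n_videos, spec.n_catch_events_per_block, replace=False)
        )
        for c in order:
            blocks.append(b)
            conds.append(c)
            catch.append(False)
            if c in catch_conds:
                for _ in range(2):
                    blocks.append(b)
                    conds.append(c)
                    catch.append(True)
    return TrialSequence(np.array(blocks), np.array(conds), np.array(catch))


# ---------------------------------------------------------------------------
# RDM embedding (classical multidimensional scaling)
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    """Point configuration approximating an RDM, with its stress."""

    points: np.ndarray  # (n_conditions, dim)
    stress: float       # normalised residual: ||D - D_hat||_F / ||D||_F


def embed_rdm(rdm: RDM | np.ndarray, dim: int) -> Embedding:
    """Embed an RDM as points whose Euclidean distances approximate it.

    Classical (Torgerson) multidimensional scaling: double-center the
    squared dissimilarities, eigendecompose, and keep the top ``dim``
    components with positive eigenvalues.  For a Euclidean RDM of
    intrinsic dimension <= ``dim`` the distances are recovered exactly
    (stress ~ 0); otherwise the best rank-``dim`` configuration is
    returned with nonzero stress.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    d = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[order], 0.0, None)
    pts = evecs[:, order] * np.sqrt(lam)
    diff = pts[:, None, :] - pts[None, :, :]
    dhat = np.sqrt((diff**2).sum(axis=-1))
    denom = np.linalg.norm(d)
    stress = float(np.linalg.norm(d - dhat) / denom) if denom > 0 else 0.0
    return Embedding(points=pts, stress=stress)


# ---------------------------------------------------------------------------
# EEG epoch generation
# ---------------------------------------------------------------------------

@dataclass
class LatentFeature:
    """One latent representational geometry injected into the EEG.

    ``snr`` scales the condition-mean pattern relative to the noise
    standard deviation (snr = 0 means no decodable signal); ``onset_ms``
    is when the geometry switches on (linear ramp over ``ramp_ms``).
    """

    name: str
    rdm: RDM
    onset_ms: float
    snr: float

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


@dataclass
class GroundTruth:
    """Target geometries plus the noise model for EEG generation.

    Noise is spatially correlated Gaussian with exponentially decaying
    channel covariance ``exp(-|i-j| / noise_spatial_scale)`` and temporal
    AR(1) dependence ``noise_ar``, marginal standard deviation
    ``noise_sd``.  This makes multivariate noise normalization in the
    decoding stage non-trivial without biophysical modelling.
    """

    features: Sequence[LatentFeature]
    noise_spatial_scale: float = 5.0
    noise_ar: float = 0.3
    noise_sd: float = 1.0
    ramp_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.noise_ar < 1:
            raise ValueError("noise_ar must be in [0, 1)")


def ar1_timecourses(
    n_series: int,
    n_windows: int,
    ar: float = 0.3,
    sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sign-symmetric AR(1) Gaussian timecourses, (n_series, n_windows).

    Marginal standard deviation ``sd`` at every window.  Used to
    simulate null subject-level statistic timecourses (no signal) for
    calibrating the group permutation test.
    """
    if not 0 <= ar < 1:
        raise ValueError("ar must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((n_series, n_windows))
    out = np.empty_like(white)
    out[:, 0] = white[:, 0] * sd
    innov = sd * np.sqrt(1.0 - ar**2)
    for t in range(1, n_windows):
        out[:, t] = ar * out[:, t - 1] + innov * white[:, t]
    return out


def _spatial_noise_chol(n_channels: int, scale: float) -> np.ndarray:
    idx = np.arange(n_channels)
    cov = np.exp(-np.abs(idx[:, None] - idx[None, :]) / max(scale, 1e-9))
    return np.linalg.cholesky(cov + 1e-12 * np.eye(n_channels))


def generate_eeg_trials(
    truth: GroundTruth,
    design: TrialSequence,
    n_channels: int = 64,
    sample_rate: float = 1000.0,
    epoch_window_ms: tuple[float, float] = (-200.0, 1000.0),
    embed_dim: int | None = None,
) -> EpochSet:
    """Simulate an :class:`EpochSet` realising the ground-truth geometry.

    Before each feature's onset latency all condition means are identical
    (zero signal, nothing to decode); from the onset the condition means
    separate according to the feature's RDM geometry (embedded into
    channel space via classical MDS, rotated by a seed-fixed orthonormal
    basis, scaled by ``snr * noise_sd``), ramping in linearly over
    ``truth.ramp_ms``.  Additive noise is spatially correlated AR(1)
    Gaussian.  Byte-identical output under a fixed seed.

    ``embed_dim`` fixes the MDS embedding dimension; the default uses
    min(n_conditions - 1, n_channels).  Requesting more dimensions than
    channels is an error.
    """
    t0, t1 = epoch_window_ms
    n_samples = int(round((t1 - t0) * sample_rate / 1000.0))
    times = t0 + np.arange(n_samples) * 1000.0 / sample_rate
    for f in truth.features:
        if not (times[0] <= f.onset_ms <= times[-1]):
            raise ValueError(
                f"feature {f.name!r} onset {f.onset_ms} ms outside epoch window"
            )

    n_cond = max(int(design.condition.max()) + 1, 1) if len(design) else 0
    master = np.random.SeedSequence(truth.seed)
    feat_seeds = master.spawn(len(truth.features) + 1)
    noise_rng = np.random.default_rng(feat_seeds[-1])

    # per-condition, per-channel signal pattern for each feature
    signal_maps = []  # (pattern (n_cond, n_channels), ramp (n_samples,))
    for f, ss in zip(truth.features, feat_seeds):
        if f.rdm.n_conditions != n_cond:
            raise ValueError(
                f"feature {f.name!r} RDM has {f.rdm.n_conditions} conditions, "
                f"design has {n_cond}"
            )
        if embed_dim is None:
            dim = min(n_cond - 1, n_channels) if n_cond > 1 else 1
        else:
            dim = embed_dim
        if n_channels < dim:
            raise ValueError(
                f"n_channels={n_channels} smaller than embedding dimension {dim}"
            )
        emb = embed_rdm(f.rdm, dim)
        pts = emb.points - emb.points.mean(axis=0, keepdims=True)
        # unit RMS inter-condition spread, then SNR scaling
        rms = np.sqrt((pts**2).sum(axis=1).mean())
        if rms > 0:
            pts = pts / rms
        rng_f = np.random.default_rng(ss)
        q, _ = np.linalg.qr(rng_f.standard_normal((n_channels, n_channels)))
        pattern = pts @ q[:, : pts.shape[1]].T * (f.snr * truth.noise_sd)
        ramp = np.clip((times - f.onset_ms) / max(truth.ramp_ms, 1e-9), 0.0, 1.0)
        signal_maps.append((pattern, ramp))

    chol = _spatial_noise_chol(n_channels, truth.noise_spatial_scale)
    ar = truth.noise_ar
    innov_sd = truth.noise_sd * np.sqrt(1.0 - ar**2)

    data = np.zeros((len(design), n_channels, n_samples))
    for pattern, ramp in signal_maps:
        data += pattern[design.condition][:, :, None] * ramp[None, None, :]
    # AR(1) over time per (trial, channel), then spatial mixing
    white = noise_rng.standard_normal(data.shape)
    ar_noise = np.empty_like(white)
    ar_noise[:, :, 0] = white[:, :, 0] * truth.noise_sd
    for t in range(1, n_samples):
        ar_noise[:, :, t] = ar * ar_noise[:, :, t - 1] + innov_sd * white[:, :, t]
    data += np.einsum("ij,njt->nit", chol, ar_noise)

    return EpochSet(
        data,
        times,
        sample_rate,
        labels=design.condition,
        is_catch=design.is_catch,
        meta={
            "seed": truth.seed,
            "onsets_ms": {f.name: f.onset_ms for f in truth.features},
            "snr": {f.name: f.snr for f in truth.features},
        },
    )


# ---------------------------------------------------------------------------
# ROI RDM sets with known variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class SyntheticROISet:
    """ROI RDMs mixed from shared and unique latent components.

    ``rdms`` maps ROI name -> RDM; ``shared_weights`` / ``unique_weights``
    are the nonnegative mixing weights, and ``shared_component`` /
    ``unique_components`` the standardized latent RDM vectors, so tests
    can verify recovered unique/shared variance against ground truth.
    """

    rdms: dict[str, RDM]
    shared_weights: dict[str, float]
    unique_weights: dict[str, float]
    shared_component: np.ndarray
    unique_components: dict[str, np.ndarray]
    noise_sd: float
    seed: int


def _zscore_vec(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def generate_roi_rdm_set(
    shared: RDM,
    uniques: Sequence[RDM],
    weights: Sequence[tuple[float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> SyntheticROISet:
    """Build ROI RDMs as weighted mixes of shared + unique components.

    Each ROI i gets the vectorized RDM
    ``w_shared_i * z(shared) + w_unique_i * z(unique_i) + noise`` where
    ``z`` standardizes the upper-triangle vector and the noise is i.i.d.
    Gaussian on the upper triangle (hence symmetric as a matrix).  The
    result is shifted/rescaled to nonnegative entries with maximum 1, a
    monotone map that leaves rank-based analyses untouched.  The exact
    mixing weights and latent components are stored as ground truth.
    """
    n = shared.n_conditions
    uniques = list(uniques)
    if any(u.n_conditions != n for u in uniques):
        raise ValueError("all RDMs must have the same number of conditions")
    if len(weights) != len(uniques):
        raise ValueError("need one (shared, unique) weight pair per ROI")
    if any(ws < 0 or wu < 0 for ws, wu in weights):
        raise ValueError("weights must be >= 0")
    if names is None:
        names = [f"roi{i}" for i in range(len(uniques))]

    rng = np.random.default_rng(seed)
    sh_vec = _zscore_vec(vectorize_rdm(shared))
    rdms: dict[str, RDM] = {}
    shared_w, unique_w, unique_c = {}, {}, {}
    for name, u, (ws, wu) in zip(names, uniques, weights):
        u_vec = _zscore_vec(vectorize_rdm(u))
        v = ws * sh_vec + wu * u_vec
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.shape)
        v = v - v.min()
        if v.max() > 0:
            v = v / v.max()
        rdms[name] = devectorize_rdm(v, shared.condition_ids)
        shared_w[name], unique_w[name], unique_c[name] = ws, wu, u_vec
    return SyntheticROISet(
        rdms=rdms,
        shared_weights=shared_w,
        unique_weights=unique_w,
        shared_component=sh_vec,
        unique_components=unique_c,
        noise_sd=noise_sd,
        seed=seed,
    )
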