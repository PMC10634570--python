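"""Event-related potential (ERP) analysis: condition averages and contrasts.

Condition ERPs are pointwise trial averages per channel; the grand
average is the unweighted mean over participants, restricted to channels
present for every participant.  The condition contrast averages each
participant's ERPs into successive 100-ms time slices, runs a paired
t test across participants per channel x slice, Bonferroni-corrects, and
reports z-scored t values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats

from .preprocess import EpochSet

__all__ = ["ERPMap", "ContrastResult", "condition_erp", "grand_average", "contrast_slices"]


@dataclass
class ERPMap:
    """Channels x samples mean voltage for one condition."""

    data: np.ndarray
    times: np.ndarray
    channel_names: Sequence[str]
    n_trials: int
    condition: Any = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ERP data must be (channels, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ERP values must be finite")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data")


@dataclass
class ContrastResult:
    """z-scored t map of a condition contrast over channels x time slices.

    ``mask`` is True only where the (uncorrected) paired-t p value beats
    the Bonferroni-corrected alpha; ``slice_edges_ms`` has length
    n_slices + 1.
    """

    z: np.ndarray
    t: np.ndarray
    mask: np.ndarray
    slice_edges_ms: np.ndarray
    channel_names: Sequence[str]
    alpha: float
    meta: dict = field(default_factory=dict)


def condition_erp(epochs: EpochSet, condition: Any) -> ERPMap:
    """Pointwise mean over the trials of one condition."""
    sel = (epochs.labels == condition) & epochs.good_trials()
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no trials with label {condition!r}")
    return ERPMap(
        data=epochs.data[sel].mean(axis=0),
        times=epochs.times,
        channel_names=epochs.channel_names,
        n_trials=n,
        condition=condition,
    )


def grand_average(
    erps: Sequence[ERPMap], common_channels: Sequence[str] | None = None
) -> ERPMap:
    """Unweighted mean ERP over participants on common channels only.

    If ``common_channels`` is not given, the (order-preserving)
    intersection of every participant's channels is used; participants
    with extra channels contribute only the shared subset.
    """
    if len(erps) == 0:
        raise ValueError("need at least one ERP")
    if common_channels is None:
        common = [ch for ch in erps[0].channel_names
                  if all(ch in e.channel_names for e in erps[1:])]
    else:
        common = list(common_channels)
    if len(common) == 0:
        raise ValueError("empty common-channel set")
    stacked = np.stack(
        [e.data[[e.channel_names.index(ch) for ch in common]] for e in erps]
    )
    return ERPMap(
        data=stacked.mean(axis=0),
        times=erps[0].times,
        channel_names=common,
        n_trials=sum(e.n_trials for e in erps),
        condition=erps[0].condition,
    )


def _slice_average(erp: ERPMap, edges: np.ndarray) -> np.ndarray:
    """(channels, n_slices) means over [edge_k, edge_{k+1}) intervals."""
    out = np.empty((erp.data.shape[0], len(edges) - 1))
    for k in range(len(edges) - 1):
        m = (erp.times >= edges[k]) & (erp.times < edges[k + 1])
        out[:, k] = erp.data[:, m].mean(axis=1)
    return out


def contrast_slices(
    erps_a: Sequence[ERPMap],
    erps_b: Sequence[ERPMap],
    slice_width_ms: float = 100.0,
    alpha: float = 0.05,
    bonferroni_over: str = "cells",
) -> ContrastResult:
    """Paired condition contrast on slice-averaged amplitudes.

    Each participant contributes an (a, b) ERP pair on identical
    channels/times.  ERPs are averaged into successive
    ``slice_width_ms`` slices spanning the epoch, a paired t test across
    participants is run per channel x slice on the slice means, and the
    resulting t map is z-scored (mean 0, SD 1 across all cells of the
    map — the z-scoring population is a display choice, not part of the
    inference).  Significance uses the raw paired-t p values with
    Bonferroni correction over ``"cells"`` (channels x slices, default,
    stricter) or ``"channels"``.
    """
    if len(erps_a) != len(erps_b):
        raise ValueError("need the same participants in both conditions")
    if len(erps_a) < 2:
        raise ValueError("need at least 2 participants for a paired t test")
    ref = erps_a[0]
    dt = ref.times[1] - ref.times[0] if len(ref.times) > 1 else 0.0
    edges = np.arange(ref.times[0], ref.times[-1] + dt + 1e-9, slice_width_ms)
    if len(edges) < 2:
        raise ValueError("epoch shorter than one slice")

    diffs = np.stack(
        [_slice_average(a, edges) - _slice_average(b, edges)
         for a, b in zip(erps_a, erps_b)]
    )  # (participants, channels, slices)
    tvals, pvals = stats.ttest_rel(diffs, np.zeros_like(diffs), axis=0)
    tvals = np.nan_to_num(tvals, nan=0.0)
    pvals = np.nan_to_num(pvals, nan=1.0)

    sd = tvals.std()
    z = (tvals - tvals.mean()) / (sd if sd > 0 else 1.0)

    n_cells = tvals.size if bonferroni_over == "cells" else tvals.shape[0]
    mask = pvals < alpha / n_cells
    return ContrastResult(
        z=z,
        t=tvals,
        mask=mask,
        slice_edges_ms=edges,
        channel_names=ref.channel_names,
        alpha=alpha,
        meta={"bonferroni_over": bonferroni_over, "n_participants": len(erps_a)},
    )
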