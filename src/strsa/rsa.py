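"""Representational similarity analysis of time-resolved EEG RDMs.

Links each subject's time-resolved neural RDM to model RDMs (stimulus
features) and to fMRI ROI RDMs (EEG-fMRI fusion) by Spearman rank
correlation of their vectorized upper triangles, window by window.  Also
provides the joint multiple-regression variant (all predictors at once,
on rank-transformed standardized vectors), the leave-one-subject-out
noise ceiling, onset-latency read-off from cluster-corrected
significance masks, and the Mann-Whitney U comparison of onset-latency
samples between predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats

from .rdm import RDM, TimeResolvedRDM, vectorize_rdm

__all__ = [
    "RSATimecourse",
    "LatencyEstimate",
    "rank_correlation_timecourse",
    "regression_timecourse",
    "noise_ceiling",
    "onset_latency",
    "latency_difference_test",
]


@dataclass
class RSATimecourse:
    """Per-window statistics linking a neural RDM to predictor RDM(s).

    ``values`` is (n_windows,) for a single predictor (Spearman r) or
    (n_windows, n_predictors) for a regression (betas).  Windows where
    the statistic is undefined (constant RDM vector) hold NaN and are
    listed in ``flagged_windows``.
    """

    values: np.ndarray
    window_centers_ms: np.ndarray
    predictor: str | Sequence[str]
    kind: str = "spearman"
    flagged_windows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    meta: dict = field(default_factory=dict)


@dataclass
class LatencyEstimate:
    """Onset latency of a predictor's earliest significant cluster."""

    predictor: str
    onset_ms: float | None
    definition: str = "first window of first significant cluster"
    samples: np.ndarray | None = None  # per-subject or bootstrap samples


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)  # average ranks for ties


def _spearman(a_ranked: np.ndarray, b: np.ndarray) -> float:
    br = _rank(b)
    if a_ranked.std() == 0 or br.std() == 0:
        return np.nan
    return float(np.corrcoef(a_ranked, br)[0, 1])


def rank_correlation_timecourse(
    eeg: TimeResolvedRDM, model: RDM, name: str | None = None
) -> RSATimecourse:
    """Spearman correlation of the neural RDM with a model RDM per window.

    Both RDMs are vectorized identically (upper triangle, row-major);
    ties get average ranks.  Windows where either vector is constant are
    NaN and flagged rather than raised.
    """
    if model.n_conditions != eeg.n_conditions:
        raise ValueError("condition sets of EEG and model RDM must match")
    mv = vectorize_rdm(model)
    mr = _rank(mv)
    vecs = eeg.vectors()
    out = np.array([_spearman(mr, v) for v in vecs])
    return RSATimecourse(
        values=out,
        window_centers_ms=eeg.window_centers_ms,
        predictor=name or str(model.meta.get("method", "model")),
        kind="spearman",
        flagged_windows=np.flatnonzero(~np.isfinite(out)),
    )


def _rank_z(v: np.ndarray) -> np.ndarray:
    r = _rank(v)
    sd = r.std()
    return (r - r.mean()) / (sd if sd > 0 else 1.0)


def regression_timecourse(
    eeg: TimeResolvedRDM,
    models: Sequence[RDM],
    names: Sequence[str] | None = None,
    rank_transform: bool = True,
) -> RSATimecourse:
    """Joint multiple regression of the neural RDM on all model RDMs.

    Per window, ordinary least squares of the neural RDM vector on all
    predictor vectors simultaneously, returning one beta per model.  By
    default all vectors are rank-transformed and z-scored first, so with
    a single predictor the beta equals the Spearman correlation; pass
    ``rank_transform=False`` for raw-value regression (vectors are then
    only standardized).
    """
    if len(models) == 0:
        raise ValueError("need at least one model RDM")
    if names is None:
        names = [str(m.meta.get("method", f"model{i}")) for i, m in enumerate(models)]
    tfm = _rank_z if rank_transform else lambda v: (v - v.mean()) / (v.std() or 1.0)
    x = np.column_stack([tfm(vectorize_rdm(m)) for m in models])
    design = np.column_stack([np.ones(x.shape[0]), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient predictor design matrix")
    betas = np.empty((eeg.n_windows, len(models)))
    flagged = []
    for w, v in enumerate(eeg.vectors()):
        if v.std() == 0:
            betas[w] = np.nan
            flagged.append(w)
            continue
        coef, *_ = np.linalg.lstsq(design, tfm(v), rcond=None)
        betas[w] = coef[1:]
    return RSATimecourse(
        values=betas,
        window_centers_ms=eeg.window_centers_ms,
        predictor=list(names),
        kind="regression",
        flagged_windows=np.array(flagged, dtype=int),
        meta={"rank_transform": rank_transform},
    )


def noise_ceiling(subject_rdms: Sequence[TimeResolvedRDM]) -> np.ndarray:
    """Leave-one-subject-out noise ceiling per window.

    Each subject's RDM vector is Spearman-correlated with the mean RDM
    vector of all other subjects; the across-subject mean of these
    correlations estimates the best correlation any model could achieve
    given between-subject consistency.
    """
    if len(subject_rdms) < 2:
        raise ValueError("need at least 2 subjects")
    stacks = np.stack([s.vectors() for s in subject_rdms])  # (subj, win, pairs)
    n_subj, n_win, _ = stacks.shape
    total = stacks.sum(axis=0)
    out = np.empty(n_win)
    for w in range(n_win):
        rs = []
        for s in range(n_subj):
            loo = (total[w] - stacks[s, w]) / (n_subj - 1)
            rs.append(_spearman(_rank(stacks[s, w]), loo))
        out[w] = np.nanmean(rs)
    return out


def onset_latency(
    timecourse: RSATimecourse,
    significance,
    predictor: str | None = None,
    definition: str = "earliest_cluster",
) -> LatencyEstimate:
    """Onset latency from a cluster-corrected significance result.

    ``significance`` is the boolean per-window mask from the group test,
    or a ``ClusterResult`` (required for ``definition="largest_cluster"``),
    aligned to the timecourse windows.  ``definition`` selects the
    read-off:

    * ``"earliest_cluster"`` (default): center time of the first window
      of the earliest significant cluster;
    * ``"largest_cluster"``: center time of the first window of the
      significant cluster with the largest cluster sum — robust against
      isolated spurious pre-onset clusters when a dominant effect exists.

    An empty mask / no significant cluster yields an undefined onset
    (None), not an error.
    """
    n_win = len(timecourse.window_centers_ms)
    clusters = getattr(significance, "clusters", None)
    mask = getattr(significance, "mask", significance)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != n_win:
        raise ValueError("mask length must match timecourse windows")
    name = predictor or (
        timecourse.predictor if isinstance(timecourse.predictor, str)
        else ",".join(timecourse.predictor)
    )
    if definition == "earliest_cluster":
        hits = np.flatnonzero(mask)
        onset = float(timecourse.window_centers_ms[hits[0]]) if hits.size else None
    elif definition == "largest_cluster":
        if clusters is None:
            raise ValueError(
                "largest_cluster definition requires a ClusterResult"
            )
        sig = [c for c in clusters if c.significant]
        onset = (
            float(timecourse.window_centers_ms[
                max(sig, key=lambda c: c.cluster_sum).start
            ]) if sig else None
        )
    else:
        raise ValueError(f"unknown onset definition {definition!r}")
    return LatencyEstimate(predictor=name, onset_ms=onset, definition=definition)


def latency_difference_test(
    samples_a: Sequence[float], samples_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two onset-latency samples.

    Exact for small samples without ties, normal approximation otherwise
    (scipy's automatic policy).  Returns (U, p).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 latency samples per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
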