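"""Time-resolved pairwise EEG decoding into per-subject RDMs.

The pipeline mirrors standard multivariate EEG pattern analysis:

1. source trials are split into cross-validation folds (2 by default),
   stratified by condition, *before* pseudo-trial formation so no source
   trial leaks across folds;
2. pseudo-trials are formed by averaging six to eight same-condition
   trials within each fold to raise SNR;
3. multivariate noise normalization whitens channels with the inverse
   square root of a shrinkage-regularized within-condition channel
   covariance estimated on the training fold only;
4. for every unordered condition pair and sliding time window, a linear
   support vector machine (libsvm via scikit-learn, C = 1) is trained on
   the training fold — features are all channels at the window's samples —
   and tested on the held-out fold;
5. the whole process is repeated (10 times by default) with fresh random
   fold splits and groupings, and accuracies are averaged.

Pairwise accuracy, arranged condition x condition per window, is the
time-resolved neural RDM: high accuracy = more distinct patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.svm import SVC

from .preprocess import EpochSet
from .rdm import TimeResolvedRDM

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoTrialSet",
    "DecodingResult",
    "make_pseudotrials",
    "noise_normalize",
    "sliding_windows",
    "pairwise_decode",
    "decoding_to_rdms",
]


@dataclass
class PseudoTrialSet:
    """Averaged pseudo-trials with fold assignment.

    Each pseudo-trial is the mean of >= 2 disjoint source trials of one
    condition, all from the same fold; folds partition source trials, so
    no pseudo-trial ever mixes folds.
    """

    data: np.ndarray          # (n_pseudo, n_channels, n_samples)
    labels: np.ndarray        # (n_pseudo,)
    fold: np.ndarray          # (n_pseudo,) int fold index
    times: np.ndarray
    sample_rate: float
    group_size: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.fold = np.asarray(self.fold, dtype=int)
        if not (len(self.data) == len(self.labels) == len(self.fold)):
            raise ValueError("data, labels, fold must have equal length")

    @property
    def n_folds(self) -> int:
        return int(self.fold.max()) + 1 if len(self.fold) else 0


@dataclass
class DecodingResult:
    """Condition x condition x window pairwise decoding accuracies.

    Symmetric in the condition indices; the diagonal is undefined and
    stored as NaN.
    """

    accuracy: np.ndarray
    window_centers_ms: np.ndarray
    condition_ids: Sequence[Any]
    n_reps: int
    n_folds: int
    meta: dict = field(default_factory=dict)

    def mean_accuracy(self) -> np.ndarray:
        """Grand-mean accuracy over pairs, per window."""
        n = self.accuracy.shape[0]
        iu = np.triu_indices(n, k=1)
        return self.accuracy[iu[0], iu[1], :].mean(axis=0)


# ---------------------------------------------------------------------------
# Pseudo-trials
# ---------------------------------------------------------------------------

def resolve_group_size(min_trials_per_fold: int, requested: int | None = None) -> int:
    """Resolve the pseudo-trial group size against available trials.

    The target range is 6–8 source trials per pseudo-trial.  With N
    trials per condition split over folds, the default resolves to
    ``min(8, trials_per_fold)`` capped into the target range when
    possible (15 trials over 2 folds -> 7).  When fewer than 6 trials per
    fold are available the size is lowered to the largest feasible
    value >= 2, with a log entry.
    """
    if min_trials_per_fold < 2:
        raise ValueError("need at least 2 trials per condition per fold")
    g = requested if requested is not None else min(8, min_trials_per_fold)
    if g > min_trials_per_fold:
        logger.info(
            "group size %d infeasible with %d trials/fold; lowering to %d",
            g, min_trials_per_fold, min_trials_per_fold,
        )
        g = min_trials_per_fold
    if g < 6:
        logger.info("group size %d below the 6-8 target range", g)
    return max(2, g)


def make_pseudotrials(
    epochs: EpochSet,
    n_folds: int = 2,
    group_size: int | None = None,
    seed: int = 0,
) -> PseudoTrialSet:
    """Split trials into folds and average same-condition groups.

    Source trials are shuffled per condition and dealt into ``n_folds``
    near-equal folds (stratified split before averaging).  Within each
    condition x fold cell the trials are partitioned into disjoint groups
    of approximately ``group_size`` (covering every trial; group sizes
    differ by at most one) and each group's pointwise mean becomes a
    pseudo-trial.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    good = epochs.good_trials()
    labels = epochs.labels[good]
    data = epochs.data[good]
    conditions = np.unique(labels)

    counts = np.array([(labels == c).sum() for c in conditions])
    min_per_fold = int(np.min([np.min([len(s) for s in
                      np.array_split(np.arange(n), n_folds)]) for n in counts]))
    if min_per_fold < 2:
        raise ValueError(
            "some condition has fewer than 2 trials in a fold; cannot form "
            "pseudo-trials"
        )
    g = resolve_group_size(min_per_fold, group_size)

    pdata, plabels, pfold, src_fold = _split_and_group(
        data, labels, conditions, n_folds, g, rng
    )
    return PseudoTrialSet(
        data=pdata,
        labels=plabels,
        fold=pfold,
        times=epochs.times,
        sample_rate=epochs.sample_rate,
        group_size=g,
        seed=seed,
        meta={"source_fold": src_fold},
    )


def _split_and_group(
    data: np.ndarray,
    labels: np.ndarray,
    conditions: np.ndarray,
    n_folds: int,
    g: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified fold split of source trials + within-cell group means.

    Returns (pseudo data, pseudo labels, pseudo fold, source-trial fold
    assignment aligned with ``data`` rows).
    """
    pseudo, plabels, pfold = [], [], []
    src_fold = np.full(len(labels), -1, dtype=int)
    for c in conditions:
        idx = rng.permutation(np.flatnonzero(labels == c))
        for fold_i, fold_idx in enumerate(np.array_split(idx, n_folds)):
            src_fold[fold_idx] = fold_i
            n_groups = max(1, len(fold_idx) // g)
            for grp in np.array_split(fold_idx, n_groups):
                pseudo.append(data[grp].mean(axis=0))
                plabels.append(c)
                pfold.append(fold_i)
    return np.stack(pseudo), np.array(plabels), np.array(pfold), src_fold


# ---------------------------------------------------------------------------
# Multivariate noise normalization
# ---------------------------------------------------------------------------

def whitening_matrix(
    data: np.ndarray, labels: np.ndarray, shrinkage: float
) -> np.ndarray:
    """Inverse square root of the shrunk within-condition channel covariance.

    ``data`` is (trials, channels, samples); residuals are taken within
    condition (the condition mean at each timepoint is removed), the
    channel covariance is averaged over timepoints, and shrunk toward
    its diagonal by ``shrinkage``.
    """
    resid = np.asarray(data, dtype=float).copy()
    labels = np.asarray(labels)
    for c in np.unique(labels):
        sel = labels == c
        resid[sel] -= resid[sel].mean(axis=0, keepdims=True)
    n_trials, n_chan, n_samp = resid.shape
    # covariance per timepoint, averaged over timepoints
    flat = np.moveaxis(resid, 1, 2).reshape(-1, n_chan)  # (trial*time, chan)
    cov = flat.T @ flat / max(flat.shape[0] - 1, 1)
    cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) <= 1e-12 * max(np.max(evals), 1e-30):
        raise np.linalg.LinAlgError(
            "singular noise covariance; increase shrinkage or pseudo-trial count"
        )
    return (evecs / np.sqrt(evals)) @ evecs.T


def noise_normalize(
    train: PseudoTrialSet,
    apply_to: PseudoTrialSet,
    shrinkage: float = 0.1,
) -> PseudoTrialSet:
    """Whiten channels of ``apply_to`` using training-fold noise statistics.

    The within-condition residual covariance of ``train`` (averaged over
    timepoints) is shrunk toward its diagonal by ``shrinkage`` in [0, 1]
    and its inverse matrix square root is applied to every timepoint of
    ``apply_to`` — the test fold is always transformed with the
    training-fold matrix, never its own.  (Inside ``pairwise_decode``
    the covariance is estimated from training-fold *source* trials,
    which have within-condition replication even when each condition
    reduces to a single pseudo-trial per fold.)
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    w = whitening_matrix(train.data, train.labels, shrinkage)
    out = np.einsum("ij,njt->nit", w, apply_to.data)
    return PseudoTrialSet(
        data=out,
        labels=apply_to.labels,
        fold=apply_to.fold,
        times=apply_to.times,
        sample_rate=apply_to.sample_rate,
        group_size=apply_to.group_size,
        seed=apply_to.seed,
        meta={**apply_to.meta, "noise_normalized": True},
    )


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def sliding_windows(
    times: np.ndarray,
    sample_rate: float,
    window_ms: float | None = 10.0,
    step_ms: float | None = 4.0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Sample-index windows and their center times.

    Default geometry: 10-ms windows advancing by 4 ms (i.e. 6-ms overlap
    between successive windows); at 500 Hz that is 5 samples per window,
    2-sample step.  ``window_ms=None`` gives single-sample windows at the
    native sample spacing instead.
    """
    times = np.asarray(times, dtype=float)
    if window_ms is None:
        return [np.array([i]) for i in range(len(times))], times.copy()
    w = max(1, int(round(window_ms * sample_rate / 1000.0)))
    s = max(1, int(round((step_ms if step_ms is not None else window_ms)
                         * sample_rate / 1000.0)))
    starts = np.arange(0, len(times) - w + 1, s)
    if len(starts) == 0:
        raise ValueError("epoch shorter than one window")
    idx = [np.arange(st, st + w) for st in starts]
    centers = np.array([times[i].mean() for i in idx])
    return idx, centers


# ---------------------------------------------------------------------------
# Pairwise decoding
# ---------------------------------------------------------------------------

def pairwise_decode(
    epochs: EpochSet,
    window_ms: float | None = 10.0,
    step_ms: float | None = 4.0,
    n_folds: int = 2,
    n_reps: int = 10,
    group_size: int | None = None,
    shrinkage: float = 0.1,
    noise_norm: bool = True,
    C: float = 1.0,
    seed: int = 0,
) -> DecodingResult:
    """Time-resolved pairwise linear-SVM decoding of all condition pairs.

    For each repetition, trials are re-split into folds and re-averaged
    into pseudo-trials; for each fold role, window, and unordered
    condition pair, a linear SVM is trained on the training-fold
    pseudo-trials (features = all channels at the window's samples) and
    scored on the held-out fold.  Accuracies are averaged over fold roles
    and repetitions.  Deterministic under ``seed``.
    """
    win_idx, centers = sliding_windows(
        epochs.times, epochs.sample_rate, window_ms, step_ms
    )
    conditions = np.unique(epochs.labels[epochs.good_trials()])
    n_cond = len(conditions)
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    cond_pos = {c: i for i, c in enumerate(conditions)}
    n_win = len(win_idx)

    acc = np.zeros((n_cond, n_cond, n_win))
    n_eval = np.zeros((n_cond, n_cond, n_win))
    rep_seeds = np.random.SeedSequence(seed).spawn(n_reps)

    good = epochs.good_trials()
    src_data, src_labels = epochs.data[good], epochs.labels[good]

    for rep, rep_ss in enumerate(rep_seeds):
        rep_seed = int(rep_ss.generate_state(1)[0] % (2**31))
        pseudo = make_pseudotrials(epochs, n_folds, group_size, rep_seed)
        src_fold = pseudo.meta["source_fold"]
        for test_fold in range(n_folds):
            tr_mask = pseudo.fold != test_fold
            te_mask = ~tr_mask
            tr_data, tr_labels = pseudo.data[tr_mask], pseudo.labels[tr_mask]
            te_data, te_labels = pseudo.data[te_mask], pseudo.labels[te_mask]
            if noise_norm:
                # noise statistics from training-fold *source* trials only
                sel = src_fold != test_fold
                wmat = whitening_matrix(src_data[sel], src_labels[sel], shrinkage)
                tr_data = np.einsum("ij,njt->nit", wmat, tr_data)
                te_data = np.einsum("ij,njt->nit", wmat, te_data)
            if len(np.unique(tr_labels)) < 2 or len(te_labels) == 0:
                raise ValueError("degenerate fold: missing conditions")

            tr_by_cond = {c: np.flatnonzero(tr_labels == c) for c in conditions}
            te_by_cond = {c: np.flatnonzero(te_labels == c) for c in conditions}
            one_per_class = all(len(v) == 1 for v in tr_by_cond.values())
            te_cond_idx = np.array([cond_pos[c] for c in te_labels])
            for w, widx in enumerate(win_idx):
                xtr = tr_data[:, :, widx].reshape(len(tr_labels), -1)
                xte = te_data[:, :, widx].reshape(len(te_labels), -1)
                if one_per_class:
                    # With one training pseudo-trial per class, the
                    # linear-SVM boundary (any C > 0) is the perpendicular
                    # bisector of the two templates, so predictions equal
                    # the nearest-template rule — computed vectorized.
                    tmpl = np.stack(
                        [xtr[tr_by_cond[c][0]] for c in conditions]
                    )  # (n_cond, features)
                    d2 = (
                        (xte**2).sum(1)[:, None]
                        - 2.0 * xte @ tmpl.T
                        + (tmpl**2).sum(1)[None, :]
                    )  # (n_te, n_cond)
                    own = d2[np.arange(len(xte)), te_cond_idx][:, None]
                    correct = (own < d2).astype(float) + 0.5 * (own == d2)
                    # M[a, b]: mean correctness of class-a test trials vs b
                    m_sum = np.zeros((n_cond, n_cond))
                    m_cnt = np.zeros(n_cond)
                    np.add.at(m_sum, te_cond_idx, correct)
                    np.add.at(m_cnt, te_cond_idx, 1.0)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        m = m_sum / m_cnt[:, None]
                    for a in range(n_cond):
                        for b in range(a + 1, n_cond):
                            na, nb = m_cnt[a], m_cnt[b]
                            if na + nb == 0:
                                continue
                            pair_acc = (
                                (m[a, b] * na if na else 0.0)
                                + (m[b, a] * nb if nb else 0.0)
                            ) / (na + nb)
                            acc[a, b, w] += pair_acc
                            n_eval[a, b, w] += 1
                    continue
                for a in range(n_cond):
                    for b in range(a + 1, n_cond):
                        ca, cb = conditions[a], conditions[b]
                        ia, ib = tr_by_cond[ca], tr_by_cond[cb]
                        ja, jb = te_by_cond[ca], te_by_cond[cb]
                        if len(ja) + len(jb) == 0:
                            continue
                        clf = SVC(kernel="linear", C=C)
                        clf.fit(
                            np.concatenate([xtr[ia], xtr[ib]]),
                            np.concatenate([np.zeros(len(ia)), np.ones(len(ib))]),
                        )
                        pred = clf.predict(np.concatenate([xte[ja], xte[jb]]))
                        truth = np.concatenate([np.zeros(len(ja)), np.ones(len(jb))])
                        acc[a, b, w] += (pred == truth).mean()
                        n_eval[a, b, w] += 1

    upper = np.where(n_eval > 0, acc / np.maximum(n_eval, 1), 0.0)
    acc = upper + np.transpose(upper, (1, 0, 2))
    ii = np.arange(n_cond)
    acc[ii, ii, :] = np.nan
    return DecodingResult(
        accuracy=acc,
        window_centers_ms=centers,
        condition_ids=list(conditions),
        n_reps=n_reps,
        n_folds=n_folds,
        meta={"seed": seed, "window_ms": window_ms, "step_ms": step_ms,
              "shrinkage": shrinkage if noise_norm else None, "C": C},
    )


def decoding_to_rdms(result: DecodingResult) -> TimeResolvedRDM:
    """Rearrange pairwise accuracies into a time-resolved neural RDM.

    Per window, entry (i, j) is the decoding accuracy for conditions
    i vs j (patterns decoded more accurately are more dissimilar); the
    diagonal is zero.
    """
    acc = np.moveaxis(result.accuracy, 2, 0).copy()  # (win, n, n)
    n = acc.shape[1]
    ii = np.arange(n)
    acc[:, ii, ii] = 0.0
    if np.any(~np.isfinite(acc)) :
        raise ValueError("accuracies contain non-finite off-diagonal values")
    if acc.min() < 0.0 or acc.max() > 1.0:
        raise ValueError("accuracies must lie in [0, 1]")
    return TimeResolvedRDM(
        dissimilarities=acc,
        window_centers_ms=result.window_centers_ms,
        condition_ids=result.condition_ids,
        meta={"source": "pairwise_decoding", "n_reps": result.n_reps,
              "n_folds": result.n_folds},
    )
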