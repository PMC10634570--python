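"""Variance partitioning (commonality analysis) of neural RDM timecourses.

Decomposes the variance a set of 2–3 predictor RDMs explains in a target
RDM timecourse into portions unique to each predictor and shared among
every predictor combination.  With predictors 1, 2, 3 the seven subset
regressions give R²₁, R²₂, R²₃, R²₁₂, R²₁₃, R²₂₃, R²₁₂₃, from which

    UV₁   = R²₁₂₃ − R²₂₃                      (and cyclically)
    SV₁₂  = R²₁₃ + R²₂₃ − R²₃ − R²₁₂₃         (and cyclically)
    SV₁₂₃ = R²₁ + R²₂ + R²₃ − R²₁₂ − R²₁₃ − R²₂₃ + R²₁₂₃

These are the standard commonality-analysis formulas; the seven
components sum to R²₁₂₃ exactly (an algebraic identity used as a
self-check).  Shared components can be legitimately negative
(suppression); they are reported as-is with a flag, never clipped.

All variables (target and predictors) are standardized before
regression; unadjusted R² is used throughout (the identity requires it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .rdm import RDM, TimeResolvedRDM, vectorize_rdm

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceDecomposition",
    "fit_r2",
    "unique_variance",
    "shared_variance",
    "decompose_timecourse",
]


@dataclass
class VarianceDecomposition:
    """Unique/shared variance components per time window.

    ``r2`` maps predictor subsets (tuples of names) to per-window R²
    arrays; ``unique`` maps each predictor name to its UV timecourse;
    ``shared`` maps each combination (tuple of >= 2 names) to its SV
    timecourse.  ``negative_shared`` flags windows where any shared
    component is negative (suppression).
    """

    predictors: Sequence[str]
    window_centers_ms: np.ndarray
    r2: dict[tuple[str, ...], np.ndarray]
    unique: dict[str, np.ndarray]
    shared: dict[tuple[str, ...], np.ndarray]
    negative_shared: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def full_r2(self) -> np.ndarray:
        return self.r2[tuple(self.predictors)]

    def components_sum(self) -> np.ndarray:
        """Sum of all UV and SV components (equals full-model R²)."""
        out = np.zeros_like(self.full_r2())
        for v in self.unique.values():
            out = out + v
        for v in self.shared.values():
            out = out + v
        return out


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def fit_r2(y: np.ndarray, predictors: np.ndarray) -> float:
    """Ordinary least-squares coefficient of determination.

    ``predictors`` is (n_obs, k); inputs are standardized internally.
    A rank-deficient predictor subset is flagged and fit with the
    pseudoinverse (R² is then that of the minimum-norm solution).
    """
    y = _standardize(np.asarray(y, dtype=float))
    x = np.asarray(predictors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = np.column_stack([_standardize(col) for col in x.T])
    design = np.column_stack([np.ones(len(y)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("rank-deficient predictor set; using pseudoinverse fit")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tss


def _subset_r2(y: np.ndarray, x: dict[str, np.ndarray]) -> dict[tuple[str, ...], float]:
    names = list(x)
    out = {}
    for k in range(1, len(names) + 1):
        for sub in combinations(names, k):
            out[sub] = fit_r2(y, np.column_stack([x[n] for n in sub]))
    return out


def unique_variance(r2: dict[tuple[str, ...], float], poi: str) -> float:
    """UV of the predictor of interest: R²(all) − R²(all except poi)."""
    names = max(r2, key=len)
    if poi not in names:
        raise KeyError(f"unknown predictor {poi!r}")
    rest = tuple(n for n in names if n != poi)
    if rest not in r2 or names not in r2:
        raise KeyError("missing subset R² values")
    return r2[names] - r2[rest]


def shared_variance(r2: dict[tuple[str, ...], float]) -> dict[tuple[str, ...], float]:
    """All shared-variance components from the subset R² values.

    Implements the commonality-analysis expansion: for predictors
    {1,2,3}, SV₁₂ = R²₁₃ + R²₂₃ − R²₃ − R²₁₂₃ (cyclically) and
    SV₁₂₃ = R²₁+R²₂+R²₃ − R²₁₂ − R²₁₃ − R²₂₃ + R²₁₂₃; for two predictors
    SV₁₂ = R²₁ + R²₂ − R²₁₂.
    """
    names = list(max(r2, key=len))
    k = len(names)
    if k == 2:
        a, b = names
        return {(a, b): r2[(a,)] + r2[(b,)] - r2[tuple(names)]}
    if k != 3:
        raise ValueError("shared variance implemented for 2 or 3 predictors")
    a, b, c = names
    full = r2[(a, b, c)]
    sv = {
        (a, b): r2[(a, c)] + r2[(b, c)] - r2[(c,)] - full,
        (a, c): r2[(a, b)] + r2[(b, c)] - r2[(b,)] - full,
        (b, c): r2[(a, b)] + r2[(a, c)] - r2[(a,)] - full,
        (a, b, c): (
            r2[(a,)] + r2[(b,)] + r2[(c,)]
            - r2[(a, b)] - r2[(a, c)] - r2[(b, c)] + full
        ),
    }
    return sv


def decompose_timecourse(
    eeg: TimeResolvedRDM,
    predictors: dict[str, RDM] | Sequence[RDM],
    names: Sequence[str] | None = None,
) -> VarianceDecomposition:
    """Per-window unique/shared variance decomposition of a neural RDM.

    ``eeg`` is typically the subject-averaged time-resolved neural RDM;
    ``predictors`` are 2 or 3 named RDMs (e.g. the ROI triple
    EVC / TPJ-pSTS / somatosensory, or sociality with the two key ROIs).
    For every window the seven (or three) subset regressions are fit on
    standardized vectorized RDMs, then UV and SV components are derived.
    """
    if not isinstance(predictors, dict):
        if names is None:
            names = [str(p.meta.get("method", f"p{i}")) for i, p in enumerate(predictors)]
        predictors = dict(zip(names, predictors))
    if not 2 <= len(predictors) <= 3:
        raise ValueError("need 2 or 3 predictors")
    for name, p in predictors.items():
        if p.n_conditions != eeg.n_conditions:
            raise ValueError(f"predictor {name!r} condition count mismatch")
    x = {n: vectorize_rdm(p) for n, p in predictors.items()}
    pnames = list(x)
    n_win = eeg.n_windows

    subsets = [s for k in range(1, len(pnames) + 1)
               for s in combinations(pnames, k)]
    r2_tc = {s: np.empty(n_win) for s in subsets}
    for w, y in enumerate(eeg.vectors()):
        r2_w = _subset_r2(y, x)
        for s in subsets:
            r2_tc[s][w] = r2_w[s]

    full = tuple(pnames)
    uv = {n: r2_tc[full] - r2_tc[tuple(m for m in pnames if m != n)]
          for n in pnames}
    sv_keys = shared_variance({s: r2_tc[s][0] for s in subsets}).keys()
    sv = {}
    for key in sv_keys:
        sv[key] = np.array([
            shared_variance({s: r2_tc[s][w] for s in subsets})[key]
            for w in range(n_win)
        ])
    neg = np.zeros(n_win, dtype=bool)
    for v in sv.values():
        neg |= v < -1e-12
    if neg.any():
        logger.info(
            "negative shared variance (suppression) in %d window(s); "
            "reported as-is", int(neg.sum()),
        )
    return VarianceDecomposition(
        predictors=pnames,
        window_centers_ms=eeg.window_centers_ms,
        r2=r2_tc,
        unique=uv,
        shared=sv,
        negative_shared=neg,
    )
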