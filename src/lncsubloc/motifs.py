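"""RNA-binding-protein motif scanning with position weight matrices.

A PWM holds per-position base probabilities for one motif (CISBP-RNA
style, with the U column stored under T since sequences are kept in the
DNA alphabet). Scanning scores every window of the transcript with a
log-odds matrix in bits against a background distribution, and counts a
match wherever the window score strictly exceeds a fraction `alpha`
(default 0.8) of the maximal attainable score. Overlapping matches all
count; windows containing N are excluded.

Because log-odds scores can be negative, an alternative thresholding mode
``relative_range`` (min + alpha * (max - min)) is available; the default
``max_fraction`` follows the literal 80%-of-maximum rule, with a small
positive guard on the maximum for degenerate, uninformative matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet import BASE_INDEX, encode_bases
from .exceptions import ValidationError

__all__ = [
    "PWM",
    "MotifMatchResult",
    "log_odds_matrix",
    "score_window",
    "max_score",
    "min_score",
    "count_matches",
    "motif_feature_vector",
]

_UNIFORM = np.full(4, 0.25)
_MAX_SCORE_GUARD = 1e-9


@dataclass(frozen=True)
class PWM:
    """Position probability matrix for one motif; columns ordered A,C,G,T."""

    motif_id: str
    probs: np.ndarray
    pseudocount: float = 1e-3
    background: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", probs)
        bg = np.asarray(self.background, dtype=np.float64)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValidationError(
                f"PWM {self.motif_id!r}: expected shape (width, 4), got {probs.shape}"
            )
        if (probs < 0).any():
            raise ValidationError(f"PWM {self.motif_id!r}: negative probability entry")
        row_sums = probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-3):
            raise ValidationError(
                f"PWM {self.motif_id!r}: row sums deviate from 1 beyond 1e-3"
            )
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if abs(bg.sum() - 1.0) > 1e-6 or (bg <= 0).any():
            raise ValidationError("background must be a positive distribution")

    @property
    def width(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class MotifMatchResult:
    motif_id: str
    match_count: int
    threshold_score: float
    max_score: float


def log_odds_matrix(pwm: PWM) -> np.ndarray:
    """Log-odds scoring matrix in bits.

    entry(i, b) = log2((p(i,b) + c*bg(b)) / ((1 + c)*bg(b))) with
    pseudocount c; always finite.
    """
    c = pwm.pseudocount
    return np.log2((pwm.probs + c * pwm.background) / ((1.0 + c) * pwm.background))


def max_score(log_odds: np.ndarray) -> float:
    """Best attainable window score: sum of per-position maxima."""
    return float(np.max(log_odds, axis=1).sum())


def min_score(log_odds: np.ndarray) -> float:
    """Worst attainable window score: sum of per-position minima."""
    return float(np.min(log_odds, axis=1).sum())


def score_window(log_odds: np.ndarray, subsequence: str) -> float | None:
    """Score one window; None if the window contains N."""
    width = log_odds.shape[0]
    if len(subsequence) != width:
        raise ValidationError(
            f"window length {len(subsequence)} != PWM width {width}"
        )
    total = 0.0
    for i, base in enumerate(subsequence):
        idx = BASE_INDEX.get(base)
        if idx is None:
            return None
        total += log_odds[i, idx]
    return float(total)


def _window_scores(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of all N-free windows (vectorized); may be empty."""
    width = log_odds.shape[0]
    if codes.size < width:
        return np.empty(0)
    win = sliding_window_view(codes, width)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0)
    win_valid = win[valid].astype(np.intp)
    return log_odds[np.arange(width)[None, :], win_valid].sum(axis=1)


def count_matches(
    pwm: PWM,
    sequence: str,
    alpha: float = 0.8,
    threshold_mode: str = "max_fraction",
) -> MotifMatchResult:
    """Count windows scoring strictly above the relative threshold.

    max_fraction: threshold = alpha * max(max_score, tiny positive guard).
    relative_range: threshold = min + alpha * (max - min).
    Ties at exactly the threshold do not count. A sequence shorter than the
    motif yields zero matches.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    lom = log_odds_matrix(pwm)
    best = max_score(lom)
    if threshold_mode == "max_fraction":
        if best <= 0:
            warnings.warn(
                f"PWM {pwm.motif_id!r} is uninformative (max score <= 0); "
                "threshold guarded at a small positive value",
                stacklevel=2,
            )
        threshold = alpha * max(best, _MAX_SCORE_GUARD)
    elif threshold_mode == "relative_range":
        worst = min_score(lom)
        threshold = worst + alpha * (best - worst)
    else:
        raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")
    scores = _window_scores(lom, encode_bases(sequence))
    n_matches = int((scores > threshold).sum())
    return MotifMatchResult(
        motif_id=pwm.motif_id,
        match_count=n_matches,
        threshold_score=float(threshold),
        max_score=best,
    )


def motif_feature_vector(
    pwms: list[PWM] | tuple[PWM, ...],
    sequence: str,
    alpha: float = 0.8,
    threshold_mode: str = "max_fraction",
) -> np.ndarray:
    """Match counts for every motif, aligned to sorted motif_id order."""
    if not pwms:
        raise ValidationError("PWM collection is empty")
    ids = [p.motif_id for p in pwms]
    if len(set(ids)) != len(ids):
        dupes = sorted({m for m in ids if ids.count(m) > 1})
        raise ValidationError(f"duplicate motif ids: {dupes}")
    ordered = sorted(pwms, key=lambda p: p.motif_id)
    return np.array(
        [count_matches(p, sequence, alpha, threshold_mode).match_count for p in ordered],
        dtype=np.int64,
    )


def sorted_motif_ids(pwms: list[PWM] | tuple[PWM, ...]) -> list[str]:
    """Deterministic motif ordering used by the feature matrix."""
    return sorted(p.motif_id for p in pwms)
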