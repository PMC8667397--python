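"""Truncated binary cross-entropy with a dynamic drop threshold.

Noisy code annotations (spurious positives) are hard to fit and keep a large
per-entry loss mid-training.  The truncation loss exploits this: at training
iteration T a fraction D_T = min(gamma*T, D_max) of the eligible per-entry
losses — the largest ones — is zeroed, so presumed-noisy entries stop driving
gradients.  The drop rate ramps linearly from 0 to the cap ``D_max`` (default
0.15) over a warm-up, because early in training *all* losses are large and
dropping immediately would discard clean signal.

By default only positive entries (y=1) are eligible: annotation noise in code
assignment is dominated by erroneously *added* codes, and negatives vastly
outnumber positives.  A ``fixed_epsilon`` mode implementing a constant loss
threshold is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DenoiseConfig:
    """Truncation-loss settings.

    ``gamma`` (per-iteration ramp) defaults to ``D_max / warmup_iters``.
    ``stop_drop_after``: optional iteration after which no entries are dropped
    and the model learns from all remaining samples.
    """

    D_max: float = 0.15
    warmup_iters: int = 1000
    gamma: float | None = None
    positives_only: bool = True
    enabled: bool = True
    stop_drop_after: int | None = None
    fixed_epsilon: float | None = None  # literal constant-threshold mode

    def __post_init__(self):
        if not (0.0 <= self.D_max < 1.0):
            raise ValueError("D_max must be in [0, 1)")
        if self.gamma is None:
            self.gamma = self.D_max / max(self.warmup_iters, 1)
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class LossReport:
    """Per-batch record of the truncation step."""

    bce: np.ndarray  # per-entry loss matrix (batch, L)
    T: int  # iteration counter
    D_T: float  # effective drop rate
    kept_mask: np.ndarray  # boolean, False where dropped
    loss: float  # mean over total entry count, dropped entries contribute 0
    n_dropped: int


def bce_per_entry(y: np.ndarray, y_tilde: np.ndarray, clamp: float = 1e-7) -> np.ndarray:
    """Elementwise binary cross-entropy, probabilities clamped to (0,1)."""
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_tilde, dtype=np.float64), clamp, 1.0 - clamp)
    if y.shape != p.shape:
        raise ValueError("y and y_tilde shapes differ")
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def dynamic_threshold(T: int, gamma: float, D_max: float) -> float:
    """Drop rate D_T = min(gamma*T, D_max); non-decreasing, capped."""
    if T < 0:
        raise ValueError("iteration index must be >= 0")
    return min(gamma * T, D_max)


def truncation_loss(
    y: np.ndarray,
    y_tilde: np.ndarray,
    D_T: float,
    positives_only: bool = True,
) -> tuple[float, np.ndarray]:
    """Zero the top-D_T fraction of eligible per-entry losses; mean the rest.

    Exactly floor(D_T * #eligible) entries are dropped, ties at the cut broken
    by stable (row-major) entry order.  The mean is over the *total* entry
    count, so dropped entries contribute exactly 0 and D_T = 0 reproduces the
    plain mean BCE bit for bit.  Returns (loss, kept mask).
    """
    if not (0.0 <= D_T < 1.0):
        raise ValueError("D_T must be in [0, 1)")
    losses = bce_per_entry(y, y_tilde)
    eligible = (np.asarray(y) == 1) if positives_only else np.ones_like(losses, dtype=bool)
    kept = np.ones_like(losses, dtype=bool)
    n_drop = int(np.floor(D_T * int(eligible.sum())))
    if n_drop > 0:
        flat_idx = np.flatnonzero(eligible.ravel())
        vals = losses.ravel()[flat_idx]
        # stable sort descending: sort ascending on -loss keeps entry order on ties
        order = np.argsort(-vals, kind="stable")
        drop_flat = flat_idx[order[:n_drop]]
        kept.ravel()[drop_flat] = False
    loss = float(np.where(kept, losses, 0.0).sum() / losses.size)
    return loss, kept


def fixed_threshold_mask(
    y: np.ndarray, y_tilde: np.ndarray, epsilon: float, positives_only: bool = True
) -> np.ndarray:
    """Literal constant-threshold truncation: drop eligible entries with loss > epsilon."""
    losses = bce_per_entry(y, y_tilde)
    eligible = (np.asarray(y) == 1) if positives_only else np.ones_like(losses, dtype=bool)
    return ~(eligible & (losses > epsilon))


def truncation_step(
    y: np.ndarray, y_tilde: np.ndarray, T: int, config: DenoiseConfig
) -> LossReport:
    """One denoising step at iteration T under ``config``."""
    losses = bce_per_entry(y, y_tilde)
    if not config.enabled:
        kept = np.ones_like(losses, dtype=bool)
        D_T = 0.0
    elif config.fixed_epsilon is not None:
        kept = fixed_threshold_mask(y, y_tilde, config.fixed_epsilon, config.positives_only)
        D_T = float("nan")
    else:
        D_T = dynamic_threshold(T, config.gamma, config.D_max)
        if config.stop_drop_after is not None and T >= config.stop_drop_after:
            D_T = 0.0
        _, kept = truncation_loss(y, y_tilde, D_T, config.positives_only)
    loss = float(np.where(kept, losses, 0.0).sum() / losses.size)
    return LossReport(
        bce=losses,
        T=T,
        D_T=D_T,
        kept_mask=kept,
        loss=loss,
        n_dropped=int((~kept).sum()),
    )
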