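"""Quantal-size estimation from asynchronous IPSCs.

Strong stimulation of inhibitory afferents is followed by a period of
elevated quantal release (asynchronous IPSCs, measured 50-150 ms after the
stimulus).  Because spontaneous IPSCs continue throughout, the evoked
asynchronous amplitude is estimated by rate-weighted background correction:

    mu_A = (r_post * mu_post - r_pre * mu_pre) / (r_post - r_pre),

where r and mu are event rates and mean amplitudes in the pre-stimulus
baseline and post-stimulus windows.  The quantal content of a unitary IPSC
is then the ratio of the mean unitary amplitude to the mean asynchronous
(quantal) amplitude.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["WindowStats", "window_stats", "aipsc_mean_amplitude", "quantal_content"]

#: Default measurement windows (ms relative to the stimulus).
PRE_WINDOW = (-500.0, 0.0)
POST_WINDOW = (50.0, 150.0)


@dataclasses.dataclass
class WindowStats:
    """Event rates and mean amplitudes in the baseline and post-stimulus windows."""

    r_pre: float           # events/s
    r_post: float
    mu_pre: float          # pA (NaN when no events)
    mu_post: float
    n_pre: int
    n_post: int
    pre_window: tuple[float, float] = PRE_WINDOW
    post_window: tuple[float, float] = POST_WINDOW

    def __post_init__(self) -> None:
        if self.r_pre < 0 or self.r_post < 0:
            raise ValueError("rates must be nonnegative")


def window_stats(
    times_ms: np.ndarray,
    amplitudes_pA: np.ndarray,
    n_trials: int,
    pre_window: tuple[float, float] = PRE_WINDOW,
    post_window: tuple[float, float] = POST_WINDOW,
) -> WindowStats:
    """Rates and mean amplitudes of events pooled over trials.

    ``times_ms`` are stimulus-relative event times pooled across
    ``n_trials`` trials; rate = count / (window length * n_trials).  Windows
    must be disjoint.  Empty windows yield rate 0 and NaN mean amplitude.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    for w in (pre_window, post_window):
        if not w[0] < w[1]:
            raise ValueError(f"empty window {w}")
    if pre_window[1] > post_window[0] and post_window[1] > pre_window[0]:
        raise ValueError("pre and post windows must be disjoint")
    t = np.asarray(times_ms, dtype=float)
    a = np.asarray(amplitudes_pA, dtype=float)

    def _stats(win):
        m = (t >= win[0]) & (t < win[1])
        n = int(m.sum())
        rate = n / ((win[1] - win[0]) * 1e-3 * n_trials)
        mu = float(np.mean(a[m])) if n else math.nan
        return rate, mu, n

    r_pre, mu_pre, n_pre = _stats(pre_window)
    r_post, mu_post, n_post = _stats(post_window)
    return WindowStats(r_pre, r_post, mu_pre, mu_post, n_pre, n_post,
                       pre_window, post_window)


def aipsc_mean_amplitude(stats: WindowStats) -> float:
    """Background-corrected mean evoked asynchronous IPSC amplitude (pA).

    Requires an excess of events after the stimulus (r_post > r_pre);
    otherwise no evoked component exists and the estimator is undefined.
    """
    if stats.r_post <= stats.r_pre:
        raise ValueError(
            f"r_post ({stats.r_post:.3g}/s) must exceed r_pre "
            f"({stats.r_pre:.3g}/s): no excess evoked events"
        )
    if stats.r_pre == 0:
        return stats.mu_post
    return (stats.r_post * stats.mu_post - stats.r_pre * stats.mu_pre) / (
        stats.r_post - stats.r_pre
    )


def quantal_content(mean_uipsc: float, mean_aipsc: float) -> float:
    """Quantal content: mean unitary over mean asynchronous (quantal) amplitude."""
    if mean_aipsc == 0:
        raise ValueError("zero aIPSC amplitude")
    if mean_uipsc * mean_aipsc < 0:
        raise ValueError("uIPSC and aIPSC amplitudes must share a sign")
    return mean_uipsc / mean_aipsc
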