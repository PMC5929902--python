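"""Reference-free scalp-field statistics.

Global Field Power (GFP) is the spatial standard deviation of the
average-referenced electrode vector at one timepoint (population convention,
divide by the number of electrodes).  Global dissimilarity (DISS) between two
maps is the root-mean-square difference of the average-referenced,
GFP-normalised vectors and satisfies ``DISS = sqrt(2 (1 - r))`` where ``r``
is the spatial Pearson correlation.  The TANOVA is a paired randomisation
test on DISS between two conditions' group-mean maps at every timepoint,
with a temporal-stability criterion: only runs of below-alpha timepoints
strictly longer than 30 ms count as significant windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Erp

DEFAULT_N_PERM = 1000
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DURATION_MS = 30.0
_TINY = 1e-300


class UndefinedDissimilarityError(ValueError):
    """DISS requested for a map with zero Global Field Power."""


def _avg_ref(v: np.ndarray) -> np.ndarray:
    return v - v.mean(axis=-1, keepdims=True)


def gfp(v: np.ndarray) -> float | np.ndarray:
    """Global Field Power: spatial (population) SD over the last axis."""
    v = _avg_ref(np.asarray(v, float))
    return np.sqrt(np.mean(v ** 2, axis=-1))


def diss(u: np.ndarray, v: np.ndarray) -> float:
    """Global dissimilarity between two maps; in [0, 2], strength-invariant."""
    u = _avg_ref(np.asarray(u, float))
    v = _avg_ref(np.asarray(v, float))
    if u.shape != v.shape:
        raise ValueError("maps must share a montage")
    gu, gv = np.sqrt(np.mean(u ** 2)), np.sqrt(np.mean(v ** 2))
    if gu == 0 or gv == 0:
        raise UndefinedDissimilarityError("zero-GFP map has no configuration")
    return float(np.sqrt(np.mean((u / gu - v / gv) ** 2)))


@dataclass
class TanovaResult:
    times_ms: np.ndarray
    observed_diss: np.ndarray
    p_values: np.ndarray
    n_perm: int
    alpha: float
    min_duration_ms: float
    windows: list[tuple[float, float]]  # (onset_ms, offset_ms)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_ms": self.times_ms, "diss": self.observed_diss, "p": self.p_values}
        ).to_csv(path, index=False)

    def windows_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "min_duration_ms": self.min_duration_ms,
                "n_perm": self.n_perm,
                "windows": [{"onset_ms": a, "offset_ms": b} for a, b in self.windows],
            }
        )


def significant_windows(times_ms: np.ndarray, p_values: np.ndarray,
                        alpha: float = DEFAULT_ALPHA,
                        min_duration_ms: float = DEFAULT_MIN_DURATION_MS
                        ) -> list[tuple[float, float]]:
    """Maximal runs of p < alpha strictly longer than ``min_duration_ms``.

    A run's duration is offset minus onset time, so a run must span more
    than ``min_duration_ms`` of the recording; a run of exactly 30.0 ms does
    not qualify.
    """
    sig = np.asarray(p_values) < alpha
    out: list[tuple[float, float]] = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            onset, offset = float(times_ms[i]), float(times_ms[j])
            if offset - onset > min_duration_ms:
                out.append((onset, offset))
            i = j + 1
        else:
            i += 1
    return out


def _stack_condition(erps: list[Erp] | np.ndarray) -> np.ndarray:
    if isinstance(erps, np.ndarray):
        if erps.ndim != 3:
            raise ValueError("expected (n_participants, n_channels, n_times)")
        return erps
    return np.stack([e.data for e in erps])


def _diss_timecourse(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """DISS per timepoint for stacked maps of shape (..., n_ch, n_t)."""
    u = u - u.mean(axis=-2, keepdims=True)
    v = v - v.mean(axis=-2, keepdims=True)
    gu = np.sqrt(np.mean(u ** 2, axis=-2, keepdims=True))
    gv = np.sqrt(np.mean(v ** 2, axis=-2, keepdims=True))
    d = u / np.maximum(gu, _TINY) - v / np.maximum(gv, _TINY)
    return np.sqrt(np.mean(d ** 2, axis=-2))


def tanova_paired(cond_a: list[Erp] | np.ndarray, cond_b: list[Erp] | np.ndarray,
                  n_perm: int = DEFAULT_N_PERM, alpha: float = DEFAULT_ALPHA,
                  min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
                  seed: int = 0, times_ms: np.ndarray | None = None) -> TanovaResult:
    """Paired randomisation TANOVA between two conditions.

    The observed statistic at each timepoint is the DISS between the two
    group-mean maps.  The null distribution swaps the two condition maps
    independently within each participant (sign flips of the paired
    difference), sampled ``n_perm`` times; p-values use the add-one rule
    ``p = (1 + #{perm >= obs}) / (n_perm + 1)`` and can therefore never be
    smaller than ``1/(n_perm+1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values; refuse to run")
    A = _stack_condition(cond_a)
    B = _stack_condition(cond_b)
    if A.shape != B.shape:
        raise ValueError("conditions must have equal participant counts and timebase")
    n, n_ch, n_t = A.shape
    if times_ms is None:
        if isinstance(cond_a, np.ndarray):
            times_ms = np.arange(n_t, dtype=float)
        else:
            times_ms = cond_a[0].times_ms

    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    observed = _diss_timecourse(mean_a, mean_b)

    # within-participant swap: mean maps under sign pattern eps are
    # M +/- (eps @ d) / (2 n) with d the participant difference maps
    d = (A - B).reshape(n, n_ch * n_t)
    M = 0.5 * (mean_a + mean_b)
    rng = np.random.default_rng(seed)
    eps = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    D = (eps @ d).reshape(n_perm, n_ch, n_t) / n
    perm_stat = _diss_timecourse(M[None] + 0.5 * D, M[None] - 0.5 * D)

    exceed = np.sum(perm_stat >= observed[None] - 1e-12, axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    windows = significant_windows(times_ms, p, alpha, min_duration_ms)
    for a, b in windows:  # every reported window satisfies the predicate
        assert b - a > min_duration_ms
    return TanovaResult(times_ms=np.asarray(times_ms, float), observed_diss=observed,
                        p_values=p, n_perm=n_perm, alpha=alpha,
                        min_duration_ms=min_duration_ms, windows=windows)
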