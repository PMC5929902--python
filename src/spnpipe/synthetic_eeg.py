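"""Seeded synthetic epoched EEG with planted ground truth.

The generator emulates the recording setup of a symmetry 2IFC EEG study:
64-channel extended 10-20 montage, 1 kHz sampling, epochs -100..1000 ms,
24 participants, 100 trials per condition.  Every downstream quantity has a
planted ground truth:

* a sequence of quasi-stable scalp topographies (microstate templates) tiled
  over the 200-600 ms analysis window, one of which may be present only in
  symmetry conditions;
* a sustained negative offset (the SPN) at posterior electrodes PO7/PO8 over
  200-600 ms in symmetry conditions only;
* spatially correlated Gaussian sensor noise;
* optional high-amplitude artifact transients with an exact ground-truth mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_SFREQ,
    EPOCH_WINDOW_MS,
    SPN_ELECTRODES,
    SPN_WINDOW_MS,
    EpochSet,
    Montage,
    n_samples,
)
from .stimuli import TrialDesign

#: defaults of the simulated study conditions
DEFAULT_N_PARTICIPANTS = 24
DEFAULT_TRIAL_NOISE_SD = 15.0      # μV per sample per channel, single trial
DEFAULT_SPATIAL_CORR_LENGTH = 0.5  # chord-distance scale of noise correlation
DEFAULT_PARTICIPANT_GAIN_SD = 0.2  # log-normal sigma of multiplicative gain
DEFAULT_TEMPLATE_AMPLITUDE = 4.0   # μV envelope height of planted maps
DEFAULT_SPN_UV = -1.5              # planted symmetry-noise offset
RAMP_MS = 10.0                     # raised-cosine envelope ramp


class SeedFailureError(RuntimeError):
    """Could not draw sufficiently decorrelated templates for this seed."""


# ---------------------------------------------------------------------------
# template maps
# ---------------------------------------------------------------------------


def make_templates(montage: Montage, k: int, smoothness: float = 0.35,
                   seed: int | np.random.Generator = 0,
                   max_abs_corr: float = 0.7, max_retries: int = 500) -> np.ndarray:
    """Draw ``k`` average-referenced, unit-GFP scalp topographies.

    Each template mixes a few random dipolar patterns smoothed over the
    montage with an exponential distance kernel (scale ``smoothness`` in
    unit-sphere chord distance).  Templates are redrawn until all pairwise
    spatial correlations satisfy ``|r| <= max_abs_corr``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = montage.pairwise_distances()
    kernel = np.exp(-dist / smoothness)
    n = len(montage)

    def draw() -> np.ndarray:
        n_src = int(rng.integers(2, 5))
        idx = rng.choice(n, size=n_src, replace=False)
        w = rng.standard_normal(n_src)
        t = kernel[:, idx] @ w
        t = t - t.mean()
        g = np.sqrt(np.mean(t ** 2))
        if g == 0:
            return draw()
        return t / g

    templates: list[np.ndarray] = []
    retries = 0
    while len(templates) < k:
        cand = draw()
        if all(abs(np.mean(cand * t)) <= max_abs_corr for t in templates):
            templates.append(cand)
        else:
            retries += 1
            if retries > max_retries:
                raise SeedFailureError(
                    f"could not draw {k} templates with pairwise |r| <= {max_abs_corr}"
                )
    return np.array(templates)


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation between two maps across electrodes."""
    u = np.asarray(u, float) - np.mean(u)
    v = np.asarray(v, float) - np.mean(v)
    return float(np.mean(u * v) / (np.sqrt(np.mean(u ** 2)) * np.sqrt(np.mean(v ** 2))))


# ---------------------------------------------------------------------------
# planted timeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimelineSegment:
    """One quasi-stable topography interval.

    ``conditions=None`` plants the segment in every condition; otherwise only
    in the named ones.  ``amplitude_uv`` is the envelope height.
    """

    template_id: int
    onset_ms: float
    offset_ms: float
    amplitude_uv: float = DEFAULT_TEMPLATE_AMPLITUDE
    conditions: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SpnEffect:
    """Planted sustained offset at a set of electrodes, symmetry-only."""

    conditions: tuple[str, ...]
    electrodes: tuple[str, ...] = SPN_ELECTRODES
    window_ms: tuple[float, float] = SPN_WINDOW_MS
    offset_uv: float = DEFAULT_SPN_UV


@dataclass
class PlantedTimeline:
    """Template bank plus the planted segment/SPN schedule."""

    templates: np.ndarray  # (k, n_channels)
    segments: list[TimelineSegment]
    spn: SpnEffect | None = None

    def validate(self, conditions: list[str], epoch_window_ms=EPOCH_WINDOW_MS) -> None:
        k = len(self.templates)
        for seg in self.segments:
            if not 0 <= seg.template_id < k:
                raise KeyError(f"timeline references unknown template id {seg.template_id}")
        for cond in conditions:
            segs = sorted(
                (s for s in self.segments if s.conditions is None or cond in s.conditions),
                key=lambda s: s.onset_ms,
            )
            for a, b in zip(segs, segs[1:]):
                if b.onset_ms < a.offset_ms - 1e-9:
                    raise ValueError(f"overlapping segments in condition {cond!r}")
        if self.spn is not None:
            lo, hi = self.spn.window_ms
            if lo < epoch_window_ms[0] or hi > epoch_window_ms[1]:
                raise ValueError("SPN window outside epoch window")

    def segment_labels(self, condition: str, times_ms: np.ndarray) -> np.ndarray:
        """Planted template id per timepoint (-1 where nothing is planted)."""
        lab = np.full(times_ms.shape, -1, dtype=int)
        for seg in self.segments:
            if seg.conditions is None or condition in seg.conditions:
                sel = (times_ms >= seg.onset_ms - 1e-9) & (times_ms <= seg.offset_ms + 1e-9)
                lab[sel] = seg.template_id
        return lab


def _envelope(times_ms: np.ndarray, onset: float, offset: float,
              ramp_ms: float = RAMP_MS) -> np.ndarray:
    """Unit-height envelope with raised-cosine on/off ramps."""
    env = np.zeros_like(times_ms, dtype=float)
    inside = (times_ms >= onset) & (times_ms <= offset)
    env[inside] = 1.0
    if ramp_ms > 0:
        up = inside & (times_ms < onset + ramp_ms)
        env[up] = 0.5 * (1 - np.cos(np.pi * (times_ms[up] - onset) / ramp_ms))
        down = inside & (times_ms > offset - ramp_ms)
        env[down] = 0.5 * (1 - np.cos(np.pi * (offset - times_ms[down]) / ramp_ms))
    return env


def default_timeline(montage: Montage, symmetry_conditions: list[str],
                     noise_conditions: list[str], k: int = 4,
                     window_ms: tuple[float, float] = SPN_WINDOW_MS,
                     amplitude_uv: float = DEFAULT_TEMPLATE_AMPLITUDE,
                     spn_uv: float = DEFAULT_SPN_UV,
                     symmetry_only_map: int | None = "last",
                     seed: int | np.random.Generator = 0) -> PlantedTimeline:
    """Study-style timeline: ``k`` maps tiled over the analysis window.

    The last map (by default) is planted only in symmetry conditions; noise
    conditions extend the preceding map over its slot, mimicking a
    symmetry-specific late microstate.  With ``symmetry_only_map=None`` all
    segments are shared between conditions, so the planted SPN offset is the
    *only* condition difference — the configuration for amplitude-recovery
    experiments, where a condition-specific topography would contaminate the
    electrode-level difference wave.
    """
    templates = make_templates(montage, k, seed=seed)
    if symmetry_only_map == "last":
        symmetry_only_map = k - 1
    if symmetry_only_map is not None and k > 1:
        # orient the symmetry-only map so that, relative to the map the noise
        # conditions keep in its place, it contributes posterior *negativity*
        # at the SPN electrodes (template sign is otherwise arbitrary); the
        # planted amplitude difference and the planted microstate then point
        # the same way, as in the phenomenon being emulated
        rows = [montage.index(e) for e in SPN_ELECTRODES]
        prev = (symmetry_only_map - 1) % k
        delta = templates[symmetry_only_map, rows].mean() - templates[prev, rows].mean()
        if delta > 0:
            templates[symmetry_only_map] *= -1.0
    lo, hi = window_ms
    edges = np.linspace(lo, hi, k + 1)
    segments: list[TimelineSegment] = []
    for m in range(k):
        onset, offset = float(edges[m]), float(edges[m + 1])
        if m == symmetry_only_map:
            segments.append(TimelineSegment(m, onset, offset, amplitude_uv,
                                            tuple(symmetry_conditions)))
            # noise conditions keep the previous map through this slot
            prev = (m - 1) % k
            segments.append(TimelineSegment(prev, onset, offset, amplitude_uv,
                                            tuple(noise_conditions)))
        else:
            segments.append(TimelineSegment(m, onset, offset, amplitude_uv))
    spn = SpnEffect(conditions=tuple(symmetry_conditions), offset_uv=spn_uv)
    return PlantedTimeline(templates=templates, segments=segments, spn=spn)


# ---------------------------------------------------------------------------
# epoch simulation
# ---------------------------------------------------------------------------


def _noise_chol(montage: Montage, corr_length: float) -> np.ndarray:
    """Cholesky factor of the exponential spatial correlation over electrodes."""
    if corr_length <= 0:
        return np.eye(len(montage))
    K = np.exp(-montage.pairwise_distances() / corr_length)
    return np.linalg.cholesky(K + 1e-10 * np.eye(len(montage)))


def simulate_epochs(design: TrialDesign | list[str], timeline: PlantedTimeline,
                    n_participants: int = DEFAULT_N_PARTICIPANTS,
                    trial_noise_sd: float = DEFAULT_TRIAL_NOISE_SD,
                    spatial_noise_corr: float = DEFAULT_SPATIAL_CORR_LENGTH,
                    seed: int = 0, montage: Montage | None = None,
                    sfreq: float = DEFAULT_SFREQ,
                    n_trials: int | None = None,
                    participant_gain_sd: float = DEFAULT_PARTICIPANT_GAIN_SD,
                    ) -> list[EpochSet]:
    """Simulate one :class:`EpochSet` per participant.

    Conditions are taken from the design: each symmetric condition plus each
    distinct matched noise arrangement, every one with
    ``presentations_per_condition`` trials (override with ``n_trials``).
    Per trial: planted template segments (raised-cosine envelopes) + the
    planted SPN offset + spatially correlated Gaussian noise, all scaled by a
    participant-level log-normal gain (mean 1, sigma ``participant_gain_sd``).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if montage is None:
        montage = Montage.standard_64()
    if isinstance(design, TrialDesign):
        conditions = list(design.condition_names)
        for c in design.conditions:
            if c.noise_arrangement not in conditions:
                conditions.append(c.noise_arrangement)
        if n_trials is None:
            n_trials = design.presentations_per_condition
    else:
        conditions = list(design)
        if n_trials is None:
            n_trials = 100
    timeline.validate(conditions)

    nt = n_samples(EPOCH_WINDOW_MS[0], EPOCH_WINDOW_MS[1], sfreq)
    times = EPOCH_WINDOW_MS[0] + np.arange(nt) * 1000.0 / sfreq
    L = _noise_chol(montage, spatial_noise_corr)

    # noiseless signal per condition: sum of template x envelope (+ SPN)
    signals: dict[str, np.ndarray] = {}
    for cond in conditions:
        sig = np.zeros((len(montage), nt))
        for seg in timeline.segments:
            if seg.conditions is None or cond in seg.conditions:
                env = _envelope(times, seg.onset_ms, seg.offset_ms)
                sig += seg.amplitude_uv * np.outer(timeline.templates[seg.template_id], env)
        if timeline.spn is not None and cond in timeline.spn.conditions:
            env = _envelope(times, *timeline.spn.window_ms)
            rows = [montage.index(e) for e in timeline.spn.electrodes]
            sig[rows] += timeline.spn.offset_uv * env
        signals[cond] = sig

    ss = np.random.SeedSequence(seed)
    out: list[EpochSet] = []
    for p, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        gain = float(rng.lognormal(mean=-0.5 * participant_gain_sd ** 2,
                                   sigma=participant_gain_sd))
        data = {}
        for cond in conditions:
            z = rng.standard_normal((len(montage), n_trials * nt))
            noise = (trial_noise_sd * (L @ z)).reshape(len(montage), n_trials, nt)
            data[cond] = gain * signals[cond][None] + noise.transpose(1, 0, 2)
        out.append(EpochSet(data=data, montage=montage, sfreq=sfreq,
                            participant=f"p{p:02d}"))
    return out


def inject_artifacts(e: EpochSet, fraction: float = 0.06, peak_uv: float = 150.0,
                     seed: int = 0) -> EpochSet:
    """Plant high-amplitude transients in a fraction of epochs per condition.

    Returns a new :class:`EpochSet` whose ``artifact_mask`` records exactly
    which epochs carry a transient; each flagged epoch exceeds ``peak_uv`` in
    absolute value on at least one electrode.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if peak_uv <= 100.0:
        raise ValueError("peak_uv must exceed the 100 μV rejection threshold")
    rng = np.random.default_rng(seed)
    data = {c: a.copy() for c, a in e.data.items()}
    mask: dict[str, np.ndarray] = {}
    nt = next(iter(data.values())).shape[2]
    width = max(3, int(round(0.06 * nt)))  # ~60 ms bump at 1 kHz
    bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / (width - 1)))
    for cond, arr in data.items():
        n_tr = arr.shape[0]
        k = int(round(fraction * n_tr))
        flagged = rng.choice(n_tr, size=k, replace=False) if k else np.array([], dtype=int)
        m = np.zeros(n_tr, dtype=bool)
        m[flagged] = True
        mask[cond] = m
        for tr in flagged:
            ch = int(rng.integers(arr.shape[1]))
            t0 = int(rng.integers(0, nt - width))
            sign = 1.0 if rng.integers(2) else -1.0
            target = sign * 1.05 * peak_uv
            ipk = t0 + int(np.argmax(bump))
            # scale the bump so the peak sample lands exactly on the target
            arr[tr, ch, t0:t0 + width] += (target - arr[tr, ch, ipk]) * bump
        data[cond] = arr
    return e.copy_with(data=data, artifact_mask=mask)
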