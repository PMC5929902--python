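"""Epoch-domain preprocessing: from raw epochs to ERPs and SPN measures.

The processing chain mirrors a standard ERP workflow: zero-phase 40 Hz
low-pass (48 dB/octave one-pass slope), baseline correction over -100..0 ms,
+/-100 μV artifact rejection (strict inequality), per-condition averaging on
the online Cz reference, common-average re-referencing, symmetry-minus-noise
difference waves, and the SPN as the mean over PO7/PO8 within the closed
200-600 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    BASELINE_WINDOW_MS,
    SPN_ELECTRODES,
    SPN_WINDOW_MS,
    EpochSet,
    Erp,
)

REJECTION_THRESHOLD_UV = 100.0
LOWPASS_CUTOFF_HZ = 40.0
LOWPASS_SLOPE_DB_PER_OCTAVE = 48.0


class DegenerateConditionError(RuntimeError):
    """Artifact rejection removed every epoch of a condition."""


def design_lowpass(cutoff_hz: float, sfreq: float,
                   slope_db_per_octave: float = LOWPASS_SLOPE_DB_PER_OCTAVE) -> np.ndarray:
    """Butterworth SOS whose one-pass asymptotic roll-off matches the slope.

    A Butterworth filter rolls off at 6 dB/octave per pole, so 48 dB/octave
    corresponds to order 8.  Applied forward-backward (zero phase), the
    realised attenuation doubles; the stated slope refers to one pass.
    """
    if cutoff_hz >= sfreq / 2.0:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    order = int(round(slope_db_per_octave / 6.0))
    return sps.butter(order, cutoff_hz, btype="low", fs=sfreq, output="sos")


def lowpass_filter(e: EpochSet, cutoff_hz: float = LOWPASS_CUTOFF_HZ,
                   slope_db_per_octave: float = LOWPASS_SLOPE_DB_PER_OCTAVE) -> EpochSet:
    """Zero-phase low-pass along the time axis of every epoch (DC gain 1)."""
    sos = design_lowpass(cutoff_hz, e.sfreq, slope_db_per_octave)
    data = {c: sps.sosfiltfilt(sos, a, axis=-1) for c, a in e.data.items()}
    return e.copy_with(data=data)


def baseline_correct(e: EpochSet,
                     window_ms: tuple[float, float] = BASELINE_WINDOW_MS) -> EpochSet:
    """Subtract the per-epoch, per-electrode mean over the baseline window."""
    idx = e.window_indices(window_ms)
    if idx.size == 0:
        raise ValueError("empty baseline window")
    data = {c: a - a[:, :, idx].mean(axis=-1, keepdims=True) for c, a in e.data.items()}
    return e.copy_with(data=data)


@dataclass
class RejectionLog:
    indices: dict[str, np.ndarray]  # removed epoch indices per condition
    table: pd.DataFrame             # condition, n_total, n_rejected, pct

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def reject_epochs(e: EpochSet, threshold_uv: float = REJECTION_THRESHOLD_UV
                  ) -> tuple[EpochSet, RejectionLog]:
    """Drop every epoch in which any sample strictly exceeds +/-threshold.

    The comparison is strict: a sample at exactly the threshold is retained.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    data, mask_out, removed, rows = {}, {}, {}, []
    for cond, arr in e.data.items():
        bad = np.max(np.abs(arr), axis=(1, 2)) > threshold_uv
        if bad.all():
            raise DegenerateConditionError(
                f"all {arr.shape[0]} epochs of condition {cond!r} exceed "
                f"±{threshold_uv} μV"
            )
        data[cond] = arr[~bad]
        removed[cond] = np.nonzero(bad)[0]
        if e.artifact_mask and cond in e.artifact_mask:
            mask_out[cond] = e.artifact_mask[cond][~bad]
        rows.append(
            {
                "condition": cond,
                "n_total": arr.shape[0],
                "n_rejected": int(bad.sum()),
                "pct_rejected": 100.0 * bad.mean(),
            }
        )
    log = RejectionLog(indices=removed, table=pd.DataFrame(rows))
    return e.copy_with(data=data, artifact_mask=mask_out or None), log


def average_erp(e: EpochSet, condition: str) -> Erp:
    """Equal-weighted pointwise mean over the surviving epochs."""
    arr = e.data[condition]
    if arr.shape[0] == 0:
        raise ValueError(f"no epochs to average in condition {condition!r}")
    return Erp(
        data=arr.mean(axis=0),
        condition=condition,
        n_epochs=arr.shape[0],
        montage=e.montage,
        sfreq=e.sfreq,
        tmin_ms=e.tmin_ms,
        reference=e.reference,
        participant=e.participant,
    )


def rereference_common_average(erp: Erp) -> Erp:
    """Subtract the instantaneous electrode mean; idempotent."""
    data = erp.data - erp.data.mean(axis=0, keepdims=True)
    return Erp(data=data, condition=erp.condition, n_epochs=erp.n_epochs,
               montage=erp.montage, sfreq=erp.sfreq, tmin_ms=erp.tmin_ms,
               reference="common-average", participant=erp.participant)


def difference_wave(sym: Erp, noise: Erp) -> Erp:
    """Pointwise symmetry-minus-noise difference of two same-reference ERPs."""
    if sym.montage.names != noise.montage.names:
        raise ValueError("montage mismatch between ERPs")
    if sym.data.shape != noise.data.shape or sym.sfreq != noise.sfreq \
            or sym.tmin_ms != noise.tmin_ms:
        raise ValueError("timebase mismatch between ERPs")
    if sym.reference != noise.reference:
        raise ValueError("reference-state mismatch between ERPs")
    return Erp(data=sym.data - noise.data,
               condition=f"{sym.condition}-{noise.condition}",
               n_epochs=min(sym.n_epochs, noise.n_epochs),
               montage=sym.montage, sfreq=sym.sfreq, tmin_ms=sym.tmin_ms,
               reference=sym.reference, participant=sym.participant)


@dataclass(frozen=True)
class SpnMeasure:
    """Mean symmetry-minus-noise amplitude over PO7/PO8 in 200-600 ms (μV)."""

    participant: str
    condition_pair: str
    amplitude_uv: float
    electrodes: tuple[str, ...] = SPN_ELECTRODES
    window_ms: tuple[float, float] = SPN_WINDOW_MS


def spn_amplitude(diff: Erp, electrodes: tuple[str, ...] = SPN_ELECTRODES,
                  window_ms: tuple[float, float] = SPN_WINDOW_MS) -> SpnMeasure:
    """Average the difference wave over the electrode set and closed window.

    Requires a common-average-referenced difference wave: the SPN is defined
    reference-free.
    """
    if diff.reference != "common-average":
        raise ValueError("SPN is measured on common-average-referenced ERPs")
    rows = [diff.montage.index(e) for e in electrodes]
    idx = diff.window_indices(window_ms)
    amp = float(diff.data[np.ix_(rows, idx)].mean())
    return SpnMeasure(participant=diff.participant, condition_pair=diff.condition,
                      amplitude_uv=amp, electrodes=tuple(electrodes),
                      window_ms=tuple(window_ms))


def participant_erps(e: EpochSet, lowpass: bool = True,
                     reject: bool = True,
                     threshold_uv: float = REJECTION_THRESHOLD_UV,
                     common_average: bool = True,
                     reject_before_lowpass: bool = False) -> dict[str, Erp]:
    """Full single-participant chain: filter, baseline, reject, average,
    re-reference.  Returns one ERP per condition.

    The amplitude test runs after filtering by default;
    ``reject_before_lowpass`` applies it to the unfiltered epochs instead.
    """
    if reject and reject_before_lowpass:
        e, _ = reject_epochs(e, threshold_uv)
    if lowpass:
        e = lowpass_filter(e)
    e = baseline_correct(e)
    if reject and not reject_before_lowpass:
        e, _ = reject_epochs(e, threshold_uv)
    erps = {c: average_erp(e, c) for c in e.conditions}
    if common_average:
        erps = {c: rereference_common_average(v) for c, v in erps.items()}
    return erps


def participant_spn(erps: dict[str, Erp], sym_condition: str,
                    noise_condition: str) -> SpnMeasure:
    """SPN for one symmetry/noise condition pair from re-referenced ERPs."""
    return spn_amplitude(difference_wave(erps[sym_condition], erps[noise_condition]))
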