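"""Shared containers for the SPN/microstate pipeline.

Voltages are microvolts throughout; times are milliseconds relative to
stimulus onset; electrode positions are unit vectors on the head sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np

#: default epoch geometry: -100..1000 ms around stimulus onset at 1 kHz
EPOCH_WINDOW_MS = (-100.0, 1000.0)
BASELINE_WINDOW_MS = (-100.0, 0.0)
DEFAULT_SFREQ = 1000.0

#: SPN measurement convention: posterior electrode pair, 200-600 ms window
SPN_ELECTRODES = ("PO7", "PO8")
SPN_WINDOW_MS = (200.0, 600.0)

#: 64-channel extended 10-20 layout (online reference Cz is recorded as a
#: flat channel would be in hardware; here it is an ordinary channel).
STANDARD_64 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "Iz",
]


@dataclass(frozen=True)
class Montage:
    """Electrode names with unit-sphere 3-D positions and a 2-D projection."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 3), unit norm

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("electrode names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length electrode position")
        object.__setattr__(self, "positions", pos / norms[:, None])

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not in montage") from None

    @property
    def pos2d(self) -> np.ndarray:
        """Azimuthal-equidistant projection, head seen from above, nasion up."""
        x, y, z = self.positions.T
        theta = np.arccos(np.clip(z, -1.0, 1.0))
        rho = np.hypot(x, y)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(rho > 0, x / rho, 0.0)
            uy = np.where(rho > 0, y / rho, 0.0)
        return np.column_stack([theta * ux, theta * uy])

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean chord distances between electrodes on the unit sphere."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)

    @classmethod
    def standard_64(cls) -> "Montage":
        """Extended 10-20 montage of 64 channels (incl. PO7, PO8, Cz)."""
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = mne.channels.make_standard_montage("colin27_1005")
        ch_pos = std.get_positions()["ch_pos"]
        pos = np.array([ch_pos[name] for name in STANDARD_64])
        # centre the sphere on the mean position so directions are radial
        pos = pos - pos.mean(axis=0)
        return cls(tuple(STANDARD_64), pos)

    def write_sfp(self, path) -> None:
        with open(path, "w") as fh:
            for name, p in zip(self.names, self.positions):
                fh.write(f"{name}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")

    @classmethod
    def read_sfp(cls, path) -> "Montage":
        names, pos = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                names.append(parts[0])
                pos.append([float(v) for v in parts[1:4]])
        return cls(tuple(names), np.array(pos))


def n_samples(tmin_ms: float, tmax_ms: float, sfreq: float) -> int:
    """Sample count for a closed [tmin, tmax] window at rate sfreq."""
    return int(round((tmax_ms - tmin_ms) * sfreq / 1000.0)) + 1


@dataclass
class EpochSet:
    """Single-participant epoched EEG, one trial tensor per condition.

    ``data[cond]`` has shape (n_trials, n_channels, n_times) in microvolts.
    ``artifact_mask[cond]`` (simulation ground truth only) flags epochs that
    carry an injected high-amplitude transient.
    """

    data: dict[str, np.ndarray]
    montage: Montage
    sfreq: float = DEFAULT_SFREQ
    tmin_ms: float = EPOCH_WINDOW_MS[0]
    tmax_ms: float = EPOCH_WINDOW_MS[1]
    baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS
    participant: str = "p00"
    reference: str = "online-Cz"
    artifact_mask: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        nt = n_samples(self.tmin_ms, self.tmax_ms, self.sfreq)
        for cond, arr in self.data.items():
            if arr.ndim != 3 or arr.shape[1] != len(self.montage) or arr.shape[2] != nt:
                raise ValueError(
                    f"condition {cond!r}: expected (n_trials, {len(self.montage)}, {nt}), "
                    f"got {arr.shape}"
                )

    @property
    def conditions(self) -> list[str]:
        return list(self.data)

    @property
    def times_ms(self) -> np.ndarray:
        nt = n_samples(self.tmin_ms, self.tmax_ms, self.sfreq)
        return self.tmin_ms + np.arange(nt) * 1000.0 / self.sfreq

    def window_indices(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Indices of samples inside the closed window [lo, hi] ms."""
        t = self.times_ms
        lo, hi = window_ms
        if lo < self.tmin_ms - 1e-9 or hi > self.tmax_ms + 1e-9:
            raise ValueError(f"window {window_ms} outside epoch {self.tmin_ms}..{self.tmax_ms}")
        return np.nonzero((t >= lo - 1e-9) & (t <= hi + 1e-9))[0]

    def copy_with(self, **kw) -> "EpochSet":
        if "data" not in kw:
            kw["data"] = {c: a.copy() for c, a in self.data.items()}
        return replace(self, **kw)


@dataclass
class Erp:
    """Condition-average waveform: (n_channels, n_times) in microvolts."""

    data: np.ndarray
    condition: str
    n_epochs: int
    montage: Montage
    sfreq: float = DEFAULT_SFREQ
    tmin_ms: float = EPOCH_WINDOW_MS[0]
    reference: str = "online-Cz"
    participant: str = "p00"

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_times) * 1000.0 / self.sfreq

    def window_indices(self, window_ms: tuple[float, float]) -> np.ndarray:
        t = self.times_ms
        lo, hi = window_ms
        idx = np.nonzero((t >= lo - 1e-9) & (t <= hi + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"window {window_ms} outside ERP timebase")
        return idx


# ---------------------------------------------------------------------------
# HDF5 epoch container
#
# Layout:
#   /montage/names           (n,) utf-8 strings
#   /montage/positions       (n, 3) float
#   /participants/<id>/attrs: sfreq, tmin_ms, tmax_ms, baseline_ms, reference
#   /participants/<id>/<condition>/data           (trials, ch, time)
#   /participants/<id>/<condition>/artifact_mask  (trials,) bool, optional
# ---------------------------------------------------------------------------


def save_epochsets(path, epochsets: list[EpochSet]) -> None:
    if not epochsets:
        raise ValueError("nothing to save")
    mont = epochsets[0].montage
    with h5py.File(path, "w") as f:
        g = f.create_group("montage")
        g.create_dataset("names", data=np.array(mont.names, dtype=h5py.string_dtype()))
        g.create_dataset("positions", data=mont.positions)
        root = f.create_group("participants")
        for es in epochsets:
            gp = root.create_group(es.participant)
            gp.attrs["sfreq"] = es.sfreq
            gp.attrs["tmin_ms"] = es.tmin_ms
            gp.attrs["tmax_ms"] = es.tmax_ms
            gp.attrs["baseline_ms"] = es.baseline_ms
            gp.attrs["reference"] = es.reference
            for cond, arr in es.data.items():
                gc = gp.create_group(cond)
                gc.create_dataset("data", data=arr)
                if es.artifact_mask and cond in es.artifact_mask:
                    gc.create_dataset("artifact_mask", data=es.artifact_mask[cond])


def load_epochsets(path) -> list[EpochSet]:
    out = []
    with h5py.File(path, "r") as f:
        names = tuple(s.decode() if isinstance(s, bytes) else s for s in f["montage/names"][()])
        mont = Montage(names, f["montage/positions"][()])
        for pid in sorted(f["participants"]):
            gp = f["participants"][pid]
            data, mask = {}, {}
            for cond in sorted(gp):
                data[cond] = gp[cond]["data"][()]
                if "artifact_mask" in gp[cond]:
                    mask[cond] = gp[cond]["artifact_mask"][()].astype(bool)
            out.append(
                EpochSet(
                    data=data,
                    montage=mont,
                    sfreq=float(gp.attrs["sfreq"]),
                    tmin_ms=float(gp.attrs["tmin_ms"]),
                    tmax_ms=float(gp.attrs["tmax_ms"]),
                    baseline_ms=tuple(gp.attrs["baseline_ms"]),
                    participant=pid,
                    reference=str(gp.attrs["reference"]),
                    artifact_mask=mask or None,
                )
            )
    return out
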