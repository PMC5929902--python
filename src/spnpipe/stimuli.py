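"""Mirror-symmetry dot-pattern stimuli and two-interval forced-choice designs.

A stimulus is a circular field (12 deg diameter) of Gaussian dots
(sigma = 0.08 deg, truncated at 5 sigma) on a mid-grey background.  Dots are
either mirror-paired about the vertical axis (position symmetry) or placed
quasi-randomly (noise), and carry a luminance polarity (white/black) or a
colour label.  The arrangements differ in how polarity/colour is distributed
over the mirror pairs:

``anti_symmetric``
    mirror mates have opposite luminance polarity.
``polarity_grouped_anti``
    every dot left of the axis is one polarity, every dot right of it the
    other (a special case of anti-symmetry with polarity grouping).
``unsegregated``
    mirror mates share polarity; half the pairs white, half black.
``segregated``
    all mirror-paired dots one polarity, all noise dots the other
    (only defined at 50% position symmetry).
``single_polarity``
    every dot the same polarity.
``noise`` / ``polarity_grouped_noise`` / ``single_polarity_noise``
    0% position symmetry with the matching polarity layout.
``multicolour``
    mirror mates share a colour; 2-4 colours balanced across the pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

APERTURE_DEG = 12.0
DOT_SIGMA_DEG = 0.08
SIZE_SD_FACTOR = 5.0
N_DOTS_ACHROMATIC = 60
N_DOTS_CHROMATIC = 96
#: placement constraints (rejection sampling): minimum centre-to-centre
#: spacing, and an exclusion strip either side of the vertical axis so no
#: dot straddles the symmetry axis.
MIN_SPACING_DEG = 0.5
AXIS_MARGIN_DEG = 0.15
#: dots are kept this far inside the aperture so the rendered blob
#: (truncated at SIZE_SD_FACTOR * sigma) never crosses the rim
EDGE_MARGIN_DEG = SIZE_SD_FACTOR * DOT_SIGMA_DEG

POLARITIES = ("white", "black")
ARRANGEMENTS = (
    "anti_symmetric", "polarity_grouped_anti", "unsegregated", "segregated",
    "single_polarity", "noise", "polarity_grouped_noise",
    "single_polarity_noise", "multicolour",
)
NOISE_ARRANGEMENTS = ("noise", "polarity_grouped_noise", "single_polarity_noise")

#: RGB the dot tends toward when rendered on the mid-grey background
_COLOUR_RGB = {
    "white": (1.0, 1.0, 1.0), "black": (0.0, 0.0, 0.0),
    "red": (1.0, 0.0, 0.0), "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0), "yellow": (1.0, 1.0, 0.0),
}


class InvalidArrangementError(ValueError):
    """Arrangement incompatible with the requested symmetry fraction."""


class InvalidBalanceError(ValueError):
    """Exact polarity/colour balance impossible for the requested counts."""


@dataclass
class DotPattern:
    positions: np.ndarray       # (n, 2) degrees, centred on (0, 0)
    labels: list[str]           # per-dot polarity or colour
    pairing: list[tuple[int, int]]  # mirror mates (i left of axis, j right)
    arrangement: str
    position_symmetry_frac: float
    aperture_deg: float = APERTURE_DEG
    dot_sigma_deg: float = DOT_SIGMA_DEG
    size_sd_factor: float = SIZE_SD_FACTOR

    @property
    def n_dots(self) -> int:
        return len(self.labels)

    @property
    def paired_indices(self) -> set[int]:
        return {i for ij in self.pairing for i in ij}

    def to_json(self) -> str:
        return json.dumps(
            {
                "positions": self.positions.tolist(),
                "labels": self.labels,
                "pairing": [list(ij) for ij in self.pairing],
                "arrangement": self.arrangement,
                "position_symmetry_frac": self.position_symmetry_frac,
                "aperture_deg": self.aperture_deg,
                "dot_sigma_deg": self.dot_sigma_deg,
                "size_sd_factor": self.size_sd_factor,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "DotPattern":
        d = json.loads(s)
        return cls(
            positions=np.array(d["positions"], dtype=float),
            labels=list(d["labels"]),
            pairing=[tuple(ij) for ij in d["pairing"]],
            arrangement=d["arrangement"],
            position_symmetry_frac=d["position_symmetry_frac"],
            aperture_deg=d["aperture_deg"],
            dot_sigma_deg=d["dot_sigma_deg"],
            size_sd_factor=d["size_sd_factor"],
        )


# ---------------------------------------------------------------------------
# position sampling
# ---------------------------------------------------------------------------


def _sample_positions(n_pairs: int, n_noise: int, rng: np.random.Generator,
                      aperture_deg: float = APERTURE_DEG) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Rejection-sample dot centres: mirror pairs first, then noise dots.

    Mirror mates are exact float reflections (x, y) -> (-x, y).  All dots
    respect the aperture margin, the axis exclusion strip and the minimum
    spacing (including the spacing between a dot and its own mate).
    """
    r_max = aperture_deg / 2.0 - EDGE_MARGIN_DEG
    placed: list[np.ndarray] = []

    def ok(p) -> bool:
        return all(np.hypot(p[0] - q[0], p[1] - q[1]) >= MIN_SPACING_DEG for q in placed)

    def draw() -> np.ndarray:
        while True:
            p = rng.uniform(-r_max, r_max, size=2)
            if p[0] ** 2 + p[1] ** 2 < r_max ** 2 and abs(p[0]) >= AXIS_MARGIN_DEG:
                return p

    pairing: list[tuple[int, int]] = []
    for k in range(n_pairs):
        for _ in range(10000):
            p = draw()
            q = np.array([-p[0], p[1]])
            if ok(p) and ok(q) and np.hypot(p[0] - q[0], 0.0) >= MIN_SPACING_DEG:
                break
        else:  # pragma: no cover - only with pathological parameters
            raise RuntimeError("could not place dot pair under spacing constraints")
        left, right = (p, q) if p[0] < 0 else (q, p)
        placed.extend([left, right])
        pairing.append((2 * k, 2 * k + 1))
    for _ in range(n_noise):
        for _ in range(10000):
            p = draw()
            if ok(p):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place noise dot under spacing constraints")
        placed.append(p)
    return np.array(placed).reshape(-1, 2), pairing


def _split_half(n: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with floor/ceil(n/2) True entries, order randomised."""
    mask = np.zeros(n, dtype=bool)
    k = n // 2 + (rng.integers(2) if n % 2 else 0)
    mask[rng.permutation(n)[:k]] = True
    return mask


# ---------------------------------------------------------------------------
# generate_pattern
# ---------------------------------------------------------------------------


def generate_pattern(arrangement: str, n_dots: int = N_DOTS_ACHROMATIC,
                     position_symmetry_frac: float = 1.0,
                     colours: tuple[str, ...] = POLARITIES,
                     seed: int | np.random.Generator = 0,
                     balance: str = "strict") -> DotPattern:
    """Generate one stimulus with the requested polarity/colour arrangement.

    ``balance="strict"`` raises :class:`InvalidBalanceError` when an exact
    white/black pair split is impossible (odd pair count, unsegregated);
    ``"nearest"`` splits to within one pair instead.
    """
    if arrangement not in ARRANGEMENTS:
        raise InvalidArrangementError(f"unknown arrangement {arrangement!r}")
    if n_dots % 2:
        raise ValueError("n_dots must be even")
    if position_symmetry_frac not in (0.0, 0.5, 1.0):
        raise ValueError("position_symmetry_frac must be 0, 0.5 or 1.0")
    if arrangement == "segregated" and position_symmetry_frac != 0.5:
        raise InvalidArrangementError("segregated patterns require 50% position symmetry")
    if arrangement in NOISE_ARRANGEMENTS and position_symmetry_frac != 0.0:
        raise InvalidArrangementError(f"{arrangement} requires position_symmetry_frac=0")
    if arrangement == "multicolour" and not 2 <= len(colours) <= 4:
        raise ValueError("multicolour patterns use 2-4 colours")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pairs = int(round(position_symmetry_frac * n_dots / 2))
    n_noise = n_dots - 2 * n_pairs
    positions, pairing = _sample_positions(n_pairs, n_noise, rng)
    labels: list[str | None] = [None] * n_dots
    noise_idx = list(range(2 * n_pairs, n_dots))

    if arrangement == "anti_symmetric":
        for (i, j), white_left in zip(pairing, _split_half(n_pairs, rng)):
            labels[i], labels[j] = ("white", "black") if white_left else ("black", "white")
        for i, white in zip(noise_idx, _split_half(n_noise, rng)):
            labels[i] = "white" if white else "black"
    elif arrangement in ("polarity_grouped_anti", "polarity_grouped_noise"):
        left_colour, right_colour = ("white", "black") if rng.integers(2) else ("black", "white")
        for i, (x, _) in enumerate(positions):
            labels[i] = left_colour if x < 0 else right_colour
    elif arrangement == "unsegregated":
        if n_pairs % 2:
            if balance == "strict":
                raise InvalidBalanceError(
                    f"odd pair count ({n_pairs}): equal white/black pair split impossible"
                )
        for (i, j), white in zip(pairing, _split_half(n_pairs, rng)):
            labels[i] = labels[j] = "white" if white else "black"
        for i, white in zip(noise_idx, _split_half(n_noise, rng)):
            labels[i] = "white" if white else "black"
    elif arrangement == "segregated":
        signal = "white" if rng.integers(2) else "black"  # re-drawn per pattern
        other = "black" if signal == "white" else "white"
        for i, j in pairing:
            labels[i] = labels[j] = signal
        for i in noise_idx:
            labels[i] = other
    elif arrangement in ("single_polarity", "single_polarity_noise"):
        colour = colours[0]
        labels = [colour] * n_dots
    elif arrangement == "noise":
        for i, white in zip(range(n_dots), _split_half(n_dots, rng)):
            labels[i] = "white" if white else "black"
    elif arrangement == "multicolour":
        quota = {c: n_dots // len(colours) for c in colours}
        for c in list(colours)[: n_dots % len(colours)]:
            quota[c] += 1
        order = list(rng.permutation(list(colours)))
        for i, j in pairing:  # pairs consume 2 of a colour: take the fullest quota
            c = max(order, key=lambda c: quota[c])
            labels[i] = labels[j] = c
            quota[c] -= 2
        for i in noise_idx:
            c = max(order, key=lambda c: quota[c])
            labels[i] = c
            quota[c] -= 1

    return DotPattern(
        positions=positions,
        labels=labels,
        pairing=pairing,
        arrangement=arrangement,
        position_symmetry_frac=position_symmetry_frac,
    )


# ---------------------------------------------------------------------------
# verify_pattern
# ---------------------------------------------------------------------------


def verify_pattern(p: DotPattern) -> dict:
    """Diagnostic report on a pattern's geometric and label invariants.

    Pure function; reports booleans and counts, never raises.
    """
    pos = p.positions
    pair_dx = [abs(pos[i, 0] + pos[j, 0]) for i, j in p.pairing]
    pair_dy = [abs(pos[i, 1] - pos[j, 1]) for i, j in p.pairing]
    mirror_exact = bool(max(pair_dx + pair_dy, default=0.0) == 0.0)
    radii = np.hypot(pos[:, 0], pos[:, 1]) if len(pos) else np.array([])
    inside = bool(np.all(radii < p.aperture_deg / 2.0)) if len(pos) else True
    if len(pos) > 1:
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        min_spacing = float(d[np.triu_indices(len(pos), k=1)].min())
    else:
        min_spacing = np.inf

    counts = {c: p.labels.count(c) for c in sorted(set(p.labels))}
    opposite_pairs = sum(1 for i, j in p.pairing if p.labels[i] != p.labels[j])
    same_pairs = len(p.pairing) - opposite_pairs
    white_pairs = sum(1 for i, j in p.pairing if p.labels[i] == p.labels[j] == "white")
    black_pairs = sum(1 for i, j in p.pairing if p.labels[i] == p.labels[j] == "black")

    if p.arrangement == "anti_symmetric":
        labels_ok = same_pairs == 0
    elif p.arrangement in ("polarity_grouped_anti", "polarity_grouped_noise"):
        left = {p.labels[i] for i in range(p.n_dots) if pos[i, 0] < 0}
        right = {p.labels[i] for i in range(p.n_dots) if pos[i, 0] > 0}
        labels_ok = len(left) <= 1 and len(right) <= 1 and not (left & right)
    elif p.arrangement == "unsegregated":
        labels_ok = opposite_pairs == 0 and abs(white_pairs - black_pairs) <= 1
    elif p.arrangement == "segregated":
        sig = {p.labels[i] for ij in p.pairing for i in ij}
        noi = {p.labels[i] for i in range(p.n_dots) if i not in p.paired_indices}
        labels_ok = len(sig) == 1 and len(noi) == 1 and not (sig & noi)
    elif p.arrangement in ("single_polarity", "single_polarity_noise"):
        labels_ok = len(set(p.labels)) == 1
    elif p.arrangement == "noise":
        labels_ok = abs(counts.get("white", 0) - counts.get("black", 0)) <= 1
    elif p.arrangement == "multicolour":
        vals = list(counts.values())
        labels_ok = opposite_pairs == 0 and (max(vals) - min(vals) <= 2 if vals else True)
    else:  # pragma: no cover
        labels_ok = False

    n_paired = 2 * len(p.pairing)
    return {
        "mirror_exact": mirror_exact,
        "inside_aperture": inside,
        "min_spacing_deg": min_spacing,
        "spacing_ok": bool(min_spacing >= MIN_SPACING_DEG - 1e-12),
        "labels_ok": bool(labels_ok),
        "symmetry_frac_ok": bool(np.isclose(n_paired / p.n_dots, p.position_symmetry_frac)),
        "n_pairs": len(p.pairing),
        "opposite_polarity_pairs": opposite_pairs,
        "same_polarity_pairs": same_pairs,
        "white_pairs": white_pairs,
        "black_pairs": black_pairs,
        "label_counts": counts,
    }


# ---------------------------------------------------------------------------
# render_pattern
# ---------------------------------------------------------------------------


def render_pattern(p: DotPattern, pixels_per_deg: float = 20.0,
                   background_level: float = 0.5) -> np.ndarray:
    """Render to an image array (greyscale (H, W) for achromatic patterns,
    RGB (H, W, 3) otherwise), values clipped to [0, 1].

    Each dot is a 2-D Gaussian profile (sigma = ``dot_sigma_deg``, truncated
    at ``size_sd_factor`` sigma) pulling the image from the background level
    toward the dot colour; overlapping dots sum.
    """
    if pixels_per_deg <= 0:
        raise ValueError("pixels_per_deg must be positive")
    w = int(round(p.aperture_deg * pixels_per_deg))
    # pixel-centre coordinates, symmetric about x = 0 so mirrored dots render
    # onto exactly mirrored pixels
    xs = (np.arange(w) + 0.5 - w / 2.0) / pixels_per_deg
    ys = (np.arange(w) + 0.5 - w / 2.0) / pixels_per_deg
    chromatic = any(lab not in POLARITIES for lab in p.labels)
    img = np.full((w, w, 3) if chromatic else (w, w), float(background_level))

    trunc = p.size_sd_factor * p.dot_sigma_deg
    for (xd, yd), lab in zip(p.positions, p.labels):
        dx2 = (xs - xd) ** 2
        dy2 = (ys - yd) ** 2
        r2 = dy2[:, None] + dx2[None, :]
        g = np.where(r2 <= trunc * trunc, np.exp(-r2 / (2.0 * p.dot_sigma_deg ** 2)), 0.0)
        if chromatic:
            target = np.array(_COLOUR_RGB[lab])
            img += g[:, :, None] * (target - background_level)
        else:
            img += g * ((1.0 if lab == "white" else 0.0) - background_level)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# trial designs (two-interval forced choice)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionSpec:
    """One symmetric condition and its matched noise arrangement."""

    name: str
    arrangement: str
    position_symmetry_frac: float
    noise_arrangement: str
    n_dots: int = N_DOTS_ACHROMATIC
    colours: tuple[str, ...] = POLARITIES


@dataclass
class TrialDesign:
    experiment: int
    conditions: list[ConditionSpec]
    trials: pd.DataFrame  # columns: trial, condition, symmetric_interval
    presentations_per_condition: int = 100
    stimulus_ms: int = 500
    isi_ms: int = 500
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]

    def spec(self, name: str) -> ConditionSpec:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(f"unknown condition {name!r}")

    def to_csv(self, path) -> None:
        df = self.trials.copy()
        df["seed"] = self.seed
        df.to_csv(path, index=False)


_EXPERIMENT_CONDITIONS: dict[int, list[ConditionSpec]] = {
    1: [
        ConditionSpec("anti_symmetric", "anti_symmetric", 1.0, "noise"),
        ConditionSpec("polarity_grouped_anti", "polarity_grouped_anti", 1.0,
                      "polarity_grouped_noise"),
        ConditionSpec("unsegregated", "unsegregated", 1.0, "noise"),
    ],
    2: [
        ConditionSpec("anti_symmetric", "anti_symmetric", 0.5, "noise"),
        ConditionSpec("polarity_grouped_anti", "polarity_grouped_anti", 0.5,
                      "polarity_grouped_noise"),
        ConditionSpec("unsegregated", "unsegregated", 0.5, "noise"),
        ConditionSpec("segregated", "segregated", 0.5, "noise"),
        ConditionSpec("single_polarity_50", "single_polarity", 0.5,
                      "single_polarity_noise", colours=("white",)),
        ConditionSpec("single_polarity_100", "single_polarity", 1.0,
                      "single_polarity_noise", colours=("white",)),
    ],
    3: [
        ConditionSpec("two_colours", "multicolour", 1.0, "multicolour",
                      n_dots=N_DOTS_CHROMATIC, colours=("red", "green")),
        ConditionSpec("three_colours", "multicolour", 1.0, "multicolour",
                      n_dots=N_DOTS_CHROMATIC, colours=("red", "green", "blue")),
        ConditionSpec("four_colours", "multicolour", 1.0, "multicolour",
                      n_dots=N_DOTS_CHROMATIC, colours=("red", "green", "blue", "yellow")),
    ],
}


def build_design(experiment: int, seed: int = 0,
                 presentations_per_condition: int = 100) -> TrialDesign:
    """Build the seeded 2IFC trial sequence for one experiment.

    100 presentations per condition give 300 trials (3 conditions) in
    experiments 1 and 3 and 600 trials (6 conditions) in experiment 2.
    """
    if experiment not in _EXPERIMENT_CONDITIONS:
        raise ValueError(f"unknown experiment {experiment!r}")
    conditions = _EXPERIMENT_CONDITIONS[experiment]
    rng = np.random.default_rng(seed)
    names = np.repeat([c.name for c in conditions], presentations_per_condition)
    order = rng.permutation(len(names))
    intervals = rng.integers(1, 3, size=len(names))
    trials = pd.DataFrame(
        {
            "trial": np.arange(len(names)),
            "condition": names[order],
            "symmetric_interval": intervals,
        }
    )
    return TrialDesign(experiment=experiment, conditions=list(conditions), trials=trials,
                       presentations_per_condition=presentations_per_condition, seed=seed)


def simulate_observer(design: TrialDesign, pc_by_condition: dict[str, float],
                      seed: int = 0) -> pd.DataFrame:
    """Bernoulli stand-in for a human 2IFC observer.

    ``pc_by_condition`` maps condition name to the probability of a correct
    response (0.5 = chance, 1.0 = perfect).  Returns observed counts and
    proportion correct per condition.
    """
    for cond, pc in pc_by_condition.items():
        if not 0.0 <= pc <= 1.0:
            raise ValueError(f"probability for {cond!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    correct = np.array(
        [rng.random() < pc_by_condition[c] for c in design.trials["condition"]]
    )
    df = design.trials.assign(correct=correct)
    out = df.groupby("condition", sort=True)["correct"].agg(["sum", "count"])
    out["proportion_correct"] = out["sum"] / out["count"]
    return out.rename(columns={"sum": "n_correct", "count": "n_trials"}).reset_index()
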