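"""Microstate segmentation of grand-average ERPs.

Topographical Atomize & Agglomerate Hierarchical Clustering (TAAHC): every
timepoint map in the analysis window starts as its own cluster; clusters are
repeatedly dissolved — the one whose removal costs the least global
explained variance (GEV) once its members are re-absorbed — and the freed
maps reassigned to the remaining cluster with the highest signed spatial
correlation (ERP polarity convention).  The number of
template maps is selected jointly by the cross-validation criterion
(predictive residual variance penalised by the map count) and the
Krzanowski-Lai dispersion-elbow criterion.  Selected templates are then
back-fitted to individual-participant ERPs to quantify per-map explained
variance and map timing per condition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Erp, SPN_WINDOW_MS

DEFAULT_Q_RANGE = (2, 8)


def _avg_ref(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=-1, keepdims=True)


def _normalise_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-reference and scale rows to unit GFP; returns (maps, gfp)."""
    x = _avg_ref(np.asarray(x, float))
    g = np.sqrt(np.mean(x ** 2, axis=-1))
    safe = np.maximum(g, 1e-300)
    return x / safe[..., None], g


@dataclass
class Segmentation:
    """One level of the TAAHC hierarchy (a fixed number of maps q)."""

    q: int
    templates: np.ndarray          # (q, n_ch), average-referenced, unit GFP
    labels: dict[str, np.ndarray]  # per condition, per window timepoint
    times_ms: np.ndarray
    gev_total: float
    gev_per_map: np.ndarray
    sigma2: float                  # predictive residual variance
    dispersion: float              # within-cluster dispersion W(q)

    def to_json(self) -> str:
        return json.dumps(
            {
                "q": self.q,
                "templates": self.templates.tolist(),
                "labels": {c: lab.tolist() for c, lab in self.labels.items()},
                "times_ms": self.times_ms.tolist(),
                "gev_total": self.gev_total,
                "gev_per_map": self.gev_per_map.tolist(),
                "sigma2": self.sigma2,
                "dispersion": self.dispersion,
            }
        )


@dataclass
class SegmentationHierarchy:
    by_q: dict[int, Segmentation]
    window_ms: tuple[float, float]
    conditions: list[str]

    @property
    def q_values(self) -> list[int]:
        return sorted(self.by_q)

    def dispersion_curve(self) -> dict[int, float]:
        return {q: self.by_q[q].dispersion for q in self.q_values}


def _signed_corr(maps_unit: np.ndarray, templates_unit: np.ndarray) -> np.ndarray:
    """Spatial correlation between unit-GFP maps (T, N) and templates (q, N).

    With average-referenced unit-GFP rows the correlation reduces to the
    mean elementwise product.  Signed (ERP convention): polarity matters.
    """
    return maps_unit @ templates_unit.T / maps_unit.shape[-1]


def taahc_segment(grand_erps: list[Erp], window_ms: tuple[float, float] = SPN_WINDOW_MS,
                  q_range: tuple[int, int] = DEFAULT_Q_RANGE,
                  seed: int = 0) -> SegmentationHierarchy:
    """Run TAAHC jointly on all conditions' grand averages in the window.

    The maps of every condition inside the closed window are concatenated
    into one clustering problem, so all conditions share one template set.
    ``seed`` only breaks exact ties in the atomisation order.
    """
    if not grand_erps:
        raise ValueError("need at least one condition ERP")
    q_min, q_max = q_range
    conditions = [e.condition for e in grand_erps]
    idx = grand_erps[0].window_indices(window_ms)
    times_ms = grand_erps[0].times_ms[idx]
    if q_max > len(idx):
        raise ValueError("analysis window shorter than q_max samples")

    X = np.concatenate([_avg_ref(e.data[:, idx].T) for e in grand_erps])  # (T, N)
    T, N = X.shape
    Xn, gfp_t = _normalise_rows(X)
    gfp2_total = float(np.sum(gfp_t ** 2))
    rng = np.random.default_rng(seed)
    tie_break = rng.random(T) * 1e-12

    members: dict[int, list[int]] = {t: [t] for t in range(T)}
    templates: dict[int, np.ndarray] = {t: Xn[t].copy() for t in range(T)}
    assign = np.arange(T)

    def template_of(member_idx: list[int]) -> np.ndarray:
        m = Xn[member_idx].mean(axis=0)
        m = m - m.mean()
        g = np.sqrt(np.mean(m ** 2))
        return m / g if g > 0 else m

    def snapshot() -> Segmentation:
        keys = sorted(members)
        A = np.array([templates[k] for k in keys])
        remap = {k: i for i, k in enumerate(keys)}
        lab = np.array([remap[assign[t]] for t in range(T)])
        corr = _signed_corr(Xn, A)[np.arange(T), lab]
        contrib = (gfp_t * corr) ** 2
        gev_per_map = np.array(
            [contrib[lab == i].sum() for i in range(len(keys))]
        ) / gfp2_total
        # predictive residual variance with Euclidean-unit templates
        Au = A / np.linalg.norm(A, axis=1, keepdims=True)
        proj = np.einsum("tn,tn->t", X, Au[lab])
        sigma2 = float(np.sum(np.sum(X ** 2, axis=1) - proj ** 2) / (T * (N - 1)))
        W = 0.0
        for i, k in enumerate(keys):
            sub = Xn[members[k]]
            W += float(np.sum((sub - sub.mean(axis=0)) ** 2))
        labels = {}
        off = 0
        for cond in conditions:
            labels[cond] = lab[off:off + len(idx)].copy()
            off += len(idx)
        return Segmentation(q=len(keys), templates=A, labels=labels, times_ms=times_ms,
                            gev_total=float(gev_per_map.sum()), gev_per_map=gev_per_map,
                            sigma2=sigma2, dispersion=W)

    by_q: dict[int, Segmentation] = {}
    while True:
        q = len(members)
        if q_min <= q <= q_max:
            by_q[q] = snapshot()
        if q == 1 or q <= q_min:
            break
        # dissolve the cluster whose removal costs the least GEV once its
        # members are re-absorbed by the best remaining cluster: a cluster
        # duplicating another template is dissolved before a small but
        # genuinely distinct one
        keys = sorted(members)
        A = np.array([templates[k] for k in keys])
        remap = {k: i for i, k in enumerate(keys)}
        lab = np.array([remap[assign[t]] for t in range(T)])
        C2 = _signed_corr(Xn, A) ** 2
        own = C2[np.arange(T), lab]
        C2[np.arange(T), lab] = -np.inf
        alt = C2.max(axis=1)
        loss = (gfp_t ** 2) * (own - alt) + tie_break
        per_cluster = np.array([loss[lab == i].sum() for i in range(len(keys))])
        worst = keys[int(np.argmin(per_cluster))]
        freed = members.pop(worst)
        templates.pop(worst)
        rem_keys = sorted(members)
        A_rem = np.array([templates[k] for k in rem_keys])
        best = np.argmax(_signed_corr(Xn[freed], A_rem), axis=1)
        touched = set()
        for t, b in zip(freed, best):
            k = rem_keys[int(b)]
            members[k].append(t)
            assign[t] = k
            touched.add(k)
        for k in touched:
            templates[k] = template_of(members[k])
    return SegmentationHierarchy(by_q=by_q, window_ms=tuple(window_ms),
                                 conditions=conditions)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def cv_criterion(seg: Segmentation, n_electrodes: int) -> float:
    """Cross-validation criterion: sigma^2 * ((N-1)/(N-1-q))^2; lower is better."""
    q, N = seg.q, n_electrodes
    if q >= N - 1:
        raise ValueError("CV criterion undefined for q >= n_electrodes - 1")
    return float(seg.sigma2 * ((N - 1) / (N - 1 - q)) ** 2)


def kl_criterion(w_by_q: dict[int, float], m: int) -> dict[int, float]:
    """Krzanowski-Lai elbow score from the dispersion curve W(q).

    ``DIFF(q) = (q-1)^(2/m) W(q-1) - q^(2/m) W(q)``; ``KL(q) =
    |DIFF(q)| / |DIFF(q+1)|``.  ``m`` is the dimensionality of the
    clustering space (number of electrodes).  Defined for interior q only.
    """
    qs = sorted(w_by_q)
    if any(w_by_q[a] < w_by_q[b] - 1e-12 for a, b in zip(qs, qs[1:])):
        warnings.warn("dispersion curve is not monotone decreasing in q",
                      RuntimeWarning, stacklevel=2)

    def diff(q: int) -> float:
        return (q - 1) ** (2.0 / m) * w_by_q[q - 1] - q ** (2.0 / m) * w_by_q[q]

    out = {}
    for q in qs:
        if q - 1 in w_by_q and q + 1 in w_by_q:
            denom = abs(diff(q + 1))
            out[q] = abs(diff(q)) / denom if denom > 0 else np.inf
    return out


def select_q(cv_by_q: dict[int, float], kl_by_q: dict[int, float]
             ) -> tuple[int, bool]:
    """Joint choice of the number of maps.

    Returns ``(q, conflict)``: the q minimising CV when it coincides with the
    q maximising KL; on disagreement KL's argmax wins and the conflict is
    flagged.
    """
    if not cv_by_q or not kl_by_q:
        raise ValueError("empty criterion curves")
    q_cv = min(cv_by_q, key=cv_by_q.get)
    q_kl = max(kl_by_q, key=kl_by_q.get)
    return (q_kl, q_cv != q_kl)


def select_maps(hierarchy: SegmentationHierarchy, n_electrodes: int
                ) -> tuple[int, bool, dict[int, float], dict[int, float]]:
    """CV and KL curves over the hierarchy plus the joint selection."""
    cv = {q: cv_criterion(hierarchy.by_q[q], n_electrodes) for q in hierarchy.q_values}
    kl = kl_criterion(hierarchy.dispersion_curve(), m=n_electrodes)
    q, conflict = select_q(cv, kl)
    return q, conflict, cv, kl


# ---------------------------------------------------------------------------
# back-fitting
# ---------------------------------------------------------------------------


@dataclass
class BackfitTable:
    """Explained-variance shares and labels per participant and condition."""

    shares: pd.DataFrame  # participant, condition, map, ev_share
    labels: dict[tuple[str, str], np.ndarray]
    times_ms: np.ndarray
    n_skipped_zero_gfp: int = 0

    def to_csv(self, path) -> None:
        self.shares.to_csv(path, index=False)

    def share_array(self, participants: list[str], conditions: list[str],
                    n_maps: int) -> np.ndarray:
        """(participant, condition, map) tensor of explained-variance shares."""
        out = np.zeros((len(participants), len(conditions), n_maps))
        piv = self.shares.set_index(["participant", "condition", "map"])["ev_share"]
        for i, p in enumerate(participants):
            for j, c in enumerate(conditions):
                for m in range(n_maps):
                    out[i, j, m] = piv.get((p, c, m), 0.0)
        return out


def backfit(templates: np.ndarray, individual_erps: dict[str, dict[str, Erp]],
            window_ms: tuple[float, float] = SPN_WINDOW_MS) -> BackfitTable:
    """Fit template maps to individual ERPs in the analysis window.

    Every timepoint is labelled with the template of highest signed spatial
    correlation; map ``m`` then explains the share
    ``sum_{t: label=m} (GFP(t) corr(t))^2 / sum_t GFP(t)^2`` of the
    participant-condition variance.  Zero-GFP timepoints are skipped.
    """
    A, _ = _normalise_rows(templates)
    rows = []
    labels_out: dict[tuple[str, str], np.ndarray] = {}
    skipped = 0
    times_ms = None
    for pid, conds in individual_erps.items():
        for cond, erp in conds.items():
            idx = erp.window_indices(window_ms)
            if times_ms is None:
                times_ms = erp.times_ms[idx]
            X = _avg_ref(erp.data[:, idx].T)
            Xn, g = _normalise_rows(X)
            ok = g > 0
            skipped += int(np.sum(~ok))
            corr = _signed_corr(Xn, A)
            lab = np.argmax(corr, axis=1)
            lab[~ok] = -1
            c_best = corr[np.arange(len(lab)), np.maximum(lab, 0)]
            denom = float(np.sum(g[ok] ** 2))
            for m in range(len(A)):
                sel = ok & (lab == m)
                share = float(np.sum((g[sel] * c_best[sel]) ** 2) / denom) if denom else 0.0
                rows.append({"participant": pid, "condition": cond, "map": m,
                             "ev_share": share})
            labels_out[(pid, cond)] = lab
    return BackfitTable(shares=pd.DataFrame(rows), labels=labels_out,
                        times_ms=times_ms, n_skipped_zero_gfp=skipped)


def map_timing(labels: np.ndarray, times_ms: np.ndarray, n_maps: int) -> pd.DataFrame:
    """Onset/offset of each map's maximal runs and total duration per map.

    A run's duration is its offset minus onset time; a map absent from the
    labelling gets duration 0 and ``absent=True``.
    """
    rows = []
    for m in range(n_maps):
        sel = labels == m
        runs = []
        i = 0
        while i < len(sel):
            if sel[i]:
                j = i
                while j + 1 < len(sel) and sel[j + 1]:
                    j += 1
                runs.append((float(times_ms[i]), float(times_ms[j])))
                i = j + 1
            else:
                i += 1
        total = sum(b - a for a, b in runs)
        rows.append({
            "map": m,
            "onset_ms": runs[0][0] if runs else np.nan,
            "offset_ms": runs[-1][1] if runs else np.nan,
            "duration_ms": total,
            "n_runs": len(runs),
            "absent": not runs,
        })
    return pd.DataFrame(rows)


def pair_templates(recovered: np.ndarray, planted: np.ndarray) -> tuple[list[int], np.ndarray]:
    """Optimal one-to-one pairing by |spatial correlation| (exhaustive for
    small q).  Returns (permutation, |r| per planted map): recovered map
    ``perm[i]`` matches planted map ``i``."""
    from itertools import permutations

    Ru, _ = _normalise_rows(recovered)
    Pu, _ = _normalise_rows(planted)
    C = np.abs(Pu @ Ru.T / Pu.shape[-1])
    k = len(Pu)
    best, best_score = None, -np.inf
    for perm in permutations(range(len(Ru)), k):
        score = sum(C[i, perm[i]] for i in range(k))
        if score > best_score:
            best, best_score = perm, score
    return list(best), np.array([C[i, best[i]] for i in range(k)])
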