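"""Seeded calibration and parameter-recovery experiments.

Each function runs one self-contained experiment against planted ground
truth — the package's evidence that the chain measures what it claims:
identity checks on the field statistics, type-I calibration and sensitivity
of the TANOVA, recovery of the planted microstate count/templates and of the
planted SPN amplitude, artifact-rejection exactness, and the stimulus/design
arithmetic.  Problem sizes default to scaled-down versions of the study
conditions so a full battery runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import microstates, preprocess, stimuli, synthetic_eeg, topography
from .core import Erp, Montage
from .stats_report import gg_epsilon, one_sample_t, paired_t, rm_anova_gg
from .synthetic_eeg import _noise_chol


# ---------------------------------------------------------------------------
# field statistics
# ---------------------------------------------------------------------------


def diss_identity_error(n_pairs: int = 1000, n_electrodes: int = 64,
                        seed: int = 0) -> float:
    """Max |DISS - sqrt(2(1-r))| over random map pairs (independent routes)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        u, v = rng.standard_normal((2, n_electrodes))
        uc, vc = u - u.mean(), v - v.mean()
        r = np.sum(uc * vc) / np.sqrt(np.sum(uc ** 2) * np.sum(vc ** 2))
        worst = max(worst, abs(topography.diss(u, v) - np.sqrt(2.0 * (1.0 - r))))
    return worst


# ---------------------------------------------------------------------------
# TANOVA
# ---------------------------------------------------------------------------


def tanova_type_one_rate(n_datasets: int = 200, n_participants: int = 12,
                         n_timepoints: int = 50, n_perm: int = 500,
                         seed: int = 0, montage: Montage | None = None) -> float:
    """Per-timepoint rejection rate at alpha=0.05 under a planted null.

    Both conditions are drawn from the same spatially correlated noise
    distribution; the pooled fraction of timepoints with p < 0.05 estimates
    the test's realised type-I error.
    """
    if montage is None:
        montage = Montage.standard_64()
    L = _noise_chol(montage, synthetic_eeg.DEFAULT_SPATIAL_CORR_LENGTH)
    rng = np.random.default_rng(seed)
    n_ch = len(montage)
    hits = total = 0
    for d in range(n_datasets):
        A = np.einsum("ij,sjt->sit", L,
                      rng.standard_normal((n_participants, n_ch, n_timepoints)))
        B = np.einsum("ij,sjt->sit", L,
                      rng.standard_normal((n_participants, n_ch, n_timepoints)))
        res = topography.tanova_paired(A, B, n_perm=n_perm, seed=seed + 1 + d)
        hits += int(np.sum(res.p_values < 0.05))
        total += n_timepoints
    return hits / total


def tanova_sensitivity(seed: int = 0, n_participants: int = 12,
                       n_trials: int = 50, n_perm: int = 500,
                       sfreq: float = 250.0,
                       montage: Montage | None = None) -> dict:
    """Detectability of a symmetry-only topography planted in 250-550 ms.

    Returns the significant windows and the fraction of the planted span the
    (single expected) window covers.
    """
    if montage is None:
        montage = Montage.standard_64()
    tem = synthetic_eeg.make_templates(montage, 2, seed=seed)
    tl = synthetic_eeg.PlantedTimeline(templates=tem, segments=[
        synthetic_eeg.TimelineSegment(0, 0.0, 250.0),
        synthetic_eeg.TimelineSegment(1, 250.0, 550.0, conditions=("symmetry",)),
        synthetic_eeg.TimelineSegment(0, 250.0, 550.0, conditions=("noise",)),
        synthetic_eeg.TimelineSegment(0, 550.0, 1000.0),
    ])
    sets = synthetic_eeg.simulate_epochs(
        ["symmetry", "noise"], tl, n_participants=n_participants, seed=seed,
        montage=montage, sfreq=sfreq, n_trials=n_trials)
    erps = [preprocess.participant_erps(es) for es in sets]
    A = np.stack([e["symmetry"].data for e in erps])
    B = np.stack([e["noise"].data for e in erps])
    res = topography.tanova_paired(A, B, n_perm=n_perm, seed=seed,
                                   times_ms=erps[0]["symmetry"].times_ms)
    overlap = 0.0
    if len(res.windows) == 1:
        onset, offset = res.windows[0]
        overlap = (min(offset, 550.0) - max(onset, 250.0)) / 300.0
    return {"windows": res.windows, "n_windows": len(res.windows),
            "overlap_fraction": max(overlap, 0.0)}


# ---------------------------------------------------------------------------
# microstates
# ---------------------------------------------------------------------------


def grand_average_erps(epochsets, conditions) -> list[Erp]:
    erps = [preprocess.participant_erps(es) for es in epochsets]
    out = []
    for cond in conditions:
        g = np.mean([e[cond].data for e in erps], axis=0)
        e0 = erps[0][cond]
        out.append(Erp(data=g, condition=cond, n_epochs=len(erps),
                       montage=e0.montage, sfreq=e0.sfreq, tmin_ms=e0.tmin_ms,
                       reference="common-average", participant="grand"))
    return out


def microstate_recovery(n_seeds: int = 20, seed: int = 0,
                        n_participants: int = 8, n_trials: int = 30,
                        sfreq: float = 250.0,
                        montage: Montage | None = None) -> dict:
    """Recovery of 4 planted maps: joint CV/KL selection and template match.

    Each seeded run simulates the study-style timeline (map D only in the
    symmetry condition), segments the grand averages, selects q and pairs
    the recovered q=4 templates with the planted ones.
    """
    if montage is None:
        montage = Montage.standard_64()
    selected, min_r = [], []
    for s in range(n_seeds):
        tl = synthetic_eeg.default_timeline(montage, ["symmetry"], ["noise"],
                                            seed=seed + s)
        sets = synthetic_eeg.simulate_epochs(
            ["symmetry", "noise"], tl, n_participants=n_participants,
            seed=seed + s, montage=montage, sfreq=sfreq, n_trials=n_trials)
        grand = grand_average_erps(sets, ["symmetry", "noise"])
        hier = microstates.taahc_segment(grand, q_range=(2, 8), seed=seed + s)
        q, _, _, _ = microstates.select_maps(hier, len(montage))
        selected.append(q)
        _, r = microstates.pair_templates(hier.by_q[4].templates, tl.templates)
        min_r.append(float(r.min()))
    return {"selected_q": selected,
            "q4_fraction": float(np.mean([q == 4 for q in selected])),
            "min_abs_corr": min_r,
            "worst_template_corr": float(min(min_r))}


# ---------------------------------------------------------------------------
# SPN
# ---------------------------------------------------------------------------


def spn_recovery_run(seed: int, n_participants: int = 24, n_trials: int = 50,
                     sfreq: float = 250.0, spn_uv: float = -1.5,
                     montage: Montage | None = None) -> np.ndarray:
    """One SPN-recovery run: shared template segments, planted SPN, full
    preprocessing chain; returns per-participant SPN amplitudes (μV)."""
    if montage is None:
        montage = Montage.standard_64()
    tl = synthetic_eeg.default_timeline(montage, ["symmetry"], ["noise"],
                                        symmetry_only_map=None, spn_uv=spn_uv,
                                        seed=seed)
    sets = synthetic_eeg.simulate_epochs(
        ["symmetry", "noise"], tl, n_participants=n_participants, seed=seed,
        montage=montage, sfreq=sfreq, n_trials=n_trials)
    vals = []
    for es in sets:
        erps = preprocess.participant_erps(es)
        vals.append(preprocess.participant_spn(erps, "symmetry", "noise").amplitude_uv)
    return np.array(vals)


def spn_recovery(n_runs: int = 100, seed: int = 0, n_participants: int = 24,
                 n_trials: int = 50, sfreq: float = 250.0,
                 spn_uv: float = -1.5, montage: Montage | None = None) -> dict:
    """Planted-SPN recovery battery: run means and t-test power at n=24."""
    if montage is None:
        montage = Montage.standard_64()
    means, significant = [], 0
    for r in range(n_runs):
        vals = spn_recovery_run(seed + r, n_participants, n_trials, sfreq,
                                spn_uv, montage)
        means.append(float(vals.mean()))
        significant += one_sample_t(vals, 0.0).p < 0.05
    return {"run_means_uv": means,
            "grand_mean_uv": float(np.mean(means)),
            "significant_fraction": significant / n_runs}


# ---------------------------------------------------------------------------
# artifact rejection
# ---------------------------------------------------------------------------


def rejection_exactness(seed: int = 0, n_trials: int = 100,
                        peak_uv: float = 150.0,
                        montage: Montage | None = None) -> dict:
    """Planted high-amplitude transients on a bounded background: the
    epochs removed by the ±100 μV rule must equal the planted mask exactly."""
    if montage is None:
        montage = Montage.standard_64()
    tl = synthetic_eeg.default_timeline(montage, ["symmetry"], ["noise"],
                                        symmetry_only_map=None, seed=seed)
    es = synthetic_eeg.simulate_epochs(
        ["symmetry", "noise"], tl, n_participants=1, seed=seed,
        montage=montage, sfreq=250.0, n_trials=n_trials)[0]
    background_max = max(float(np.max(np.abs(a))) for a in es.data.values())
    marked = synthetic_eeg.inject_artifacts(es, fraction=0.06, peak_uv=peak_uv,
                                            seed=seed)
    _, log = preprocess.reject_epochs(marked)
    exact = all(
        np.array_equal(log.indices[c], np.nonzero(marked.artifact_mask[c])[0])
        for c in marked.conditions)
    return {"exact": bool(exact), "background_max_uv": background_max,
            "n_flagged": int(sum(m.sum() for m in marked.artifact_mask.values()))}


# ---------------------------------------------------------------------------
# stimuli and design arithmetic
# ---------------------------------------------------------------------------


def stimulus_invariants(n_specs: int = 100, seed: int = 0) -> dict:
    """Mirror exactness (zero float error), label balance and determinism
    over randomly drawn pattern specifications."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_specs):
        arrangement = rng.choice(["anti_symmetric", "polarity_grouped_anti",
                                  "unsegregated", "segregated", "single_polarity",
                                  "noise", "multicolour"])
        if arrangement == "segregated":
            frac = 0.5
        elif arrangement == "noise":
            frac = 0.0
        elif arrangement == "unsegregated":
            frac = 1.0
        else:
            frac = float(rng.choice([0.5, 1.0]))
        if arrangement == "multicolour":
            colours = ("red", "green", "blue", "yellow")[: rng.integers(2, 5)]
            n_dots = 96
        else:
            colours = ("white", "black")
            n_dots = 60
        specs.append((arrangement, n_dots, frac, colours, int(rng.integers(1 << 30))))

    mirror_err = 0.0
    balance_ok = determinism_ok = True
    for arrangement, n_dots, frac, colours, s in specs:
        a = stimuli.generate_pattern(arrangement, n_dots, frac, colours, seed=s)
        b = stimuli.generate_pattern(arrangement, n_dots, frac, colours, seed=s)
        determinism_ok &= np.array_equal(a.positions, b.positions) and a.labels == b.labels
        for i, j in a.pairing:
            mirror_err = max(mirror_err,
                             abs(a.positions[i, 0] + a.positions[j, 0]),
                             abs(a.positions[i, 1] - a.positions[j, 1]))
        rep = stimuli.verify_pattern(a)
        balance_ok &= rep["labels_ok"] and rep["symmetry_frac_ok"]
    return {"n_specs": n_specs, "max_mirror_error": mirror_err,
            "balance_ok": bool(balance_ok), "determinism_ok": bool(determinism_ok)}


def design_arithmetic() -> dict:
    """Trial totals and dot counts of the three experiments."""
    totals = {exp: stimuli.build_design(exp, seed=0).n_trials for exp in (1, 2, 3)}
    d3 = stimuli.build_design(3, seed=0)
    counts = stimuli.build_design(3, seed=0).trials["condition"].value_counts()
    return {
        "trials_exp1": totals[1],
        "trials_exp2": totals[2],
        "trials_exp3": totals[3],
        "presentations_per_condition": int(counts.iloc[0]),
        "n_dots_achromatic": stimuli.N_DOTS_ACHROMATIC,
        "n_dots_chromatic": d3.conditions[0].n_dots,
        "aperture_deg": stimuli.APERTURE_DEG,
        "dot_sigma_deg": stimuli.DOT_SIGMA_DEG,
    }


# ---------------------------------------------------------------------------
# statistical identities
# ---------------------------------------------------------------------------


def stats_identities(n_draws: int = 1000, seed: int = 0) -> dict:
    """F = t^2 on two-level designs and GG epsilon inside its closed-form
    bounds over random covariance draws."""
    rng = np.random.default_rng(seed)
    max_rel_f_err = 0.0
    for _ in range(50):
        Y = rng.standard_normal((12, 2)) + rng.normal(0, 0.5, size=2)
        F = rm_anova_gg(Y)[0].F
        t = paired_t(Y[:, 0], Y[:, 1]).t
        max_rel_f_err = max(max_rel_f_err, abs(F - t * t) / max(F, 1e-300))
    eps_ok = True
    for _ in range(n_draws):
        k = int(rng.integers(3, 7))
        A = rng.standard_normal((k, k))
        cov = A @ A.T  # random Wishart-style level covariance
        from scipy.linalg import helmert

        C = helmert(k, full=False)
        eps = gg_epsilon(C @ cov @ C.T)
        eps_ok &= (1.0 / (k - 1) - 1e-12) <= eps <= 1.0 + 1e-12
    return {"max_rel_f_error": max_rel_f_err, "epsilon_in_bounds": bool(eps_ok)}
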