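"""Group-level statistics on SPN measures and back-fit variances, plus the
pipeline driver binding simulation, preprocessing, topographic testing and
microstate segmentation into one reproducible run.

Repeated-measures ANOVAs use the univariate approach with orthonormal
contrasts: for each within-subject effect the data are projected onto the
effect's contrast space, F is the ratio of the effect to the
effect-by-subject mean square, and the Greenhouse-Geisser epsilon
``tr(S)^2 / (df tr(S^2))`` (from the sample covariance of the contrast
scores) rescales both degrees of freedom before the p-value is read off.
Original (uncorrected) degrees of freedom are reported alongside.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sst

from . import microstates, preprocess, stimuli, synthetic_eeg, topography
from .core import Montage, SPN_WINDOW_MS

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test with Cohen's d = (mean - mu0) / SD."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least two observations")
    sd = v.std(ddof=1)
    if sd == 0:
        if np.isclose(v.mean(), mu0):
            # all observations sit exactly on mu0: no evidence either way
            return TTestResult(t=0.0, df=v.size - 1, p=1.0, cohens_d=0.0)
        raise ValueError("zero variance: t-test undefined")
    res = sst.ttest_1samp(v, mu0)
    return TTestResult(t=float(res.statistic), df=v.size - 1, p=float(res.pvalue),
                       cohens_d=float((v.mean() - mu0) / sd))


def paired_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Paired t-test; Cohen's d uses the SD of the paired differences."""
    return one_sample_t(np.asarray(a, float) - np.asarray(b, float), 0.0)


def bonferroni_pairs(table: pd.DataFrame, comparisons: list[tuple[str, str]]
                     ) -> pd.DataFrame:
    """Paired t-tests with Bonferroni-adjusted p (multiplied by the number of
    comparisons, capped at 1).  ``table`` is wide: one column per level, one
    row per participant."""
    k = len(comparisons)
    rows = []
    for a, b in comparisons:
        for lev in (a, b):
            if lev not in table.columns:
                raise KeyError(f"unknown level {lev!r}")
        r = paired_t(table[a].to_numpy(), table[b].to_numpy())
        rows.append({"comparison": f"{a} vs {b}", "t": r.t, "df": r.df,
                     "p_raw": r.p, "p_bonferroni": min(1.0, r.p * k),
                     "cohens_d": r.cohens_d})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int          # uncorrected degrees of freedom (reported as such)
    df2: int
    epsilon: float    # Greenhouse-Geisser
    p_gg: float
    p_uncorrected: float
    partial_eta_sq: float


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a contrast-space covariance matrix.

    ``eps = tr(S)^2 / (q tr(S S))`` for a q x q covariance S; bounded in
    [1/q, 1].
    """
    S = np.asarray(cov, float)
    q = S.shape[0]
    tr = np.trace(S)
    denom = q * np.sum(S * S.T)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr * tr / denom, 1.0 / q, 1.0))


def _contrast(levels: int) -> np.ndarray:
    """Orthonormal contrast rows spanning the space orthogonal to the mean."""
    return sla.helmert(levels, full=False)


def rm_anova_gg(data: np.ndarray, factor_names: list[str] | None = None
                ) -> list[AnovaResult]:
    """Fully-crossed within-subject ANOVA on a (subjects, l1, ..., lk) array.

    Returns one :class:`AnovaResult` per main effect and interaction.  Any
    number of within factors is supported; each effect's error term is its
    interaction with subjects.  Missing cells are not allowed.
    """
    Y = np.asarray(data, float)
    if np.any(~np.isfinite(Y)):
        raise ValueError("missing cells in the measurement table")
    n = Y.shape[0]
    shape = Y.shape[1:]
    k = len(shape)
    if k == 0:
        raise ValueError("need at least one within factor")
    if factor_names is None:
        factor_names = [f"F{i + 1}" for i in range(k)]
    Yf = Y.reshape(n, -1)

    results = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            mats = []
            for f in range(k):
                if f in combo:
                    mats.append(_contrast(shape[f]))
                else:
                    mats.append(np.full((1, shape[f]), 1.0 / shape[f]))
            K = mats[0]
            for M in mats[1:]:
                K = np.kron(K, M)
            Z = Yf @ K.T                      # (n, q) contrast scores
            q = Z.shape[1]
            zbar = Z.mean(axis=0)
            resid = Z - zbar
            ss_eff = n * float(zbar @ zbar)
            ss_err = float(np.sum(resid ** 2))
            df1, df2 = q, q * (n - 1)
            ms_err = ss_err / df2
            F = (ss_eff / df1) / ms_err if ms_err > 0 else np.inf
            S = resid.T @ resid / (n - 1)
            eps = gg_epsilon(S)
            p_unc = float(sst.f.sf(F, df1, df2))
            p_gg = float(sst.f.sf(F, eps * df1, eps * df2))
            results.append(AnovaResult(
                effect=" x ".join(factor_names[f] for f in combo),
                F=float(F), df1=df1, df2=df2, epsilon=eps, p_gg=p_gg,
                p_uncorrected=p_unc,
                partial_eta_sq=float(ss_eff / (ss_eff + ss_err)),
            ))
    return results


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Declarative description of one simulated study run.

    Defaults reproduce the study conditions (24 participants, 100 trials per
    condition, 1 kHz); smaller values scale the run down proportionally.
    """

    experiment: int = 1
    seed: int = 0
    n_participants: int = 24
    n_trials: int = 100
    sfreq: float = 1000.0
    trial_noise_sd: float = synthetic_eeg.DEFAULT_TRIAL_NOISE_SD
    spn_uv: float = synthetic_eeg.DEFAULT_SPN_UV
    n_maps: int = 4
    artifact_fraction: float = 0.06
    artifact_peak_uv: float = 150.0
    n_perm: int = topography.DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    min_duration_ms: float = topography.DEFAULT_MIN_DURATION_MS
    q_range: tuple[int, int] = microstates.DEFAULT_Q_RANGE
    window_ms: tuple[float, float] = SPN_WINDOW_MS
    out_dir: str | None = None
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.q_range = tuple(cfg.q_range)
        cfg.window_ms = tuple(cfg.window_ms)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, preprocess, measure the SPN, run TANOVA, segment microstates,
    back-fit and test: the full chain, reproducible from (config, seed).

    Returns a bundle with the SPN table, one TANOVA per condition pair, the
    segmentation hierarchy, the back-fit table, the group statistics and a
    machine-readable ``summary`` dict; optionally writes tables/figures to
    ``config.out_dir``.
    """
    stage = "design"
    try:
        design = stimuli.build_design(config.experiment, seed=config.seed,
                                      presentations_per_condition=config.n_trials)
        sym_conditions = design.condition_names
        noise_conditions = []
        for c in design.conditions:
            if c.noise_arrangement not in noise_conditions:
                noise_conditions.append(c.noise_arrangement)

        stage = "simulate"
        montage = Montage.standard_64()
        timeline = synthetic_eeg.default_timeline(
            montage, sym_conditions, noise_conditions, k=config.n_maps,
            window_ms=config.window_ms, spn_uv=config.spn_uv, seed=config.seed)
        epochsets = synthetic_eeg.simulate_epochs(
            design, timeline, n_participants=config.n_participants,
            trial_noise_sd=config.trial_noise_sd, seed=config.seed,
            montage=montage, sfreq=config.sfreq, n_trials=config.n_trials)
        epochsets = [
            synthetic_eeg.inject_artifacts(es, config.artifact_fraction,
                                           config.artifact_peak_uv,
                                           seed=config.seed + 1000 + i)
            for i, es in enumerate(epochsets)
        ]

        stage = "preprocess"
        erps_by_pid = {es.participant: preprocess.participant_erps(es)
                       for es in epochsets}
        participants = sorted(erps_by_pid)

        stage = "spn"
        pairs = [(c.name, c.noise_arrangement) for c in design.conditions]
        spn_rows = []
        for pid in participants:
            for sym, noi in pairs:
                m = preprocess.participant_spn(erps_by_pid[pid], sym, noi)
                spn_rows.append({"participant": pid, "condition": sym,
                                 "noise_condition": noi,
                                 "spn_uv": m.amplitude_uv})
        spn_table = pd.DataFrame(spn_rows)
        spn_tests = {}
        for sym, _ in pairs:
            vals = spn_table.query("condition == @sym")["spn_uv"].to_numpy()
            spn_tests[sym] = one_sample_t(vals, 0.0)

        stage = "tanova"
        tanova_results = {}
        for sym, noi in pairs:
            A = np.stack([erps_by_pid[p][sym].data for p in participants])
            B = np.stack([erps_by_pid[p][noi].data for p in participants])
            tanova_results[sym] = topography.tanova_paired(
                A, B, n_perm=config.n_perm, alpha=config.alpha,
                min_duration_ms=config.min_duration_ms, seed=config.seed,
                times_ms=erps_by_pid[participants[0]][sym].times_ms)

        stage = "segment"
        all_conditions = sym_conditions + noise_conditions
        grand = []
        for cond in all_conditions:
            gdata = np.mean([erps_by_pid[p][cond].data for p in participants], axis=0)
            e0 = erps_by_pid[participants[0]][cond]
            grand.append(type(e0)(data=gdata, condition=cond,
                                  n_epochs=len(participants), montage=montage,
                                  sfreq=e0.sfreq, tmin_ms=e0.tmin_ms,
                                  reference="common-average", participant="grand"))
        hierarchy = microstates.taahc_segment(grand, window_ms=config.window_ms,
                                              q_range=config.q_range,
                                              seed=config.seed)
        q_sel, conflict, cv_by_q, kl_by_q = microstates.select_maps(
            hierarchy, n_electrodes=len(montage))
        seg = hierarchy.by_q[q_sel]

        stage = "backfit"
        table = microstates.backfit(seg.templates, erps_by_pid, config.window_ms)
        shares = table.share_array(participants,
                                   [pairs[0][0], pairs[0][1]], q_sel)
        anova = rm_anova_gg(shares, ["stimulus_type", "map"])
        interaction = next(a for a in anova if a.effect == "stimulus_type x map")

        # which maps are condition-specific? compare grand-average durations
        timing = {cond: microstates.map_timing(seg.labels[cond], seg.times_ms, q_sel)
                  for cond in all_conditions}
        sym_only_maps = sorted(
            m for m in range(q_sel)
            if all(not timing[c].loc[m, "absent"] for c in sym_conditions)
            and all(bool(timing[c].loc[m, "absent"]) for c in noise_conditions)
        )

        stage = "report"
        summary = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
            "n_trials_total": int(design.n_trials),
            "spn_group_mean_uv": {
                sym: float(spn_table.query("condition == @sym")["spn_uv"].mean())
                for sym, _ in pairs
            },
            "spn_t_tests": {
                sym: {"t": r.t, "df": r.df, "p": r.p, "d": r.cohens_d}
                for sym, r in spn_tests.items()
            },
            "tanova_windows": {
                sym: [[a, b] for a, b in res.windows]
                for sym, res in tanova_results.items()
            },
            "selected_q": int(q_sel),
            "cv_kl_conflict": bool(conflict),
            "gev_total": float(seg.gev_total),
            "stimulus_type_x_map": {
                "F": interaction.F, "df": [interaction.df1, interaction.df2],
                "epsilon": interaction.epsilon, "p_gg": interaction.p_gg,
                "partial_eta_sq": interaction.partial_eta_sq,
            },
            "condition_specific_maps": sym_only_maps,
        }
        bundle = {
            "design": design,
            "spn_table": spn_table,
            "spn_tests": spn_tests,
            "tanova": tanova_results,
            "hierarchy": hierarchy,
            "segmentation": seg,
            "cv_by_q": cv_by_q,
            "kl_by_q": kl_by_q,
            "backfit": table,
            "anova": anova,
            "timing": timing,
            "summary": summary,
        }
        if config.out_dir:
            stage = "write"
            _write_bundle(bundle, config, montage)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_bundle(bundle: dict, config: PipelineConfig, montage: Montage) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    bundle["spn_table"].to_csv(os.path.join(out, "spn_table.csv"), index=False)
    for sym, res in bundle["tanova"].items():
        res.to_csv(os.path.join(out, f"tanova_{sym}.csv"))
    with open(os.path.join(out, "tanova_windows.json"), "w") as fh:
        json.dump(bundle["summary"]["tanova_windows"], fh, indent=2, sort_keys=True)
    with open(os.path.join(out, "segmentation.json"), "w") as fh:
        fh.write(bundle["segmentation"].to_json())
    bundle["backfit"].to_csv(os.path.join(out, "backfit.csv"))
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, sort_keys=True)
    if config.make_figures:
        plot_templates(bundle["segmentation"].templates, montage,
                       os.path.join(out, "templates.png"))
        plot_spn(bundle, os.path.join(out, "spn_waveforms.png"))


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def plot_topomap(ax, values: np.ndarray, montage: Montage) -> None:
    """Interpolated scalp map, head seen from above with the nasion up."""
    import matplotlib.tri as mtri

    xy = montage.pos2d
    tri = mtri.Triangulation(xy[:, 0], xy[:, 1])
    ax.tricontourf(tri, values, levels=24, cmap="RdBu_r")
    r = np.max(np.hypot(xy[:, 0], xy[:, 1])) * 1.05
    circ = np.linspace(0, 2 * np.pi, 181)
    ax.plot(r * np.cos(circ), r * np.sin(circ), color="k", lw=1)
    ax.plot([0], [r * 1.05], marker="^", color="k", ms=6)  # nasion marker
    ax.scatter(xy[:, 0], xy[:, 1], s=2, c="k")
    ax.set_aspect("equal")
    ax.set_axis_off()


def plot_templates(templates: np.ndarray, montage: Montage, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    q = len(templates)
    fig, axes = plt.subplots(1, q, figsize=(2.2 * q, 2.4))
    for m, ax in enumerate(np.atleast_1d(axes)):
        plot_topomap(ax, templates[m], montage)
        ax.set_title(f"map {chr(65 + m)}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spn(bundle: dict, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for sym, res in bundle["tanova"].items():
        ax.plot(res.times_ms, res.observed_diss, label=sym, lw=1)
        for a, b in res.windows:
            ax.axvspan(a, b, color="0.85", zorder=0)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("DISS")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
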