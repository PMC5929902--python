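import numpy as np
import pytest

from spnpipe import microstates as ms
from spnpipe import stats_report as sr
from spnpipe import synthetic_eeg as se
from spnpipe.core import Erp
from tests.conftest import grand_average_erps


def tiled_erp(montage, templates, amplitude=4.0, sfreq=250.0, condition="c"):
    """ERP whose 200-600 ms window is an exact noiseless template tiling."""
    nt = 276
    t = -100.0 + np.arange(nt) * 1000.0 / sfreq
    data = np.zeros((len(montage), nt))
    idx = np.nonzero((t >= 200.0) & (t <= 600.0))[0]
    k = len(templates)
    true = []
    for i, ix in enumerate(idx):
        m = min(i * k // len(idx), k - 1)
        data[:, ix] = amplitude * templates[m]
        true.append(m)
    erp = Erp(data=data, condition=condition, n_epochs=1, montage=montage,
              sfreq=sfreq, reference="common-average")
    return erp, np.array(true)


def labels_match_up_to_relabelling(lab, true):
    mapping = {}
    for a, b in zip(lab, true):
        if b in mapping and mapping[b] != a:
            return False
        mapping[b] = a
    return len(set(mapping.values())) == len(mapping)


class TestTaahc:
    def test_noiseless_tiling_recovered_exactly(self, montage):
        tem = se.make_templates(montage, 4, seed=2)
        erp, true = tiled_erp(montage, tem)
        hier = ms.taahc_segment([erp], q_range=(2, 8), seed=0)
        seg = hier.by_q[4]
        assert labels_match_up_to_relabelling(seg.labels["c"], true)
        _, r = ms.pair_templates(seg.templates, tem)
        assert np.all(r > 1 - 1e-9)
        assert abs(seg.gev_total - 1.0) < 1e-12

    def test_single_cluster_covers_everything(self, montage):
        tem = se.make_templates(montage, 2, seed=3)
        erp, _ = tiled_erp(montage, tem)
        hier = ms.taahc_segment([erp], q_range=(1, 4), seed=0)
        seg = hier.by_q[1]
        assert np.all(seg.labels["c"] == 0)

    def test_gev_is_nested_along_the_hierarchy(self, montage, small_epochsets):
        grand, _ = grand_average_erps(small_epochsets, ["symmetry", "noise"])
        hier = ms.taahc_segment(grand, q_range=(2, 8), seed=1)
        gev = [hier.by_q[q].gev_total for q in hier.q_values]
        assert all(0.0 <= g <= 1.0 for g in gev)
        assert all(b >= a - 1e-9 for a, b in zip(gev, gev[1:]))

    def test_window_shorter_than_q_max_rejected(self, montage):
        tem = se.make_templates(montage, 2, seed=0)
        erp, _ = tiled_erp(montage, tem)
        with pytest.raises(ValueError):
            ms.taahc_segment([erp], window_ms=(200.0, 216.0), q_range=(2, 8))


class TestModelSelection:
    def test_cv_zero_for_perfect_fit(self, montage):
        tem = se.make_templates(montage, 4, seed=2)
        erp, _ = tiled_erp(montage, tem)
        seg = ms.taahc_segment([erp], q_range=(4, 4), seed=0).by_q[4]
        assert ms.cv_criterion(seg, 64) < 1e-20

    def test_cv_scales_by_exact_df_ratio(self, montage):
        tem = se.make_templates(montage, 4, seed=2)
        erp, _ = tiled_erp(montage, tem)
        seg4 = ms.taahc_segment([erp], q_range=(4, 4), seed=0).by_q[4]
        a = type(seg4)(q=4, templates=seg4.templates, labels=seg4.labels,
                       times_ms=seg4.times_ms, gev_total=0, gev_per_map=seg4.gev_per_map,
                       sigma2=2.0, dispersion=0)
        b = type(seg4)(q=8, templates=seg4.templates, labels=seg4.labels,
                       times_ms=seg4.times_ms, gev_total=0, gev_per_map=seg4.gev_per_map,
                       sigma2=2.0, dispersion=0)
        ratio = ms.cv_criterion(b, 64) / ms.cv_criterion(a, 64)
        assert np.isclose(ratio, ((63 - 4) / (63 - 8)) ** 2, rtol=1e-12)

    def test_cv_undefined_at_too_many_maps(self, montage):
        tem = se.make_templates(montage, 4, seed=2)
        erp, _ = tiled_erp(montage, tem)
        seg = ms.taahc_segment([erp], q_range=(4, 4), seed=0).by_q[4]
        with pytest.raises(ValueError):
            ms.cv_criterion(seg, n_electrodes=5)

    def test_kl_finds_a_sharp_elbow(self):
        w = {1: 100.0, 2: 60.0, 3: 30.0, 4: 5.0, 5: 4.5, 6: 4.2, 7: 4.0, 8: 3.9}
        kl = ms.kl_criterion(w, m=64)
        assert max(kl, key=kl.get) == 4
        assert kl[4] > 10 * max(v for q, v in kl.items() if q != 4)

    def test_kl_flat_for_linear_dispersion(self):
        w = {q: 100.0 - 10.0 * q for q in range(1, 9)}
        kl = ms.kl_criterion(w, m=64)
        vals = np.array(list(kl.values()))
        assert vals.max() / vals.min() < 1.2  # no pronounced maximum

    def test_kl_warns_on_nonmonotone_dispersion(self):
        w = {1: 10.0, 2: 12.0, 3: 5.0, 4: 4.0}
        with pytest.warns(RuntimeWarning):
            ms.kl_criterion(w, m=64)

    def test_select_q_agreement_and_conflict(self):
        cv = {3: 2.0, 4: 1.0, 5: 1.5}
        kl = {3: 1.0, 4: 9.0, 5: 1.0}
        assert ms.select_q(cv, kl) == (4, False)
        cv2 = {3: 2.0, 4: 1.5, 5: 1.0}
        assert ms.select_q(cv2, kl) == (4, True)
        with pytest.raises(ValueError):
            ms.select_q({}, {})

    def test_recovery_of_planted_map_count(self, montage):
        """Planted 4-map study conditions: the joint CV/KL selection returns
        q=4 and templates match the planted maps after optimal pairing."""
        tl = se.default_timeline(montage, ["symmetry"], ["noise"], seed=21)
        sets = se.simulate_epochs(["symmetry", "noise"], tl, n_participants=8,
                                  seed=21, montage=montage, sfreq=250.0, n_trials=30)
        grand, _ = grand_average_erps(sets, ["symmetry", "noise"])
        hier = ms.taahc_segment(grand, q_range=(2, 8), seed=21)
        q, conflict, cv, kl = ms.select_maps(hier, 64)
        assert q == 4
        # CV rules out too-few maps even though its curve flattens beyond q=4
        assert cv[4] < cv[2] and cv[4] < cv[3]
        _, r = ms.pair_templates(hier.by_q[4].templates, tl.templates)
        assert np.all(r >= 0.95)


class TestBackfit:
    def test_noiseless_self_fit_is_exact(self, montage):
        tem = se.make_templates(montage, 4, seed=5)
        erp, true = tiled_erp(montage, tem)
        table = ms.backfit(tem, {"p00": {"c": erp}})
        lab = table.labels[("p00", "c")]
        assert np.array_equal(lab, true)
        total = table.shares.query("participant == 'p00'")["ev_share"].sum()
        assert abs(total - 1.0) < 1e-10

    def test_pure_noise_spreads_over_maps(self, montage):
        tem = se.make_templates(montage, 4, seed=6)
        rng = np.random.default_rng(0)
        nt = 276
        data = rng.standard_normal((64, nt))
        erp = Erp(data=data, condition="c", n_epochs=1, montage=montage,
                  sfreq=250.0, reference="common-average")
        table = ms.backfit(tem, {"p00": {"c": erp}})
        shares = table.shares["ev_share"].to_numpy()
        assert np.all(shares > 0.0) and np.all(shares < 0.75)

    def test_polarity_is_signed(self, montage):
        """Flipping a map's polarity changes its assignment (ERP convention):
        -t0 is closer to an uncorrelated template than to t0 itself."""
        tem = se.make_templates(montage, 2, seed=7)
        nt = 276
        t = -100.0 + np.arange(nt) * 4.0
        data = np.zeros((64, nt))
        data[:, (t >= 200) & (t <= 600)] = -tem[0][:, None]
        erp = Erp(data=data, condition="c", n_epochs=1, montage=montage,
                  sfreq=250.0, reference="common-average")
        lab = ms.backfit(tem, {"p00": {"c": erp}}).labels[("p00", "c")]
        assert np.all(lab == 1)

    def test_condition_specific_map_detected_if_and_only_if_planted(self, montage):
        """The stimulus-type x map interaction on explained variance fires
        when a symmetry-only map is planted and stays quiet under the null."""
        def interaction_p(seed, planted):
            tl = se.default_timeline(
                montage, ["symmetry"], ["noise"],
                symmetry_only_map="last" if planted else None,
                spn_uv=0.0, seed=seed)
            sets = se.simulate_epochs(["symmetry", "noise"], tl, n_participants=8,
                                      seed=seed, montage=montage, sfreq=250.0,
                                      n_trials=20)
            grand, erps = grand_average_erps(sets, ["symmetry", "noise"])
            seg = ms.taahc_segment(grand, q_range=(4, 4), seed=seed).by_q[4]
            by_pid = {f"p{i:02d}": e for i, e in enumerate(erps)}
            table = ms.backfit(seg.templates, by_pid)
            shares = table.share_array(sorted(by_pid), ["symmetry", "noise"], 4)
            res = sr.rm_anova_gg(shares, ["stimulus_type", "map"])
            return next(r for r in res if r.effect == "stimulus_type x map").p_gg

        planted_p = [interaction_p(s, True) for s in range(4)]
        null_p = [interaction_p(s, False) for s in range(6)]
        assert all(p < 0.05 for p in planted_p)
        assert sum(p < 0.05 for p in null_p) <= 1


def test_zero_noise_simulation_backfits_to_the_planted_sequence(montage):
    """Noise-free simulated epochs, back-fitted with the planted templates,
    reproduce the planted label sequence wherever the envelope is nonzero
    (boundary samples, where adjacent ramps both reach zero, are skipped)."""
    tl = se.default_timeline(montage, ["symmetry"], ["noise"], spn_uv=0.0,
                             seed=13)
    sets = se.simulate_epochs(["symmetry", "noise"], tl, n_participants=1,
                              trial_noise_sd=0.0, participant_gain_sd=0.0,
                              seed=13, montage=montage, sfreq=250.0, n_trials=1)
    erps = {"p00": {c: Erp(data=sets[0].data[c][0], condition=c, n_epochs=1,
                           montage=montage, sfreq=250.0,
                           reference="common-average")
                    for c in ("symmetry", "noise")}}
    table = ms.backfit(tl.templates, erps)
    for cond in ("symmetry", "noise"):
        lab = table.labels[("p00", cond)]
        times = table.times_ms
        planted = tl.segment_labels(cond, times)
        ok = lab >= 0  # zero-GFP boundary dips are skipped and labelled -1
        assert np.array_equal(lab[ok], planted[ok])
        assert np.mean(ok) > 0.9


class TestTiming:
    def test_single_map_spans_the_window(self):
        t = np.arange(200.0, 601.0, 4.0)
        lab = np.zeros(len(t), dtype=int)
        df = ms.map_timing(lab, t, n_maps=1)
        assert df.loc[0, "onset_ms"] == 200.0 and df.loc[0, "offset_ms"] == 600.0
        assert df.loc[0, "duration_ms"] == 400.0

    def test_planted_run_located_within_one_sample(self):
        t = np.arange(200.0, 601.0, 4.0)
        lab = np.zeros(len(t), dtype=int)
        sel = (t >= 450.0) & (t <= 560.0)
        lab[sel] = 1
        df = ms.map_timing(lab, t, n_maps=2)
        assert abs(df.loc[1, "onset_ms"] - 450.0) <= 4.0
        assert abs(df.loc[1, "offset_ms"] - 560.0) <= 4.0

    def test_absent_map_is_flagged(self):
        t = np.arange(200.0, 601.0, 4.0)
        lab = np.zeros(len(t), dtype=int)
        df = ms.map_timing(lab, t, n_maps=2)
        assert bool(df.loc[1, "absent"]) and df.loc[1, "duration_ms"] == 0.0
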