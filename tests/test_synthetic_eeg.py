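import numpy as np
import pytest

from spnpipe import synthetic_eeg as se
from spnpipe.core import Montage, load_epochsets, save_epochsets
from spnpipe.synthetic_eeg import (
    PlantedTimeline,
    SeedFailureError,
    TimelineSegment,
    inject_artifacts,
    make_templates,
    simulate_epochs,
    spatial_correlation,
)


class TestTemplates:
    def test_single_template_is_average_referenced_unit_gfp(self, montage):
        t = make_templates(montage, 1, seed=0)
        assert abs(t[0].mean()) < 1e-12
        assert abs(np.sqrt(np.mean(t[0] ** 2)) - 1.0) < 1e-12

    def test_pairwise_decorrelation_bound(self, montage):
        t = make_templates(montage, 4, seed=1)
        C = np.array([[spatial_correlation(a, b) for b in t] for a in t])
        assert np.allclose(np.diag(C), 1.0)
        off = C[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) <= 0.7)

    def test_seed_determinism(self, montage):
        assert np.array_equal(make_templates(montage, 3, seed=5),
                              make_templates(montage, 3, seed=5))

    def test_impossible_decorrelation_raises(self, montage):
        with pytest.raises(SeedFailureError):
            make_templates(montage, 30, seed=0, max_abs_corr=0.05, max_retries=20)

    def test_k_validation(self, montage):
        with pytest.raises(ValueError):
            make_templates(montage, 0, seed=0)


class TestTimeline:
    def test_unknown_template_id_rejected(self, montage):
        tl = PlantedTimeline(templates=make_templates(montage, 1, seed=0),
                             segments=[TimelineSegment(3, 0, 100)])
        with pytest.raises(KeyError):
            tl.validate(["a"])

    def test_overlapping_segments_rejected(self, montage):
        tem = make_templates(montage, 2, seed=0)
        tl = PlantedTimeline(templates=tem, segments=[
            TimelineSegment(0, 0, 300), TimelineSegment(1, 200, 400)])
        with pytest.raises(ValueError):
            tl.validate(["a"])

    def test_condition_specific_segments_do_not_conflict(self, montage):
        tem = make_templates(montage, 2, seed=0)
        tl = PlantedTimeline(templates=tem, segments=[
            TimelineSegment(0, 200, 400, conditions=("sym",)),
            TimelineSegment(1, 200, 400, conditions=("noise",))])
        tl.validate(["sym", "noise"])  # no overlap within either condition

    def test_default_timeline_plants_symmetry_only_map(self, montage):
        tl = se.default_timeline(montage, ["sym"], ["noi"], k=4, seed=0)
        t = np.arange(200.0, 601.0, 4.0)
        lab_sym = tl.segment_labels("sym", t)
        lab_noi = tl.segment_labels("noi", t)
        assert 3 in lab_sym and 3 not in lab_noi
        assert set(lab_noi) <= {0, 1, 2}


class TestSimulation:
    def test_zero_noise_segment_interior_equals_template(self, montage):
        tem = make_templates(montage, 1, seed=2)
        tl = PlantedTimeline(templates=tem,
                             segments=[TimelineSegment(0, 200, 600, amplitude_uv=1.0)])
        sets = simulate_epochs(["c"], tl, n_participants=1, trial_noise_sd=0.0,
                               participant_gain_sd=0.0, seed=0, montage=montage,
                               sfreq=250.0, n_trials=2)
        es = sets[0]
        t = es.times_ms
        interior = (t >= 215) & (t <= 585)  # clear of the 10 ms ramps
        for trial in es.data["c"]:
            assert np.allclose(trial[:, interior], tem[0][:, None], atol=1e-12)
        outside = t < 195
        assert np.allclose(es.data["c"][:, :, outside], 0.0)

    def test_planted_spn_appears_only_in_symmetry_conditions(self, montage):
        tem = make_templates(montage, 1, seed=3)
        tl = PlantedTimeline(
            templates=tem,
            segments=[TimelineSegment(0, 200, 600, amplitude_uv=2.0)],
            spn=se.SpnEffect(conditions=("sym",), offset_uv=-1.5))
        sets = simulate_epochs(["sym", "noi"], tl, n_participants=1,
                               trial_noise_sd=0.0, participant_gain_sd=0.0,
                               seed=0, montage=montage, sfreq=250.0, n_trials=3)
        es = sets[0]
        diff = es.data["sym"].mean(axis=0) - es.data["noi"].mean(axis=0)
        t = es.times_ms
        interior = (t >= 215) & (t <= 585)
        po = [montage.index("PO7"), montage.index("PO8")]
        assert np.allclose(diff[np.ix_(po, np.nonzero(interior)[0])], -1.5, atol=1e-12)
        others = [i for i in range(len(montage)) if i not in po]
        assert np.allclose(diff[others], 0.0, atol=1e-12)

    def test_planted_spn_is_linear_in_the_offset(self, montage):
        tem = make_templates(montage, 1, seed=3)

        def diff_at(offset):
            tl = PlantedTimeline(templates=tem,
                                 segments=[TimelineSegment(0, 200, 600)],
                                 spn=se.SpnEffect(conditions=("sym",), offset_uv=offset))
            sets = simulate_epochs(["sym", "noi"], tl, n_participants=1,
                                   trial_noise_sd=0.0, participant_gain_sd=0.0,
                                   seed=0, montage=montage, sfreq=250.0, n_trials=1)
            es = sets[0]
            return es.data["sym"][0] - es.data["noi"][0]

        assert np.allclose(diff_at(-3.0), 2.0 * diff_at(-1.5), atol=1e-12)

    def test_study_scale_structure(self, montage, shared_timeline):
        from spnpipe.stimuli import build_design

        design = build_design(1, seed=0)
        assert design.presentations_per_condition == 100
        sets = simulate_epochs(design, shared_timeline_for_design(montage),
                               n_participants=24, seed=0, montage=montage,
                               sfreq=250.0, n_trials=4)
        assert len(sets) == 24
        # symmetric conditions plus their two distinct noise arrangements
        assert set(sets[0].conditions) == {
            "anti_symmetric", "polarity_grouped_anti", "unsegregated",
            "noise", "polarity_grouped_noise"}
        for es in sets[:2]:
            for arr in es.data.values():
                assert arr.shape == (4, 64, 276)

    def test_seed_determinism(self, montage, shared_timeline):
        a = simulate_epochs(["symmetry", "noise"], shared_timeline, 2, seed=9,
                            montage=montage, sfreq=250.0, n_trials=3)
        b = simulate_epochs(["symmetry", "noise"], shared_timeline, 2, seed=9,
                            montage=montage, sfreq=250.0, n_trials=3)
        for x, y in zip(a, b):
            for cond in x.conditions:
                assert np.array_equal(x.data[cond], y.data[cond])


def shared_timeline_for_design(montage):
    return se.default_timeline(
        montage,
        ["anti_symmetric", "polarity_grouped_anti", "unsegregated"],
        ["noise", "polarity_grouped_noise"],
        symmetry_only_map=None, seed=11)


class TestArtifacts:
    def test_zero_fraction_leaves_data_untouched(self, small_epochsets):
        es = small_epochsets[0]
        out = inject_artifacts(es, fraction=0.0, peak_uv=150.0, seed=0)
        for cond in es.conditions:
            assert np.array_equal(out.data[cond], es.data[cond])
            assert not out.artifact_mask[cond].any()

    def test_fraction_controls_flagged_count(self, montage, shared_timeline):
        sets = simulate_epochs(["symmetry", "noise"], shared_timeline, 1, seed=1,
                               montage=montage, sfreq=250.0, n_trials=100)
        out = inject_artifacts(sets[0], fraction=0.06, peak_uv=150.0, seed=0)
        for cond in out.conditions:
            assert out.artifact_mask[cond].sum() == 6

    def test_flagged_epochs_exceed_planted_peak(self, small_epochsets):
        out = inject_artifacts(small_epochsets[0], fraction=0.2, peak_uv=150.0, seed=4)
        for cond in out.conditions:
            flagged = out.data[cond][out.artifact_mask[cond]]
            assert np.all(np.max(np.abs(flagged), axis=(1, 2)) >= 150.0)

    def test_parameter_validation(self, small_epochsets):
        with pytest.raises(ValueError):
            inject_artifacts(small_epochsets[0], fraction=1.5, peak_uv=150.0)
        with pytest.raises(ValueError):
            inject_artifacts(small_epochsets[0], fraction=0.1, peak_uv=90.0)


class TestContainers:
    def test_hdf5_roundtrip(self, tmp_path, small_epochsets):
        marked = [inject_artifacts(es, 0.1, 150.0, seed=i)
                  for i, es in enumerate(small_epochsets[:2])]
        path = tmp_path / "epochs.h5"
        save_epochsets(path, marked)
        back = load_epochsets(path)
        assert [b.participant for b in back] == [m.participant for m in marked]
        for orig, rec in zip(marked, back):
            assert rec.sfreq == orig.sfreq and rec.tmin_ms == orig.tmin_ms
            for cond in orig.conditions:
                assert np.array_equal(rec.data[cond], orig.data[cond])
                assert np.array_equal(rec.artifact_mask[cond],
                                      orig.artifact_mask[cond])

    def test_sfp_roundtrip(self, tmp_path, montage):
        path = tmp_path / "montage.sfp"
        montage.write_sfp(path)
        back = Montage.read_sfp(path)
        assert back.names == montage.names
        assert np.allclose(back.positions, montage.positions, atol=1e-5)

    def test_montage_has_the_measurement_electrodes(self, montage):
        for name in ("PO7", "PO8", "Cz"):
            montage.index(name)
        with pytest.raises(KeyError):
            montage.index("XX9")
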