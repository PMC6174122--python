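"""Generator contracts: protocol structure, exact ground truth, determinism."""

import numpy as np
import pytest

from sprintox.core import SprintTimeline
from sprintox.performance import fatigue_index, per_sprint_power
from sprintox.synthetic import (
    ProtocolConfig,
    generate_neuromuscular_traces,
    generate_nirs_traces,
    generate_power_profile,
    generate_study,
    simulate_endpoint_table,
    write_study,
)
from sprintox.pipeline import read_study


class TestPowerProfile:
    def test_single_sprint_plateau_and_recovery(self):
        trace, tl = generate_power_profile(1, 800.0, 0.0, 0.0, seed=0)
        means, _ = per_sprint_power(trace, tl)
        assert means[0] == pytest.approx(800.0, abs=1e-9)
        # recovery segments sit at the 20-W ergometer resistance
        rec = trace.segment(tl.ends[0] + 1.0, tl.ends[0] + 15.0)
        assert np.allclose(rec, 20.0)

    def test_geometric_sprint_means(self):
        trace, tl = generate_power_profile(5, 600.0, 0.1, 0.0, seed=0)
        means, _ = per_sprint_power(trace, tl)
        assert np.allclose(means, [600.0, 540.0, 486.0, 437.4, 393.66], atol=1e-9)

    def test_noisy_sdec_matches_geometric_closed_form(self):
        trace, tl = generate_power_profile(30, 700.0, 0.02, 20.0, seed=1)
        means, _ = per_sprint_power(trace, tl)
        closed = (1.0 - np.mean(0.98 ** np.arange(30))) * 100.0
        assert fatigue_index(means) == pytest.approx(closed, abs=2.0)

    def test_timeline_structure(self):
        _, tl = generate_power_profile(7, 500.0)
        assert tl.n_sprints == 7
        assert np.allclose(tl.ends - tl.starts, 10.0)
        assert np.allclose(np.diff(tl.starts), 30.0)

    @pytest.mark.parametrize("kwargs", [
        {"n_sprints": 0, "peak_power": 500.0},
        {"n_sprints": 3, "peak_power": -10.0},
        {"n_sprints": 3, "peak_power": 500.0, "decrement_rate": 1.0},
    ])
    def test_rejects_bad_inputs(self, kwargs):
        with pytest.raises(ValueError):
            generate_power_profile(**kwargs)


class TestNirsGenerator:
    def test_noise_free_round_trip_single_sprint(self):
        tl = SprintTimeline.regular(1, first_start_s=30.0)
        out = generate_nirs_traces(tl, delta_schedule=[10.0])
        assert out.true_deltas["HHb"][0] == pytest.approx(10.0, abs=1e-9)
        t = out.hhb.times()
        seg = out.clean["HHb"][(t >= 30.0) & (t <= 40.0)]
        assert seg.max() - seg.min() == pytest.approx(10.0, abs=1e-9)

    def test_hhb_max_after_min_within_each_sprint(self):
        tl = SprintTimeline.regular(6, first_start_s=30.0)
        out = generate_nirs_traces(tl, delta_schedule=np.linspace(10, 6, 6))
        t = out.hhb.times()
        for a, b in tl.intervals():
            seg = out.clean["HHb"][(t >= a) & (t < b)]
            assert np.argmax(seg) > np.argmin(seg)

    def test_schedule_length_mismatch_rejected(self):
        tl = SprintTimeline.regular(4, first_start_s=30.0)
        with pytest.raises(ValueError, match="entries"):
            generate_nirs_traces(tl, delta_schedule=[10.0, 9.0])

    def test_artifact_below_cutoff_rejected(self):
        tl = SprintTimeline.regular(2, first_start_s=30.0)
        with pytest.raises(ValueError, match="cutoff"):
            generate_nirs_traces(tl, delta_schedule=[10.0, 9.0],
                                 artifact_amp=3.0, artifact_freq=0.1)

    def test_thb_truth_is_sum_of_components(self):
        tl = SprintTimeline.regular(3, first_start_s=30.0)
        out = generate_nirs_traces(tl, delta_schedule=[10.0, 9.0, 8.0])
        assert np.allclose(out.clean["tHb"],
                           out.clean["O2Hb"] + out.clean["HHb"])


class TestNeuromuscularGenerator:
    def test_full_activation_means_no_superimposed_increment(self):
        rec = generate_neuromuscular_traces(300.0, 100.0, 60.0, 54.0, 30.0)
        assert rec.truth["superimposed"] == 0.0

    def test_p10_over_p100_by_construction(self):
        rec = generate_neuromuscular_traces(300.0, 85.0, 60.0, 54.0, 30.0)
        assert rec.truth["p10_over_p100"] == pytest.approx(0.90)

    def test_markers_separated_by_two_seconds(self):
        rec = generate_neuromuscular_traces(300.0, 85.0, 60.0, 54.0, 30.0)
        times = sorted(rec.markers.values())
        assert np.allclose(np.diff(times), 2.0)

    def test_val_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_neuromuscular_traces(300.0, 120.0, 60.0, 54.0, 30.0)


class TestStudy:
    def test_shape_and_truth_invariants(self, small_study):
        assert len(small_study.records) == 3 * 3
        for (pid, cond), gt in small_study.ground_truth.entries.items():
            assert gt["n_sprints"] >= 1
            assert np.all(gt["sprint_mean_powers"] > 0)
            assert 0.0 <= gt["val_pre"] <= 100.0
            assert 0.0 <= gt["val_post"] <= 100.0

    def test_same_seed_is_bit_identical(self):
        a = generate_study(n_participants=2, seed=5)
        b = generate_study(n_participants=2, seed=5)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.power.values, rb.power.values)
            assert np.array_equal(ra.nirs_muscle.hhb.values,
                                  rb.nirs_muscle.hhb.values)
            assert np.array_equal(ra.nm_post.emg.values, rb.nm_post.emg.values)

    def test_different_seed_differs(self):
        a = generate_study(n_participants=2, seed=5)
        b = generate_study(n_participants=2, seed=6)
        assert not np.array_equal(a.records[0].power.values,
                                  b.records[0].power.values)

    def test_rejects_single_participant(self):
        with pytest.raises(ValueError):
            generate_study(n_participants=1, seed=0)

    def test_disk_round_trip(self, tmp_path, small_study):
        write_study(small_study, tmp_path / "ds")
        assert (tmp_path / "ds" / "manifest.csv").exists()
        loaded = read_study(tmp_path / "ds")
        orig = small_study.records[0]
        back = loaded.get(orig.participant, orig.condition)
        assert np.allclose(back.power.values, orig.power.values, atol=1e-5)
        assert np.allclose(back.timeline.starts, orig.timeline.starts)
        gt = loaded.ground_truth.get(orig.participant, orig.condition)
        assert gt["n_sprints"] == orig.timeline.n_sprints


class TestEndpointSimulator:
    def test_condition_means_follow_factors(self):
        tab = simulate_endpoint_table(200, 30.0, 0.0, 0.0,
                                      factors={0: 1.0, 45: 0.5, 60: 0.25},
                                      seed=0)
        m = tab.groupby("condition")["value"].mean()
        assert m[0] == pytest.approx(30.0)
        assert m[45] == pytest.approx(15.0)
        assert m[60] == pytest.approx(7.5)

    def test_participant_intercept_shared_across_conditions(self):
        tab = simulate_endpoint_table(5, 0.0, 10.0, 0.0, seed=3)
        pivot = tab.pivot(index="participant", columns="condition",
                          values="value")
        assert np.allclose(pivot.std(axis=1), 0.0)
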