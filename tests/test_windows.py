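"""Sample aggregation, window construction and behavior dropping."""

import numpy as np
import pytest

from ethoclock.core import BehaviorCatalog, PhaseSchedule, phase_of
from ethoclock.windows import (
    NO_DOMINANT,
    aggregate_samples,
    build_windows,
    drop_behaviors,
    flatten_windows,
)
from .conftest import alternating_stream, make_stream


@pytest.fixture
def catalog4():
    return BehaviorCatalog(("Sleep", "Twitch", "Walk", "Dig"))


class TestAggregateSamples:
    def test_composition_reflects_frame_shares(self, catalog4):
        # 60 frames Sleep then 40 frames Twitch at 10 fps, one 100-frame sample
        s = make_stream(catalog4, [(0, 0, 6.0), (1, 6.0, 4.0)])
        out = aggregate_samples(s, fps=10, frames_per_sample=100)
        assert out.n_samples == 1
        assert out.composition[0].tolist() == pytest.approx([0.6, 0.4, 0.0, 0.0])
        assert out.dominant[0] == 0
        assert out.composition.sum(axis=1) == pytest.approx(1.0)

    def test_tie_breaks_to_earlier_bout(self, catalog4):
        s = make_stream(catalog4, [(2, 0, 5.0), (1, 5.0, 5.0)])
        out = aggregate_samples(s, fps=10, frames_per_sample=100)
        assert out.composition[0, 1] == out.composition[0, 2] == 0.5
        assert out.dominant[0] == 2  # Walk's bout starts first

    def test_trailing_partial_sample_discarded(self, catalog4):
        s = make_stream(catalog4, [(0, 0, 25.0)])
        out = aggregate_samples(s, fps=10, frames_per_sample=100)
        assert out.n_samples == 2

    def test_stream_shorter_than_one_sample_rejected(self, catalog4):
        s = make_stream(catalog4, [(0, 0, 2.0)])
        with pytest.raises(ValueError):
            aggregate_samples(s, fps=10, frames_per_sample=100)


class TestBuildWindows:
    def test_stride1_count_on_single_phase(self, catalog4):
        s = alternating_stream(catalog4, total_s=660.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)  # 3-s samples
        ws = build_windows(samples, PhaseSchedule(), window_len=100, stride=1)
        assert ws.n_windows == samples.n_samples - 100 + 1
        assert (ws.labels == phase_of(0.0, PhaseSchedule())).all()

    def test_straddling_windows_dropped_and_counted(self, catalog4):
        sched = PhaseSchedule(day_len_s=150.0, night_len_s=150.0)
        s = alternating_stream(catalog4, total_s=900.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)
        ws = build_windows(samples, sched, window_len=20, stride=1)
        n_dropped = ws.n_candidates - ws.n_windows
        assert n_dropped > 0
        # labels agree with the phase at every constituent sample start
        for w in range(ws.n_windows):
            t0 = ws.start_s[w]
            starts = t0 + np.arange(20) * samples.sample_s
            assert (phase_of(starts, sched) == ws.labels[w]).all()

    def test_stride_equal_to_window_len_tiles(self, catalog4):
        s = alternating_stream(catalog4, total_s=660.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)
        ws = build_windows(samples, PhaseSchedule(), window_len=10, stride=10)
        assert ws.n_windows == samples.n_samples // 10

    def test_onehot_encoding_rows_are_unit_vectors(self, catalog4):
        s = alternating_stream(catalog4, total_s=330.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)
        ws = build_windows(samples, PhaseSchedule(), window_len=10, encoding="onehot")
        sums = ws.sequential.sum(axis=2)
        assert np.all((sums == 1.0) | (sums == 0.0))

    def test_too_few_samples_rejected(self, catalog4):
        s = alternating_stream(catalog4, total_s=60.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)
        with pytest.raises(ValueError):
            build_windows(samples, PhaseSchedule(), window_len=100)


class TestFlatten:
    def test_step_major_layout(self, catalog4):
        s = alternating_stream(catalog4, total_s=330.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)
        ws = build_windows(samples, PhaseSchedule(), window_len=2)
        flat = flatten_windows(ws)
        assert flat.shape[1] == 2 * 4
        w = 3
        for t in range(2):
            for b in range(4):
                assert flat[w, t * 4 + b] == ws.sequential[w, t, b]

    def test_flatten_reshape_roundtrip(self, catalog4):
        s = alternating_stream(catalog4, total_s=330.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)
        ws = build_windows(samples, PhaseSchedule(), window_len=5)
        flat = flatten_windows(ws)
        assert np.array_equal(flat.reshape(ws.sequential.shape), ws.sequential)


class TestDropBehaviors:
    def test_full_keep_is_identity(self, catalog4):
        s = alternating_stream(catalog4, total_s=330.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)
        out = drop_behaviors(samples, catalog4.names)
        assert np.array_equal(out.composition, samples.composition)
        assert np.array_equal(out.dominant, samples.dominant)

    def test_no_renormalization_after_drop(self, catalog4):
        s = make_stream(catalog4, [(0, 0, 6.0), (1, 6.0, 4.0)])
        samples = aggregate_samples(s, fps=10, frames_per_sample=100)
        out = drop_behaviors(samples, ["Twitch", "Walk"])
        assert out.catalog.size == 2
        assert out.composition[0].sum() == pytest.approx(0.4)

    def test_fully_dropped_sample_gets_reserved_dominant(self, catalog4):
        s = make_stream(catalog4, [(0, 0, 10.0)])
        samples = aggregate_samples(s, fps=10, frames_per_sample=100)
        out = drop_behaviors(samples, ["Dig"])
        assert out.dominant[0] == NO_DOMINANT
        assert out.composition[0].sum() == 0.0

    def test_empty_keep_rejected(self, catalog4):
        s = make_stream(catalog4, [(0, 0, 10.0)])
        samples = aggregate_samples(s, fps=10, frames_per_sample=100)
        with pytest.raises(ValueError):
            drop_behaviors(samples, [])


class TestPersistence:
    def test_save_load_roundtrip(self, catalog4, tmp_path):
        s = alternating_stream(catalog4, total_s=330.0)
        samples = aggregate_samples(s, fps=10, frames_per_sample=30)
        ws = build_windows(samples, PhaseSchedule(), window_len=10)
        path = tmp_path / "ws.npz"
        ws.save(path)
        back = type(ws).load(path)
        assert np.array_equal(back.sequential, ws.sequential)
        assert np.array_equal(back.labels, ws.labels)
        assert back.catalog == ws.catalog
        assert back.content_hash() == ws.content_hash()
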