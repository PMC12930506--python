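"""Layout sampling, community simulation and image rendering."""

import numpy as np
import pytest

from mimicomm.community import (
    NoiseModel,
    SampleLayout,
    arrange_central_senders,
    render_images,
    sample_random_layout,
    simulate_sample,
    timecourses_to_frame,
)
from mimicomm.signal_model import GateParams, STAR_DEFAULTS
from mimicomm.spatial import timepoint_columns

from _oracles import quad_reporter_trace


class TestRandomLayout:
    def test_empty_counts_give_empty_layout(self):
        layout = sample_random_layout({}, seed=0)
        assert len(layout) == 0

    def test_no_overlap_and_inside_droplet(self):
        layout = sample_random_layout(
            {"receiver": 100, "star_sender": 50, "trigger_sender": 50},
            droplet_radius=1.5,
            seed=1,
        )
        assert len(layout) == 200
        p, radii = layout.positions, layout.diameters / 2000.0
        # brute-force pairwise separation check
        for i in range(len(p)):
            d = np.sqrt(((p - p[i]) ** 2).sum(axis=1))
            d[i] = np.inf
            assert np.all(d >= radii + radii[i] - 1e-9)
        assert np.all(np.sqrt((p**2).sum(axis=1)) <= 1.5 - radii + 1e-9)
        counts = layout.counts()
        assert counts["receiver"] == 100 and counts["star_sender"] == 50

    @pytest.mark.parametrize("total", [28, 520])
    def test_paper_range_of_sample_sizes_is_generatable(self, total):
        n_r = total // 2
        n_s = (total - n_r) // 2
        layout = sample_random_layout(
            {"receiver": n_r, "star_sender": n_s, "trigger_sender": total - n_r - n_s},
            droplet_radius=1.5,
            seed=3,
        )
        assert len(layout) == total

    def test_deterministic_given_seed(self):
        a = sample_random_layout({"receiver": 30, "star_sender": 10}, seed=9)
        b = sample_random_layout({"receiver": 30, "star_sender": 10}, seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.dna_loads, b.dna_loads)
        assert np.array_equal(a.autofluorescence, b.autofluorescence)

    def test_infeasible_packing_reports_achievable_count(self):
        with pytest.raises(RuntimeError, match="achieved"):
            sample_random_layout(
                {"receiver": 500}, droplet_radius=0.3, seed=0, max_tries=5000
            )

    def test_load_distribution_matches_requested_cv(self):
        layout = sample_random_layout({"receiver": 4000}, droplet_radius=8.0, seed=2)
        loads = layout.dna_loads
        assert loads.mean() == pytest.approx(1.0, abs=0.03)
        assert loads.std() / loads.mean() == pytest.approx(0.35, abs=0.04)


class TestCentralArrangement:
    def test_senders_only_all_within_patch(self):
        layout = arrange_central_senders(n_senders=20, n_receivers=0, seed=1)
        r = np.sqrt((layout.positions**2).sum(axis=1))
        assert np.all(layout.labels == "dual_sender")
        assert np.all(r <= 0.5)

    def test_radial_partition_of_populations(self):
        layout = arrange_central_senders(seed=7)
        r = np.sqrt((layout.positions**2).sum(axis=1))
        senders = layout.labels == "dual_sender"
        assert np.all(r[senders] <= 0.5)
        assert np.all(r[~senders] > 0.5)
        assert np.all(r[~senders] <= 2.1)

    def test_farthest_receiver_reaches_droplet_edge(self):
        layout = arrange_central_senders(seed=7)
        r = np.sqrt((layout.positions**2).sum(axis=1))
        assert r[layout.labels == "receiver"].max() == pytest.approx(2.1, abs=0.15)

    def test_patch_must_fit_in_droplet(self):
        with pytest.raises(ValueError):
            arrange_central_senders(patch_radius=3.0, droplet_radius=2.1)


class TestSimulateSample:
    def test_no_senders_all_traces_equal_shared_background(self):
        layout = sample_random_layout(
            {"receiver": 12}, seed=4, load_cv=1e-12, autofl_sd=0.0
        )
        courses = simulate_sample(layout)
        mat = np.vstack([c.intensity for c in courses])
        assert np.allclose(mat, mat[0])

    def test_traces_nonnegative_and_nondecreasing(self):
        layout = sample_random_layout(
            {"receiver": 30, "star_sender": 15, "trigger_sender": 15}, seed=6
        )
        for c in simulate_sample(layout):
            assert np.all(c.intensity >= 0)
            assert np.all(np.diff(c.intensity) >= -1e-9)

    def test_single_pair_trace_matches_quadrature_oracle(self, gate):
        layout = SampleLayout(
            droplet_radius=1.5,
            positions=[[0.0, 0.0], [0.3, 0.0]],
            labels=["star_sender", "receiver"],
            diameters=[70.0, 70.0],
            dna_loads=[1.0, 1.3],
            autofluorescence=[0.0, 0.0],
        )
        trace = simulate_sample(layout, gate, escape_fraction=0.0)[1].intensity
        oracle = quad_reporter_trace(
            (0, 0), (0.3, 0), STAR_DEFAULTS, gate, 1.3, 300.0
        )
        assert trace[-1] == pytest.approx(oracle, rel=0.01)

    def test_receivers_near_dual_senders_activate_most(self):
        layout = arrange_central_senders(n_senders=15, n_receivers=60, seed=3)
        df = timecourses_to_frame(layout, simulate_sample(layout))
        recv = df[df.label == "receiver"]
        r = np.sqrt(recv.x_mm**2 + recv.y_mm**2)
        end = recv[timepoint_columns(df)[-1]]
        near = end[r < 1.0].mean()
        far = end[r > 1.6].mean()
        assert near > 2 * far

    def test_frame_schema(self):
        layout = sample_random_layout({"receiver": 5, "star_sender": 2}, seed=1)
        df = timecourses_to_frame(layout, simulate_sample(layout))
        assert list(df.columns[:6]) == [
            "mimic_id", "x_mm", "y_mm", "diameter_um", "label", "load",
        ]
        assert timepoint_columns(df) == [f"t{15 * i}" for i in range(21)]


class TestRenderImages:
    def test_empty_layout_renders_pure_noise(self):
        from mimicomm.imaging import detect_circles

        layout = sample_random_layout({}, droplet_radius=0.4, seed=0)
        channels = render_images(layout, np.zeros((0,)), seed=1)
        assert detect_circles(channels["brightfield"]) == []

    def test_nucleus_intensity_recovered_within_noise(self):
        layout = sample_random_layout({"receiver": 10}, droplet_radius=0.5, seed=2)
        value = 800.0
        channels = render_images(layout, np.full(len(layout), value), seed=2)
        img = channels["sfgfp"]
        half = 0.5 + 0.1  # droplet + margin, mm
        for (x, y), d in zip(layout.positions, layout.diameters):
            cx, cy = (x + half) * 250, (y + half) * 250
            rr = 0.4 * d / 2.0 / 4.0
            yy, xx = np.mgrid[int(cy - rr):int(cy + rr), int(cx - rr):int(cx + rr)]
            m = (xx - cx) ** 2 + (yy - cy) ** 2 <= rr**2
            mean = img[yy[m], xx[m]].mean() - 100.0
            assert mean == pytest.approx(value, rel=0.05)

    def test_deterministic_given_seed(self):
        layout = sample_random_layout({"receiver": 5}, droplet_radius=0.4, seed=3)
        a = render_images(layout, np.full(5, 100.0), seed=11)
        b = render_images(layout, np.full(5, 100.0), seed=11)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_noise_model_can_be_disabled(self):
        layout = sample_random_layout({"receiver": 3}, droplet_radius=0.4, seed=3)
        a = render_images(layout, np.zeros(3), noise=NoiseModel(enabled=False), seed=1)
        b = render_images(layout, np.zeros(3), noise=NoiseModel(enabled=False), seed=2)
        assert np.array_equal(a["brightfield"], b["brightfield"])

    def test_invalid_pixel_size_rejected(self):
        layout = sample_random_layout({"receiver": 2}, droplet_radius=0.4, seed=0)
        with pytest.raises(ValueError):
            render_images(layout, np.zeros(2), pixel_size=0.0)
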