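"""Local densities, correlation scans, fold changes, LOESS, positional nulls."""

import numpy as np
import pandas as pd
import pytest

from mimicomm.spatial import (
    density_table,
    endpoint_column,
    fold_change,
    local_density,
    loess_surface,
    pearson,
    positional_independence,
    radius_scan,
)

from _oracles import brute_force_density


def make_sample(positions, labels, values, loads=None):
    """Minimal mimic-record frame with a single end point column."""
    positions = np.asarray(positions, dtype=float)
    df = pd.DataFrame(
        {
            "mimic_id": np.arange(len(positions)),
            "x_mm": positions[:, 0],
            "y_mm": positions[:, 1],
            "diameter_um": 70.0,
            "label": labels,
            "load": loads if loads is not None else 1.0,
            "t300": values,
        }
    )
    return df


class TestLocalDensity:
    def test_counts_and_area_example(self):
        # senders at 100, 500, 700 um; radius 600 um captures two of them
        recv = pd.Series({"mimic_id": 0, "x_mm": 0.0, "y_mm": 0.0})
        sample = make_sample(
            [[0, 0], [0.1, 0], [0.5, 0], [0.7, 0]],
            ["receiver", "star_sender", "star_sender", "star_sender"],
            0.0,
        )
        d = local_density(recv, sample, 600.0, "star_sender")
        assert d == pytest.approx(2 / (np.pi * 0.6**2), abs=1e-4)
        assert d == pytest.approx(1.768, abs=2e-3)

    def test_no_members_give_zero(self):
        recv = pd.Series({"mimic_id": 0, "x_mm": 0.0, "y_mm": 0.0})
        sample = make_sample([[0, 0]], ["receiver"], 0.0)
        assert local_density(recv, sample, 600.0, "star_sender") == 0.0

    def test_doubling_radius_quarters_density(self):
        recv = pd.Series({"mimic_id": 0, "x_mm": 0.0, "y_mm": 0.0})
        sample = make_sample(
            [[0, 0], [0.1, 0]], ["receiver", "star_sender"], 0.0
        )
        d1 = local_density(recv, sample, 400.0, "star_sender")
        d2 = local_density(recv, sample, 800.0, "star_sender")
        assert d2 == pytest.approx(d1 / 4)

    def test_zero_radius_rejected(self):
        recv = pd.Series({"mimic_id": 0, "x_mm": 0.0, "y_mm": 0.0})
        sample = make_sample([[0, 0]], ["receiver"], 0.0)
        with pytest.raises(ValueError):
            local_density(recv, sample, 0.0, "receiver")

    def test_vectorised_table_matches_brute_force(self):
        rng = np.random.default_rng(0)
        n = 120
        pos = rng.uniform(-1.2, 1.2, size=(n, 2))
        labels = rng.choice(["receiver", "star_sender", "trigger_sender"], size=n)
        sample = make_sample(pos, labels, rng.uniform(size=n))
        tab = density_table(sample, 450.0)
        recv_pos = pos[labels == "receiver"]
        for k, (x, y) in enumerate(recv_pos):
            for pop in ("star_sender", "trigger_sender", "receiver"):
                expected = brute_force_density(
                    (x, y), pos[labels == pop], 450.0, exclude_self=(pop == "receiver")
                )
                assert tab[f"density_{pop}"].iloc[k] == pytest.approx(expected)

    def test_edge_correction_shrinks_area_near_boundary(self):
        sample = make_sample(
            [[1.4, 0.0], [1.3, 0.0]], ["receiver", "star_sender"], 0.0
        )
        plain = density_table(sample, 600.0)
        corr = density_table(sample, 600.0, edge_correction=True, droplet_radius=1.5)
        assert corr["density_star_sender"].iloc[0] > plain["density_star_sender"].iloc[0]


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_value_exact(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_flagged_undefined(self):
        assert np.isnan(pearson([1, 2, 3], [5, 5, 5]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestRadiusScan:
    def _linear_sample(self, r0=600.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 80
        pos = rng.uniform(-1.2, 1.2, size=(n, 2))
        labels = np.array(
            ["receiver"] * 40 + ["star_sender"] * 25 + ["trigger_sender"] * 15,
            dtype=object,
        )
        sample = make_sample(pos, labels, 0.0)
        dens = density_table(sample, r0)
        vals = np.zeros(n)
        vals[labels == "receiver"] = 3.0 * dens["density_star_sender"].to_numpy() + 1.0
        sample["t300"] = vals
        return sample

    def test_exact_linear_dependence_gives_unit_correlation(self):
        sample = self._linear_sample()
        scan = radius_scan([sample], radii=np.array([300.0, 600.0, 900.0]))
        i = 1  # the construction radius
        assert scan.mean_r["star_sender"][i] == pytest.approx(1.0, abs=1e-12)
        assert scan.argmax_um["star_sender"] == 600.0

    def test_permuted_values_decorrelate(self):
        sample = self._linear_sample()
        rng = np.random.default_rng(1)
        recv = sample["label"] == "receiver"
        sample.loc[recv, "t300"] = rng.permutation(sample.loc[recv, "t300"].to_numpy())
        scan = radius_scan([sample], radii=np.array([600.0]))
        assert abs(scan.mean_r["star_sender"][0]) < 2 / np.sqrt(recv.sum())

    def test_invariant_under_rigid_motion(self):
        sample = self._linear_sample()
        scan_a = radius_scan([sample])
        th = 0.61
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = sample.copy()
        xy = moved[["x_mm", "y_mm"]].to_numpy() @ R.T + np.array([0.7, -1.3])
        moved[["x_mm", "y_mm"]] = xy
        scan_b = radius_scan([moved])
        for pop in scan_a.mean_r:
            assert np.allclose(
                scan_a.mean_r[pop], scan_b.mean_r[pop], atol=1e-9, equal_nan=True
            )

    def test_degenerate_samples_rejected(self):
        sample = make_sample([[0, 0], [0.1, 0]], ["receiver", "receiver"], 1.0)
        with pytest.raises(ValueError):
            radius_scan([sample])


class TestFoldChange:
    def _baseline(self, values):
        return make_sample(
            [[i * 0.2, 0] for i in range(len(values))],
            ["receiver"] * len(values),
            values,
        )

    def test_receiver_at_baseline_mean_is_unit_fold(self):
        base = self._baseline([10.0, 10.0, 10.0])
        assert fold_change([10.0], [base])[0] == pytest.approx(1.0)

    def test_arithmetic_example(self):
        base = self._baseline([10.0, 10.0, 10.0])
        assert fold_change([35.0], [base])[0] == pytest.approx(3.5)

    def test_no_sender_sample_self_normalises_to_unit_mean(self):
        vals = [8.0, 12.0, 9.0, 11.0]
        base = self._baseline(vals)
        assert fold_change(vals, [base]).mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = self._baseline([5.0, 15.0, 10.0])
        f1 = fold_change([20.0, 30.0], [base])
        base_scaled = self._baseline([50.0, 150.0, 100.0])
        f2 = fold_change([200.0, 300.0], [base_scaled])
        assert np.allclose(f1, f2)

    def test_zero_baseline_rejected(self):
        base = self._baseline([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            fold_change([1.0], [base])

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            fold_change([1.0], [])


class TestLoessSurface:
    def test_constant_response_gives_flat_surface(self):
        rng = np.random.default_rng(0)
        S, T = rng.uniform(0, 10, 50), rng.uniform(0, 5, 50)
        _, _, surf = loess_surface(S, T, np.full(50, 3.3))
        assert np.allclose(surf, 3.3)

    def test_planted_plane_recovered_at_interior_nodes(self):
        rng = np.random.default_rng(1)
        S, T = rng.uniform(0, 10, 300), rng.uniform(0, 5, 300)
        z = 2.0 + 0.8 * S + 1.5 * T
        sg, tg, surf = loess_surface(S, T, z, grid=15, span=0.4)
        truth = 2.0 + 0.8 * sg[None, :] + 1.5 * tg[:, None]
        interior = np.s_[3:-3, 3:-3]
        rel = np.abs(surf[interior] / truth[interior] - 1)
        assert rel.max() < 0.02

    def test_collinear_densities_rejected(self):
        S = np.linspace(0, 10, 40)
        with pytest.raises(ValueError):
            loess_surface(S, np.zeros(40), S)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_surface([1, 2], [1, 2], [1, 2])

    def test_invalid_span_rejected(self):
        rng = np.random.default_rng(2)
        S, T = rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)
        with pytest.raises(ValueError):
            loess_surface(S, T, S + T, span=1.5)


class TestPositionalIndependence:
    def test_value_equal_to_x_gives_unit_correlation(self):
        pos = np.column_stack([np.linspace(-1, 1, 20), np.zeros(20)])
        sample = make_sample(pos, ["receiver"] * 20, pos[:, 0])
        r_x, r_y = positional_independence(sample)
        assert r_x == pytest.approx(1.0)
        assert np.isnan(r_y)  # y constant -> undefined flag

    def test_radial_structure_is_axis_null(self):
        # strong radial gradient, rotationally symmetric: both axis
        # correlations stay near zero despite structure
        rng = np.random.default_rng(3)
        th = rng.uniform(0, 2 * np.pi, 400)
        r = np.sqrt(rng.uniform(0, 1, 400)) * 2.0
        pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
        sample = make_sample(pos, ["receiver"] * 400, np.exp(-r))
        r_x, r_y = positional_independence(sample)
        assert abs(r_x) < 0.1 and abs(r_y) < 0.1

    def test_too_few_receivers_rejected(self):
        sample = make_sample([[0, 0]], ["receiver"], 1.0)
        with pytest.raises(ValueError):
            positional_independence(sample)

    def test_endpoint_column_detection(self):
        sample = make_sample([[0, 0]], ["receiver"], 1.0)
        sample["t15"] = 0.5
        assert endpoint_column(sample) == "t300"
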