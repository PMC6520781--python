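import numpy as np
import pytest

from pidquant import (
    LabelMask,
    membrane_distance_histogram,
    pearson_r2,
    sweep_distance,
    true_extranuclear,
)

from conftest import spotset, square_mask


def disk_mask(shape, disks, pixel_size_um, kind):
    labels = np.zeros(shape, dtype=np.int64)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for lab, cy, cx, r in disks:
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        labels[inside & (labels == 0)] = lab
    return LabelMask(labels, pixel_size_um=pixel_size_um, kind=kind)


class TestPearsonR2:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_zero_covariance_pair(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])  # orthogonal to x by construction
        assert np.dot(x - x.mean(), y - y.mean()) == 0
        assert pearson_r2(x, y) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_value(self):
        # cov = 4.5, var_x = 5, var_y = 4.75 (deviation sums) -> 4.5²/(5·4.75)
        assert pearson_r2([1, 2, 3, 4], [1, 2, 2, 4]) == pytest.approx(
            4.5**2 / (5 * 4.75)
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r2([1, 1, 1], [1, 2, 3])

    def test_affine_invariance(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.5, size=20)
        assert pearson_r2(3 * x - 7, y) == pytest.approx(pearson_r2(x, -2 * y + 1))


class TestTrueExtranuclear:
    def setup_method(self):
        # two nuclei inside larger same-numbered whole-cell squares
        self.nuclei = square_mask(
            (40, 40), [(1, 10, 16, 10, 16), (2, 24, 30, 24, 30)], pixel_size_um=0.5
        )
        self.cells = square_mask(
            (40, 40),
            [(1, 6, 20, 6, 20), (2, 20, 34, 20, 34)],
            pixel_size_um=0.5,
            kind="whole_cell",
        )

    def test_all_nuclear_spots_give_zero_truth(self):
        spots = spotset([(12.0, 12.0), (26.0, 26.0)])
        out = true_extranuclear(spots, self.nuclei, self.cells)
        assert (out["truth"] == 0).all()

    def test_subtraction(self):
        spots = spotset([(12.0, 12.0)] * 5 + [(8.0, 12.0)] * 2)  # 7 in cell, 5 in nucleus
        out = true_extranuclear(spots, self.nuclei, self.cells)
        row = out.set_index("cell_id").loc[1]
        assert (row["n_cell"], row["n_nucleus"], row["truth"]) == (7, 5, 2)

    def test_spots_outside_cells_excluded(self):
        spots = spotset([(2.0, 36.0), (37.0, 2.0)])
        out = true_extranuclear(spots, self.nuclei, self.cells)
        assert out["n_cell"].sum() == 0

    def test_uncontained_nucleus_rejected(self):
        bad_cells = square_mask(
            (40, 40), [(1, 11, 15, 11, 15)], pixel_size_um=0.5, kind="whole_cell"
        )  # smaller than nucleus 1
        with pytest.raises(ValueError, match="not contained"):
            true_extranuclear(spotset([]), self.nuclei, bad_cells)


class TestSweepDistance:
    def _sample(self, seed, scale=1.0):
        """One toy sample: interior square cells with spots planted so the
        estimate at any distance >= 2 μm equals the truth."""
        rng = np.random.default_rng(seed)
        nuclei = square_mask(
            (60, 60), [(1, 10, 18, 10, 18), (2, 36, 44, 36, 44)], pixel_size_um=0.5
        )
        cells = square_mask(
            (60, 60),
            [(1, 6, 22, 6, 22), (2, 32, 48, 32, 48)],
            pixel_size_um=0.5,
            kind="whole_cell",
        )
        pts = [(14.0, 14.0)] * int(rng.poisson(8 * scale)) + [
            (14.0, 20.0)
        ] * int(rng.poisson(3 * scale))
        return spotset(pts), nuclei, cells

    def test_estimate_equal_truth_gives_r2_one(self):
        samples = [self._sample(s, scale=1 + s) for s in range(5)]
        res = sweep_distance(samples, candidate_d_um=(2, 4, 6, 8))
        for d, r2 in res.r2_per_d.items():
            assert r2 == pytest.approx(1.0)
        assert res.optimal_d_um == 2.0  # ties resolve toward the smaller d
        assert res.n_units == 5

    def test_default_candidates(self):
        samples = [self._sample(s, scale=1 + s) for s in range(4)]
        res = sweep_distance(samples)
        assert res.candidate_d_um == (2.0, 4.0, 6.0, 8.0)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            sweep_distance([self._sample(0)], unit="sample")

    def test_planted_offset_recovered(self):
        # membranes planted exactly 4 μm from every nucleus, no stray
        # particles: estimates at d = 4, 6, 8 all equal the truth (r² = 1),
        # d = 2 truncates the annulus, so the tie-break must return 4
        from pidquant import TissueSimParams, simulate_field
        from pidquant.spot_detection import SpotSet

        samples = []
        for i, s in enumerate(np.geomspace(0.5, 2.0, 6)):
            p = TissueSimParams(
                n_cells=60,
                field_shape=(640, 640),
                seed=300 + i,
                membrane_offset_um=(4.0, 0.0),
                stray_rate_per_um2=0.0,
                nuclear_counts=(10 * s, 5.0),
                extranuclear_counts=(3 * s, 5.0),
            )
            _, nuclei, cells, truth = simulate_field(p)
            spots = SpotSet(
                truth.spots["x_px"].to_numpy(),
                truth.spots["y_px"].to_numpy(),
                np.ones(len(truth.spots)),
            )
            samples.append((spots, nuclei, cells))
        res = sweep_distance(samples)
        assert res.r2_per_d[4.0] == pytest.approx(1.0)
        assert res.r2_per_d[2.0] < 1.0
        assert res.optimal_d_um == 4.0


class TestMembraneDistanceHistogram:
    def test_concentric_disks_distance(self):
        # nucleus radius 8 px, cell radius 16 px, 0.5 μm/px -> 4 μm offset
        nuclei = disk_mask((64, 64), [(1, 32, 32, 8)], 0.5, "nucleus")
        cells = disk_mask((64, 64), [(1, 32, 32, 16)], 0.5, "whole_cell")
        hist = membrane_distance_histogram(nuclei, cells, bin_edges_um=(1, 3, 5, 7, 9))
        assert hist.per_cell_um.loc[1] == pytest.approx(4.0, abs=0.5)
        assert hist.counts.tolist() == [0, 1, 0, 0]

    def test_identical_cells_occupy_single_bin_and_total_is_conserved(self):
        disks_n = [(k, 16 + 30 * (k - 1) // 3 * 0 + 16, 16 + 30 * ((k - 1) % 3), 5) for k in (1, 2, 3)]
        nuclei = disk_mask((96, 96), [(k, 30, 16 + 30 * (k - 1), 5) for k in (1, 2, 3)], 0.5, "nucleus")
        cells = disk_mask((96, 96), [(k, 30, 16 + 30 * (k - 1), 9) for k in (1, 2, 3)], 0.5, "whole_cell")
        hist = membrane_distance_histogram(nuclei, cells, bin_edges_um=(1, 3, 5, 7, 9))
        assert hist.counts.sum() == 3
        assert (hist.counts > 0).sum() == 1
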