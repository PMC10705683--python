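"""ECM field initialization, orientation remodeling and stiffening."""

import numpy as np
import pytest
from scipy import stats

from tacsim import (
    RemodelParams,
    init_random_field,
    read_grid,
    remodel_orientation,
    stiffen_for_growth,
    stiffen_for_migration,
    write_grid_hdf5,
    write_grid_text,
)
from tacsim.ecm import read_grid_hdf5, read_grid_text

from conftest import uniform_grid


class TestInitRandomField:
    def test_orientations_are_unit_vectors(self, small_grid):
        norms = np.linalg.norm(small_grid.orientation, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_stiffness_uniform_at_xi0(self):
        g = init_random_field((10, 10), 4.0, xi0=1.0, seed=3)
        assert np.all(g.stiffness == 1.0)

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError):
            init_random_field((10, 10), 0.0, seed=1)
        with pytest.raises(ValueError):
            init_random_field((10, 10), -4.0, seed=1)

    def test_angle_distribution_matches_two_uniform_construction(self):
        """Fibril angles must follow the law of atan2 of two independent
        uniforms on [-1, 1] (mass concentrated toward the square's
        diagonals), checked by a chi-square test against a brute-force
        sampled reference at the 1% level."""
        g = init_random_field((100, 100), 4.0, seed=42)
        h = g.orientation.reshape(-1, 2)
        angles = np.arctan2(h[:, 1], h[:, 0]) % np.pi  # fold: fibrils axial
        nbins = 18
        # independent oracle: direct sampling of the stated construction
        oracle_rng = np.random.default_rng(999)
        eps = oracle_rng.uniform(-1.0, 1.0, size=(1_000_000, 2))
        ref = np.arctan2(eps[:, 1], eps[:, 0]) % np.pi
        edges = np.linspace(0.0, np.pi, nbins + 1)
        obs, _ = np.histogram(angles, bins=edges)
        ref_counts, _ = np.histogram(ref, bins=edges)
        expected = ref_counts / ref_counts.sum() * obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=nbins - 1)
        assert p > 0.01

    def test_seed_reproducibility(self):
        a = init_random_field((15, 15), 4.0, seed=5)
        b = init_random_field((15, 15), 4.0, seed=5)
        assert np.array_equal(a.orientation, b.orientation)


class TestRemodelOrientation:
    def test_beta_zero_is_identity(self, small_grid):
        pullers = [(np.array([40.0, 40.0]), np.array([0.0, 1.0]))]
        pushers = [(np.array([20.0, 20.0]), np.array([1.0, 0.0]))]
        out = remodel_orientation(small_grid, pushers, pullers, 8.0, 0.0)
        assert np.array_equal(out.orientation, small_grid.orientation)

    def test_beta_one_single_puller_dominates(self, small_grid):
        u = np.array([0.0, 1.0])
        out = remodel_orientation(small_grid, [], [(np.array([40.0, 40.0]), u)], 8.0, 1.0)
        node = out.orientation[10, 10]  # node at the puller center
        assert np.isclose(abs(node @ u), 1.0, atol=1e-9)

    def test_half_mix_of_orthogonal_directions(self):
        """beta=0.5, h=(1,0), single puller along (0,1): the mixed
        orientation is the normalized average, (sqrt2/2, sqrt2/2)."""
        g = uniform_grid(direction=(1.0, 0.0))
        out = remodel_orientation(g, [], [(np.array([40.0, 40.0]), np.array([0.0, 1.0]))], 8.0, 0.5)
        expected = np.array([np.sqrt(2) / 2, np.sqrt(2) / 2])
        assert np.allclose(out.orientation[10, 10], expected, atol=1e-12)

    def test_antiparallel_contribution_sign_aligned(self):
        """A pull direction opposing the current fibril axis reinforces it
        (nematic flip) instead of cancelling it."""
        g = uniform_grid(direction=(1.0, 0.0))
        out = remodel_orientation(g, [], [(np.array([40.0, 40.0]), np.array([-1.0, 0.0]))], 8.0, 0.5)
        assert np.allclose(out.orientation[10, 10], [1.0, 0.0], atol=1e-12)

    def test_degenerate_cancellation_keeps_previous(self):
        """beta=1 with two exactly opposing (post-alignment orthogonal)
        contributions that sum to zero must keep the old orientation."""
        g = uniform_grid(direction=(1.0, 0.0))
        # two pullers through the same node along +y and -y: after nematic
        # alignment to h=(1,0) both have dot 0, signs +1, so they cancel
        pullers = [
            (np.array([40.0, 40.0]), np.array([0.0, 1.0])),
            (np.array([40.0, 40.0]), np.array([0.0, -1.0])),
        ]
        out = remodel_orientation(g, [], pullers, 8.0, 1.0)
        assert np.allclose(out.orientation[10, 10], [1.0, 0.0])

    def test_unit_norm_preserved_everywhere(self, small_grid, rng):
        pushers = [(rng.uniform(10, 70, 2), rng.normal(size=2)) for _ in range(5)]
        pullers = [(rng.uniform(10, 70, 2), rng.normal(size=2)) for _ in range(5)]
        out = remodel_orientation(small_grid, pushers, pullers, 8.0, 0.7)
        assert np.allclose(np.linalg.norm(out.orientation, axis=-1), 1.0, atol=1e-9)

    def test_locality_beyond_interaction_disk(self, small_grid):
        """Nodes farther than R+3*dx from every cell are bitwise unchanged."""
        center = np.array([40.0, 40.0])
        out = remodel_orientation(small_grid, [(center, np.array([1.0, 0.0]))], [], 8.0, 1.0)
        coords = small_grid.node_coords()
        far = np.linalg.norm(coords - center, axis=-1) > 8.0 + 3 * 4.0
        assert np.array_equal(out.orientation[far], small_grid.orientation[far])


class TestStiffenForMigration:
    def test_weighted_gain_under_cell(self, small_grid):
        """Node at d = 0.5 R from the pulling cell gains 3*beta*delta_xi."""
        p = RemodelParams(beta=0.5, delta_xi=4e-5)
        center = np.array([44.0, 40.0])  # node (10,10) at distance 4 = 0.5R
        out = stiffen_for_migration(small_grid, center, 8.0, p)
        gain = out.stiffness[10, 10] - small_grid.stiffness[10, 10]
        assert np.isclose(gain, 3 * 0.5 * 4e-5, atol=1e-15)

    def test_annulus_weights(self):
        g = uniform_grid(shape=(41, 41))
        p = RemodelParams(beta=1.0, delta_xi=1.0, xi_max=1e9)
        center = np.array([80.0, 80.0])  # node (20, 20)
        out = stiffen_for_migration(g, center, 8.0, p)
        gains = out.stiffness - g.stiffness
        assert gains[21, 20] == 3.0  # d = 4 <= R
        assert gains[20, 22] == 3.0  # d = 8 = R (inclusive)
        assert gains[22, 21] == 2.0  # d = sqrt(80) ~ 8.94 in (8, 10]
        assert gains[23, 20] == 1.0  # d = 12 in (10, 12]
        assert gains[23, 21] == 0.0  # d ~ 12.6 beyond the outer ring
        assert gains[20, 20] == 0.0  # exact center excluded (0 < d)

    def test_far_nodes_unchanged(self, small_grid, remodel_params):
        out = stiffen_for_migration(small_grid, [40.0, 40.0], 8.0, remodel_params)
        coords = small_grid.node_coords()
        far = np.linalg.norm(coords - [40.0, 40.0], axis=-1) > 12.0
        assert np.array_equal(out.stiffness[far], small_grid.stiffness[far])

    def test_cap_at_xi_max(self):
        g = uniform_grid(xi0=1.0)
        g.stiffness[:] = 500.0
        out = stiffen_for_migration(g, [40.0, 40.0], 8.0, RemodelParams())
        assert np.all(out.stiffness == 500.0)


class TestStiffenForGrowth:
    def test_enclosed_nodes_receive_no_ring_gain(self):
        """The annulus weight is zero under the cell body; with nothing to
        redistribute (enclosed stiffness zero) enclosed nodes are untouched."""
        g = uniform_grid(shape=(41, 41), xi0=1.0)
        g.stiffness[:] = 0.0
        p = RemodelParams(beta=1.0, delta_xi=1.0, xi_max=1e9, xi0=1.0)
        out = stiffen_for_growth(g, [80.0, 80.0], 8.0, p)
        gains = out.stiffness - g.stiffness
        assert gains[20, 20] == 0.0  # center
        assert gains[21, 20] == 0.0  # d = 4 <= R: enclosed
        assert gains[22, 21] == 3.0  # d ~ 8.94 in (8, 10]
        assert gains[23, 20] == 2.0  # d = 12 in (10, 12]
        assert gains[23, 21] == 1.0  # d ~ 12.65 in (12, 14]
        assert gains[24, 20] == 0.0  # d = 16 beyond the outer ring

    def test_no_enclosed_nodes_gives_pure_delta_xi(self):
        """A cell too small to enclose any node stiffens its innermost ring
        by exactly 3*delta_xi at beta=1 (dzeta = 0)."""
        g = uniform_grid(shape=(21, 21), xi0=1.0)
        p = RemodelParams(beta=1.0, delta_xi=1e-3, xi_max=1e9)
        center = np.array([42.0, 42.0])  # off-node; R=1.5 encloses nothing
        out = stiffen_for_growth(g, center, 1.5, p)
        gains = out.stiffness - g.stiffness
        # node (10,10) at distance sqrt(8) ~ 2.83 um: within (R, R+dx/2]
        assert np.isclose(gains[10, 10], 3e-3)

    def test_redistribution_conserves_total_stiffness(self, small_grid):
        """With delta_xi = 0 the displaced enclosed stiffness reappears on
        the ring: total field stiffness is conserved (independent oracle:
        plain sums before/after)."""
        p = RemodelParams(beta=0.5, delta_xi=0.0, xi_max=1e12)
        before = small_grid.stiffness.sum()
        out = stiffen_for_growth(small_grid, [40.0, 40.0], 8.0, p)
        assert np.isclose(out.stiffness.sum(), before, rtol=1e-12)
        # and the enclosed nodes were actually displaced
        coords = small_grid.node_coords()
        enclosed = np.linalg.norm(coords - [40.0, 40.0], axis=-1) <= 8.0
        assert np.all(out.stiffness[enclosed] == 0.0)

    def test_repeat_capture_is_noop(self, small_grid):
        p = RemodelParams(beta=0.5, delta_xi=0.0, xi_max=1e12)
        once = stiffen_for_growth(small_grid, [40.0, 40.0], 8.0, p)
        twice = stiffen_for_growth(once, [40.0, 40.0], 8.0, p)
        assert np.array_equal(once.stiffness, twice.stiffness)

    def test_cap_at_xi_max(self):
        g = uniform_grid(shape=(41, 41))
        g.stiffness[:] = 499.9999
        out = stiffen_for_growth(g, [80.0, 80.0], 8.0, RemodelParams(beta=1.0, delta_xi=1.0))
        assert np.all(out.stiffness <= 500.0)


class TestGridIO:
    def test_text_round_trip(self, small_grid, tmp_path):
        path = tmp_path / "grid.txt"
        write_grid_text(small_grid, path, step=3)
        back = read_grid_text(path)
        assert back.spacing == small_grid.spacing
        assert np.array_equal(back.origin, small_grid.origin)
        assert np.allclose(back.orientation, small_grid.orientation, atol=1e-12)
        assert np.allclose(back.stiffness, small_grid.stiffness, atol=1e-12)

    def test_hdf5_round_trip(self, small_grid, tmp_path):
        path = tmp_path / "grid.h5"
        write_grid_hdf5(small_grid, path)
        back = read_grid_hdf5(path)
        assert np.array_equal(back.orientation, small_grid.orientation)
        assert np.array_equal(back.stiffness, small_grid.stiffness)

    def test_dispatch_by_suffix(self, small_grid, tmp_path):
        write_grid_text(small_grid, tmp_path / "g.txt")
        write_grid_hdf5(small_grid, tmp_path / "g.h5")
        assert read_grid(tmp_path / "g.txt").shape == small_grid.shape
        assert read_grid(tmp_path / "g.h5").shape == small_grid.shape
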