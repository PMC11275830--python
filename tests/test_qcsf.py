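"""Tests for the grid posterior and EIG-based adaptive stimulus selection."""

import math

import numpy as np
import pytest

from csfpolar import CSFParams, make_stimulus_space
from csfpolar.csf_core import DEFAULT_PSYCHOMETRIC
from csfpolar.qcsf import (
    PosteriorGrid,
    StimulusLikelihoodTable,
    expected_information_gain,
    select_next_stimulus,
    update_posterior,
)
from csfpolar.synthetic_data import simulate_session


def two_node_grid(w0=0.5):
    """Minimal 2 x 1 x 1 grid for hand-computable Bayes updates."""
    return PosteriorGrid(
        np.array([1.2, 2.0]), np.array([0.2]), np.array([2.9]),
        np.array([w0, 1.0 - w0]),
    )


def binary_entropy(p):
    out = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            out -= q * math.log2(q)
    return out


class TestStimulusSpace:
    def test_default_endpoints(self, default_space):
        assert default_space.contrasts[0] == pytest.approx(0.001)
        assert default_space.contrasts[-1] == pytest.approx(1.0)
        assert default_space.sfs[0] == pytest.approx(0.5)
        assert default_space.sfs[-1] == pytest.approx(16.0)
        assert default_space.contrasts.size == 60
        assert default_space.sfs.size == 12

    def test_log_even_spacing_ratio(self, default_space):
        ratios = default_space.contrasts[1:] / default_space.contrasts[:-1]
        assert np.allclose(ratios, (1 / 0.001) ** (1 / 59), rtol=1e-12)

    def test_two_levels_are_endpoints_only(self):
        space = make_stimulus_space(n_contrasts=2, c_range=(0.001, 1.0))
        assert np.allclose(space.contrasts, [0.001, 1.0])

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            make_stimulus_space(c_range=(0.0, 1.0))
        with pytest.raises(ValueError):
            make_stimulus_space(n_contrasts=1)


class TestUpdatePosterior:
    def test_flat_likelihood_leaves_posterior_unchanged(self, small_grid):
        # zero contrast: p = guess rate for every node
        out = update_posterior(small_grid, sf=2.0, contrast=0.0, response=1)
        assert np.allclose(out.weights, small_grid.weights, atol=1e-15)

    def test_matches_hand_computed_two_node_bayes(self):
        grid = two_node_grid(0.3)
        like = grid.response_probabilities(2.0, 0.05)
        post = update_posterior(grid, 2.0, 0.05, 1)
        manual = np.array([0.3, 0.7]) * like
        manual /= manual.sum()
        assert np.allclose(post.weights, manual, atol=1e-12)
        post0 = update_posterior(grid, 2.0, 0.05, 0)
        manual0 = np.array([0.3, 0.7]) * (1 - like)
        manual0 /= manual0.sum()
        assert np.allclose(post0.weights, manual0, atol=1e-12)

    def test_correct_responses_raise_sensitivity_estimate(self, small_grid):
        grid = small_grid
        means = [grid.mean_log10()[0]]
        for _ in range(30):
            grid = update_posterior(grid, sf=8.0, contrast=0.02, response=1)
            means.append(grid.mean_log10()[0])
        assert np.all(np.diff(means) >= -1e-12)
        assert means[-1] > means[0]

    def test_normalization_preserved_over_many_updates(self, rng):
        grid = PosteriorGrid.uniform(shape=(6, 6, 4))
        for _ in range(10_000):
            sf = float(rng.uniform(0.5, 16.0))
            c = float(rng.uniform(0.001, 1.0))
            grid = update_posterior(grid, sf, c, int(rng.integers(0, 2)))
        assert abs(grid.weights.sum() - 1.0) < 1e-9


class TestExpectedInformationGain:
    def test_point_mass_posterior_has_zero_eig(self, default_space):
        w = np.zeros(2)
        w[0] = 1.0
        grid = PosteriorGrid(np.array([1.2, 2.0]), np.array([0.2]),
                             np.array([2.9]), w)
        for sf in (0.5, 2.0, 16.0):
            assert expected_information_gain(grid, sf, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_matches_two_outcome_enumeration(self):
        """EIG equals the brute-force enumeration over both outcomes."""
        grid = two_node_grid(0.4)
        sf, c = 2.0, 0.04
        like = grid.response_probabilities(sf, c)
        w = grid.weights
        p1 = float(w @ like)
        expected = (
            binary_entropy(w[0])
            - p1 * binary_entropy(w[0] * like[0] / p1)
            - (1 - p1) * binary_entropy(w[0] * (1 - like[0]) / (1 - p1))
        )
        assert expected_information_gain(grid, sf, c) == pytest.approx(expected, abs=1e-10)

    def test_batched_table_matches_single_stimulus_path(self, small_grid, default_space):
        table = StimulusLikelihoodTable(small_grid, default_space)
        eig = table.eig_all(small_grid.weights)
        for idx in (0, 173, 500, 719):
            sf, c = default_space.stimulus(idx)
            assert eig[idx] == pytest.approx(
                expected_information_gain(small_grid, sf, c), abs=1e-10
            )

    def test_bounded_by_posterior_entropy_on_random_grids(self, small_grid, default_space, rng):
        table = StimulusLikelihoodTable(small_grid, default_space)
        for _ in range(5):
            w = rng.dirichlet(np.ones(small_grid.n_nodes) * 0.2)
            eig = table.eig_all(w)
            h = float(-(w[w > 0] * np.log2(w[w > 0])).sum())
            assert np.all(eig >= -1e-12)
            assert np.all(eig <= h + 1e-9)


class TestSelectNextStimulus:
    def test_point_mass_tie_breaks_to_lowest_sf_then_contrast(self, default_space):
        w = np.zeros(2)
        w[1] = 1.0
        grid = PosteriorGrid(np.array([1.2, 2.0]), np.array([0.2]),
                             np.array([2.9]), w)
        sf, c = select_next_stimulus(grid, default_space)
        assert sf == pytest.approx(default_space.sfs[0])
        assert c == pytest.approx(default_space.contrasts[0])

    def test_attains_exhaustive_table_maximum(self, small_grid, default_space):
        table = StimulusLikelihoodTable(small_grid, default_space)
        eig = table.eig_all(small_grid.weights)
        sf, c = select_next_stimulus(small_grid, default_space, table=table)
        idx = np.argmax(eig)
        assert (sf, c) == default_space.stimulus(int(idx))

    def test_selected_beats_space_corners(self, small_grid, default_space):
        table = StimulusLikelihoodTable(small_grid, default_space)
        eig = table.eig_all(small_grid.weights)
        best = eig.max()
        n_c = default_space.contrasts.size
        corners = [0, n_c - 1, (default_space.sfs.size - 1) * n_c,
                   default_space.n_stimuli - 1]
        assert all(best >= eig[k] for k in corners)


class TestSessionEfficiency:
    def test_qcsf_beats_random_placement_entropy(self, default_space):
        """Adaptive placement ends with lower posterior entropy than
        random placement for matched trial counts, on average."""
        import pandas as pd

        from csfpolar.qcsf import PosteriorGrid
        from csfpolar.synthetic_data import _simulate_cells, sample_population, default_study_spec

        spec = default_study_spec(n_observers=20)
        cohort = sample_population(spec, seed=5)
        cells = cohort[cohort["location"] == "horizontal"].reset_index(drop=True)
        grid = PosteriorGrid.uniform(shape=(14, 14, 8))

        def final_entropies(policy, seed):
            rng = np.random.default_rng(seed)
            df = _simulate_cells(cells, 40, policy, default_space,
                                 DEFAULT_PSYCHOMETRIC, rng, grid.copy(), None)
            if policy == "qcsf":
                w = df.attrs["final_weights"]
            else:
                # replay random trials through the same grid posterior
                w = np.tile(grid.weights, (len(cells), 1))
                from csfpolar.csf_core import _p_correct_arrays
                for c_idx in range(len(cells)):
                    sub = df[df["observer_id"] == cells.loc[c_idx, "observer_id"]]
                    g = grid.copy()
                    from csfpolar.qcsf import update_posterior
                    for _, t in sub.iterrows():
                        g = update_posterior(g, t["sf_cpd"], t["contrast"],
                                             int(t["response"]))
                    w[c_idx] = g.weights
            ent = -np.sum(np.where(w > 0, w * np.log2(np.maximum(w, 1e-300)), 0.0), axis=1)
            return ent

        h_q = final_entropies("qcsf", 7)
        h_r = final_entropies("random", 7)
        assert h_q.mean() < h_r.mean()

    def test_long_session_recovers_generating_parameters(self, default_space):
        """Posterior means converge to truth with 2000 adaptive trials."""
        truths = [CSFParams(40, 1.2, 2.5), CSFParams(90, 2.0, 3.2),
                  CSFParams(25, 0.8, 2.9)]
        shared_grid = PosteriorGrid.uniform(shape=(16, 16, 10))
        shared_table = StimulusLikelihoodTable(shared_grid, default_space)
        errors = []
        for k, p in enumerate(truths):
            df = simulate_session(p, 2000, policy="qcsf", space=default_space,
                                  seed=100 + k, grid=shared_grid,
                                  table=shared_table)
            grid = df.attrs["grid"]
            w = df.attrs["final_weights"][0]
            post = PosteriorGrid(grid.axis_log_peak_cs, grid.axis_log_peak_sf,
                                 grid.axis_bandwidth, w)
            errors.append(abs(post.mean_log10()[0] - math.log10(p.peak_cs)))
        assert np.median(errors) < 0.05
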