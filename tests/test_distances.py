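"""Gower terms, neighborhood distances and abundance-weighted centering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import darkneighbors as dn
from darkneighbors.distances import (
    MULTIVARIATE,
    NN,
    biotic_design_tables,
    centered_weighted_distance,
    compute_center,
    distance_tensor,
    env_predictor_tables,
    gower_multivariate,
    neighborhood_distance,
    pairwise_trait_distance,
    resolve_neighborhood,
)
from darkneighbors.tables import CommunityTable

from conftest import make_pool

unit = st.floats(0.0, 1.0, allow_nan=False)


def _rand_traits(rng, n, t=3, prefix="sp"):
    return pd.DataFrame(
        rng.uniform(size=(n, t)),
        index=[f"{prefix}{i:03d}" for i in range(n)],
        columns=[f"trait_{j+1}" for j in range(t)],
    )


class TestGower:
    @pytest.mark.parametrize("a,b,expected", [(0.3, 0.3, 0.0), (0.0, 1.0, 1.0), (0.2, 0.7, 0.5)])
    def test_single_trait_term(self, a, b, expected):
        assert pairwise_trait_distance(a, b) == pytest.approx(expected)

    def test_multivariate_is_mean_of_terms(self):
        assert gower_multivariate([0.2, 0.5, 0.9], [0.2, 0.7, 0.5]) == pytest.approx(0.2)
        assert gower_multivariate([0.1, 0.9], [0.1, 0.9]) == 0.0

    def test_matches_sum_count_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            t = rng.integers(1, 6)
            a, b = rng.uniform(size=t), rng.uniform(size=t)
            oracle = sum(abs(x - y) for x, y in zip(a, b)) / t
            assert gower_multivariate(a, b) == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(unit, unit, unit), min_size=1, max_size=5))
    def test_metric_properties(self, rows):
        x, y, z = (np.array(v) for v in zip(*rows))
        dxy = gower_multivariate(x, y)
        assert 0.0 <= dxy <= 1.0
        assert dxy == pytest.approx(gower_multivariate(y, x), abs=1e-12)
        assert gower_multivariate(x, x) == 0.0
        assert dxy <= gower_multivariate(x, z) + gower_multivariate(z, y) + 1e-12


class TestNeighborhoodSpec:
    @pytest.mark.parametrize("p,n,k", [
        (0.3, 87, 27),       # ceil(26.1) on an 87-species pool
        (1.0, 228, 228),     # full 228-species pool
        (NN, 500, 1),
        (0.1, 610, 61),      # exact tenths must not suffer float round-up
    ])
    def test_rounds_up_to_member_count(self, p, n, k):
        assert resolve_neighborhood(p, n).k == k

    @pytest.mark.parametrize("p", [0.05, 1.1, -0.2, "np"])
    def test_off_grid_proportion_rejected(self, p):
        with pytest.raises(ValueError):
            resolve_neighborhood(p, 100)


class TestNeighborhoodDistance:
    def test_small_example_and_edge_ks(self):
        d = [0.05, 0.10, 0.30, 0.55]
        assert neighborhood_distance(d, 2) == pytest.approx(0.075)
        assert neighborhood_distance(d, 1) == pytest.approx(min(d))
        assert neighborhood_distance(d, 4) == pytest.approx(np.mean(d))

    def test_equals_sort_and_average_oracle(self, rng):
        for _ in range(100):
            d = rng.uniform(size=rng.integers(1, 30))
            for k in range(1, len(d) + 1):
                oracle = float(np.mean(sorted(d)[:k]))
                assert neighborhood_distance(d, k) == pytest.approx(oracle, abs=1e-12)

    def test_monotone_nondecreasing_in_k(self, rng):
        for _ in range(100):
            d = rng.uniform(size=rng.integers(2, 40))
            vals = [neighborhood_distance(d, k) for k in range(1, len(d) + 1)]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
            assert vals[0] <= vals[-1] + 1e-12  # NN <= MP


class TestEnvPredictors:
    def test_identical_member_has_zero_predictors_and_success(self):
        traits = pd.DataFrame(
            {"t1": [0.4, 0.4, 0.4, 0.9], "t2": [0.2, 0.2, 0.2, 0.8]},
            index=["a", "b", "c", "z"],
        )
        pool = make_pool(traits.index, ["a", "b", "c"])
        designs, resp = env_predictor_tables(pool, traits, [1.0])
        assert designs[1.0].loc["a"].eq(0.0).all()
        assert resp["a"] == 1
        assert resp["z"] == 0
        assert designs[1.0].loc["z"].min() > 0.4

    def test_matches_per_species_brute_force(self, rng):
        traits = _rand_traits(rng, 40)
        pool_sp = traits.index[:15]
        pool = make_pool(traits.index, pool_sp)
        sizes = [NN, 0.3, 0.7, 1.0]
        designs, resp = env_predictor_tables(pool, traits, sizes)
        for p in sizes:
            for sp in traits.index[::7]:
                refs = [q for q in pool_sp if q != sp]
                k = 1 if p == NN else int(np.ceil(p * len(pool_sp)))
                k = min(k, len(refs))
                for trait in traits.columns:
                    d = sorted(abs(traits.loc[sp, trait] - traits.loc[q, trait]) for q in refs)
                    oracle = float(np.mean(d[:k]))
                    assert designs[p].loc[sp, trait] == pytest.approx(oracle, abs=1e-12)


class TestCenteredWeighted:
    def _plot(self, counts):
        return pd.Series(counts)

    def test_two_species_hand_example(self):
        traits = pd.DataFrame({"t": [0.5, 0.3, 0.9]}, index=["target", "a", "b"])
        counts = self._plot({"a": 3, "b": 1})  # w = 0.75, 0.25; d = 0.2, 0.4
        val = centered_weighted_distance("target", counts, traits, k=2, center=0.3, trait="t")
        assert val == pytest.approx(0.75 * (0.2 - 0.3) + 0.25 * (0.4 - 0.3), abs=1e-12)

    def test_single_observed_species_reduces_to_d_minus_center(self):
        traits = pd.DataFrame({"t": [0.5, 0.1]}, index=["target", "a"])
        val = centered_weighted_distance("target", self._plot({"a": 7}), traits,
                                         k=1, center=0.25, trait="t")
        assert val == pytest.approx(0.4 - 0.25, abs=1e-12)

    def test_equal_abundance_full_neighborhood_is_mean_centered_distance(self, rng):
        traits = _rand_traits(rng, 6, t=1)
        target, others = traits.index[0], traits.index[1:]
        counts = self._plot({s: 2 for s in others})
        d = np.abs(traits.loc[others, "trait_1"].to_numpy() - traits.loc[target, "trait_1"])
        val = centered_weighted_distance(target, counts, traits, k=5, center=0.3,
                                         trait="trait_1")
        assert val == pytest.approx(np.mean(d - 0.3), abs=1e-12)

    def test_abundance_scale_invariance(self, rng):
        traits = _rand_traits(rng, 8, t=1)
        target, others = traits.index[0], traits.index[1:]
        base = {s: int(c) for s, c in zip(others, rng.integers(1, 9, len(others)))}
        for k in (1, 3, 7):
            v1 = centered_weighted_distance(target, self._plot(base), traits, k, 0.2, "trait_1")
            scaled = {s: 5 * c for s, c in base.items()}
            v2 = centered_weighted_distance(target, self._plot(scaled), traits, k, 0.2, "trait_1")
            assert v1 == pytest.approx(v2, abs=1e-12)


class TestCenter:
    def test_constant_distances_center_to_zero(self):
        traits = pd.DataFrame({"t": [0.0, 0.5, 1.0]}, index=["a", "b", "c"])
        c = compute_center(pd.DataFrame({"t": [0.2, 0.4]}, index=["a", "b"]),
                           ["a", "b"], ["a", "b"])
        # distances between a and b are 0.2 both ways; self pairs excluded
        assert c["t"] == pytest.approx(0.2)

    def test_matches_flat_average_oracle(self, rng):
        traits = _rand_traits(rng, 12, t=2)
        pool_sp = list(traits.index[:8])
        site_sp = list(traits.index[4:])
        c = compute_center(traits, pool_sp, site_sp)
        for trait in traits.columns:
            acc = [
                abs(traits.loc[i, trait] - traits.loc[j, trait])
                for i in pool_sp for j in site_sp if i != j
            ]
            assert c[trait] == pytest.approx(np.mean(acc), abs=1e-12)


class TestBioticDesign:
    def _community(self, rng, species, n_plots=4):
        rows = []
        for i in range(n_plots):
            chosen = rng.choice(species, size=min(4, len(species)), replace=False)
            for s in chosen:
                rows.append((f"p{i}", "s1", s, int(rng.integers(1, 6))))
        return CommunityTable(
            records=pd.DataFrame(rows, columns=["plot_id", "site_id", "species_id", "count"])
        )

    def test_vectorised_path_matches_reference_cell_function(self, rng):
        traits = _rand_traits(rng, 14, t=2)
        pool = make_pool(traits.index, traits.index[:10], traits.index[:5])
        community = self._community(rng, list(traits.index[:5]))
        sizes = [NN, 0.5, 1.0]
        frames, center = biotic_design_tables(pool, community, traits, sizes)
        for p in sizes:
            frame = frames[p]
            for _, row in frame.iloc[::5].iterrows():
                counts = community.plot_counts(row["plot_id"])
                m = len(counts.drop(index=row["species_id"], errors="ignore"))
                k = 1 if p == NN else int(np.ceil(p * m))
                for trait in traits.columns:
                    oracle = centered_weighted_distance(
                        row["species_id"], counts, traits, k, center[trait], trait
                    )
                    assert row[trait] == pytest.approx(oracle, abs=1e-12)

    def test_full_size_row_reduces_to_weighted_centered_sum(self, rng):
        traits = _rand_traits(rng, 10, t=1)
        pool = make_pool(traits.index, traits.index[:8], traits.index[:4])
        community = self._community(rng, list(traits.index[:4]), n_plots=3)
        frames, center = biotic_design_tables(pool, community, traits, [1.0])
        frame = frames[1.0]
        row = frame[frame["present"] == 0].iloc[0]
        w = community.relative_abundances(row["plot_id"])
        d = np.abs(traits.loc[w.index, "trait_1"].to_numpy()
                   - traits.loc[row["species_id"], "trait_1"])
        assert row["trait_1"] == pytest.approx(np.sum(w.to_numpy() * (d - center["trait_1"])),
                                               abs=1e-12)

    def test_bounds_raw_in_unit_interval_centered_in_plus_minus_one(self, assembly):
        frames, _ = biotic_design_tables(
            assembly.pool, assembly.community, assembly.traits.values, [0.5]
        )
        vals = frames[0.5][["trait_1", "trait_2"]].to_numpy()
        assert (vals >= -1.0 - 1e-12).all() and (vals <= 1.0 + 1e-12).all()
        tensor = distance_tensor(assembly.traits.values.iloc[:50],
                                 assembly.traits.values.index[:50],
                                 assembly.traits.values.index[:50])
        for mat in tensor.per_trait.values():
            assert mat.min() >= 0.0 and mat.max() <= 1.0


def test_long_format_export_round_trips(rng):
    traits = _rand_traits(rng, 5, t=2)
    tensor = distance_tensor(traits, traits.index[:3], traits.index)
    long = tensor.to_long_frame()
    assert set(long["trait"]) == {"trait_1", "trait_2", MULTIVARIATE}
    assert len(long) == 3 * 5 * 3
    row = long[(long["focal"] == traits.index[0]) & (long["reference"] == traits.index[4])
               & (long["trait"] == "trait_1")]
    expected = abs(traits.iloc[0, 0] - traits.iloc[4, 0])
    assert row["distance"].iloc[0] == pytest.approx(expected)
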