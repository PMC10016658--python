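import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import _oracles as oracle
from caninet.atlas import canine_atlas
from caninet.stats import (
    circuit_pairs,
    edge_region_average,
    edge_value_table,
    fdr_adjust,
    mann_whitney_u,
    nodal_lr_average,
    run_three_level_comparison,
)


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme

    def test_identical_samples(self):
        with pytest.warns(UserWarning, match="identical"):
            u, p = mann_whitney_u([2, 2, 2], [2, 2, 2])
        assert u == pytest.approx(4.5)  # n1*n2/2
        assert p == 1.0

    def test_exact_matches_full_enumeration(self, rng):
        """Exact p equals enumeration of all labelings for n1+n2 <= 10."""
        for n1, n2 in [(3, 3), (4, 4), (5, 5), (3, 7), (4, 6)]:
            for _ in range(5):
                x = rng.standard_normal(n1)
                y = rng.standard_normal(n2) + rng.uniform(-1, 1)
                u, p = mann_whitney_u(x, y, mode="exact")
                u_ref, p_ref = oracle.exact_mannwhitney(x, y)
                assert u == pytest.approx(u_ref)
                assert p == pytest.approx(p_ref)

    def test_approximate_close_to_permutation(self, rng):
        """Normal approximation is within 0.01 of a large permutation p at
        the study's group sizes."""
        from scipy import stats as sps

        x = rng.standard_normal(13) + 0.5
        y = rng.standard_normal(25)
        _, p_approx = mann_whitney_u(x, y, mode="approximate")
        ref = sps.mannwhitneyu(
            x,
            y,
            alternative="two-sided",
            method=sps.PermutationMethod(
                n_resamples=100_000, rng=np.random.default_rng(0)
            ),
        )
        assert p_approx == pytest.approx(float(ref.pvalue), abs=0.01)

    def test_u_convention_is_min(self, rng):
        x = rng.standard_normal(13) + 3.0
        y = rng.standard_normal(25)
        u, _ = mann_whitney_u(x, y)
        assert u <= 13 * 25 / 2

    def test_tied_exact_mode_uses_permutations(self, rng):
        x = [0.0, 0.0, 1.0, 2.0]
        y = [0.0, 3.0, 4.0, 5.0]
        u, p = mann_whitney_u(x, y, mode="exact", n_resamples=20_000, seed=0)
        assert 0.0 < p <= 1.0


class TestFdr:
    def test_known_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_empty(self):
        assert fdr_adjust([]) == []
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_reference_stepup_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 20))
            assert np.allclose(fdr_adjust(p), oracle.bh_stepup(p.tolist()))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_never_decreases_p(self, p):
        adj = fdr_adjust(p)
        assert all(a >= raw - 1e-12 for a, raw in zip(adj, p))
        assert all(a <= 1.0 + 1e-12 for a in adj)


class TestLrAveraging:
    def test_bilateral_mean_and_midline_passthrough(self):
        atlas = canine_atlas()
        nodal = pd.DataFrame(
            {"degree": np.arange(30, dtype=float)}, index=atlas.names
        )
        out = nodal_lr_average(nodal, atlas)
        amyg_l, amyg_r = atlas.nodes_of("amygdala")
        assert out.loc["amygdala", "degree"] == pytest.approx(
            (amyg_l + amyg_r) / 2.0
        )
        mes = atlas.nodes_of("mesencephalon")[0]
        assert out.loc["mesencephalon", "degree"] == float(mes)

    def test_one_missing_hemisphere_uses_other(self):
        atlas = canine_atlas()
        vals = np.arange(30, dtype=float)
        vals[atlas.nodes_of("amygdala")[0]] = np.nan
        nodal = pd.DataFrame({"Lp": vals}, index=atlas.names)
        out = nodal_lr_average(nodal, atlas)
        assert out.loc["amygdala", "Lp"] == float(atlas.nodes_of("amygdala")[1])

    def test_hemisphere_permutation_invariance(self, rng):
        atlas = canine_atlas()
        vals = rng.random(30)
        swapped = vals.copy()
        for left, right in atlas.homotopic_pairs:
            swapped[left], swapped[right] = vals[right], vals[left]
        a = nodal_lr_average(pd.DataFrame({"m": vals}, index=atlas.names), atlas)
        b = nodal_lr_average(pd.DataFrame({"m": swapped}, index=atlas.names), atlas)
        pd.testing.assert_frame_equal(a, b)


class TestEdgeAveraging:
    def _uniform_networks(self, value, densities=(0.2, 0.3)):
        z = np.full((30, 30), value)
        np.fill_diagonal(z, 0.0)
        return {d: z for d in densities}

    def test_constant_networks_give_constant_edge(self):
        atlas = canine_atlas()
        z = self._uniform_networks(0.42)
        assert edge_region_average(z, atlas, ("amygdala", "hippocampus")) == (
            pytest.approx(0.42)
        )

    def test_absent_edge_is_zero(self):
        atlas = canine_atlas()
        z = self._uniform_networks(0.0)
        assert edge_region_average(z, atlas, ("amygdala", "thalamus")) == 0.0

    def test_matches_independent_average(self, rng):
        """Region-pair z equals a hand-rolled mean over the 4 node pairs
        and all densities, zeros included."""
        atlas = canine_atlas()
        densities = (0.2, 0.25, 0.3)
        z_networks = {}
        for d in densities:
            m = np.triu(rng.random((30, 30)) * (rng.random((30, 30)) < 0.5), 1)
            z_networks[d] = m + m.T
        pair = ("frontal lobe", "thalamus")
        expected = np.mean(
            [
                z_networks[d][i, j]
                for d in densities
                for i, j in itertools.product(
                    atlas.nodes_of(pair[0]), atlas.nodes_of(pair[1])
                )
            ]
        )
        assert edge_region_average(z_networks, atlas, pair) == pytest.approx(
            expected
        )

    def test_unknown_region_fails(self):
        atlas = canine_atlas()
        with pytest.raises(KeyError):
            edge_region_average(self._uniform_networks(0.1), atlas, ("amygdala", "pons"))

    def test_circuit_pair_enumeration(self):
        atlas = canine_atlas()
        assert len(circuit_pairs(atlas)) == 10
        with_homotopic = circuit_pairs(atlas, include_homotopic=True)
        assert len(with_homotopic) == 14  # + 4 bilateral circuit regions


class TestThreeLevelComparison:
    def test_identical_groups_never_significant(self, rng):
        values = rng.random(10)
        rows = []
        for grp, ids in (("control", range(10)), ("patient", range(10, 20))):
            for i, v in zip(ids, values):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "group": grp,
                        "region": "amygdala",
                        "metric": "degree",
                        "value": v,
                    }
                )
        nodal = pd.DataFrame(rows)
        out = run_three_level_comparison(None, nodal, None, seed=0)
        assert (out["p_raw"] > 0.9).all()
        assert (out["u_statistic"] == 10 * 10 / 2).all()

    def test_fdr_never_below_raw_and_families_respected(self, default_cohort):
        from caninet.pipeline import build_subject_tables

        subjects, _ = default_cohort
        g, n, e, _, _ = build_subject_tables(
            subjects, include_sigma=False, seed=0
        )
        atlas = canine_atlas()
        circ = n[n["region"].isin((*atlas.circuit_regions, atlas.control_region))]
        out = run_three_level_comparison(g, circ, e, seed=0)
        assert (out["p_fdr"] >= out["p_raw"] - 1e-12).all()
        assert (out["u_statistic"] <= 25 * 13 / 2).all()
        # families have the expected sizes: 5 global (no sigma computed
        # here), 6 regions x 5 metrics nodal, 10 circuit pairs
        assert (out["level"] == "nodal").sum() == 30
        assert (out["level"] == "edge").sum() == 10

    def test_direction_matches_medians(self):
        edge = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["control"] * 4 + ["patient"] * 4,
                "pair": ["a - b"] * 8,
                "z": [0.1, 0.2, 0.15, 0.12, 0.5, 0.6, 0.55, 0.58],
            }
        )
        out = run_three_level_comparison(None, None, edge, seed=0)
        assert out.loc[0, "direction"] == 1
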