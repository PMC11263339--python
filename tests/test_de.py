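"""NB exact test, dispersion estimation, fold changes and BH adjustment.

The independent oracle for the exact test enumerates every per-sample count
vector with the observed total, computes its joint probability from
scipy.stats.nbinom pmfs, aggregates by the group-A sum, and sums the
conditional probabilities of all splits as or less likely than the observed
one.  It never uses the closed-form conditional law the implementation is
built on.
"""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom, poisson

from intersexpr.de import (
    bh_adjust,
    compare_groups,
    equalize_libraries,
    estimate_dispersion,
    exact_nb_pvalue,
    nb_exact_test,
)
from intersexpr.io import CountMatrix
from intersexpr.simulate import simulate_counts

from .conftest import flat_truth, two_group_design


def enumeration_oracle(a_obs, total, n_a, n_b, phi, mu=1.0):
    """Brute-force conditional two-sided p-value via composition enumeration."""
    if phi > 0:
        r = 1.0 / phi
        pmf = nbinom.pmf(np.arange(total + 1), r, r / (r + mu))
    else:
        pmf = poisson.pmf(np.arange(total + 1), mu)
    dist = np.zeros(total + 1)
    for head in product(range(total + 1), repeat=n_a + n_b - 1):
        s = sum(head)
        if s > total:
            continue
        vec = head + (total - s,)
        dist[sum(vec[:n_a])] += np.prod(pmf[list(vec)])
    dist /= dist.sum()
    return float(dist[dist <= dist[a_obs] * (1 + 1e-9)].sum())


class TestExactTest:
    def test_zero_total_gives_p_one(self):
        assert exact_nb_pvalue(0, 0, 3, 3, 0.1) == 1.0

    def test_balanced_split_is_modal(self):
        # equal group sizes, perfectly balanced split: every outcome is as or
        # less likely than the observed one
        assert exact_nb_pvalue(10, 20, 3, 3, 0.2) == pytest.approx(1.0)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.2, 0.5])
    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (2, 3), (3, 3)])
    def test_matches_enumeration_oracle(self, phi, n_a, n_b):
        """Exact agreement with the brute-force oracle for small totals."""
        rng = np.random.default_rng(phi_seed := int(phi * 100) + n_a * 10 + n_b)
        for _ in range(4):
            total = int(rng.integers(1, 14))
            a_obs = int(rng.integers(0, total + 1))
            want = enumeration_oracle(a_obs, total, n_a, n_b, phi)
            got = exact_nb_pvalue(a_obs, total, n_a, n_b, phi)
            assert got == pytest.approx(want, abs=1e-12)

    def test_oracle_agreement_at_total_30(self):
        want = enumeration_oracle(25, 30, 2, 2, 0.3)
        got = exact_nb_pvalue(25, 30, 2, 2, 0.3)
        assert got == pytest.approx(want, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        total=st.integers(min_value=1, max_value=200),
        frac=st.floats(min_value=0, max_value=1),
        phi=st.floats(min_value=0, max_value=1),
    )
    def test_swapping_groups_leaves_p_unchanged(self, total, frac, phi):
        a_obs = round(frac * total)
        p_ab = exact_nb_pvalue(a_obs, total, 3, 3, phi)
        p_ba = exact_nb_pvalue(total - a_obs, total, 3, 3, phi)
        assert p_ab == pytest.approx(p_ba, rel=1e-9)
        assert 0 < p_ab <= 1


class TestDispersion:
    def test_constant_counts_give_zero_per_gene(self):
        design = two_group_design(n_reps=3)
        data = pd.DataFrame(
            np.full((5, 6), 50, dtype=np.int64),
            index=[f"g{i}" for i in range(5)],
            columns=design.sample_ids,
        )
        est = estimate_dispersion(CountMatrix(data), design, "U_male_reproductive",
                                  "U_female_reproductive")
        assert (est.per_gene == 0).all()

    def test_poisson_data_estimates_near_zero(self):
        design = two_group_design(n_reps=30)
        truth = flat_truth(400, baseline=100.0, dispersion=0.0)
        cm = simulate_counts(design, truth, seed=5)
        est = estimate_dispersion(cm, design, "U_male_reproductive", "U_female_reproductive")
        assert abs(est.common) < 0.01

    def test_recovers_planted_dispersion(self):
        """phi = 0.2 at 50 replicates: the delivered (shrunk) estimates land
        within 25% of truth for at least 90% of genes."""
        design = two_group_design(n_reps=50)
        truth = flat_truth(1000, baseline=100.0, dispersion=0.2)
        cm = simulate_counts(design, truth, seed=11)
        est = estimate_dispersion(cm, design, "U_male_reproductive", "U_female_reproductive")
        within = ((est.shrunk >= 0.15) & (est.shrunk <= 0.25)).mean()
        assert within >= 0.90

    def test_single_replicate_design_instructs_fixed_phi(self):
        design = two_group_design(n_reps=1)
        data = pd.DataFrame(
            [[3, 9]], index=["g"], columns=design.sample_ids
        ).astype(np.int64)
        with pytest.raises(ValueError, match="fixed dispersion"):
            estimate_dispersion(CountMatrix(data), design, "U_male_reproductive",
                                "U_female_reproductive")


class TestCompareGroups:
    def test_equal_means_give_zero_log2fc(self):
        design = two_group_design(n_reps=3)
        data = pd.DataFrame(
            np.full((4, 6), 80, dtype=np.int64),
            index=[f"g{i}" for i in range(4)],
            columns=design.sample_ids,
        )
        de = compare_groups(CountMatrix(data), design, "U_male_reproductive",
                            "U_female_reproductive")
        assert np.allclose(de["log2fc"], 0.0)

    def test_overlapping_groups_rejected(self):
        design = two_group_design(n_reps=3)
        truth = flat_truth(5)
        cm = simulate_counts(design, truth, seed=1)
        with pytest.raises(ValueError, match="overlap"):
            nb_exact_test(cm, design, "U_male_reproductive", "U_male_reproductive")

    def test_swapping_orientation_negates_log2fc(self):
        design = two_group_design(n_reps=3)
        truth = flat_truth(50, baseline=60.0, dispersion=0.1)
        cm = simulate_counts(design, truth, seed=2)
        ab = compare_groups(cm, design, "U_male_reproductive", "U_female_reproductive")
        ba = compare_groups(cm, design, "U_female_reproductive", "U_male_reproductive")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_library_equalization_targets_geometric_mean(self):
        cm = CountMatrix(
            pd.DataFrame({"s1": [100, 300], "s2": [25, 75]}, index=["a", "b"]).astype(np.int64)
        )
        pseudo = equalize_libraries(cm)
        geo = np.sqrt(400 * 100)
        assert pseudo["s1"].sum() == pytest.approx(geo, rel=0.01)
        assert pseudo["s2"].sum() == pytest.approx(geo, rel=0.01)


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        """p = (0.01, 0.02, 0.03) over 3 genes -> all adjusted to 0.03."""
        adj = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_matches_hand_definition_on_fixed_vector(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        # hand step-up: adj_(i) = min_{j>=i} p_(j) * m / j
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(ranked[::-1])[::-1]
        want = np.empty(m)
        want[order] = np.minimum(hand, 1.0)
        assert np.allclose(bh_adjust(p), want)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_monotone_in_p_and_bounded(self, pvals):
        p = np.asarray(pvals)
        adj = bh_adjust(p)
        assert (adj <= 1).all() and (adj >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
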