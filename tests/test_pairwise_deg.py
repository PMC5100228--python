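"""Exact two-library test, BH-FDR, and the pairwise screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tagdge import (
    GeneModel,
    TagLibrary,
    ac_conditional_prob,
    ac_two_sided_p,
    bh_fdr,
    screen_pairwise,
)
from tagdge.synthetic_data import SimulationConfig, simulate_experiment, simulate_null_pair

from _oracles import ac_pmf_exact, ac_two_sided_exact, bh_stepup_exact


@pytest.mark.parametrize(
    "x, y, n1, n2, expected",
    [
        (0, 0, 100, 100, 0.5),  # 0!/(0!0!2^1)
        (1, 1, 100, 100, 0.25),  # 2!/(1!1!2^3)
        (0, 5, 100, 100, 1 / 64),  # geometric term
    ],
)
def test_conditional_prob_hand_values(x, y, n1, n2, expected):
    assert ac_conditional_prob(x, y, n1, n2) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        (0, 0, 1.0),  # S = 0.5 exactly
        (5, 5, 1.0),  # S = 0.5 exactly by symmetry
        (0, 5, 0.03125),  # 2 * 2^-6
    ],
)
def test_two_sided_equal_library_cases(x, y, expected):
    assert ac_two_sided_p(x, y, 10**6, 10**6) == expected


@pytest.mark.parametrize("x", [0, 1, 5, 20])
@pytest.mark.parametrize("ratio", [(2, 1), (1, 1), (1, 2)])
def test_conditional_distribution_normalizes(x, ratio):
    n1, n2 = (10**6 * r for r in ratio)
    y = np.arange(0, 4000)
    total = ac_conditional_prob(x, y, n1, n2).sum()
    assert total == pytest.approx(1.0, abs=1e-9)


def test_log_space_matches_exact_rational_small_counts():
    for n1, n2 in ((100, 50), (100, 100), (100, 200)):
        for x in range(13):
            for y in range(13):
                exact = float(ac_pmf_exact(x, y, n1, n2))
                assert ac_conditional_prob(x, y, n1, n2) == pytest.approx(exact, rel=1e-12)
                exact2 = float(ac_two_sided_exact(x, y, n1, n2))
                got = ac_two_sided_p(x, y, n1, n2)
                assert got == pytest.approx(exact2, rel=1e-12, abs=1e-300)


@settings(derandomize=True, max_examples=150)
@given(
    st.integers(min_value=0, max_value=50),
    st.integers(min_value=0, max_value=50),
    st.integers(min_value=10**3, max_value=10**7),
    st.integers(min_value=10**3, max_value=10**7),
)
def test_two_sided_symmetry(x, y, n1, n2):
    assert ac_two_sided_p(x, y, n1, n2) == pytest.approx(
        ac_two_sided_p(y, x, n2, n1), abs=1e-9
    )


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ac_conditional_prob(-1, 0, 10, 10)
    with pytest.raises(ValueError):
        ac_two_sided_p(0, -2, 10, 10)


class TestBhFdr:
    def test_hand_example(self):
        assert list(bh_fdr([0.01, 0.02, 0.03, 0.04])) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_clamped(self):
        assert list(bh_fdr([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_stepup_definition(self, pvals):
        assert list(bh_fdr(pvals)) == pytest.approx(bh_stepup_exact(pvals), abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert list(bh_fdr(p)[perm]) == pytest.approx(list(bh_fdr(p[perm])))


def test_null_calibration_is_conservative():
    """On paired Poisson null counts the discrete test rejects at most ~5%."""
    lib1, lib2 = simulate_null_pair(10_000, 10**6, seed=11)
    gid = sorted(lib1.counts)
    x = np.array([lib1.counts[g] for g in gid])
    y = np.array([lib2.counts[g] for g in gid])
    p = ac_two_sided_p(x, y, lib1.total_tags, lib2.total_tags)
    frac = float((p < 0.05).mean())
    assert 0.01 <= frac <= 0.06


def test_screen_direction_thresholds():
    genes = [GeneModel(g, 1000) for g in ("up", "flat", "down", "pad")]
    # padded so both totals are 1500: the flat gene is then exactly null
    lib1 = TagLibrary("a", {"up": 10, "flat": 500, "down": 800, "pad": 190})
    lib2 = TagLibrary("b", {"up": 700, "flat": 500, "down": 15, "pad": 285})
    recs = {r.gene_id: r for r in screen_pairwise(lib1, lib2, genes)}
    assert recs["up"].direction == "up"
    assert recs["down"].direction == "down"
    assert recs["flat"].direction == "ns"
    assert recs["flat"].p_raw == 1.0


def test_screen_mostly_true_positives_on_planted_data():
    cfg = SimulationConfig(
        n_genes=3000,
        conditions=(("Ck", 1), ("Cr", 1)),
        n_de=100,
        log2fc=2.0,
        de_conditions=("Cr",),
        module_size=0,
        planted_term_size=0,
        seed=1,
    )
    genes, libs, _, truth = simulate_experiment(cfg)
    recs = screen_pairwise(libs[0], libs[1], genes)
    called = {r.gene_id for r in recs if r.direction != "ns"}
    assert called, "no genes called"
    null_calls = called - set(truth.de_genes)
    assert len(null_calls) / len(called) <= 0.10
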