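"""Hypergeometric enrichment, Bonferroni, rich factor, GO-domain tabulation."""

import numpy as np
import pytest

from tagdge import (
    AnnotationMap,
    bonferroni,
    enrich,
    enrichment_p,
    rich_factor,
    wego_tabulate,
)
from tagdge.data_model import ConfigurationError
from tagdge.pairwise_deg import screen_pairwise
from tagdge.synthetic_data import SimulationConfig, simulate_experiment

from _oracles import hypergeom_upper_exact


@pytest.mark.parametrize(
    "N, n, M, m, expected",
    [
        (10, 5, 5, 5, 1 / 252),  # C(5,5)C(5,0)/C(10,5)
        (4, 2, 2, 1, 5 / 6),  # 1 - C(2,0)C(2,2)/C(4,2)
        (100, 10, 20, 0, 1.0),  # empty sum
    ],
)
def test_hand_enumerated_values(N, n, M, m, expected):
    assert enrichment_p(N, n, M, m) == pytest.approx(expected, rel=1e-10)


def test_matches_exact_enumeration_small_universe():
    for N in range(1, 16):
        for M in range(N + 1):
            for n in range(N + 1):
                for m in range(min(M, n) + 1):
                    exact = float(hypergeom_upper_exact(N, n, M, m))
                    assert enrichment_p(N, n, M, m) == pytest.approx(exact, rel=1e-10)


def test_monotone_in_overlap():
    ps = [enrichment_p(50, 10, 12, m) for m in range(11)]
    assert ps == sorted(ps, reverse=True)


def test_invalid_configuration_rejected():
    with pytest.raises(ValueError):
        enrichment_p(10, 5, 12, 1)  # M > N
    with pytest.raises(ValueError):
        enrichment_p(10, 5, 5, 6)  # m > min(n, M)


def test_bonferroni():
    assert bonferroni(0.01, 5) == pytest.approx(0.05)
    assert bonferroni(0.5, 10) == 1.0
    assert bonferroni(0.3, 1) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        bonferroni(0.1, 0)


def test_rich_factor():
    assert rich_factor(4, 16) == 0.25
    assert rich_factor(0, 7) == 0.0
    assert rich_factor(7, 7) == 1.0
    with pytest.raises(ValueError):
        rich_factor(1, 0)


def _toy_map():
    return AnnotationMap(
        namespace="GO_BP",
        term_genes={
            "T1": {f"g{i}" for i in range(5)},
            "T2": {f"g{i}" for i in range(3, 10)},
        },
        labels={"T1": "term one", "T2": "term two"},
    )


def test_enrich_toy_universe():
    amap = AnnotationMap(namespace="GO_BP", term_genes={"T": {f"g{i}" for i in range(5)}})
    amap.term_genes["BG"] = {f"g{i}" for i in range(10)}  # fills the universe to 10
    recs = enrich({f"g{i}" for i in range(5)}, amap)
    by_id = {r.term_id: r for r in recs}
    assert by_id["T"].p_raw == pytest.approx(1 / 252, rel=1e-10)
    assert by_id["T"].rich_factor == 1.0
    assert recs[0].term_id == "T"  # sorted by p


def test_enrich_saturated_deg_set():
    amap = _toy_map()
    recs = enrich(amap.universe, amap)
    assert all(r.p_raw == pytest.approx(1.0) for r in recs)
    assert all(r.rich_factor == 1.0 for r in recs)


def test_enrich_drops_unannotated_genes():
    amap = _toy_map()
    recs = enrich({"g0", "g1", "not_annotated"}, amap)
    assert all(r.n_deg == 2 for r in recs)


def test_enrich_empty_annotation_rejected():
    with pytest.raises(ConfigurationError):
        enrich({"g1"}, AnnotationMap(namespace="GO_BP"))


def test_planted_term_ranks_first_and_significant():
    for seed in (1, 2, 3, 4, 5):
        cfg = SimulationConfig(
            seed=seed, n_genes=2000, conditions=(("Ck", 1), ("Cr", 1)),
            n_de=100, de_conditions=("Cr",), module_size=0,
        )
        genes, libs, annotations, truth = simulate_experiment(cfg)
        recs = screen_pairwise(libs[0], libs[1], genes)
        deg = {r.gene_id for r in recs if r.direction != "ns"}
        results = enrich(deg, annotations["GO_BP"], alpha=0.05)
        assert results[0].term_id == truth.enriched_term
        assert results[0].significant


def test_null_deg_sets_rarely_significant():
    """Random DEG draws: Bonferroni keeps the family-wise error at bay."""
    rng = np.random.default_rng(42)
    cfg = SimulationConfig(
        seed=6, n_genes=1000, conditions=(("Ck", 1), ("Cr", 1)), n_de=0,
        de_conditions=(), module_size=0, planted_term_size=0, n_terms=50,
    )
    _, _, annotations, _ = simulate_experiment(cfg)
    amap = annotations["GO_BP"]
    universe = sorted(amap.universe)
    n_sig = n_terms = 0
    for _ in range(200):
        deg = set(rng.choice(universe, size=50, replace=False))
        recs = enrich(deg, amap)
        n_sig += sum(r.significant for r in recs)
        n_terms += len(recs)
    assert n_sig / n_terms <= 0.05


def test_wego_tabulation():
    bp = AnnotationMap(namespace="GO_BP", term_genes={"T1": {"g1", "g2"}, "T2": {"g1"}})
    table = wego_tabulate([bp], {"setA": {"g1"}, "empty": set(), "dupes": ["g2", "g2"]})
    rows = {(r.term_id, r.set_name): r.gene_count for r in table.itertuples()}
    assert rows == {("T1", "setA"): 1, ("T2", "setA"): 1, ("T1", "dupes"): 1}
    kegg = AnnotationMap(namespace="KEGG", term_genes={"k": {"g1"}})
    with pytest.raises(ConfigurationError):
        wego_tabulate([kegg], {"s": {"g1"}})
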