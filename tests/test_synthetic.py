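"""The synthetic-experiment generator: determinism, planted structure, noise model."""

import numpy as np
import pytest

from tagdge import screen_pairwise
from tagdge.data_model import ConfigurationError
from tagdge.synthetic_data import (
    SimulationConfig,
    read_truth,
    simulate_experiment,
    simulate_null_pair,
    write_truth,
)


def _small(seed=0, **kw):
    defaults = dict(
        n_genes=100, conditions=(("A", 2), ("B", 2)), n_de=5, de_conditions=("B",),
        module_size=3, planted_term_size=4, n_terms=10, library_size_mean=10**5, seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_object_counts():
    genes, libs, annotations, truth = simulate_experiment(_small())
    assert len(genes) == 100
    assert len(libs) == 4
    assert set(annotations) == {"GO_BP", "GO_CC", "GO_MF", "KEGG"}
    assert len(truth.de_genes) == 5
    assert len(truth.module_genes) == 3
    assert truth.enriched_term in annotations["GO_BP"].term_genes


def test_seed_determinism():
    g1, l1, a1, t1 = simulate_experiment(_small(seed=9))
    g2, l2, a2, t2 = simulate_experiment(_small(seed=9))
    assert g1 == g2
    assert [l.counts for l in l1] == [l.counts for l in l2]
    assert t1.de_genes == t2.de_genes
    assert a1["GO_BP"].term_genes == a2["GO_BP"].term_genes
    g3, l3, _, _ = simulate_experiment(_small(seed=10))
    assert [l.counts for l in l3] != [l.counts for l in l1]


def test_infeasible_configs_rejected():
    with pytest.raises(ConfigurationError):
        simulate_experiment(_small(planted_term_size=101))
    with pytest.raises(ConfigurationError):
        simulate_experiment(_small(n_de=99, module_size=3))
    with pytest.raises(ConfigurationError):
        simulate_experiment(_small(de_conditions=("nope",)))
    with pytest.raises(ConfigurationError):
        simulate_experiment(_small(dispersion=-1.0))


def test_planted_term_concentrates_on_de_genes():
    _, _, annotations, truth = simulate_experiment(_small())
    planted = annotations["GO_BP"].term_genes[truth.enriched_term]
    assert planted <= set(truth.de_genes) or len(planted & set(truth.de_genes)) >= 4


def test_poisson_fano_factor_near_one():
    cfg = SimulationConfig(
        n_genes=100, conditions=(("A", 60),), n_de=0, de_conditions=(),
        module_size=0, planted_term_size=0, n_terms=1, library_size_mean=10**5, seed=3,
    )
    genes, libs, _, _ = simulate_experiment(cfg)
    counts = np.array([[lib.counts[g.gene_id] for lib in libs] for g in genes], dtype=float)
    means = counts.mean(axis=1)
    fano = counts.var(axis=1, ddof=1)[means >= 50] / means[means >= 50]
    assert fano.size >= 50
    assert 0.8 <= fano.mean() <= 1.2


def test_overdispersion_inflates_variance():
    cfg = SimulationConfig(
        n_genes=100, conditions=(("A", 60),), n_de=0, de_conditions=(),
        module_size=0, planted_term_size=0, n_terms=1, library_size_mean=10**5,
        dispersion=0.2, seed=3,
    )
    genes, libs, _, _ = simulate_experiment(cfg)
    counts = np.array([[lib.counts[g.gene_id] for lib in libs] for g in genes], dtype=float)
    means = counts.mean(axis=1)
    fano = counts.var(axis=1, ddof=1)[means >= 50] / means[means >= 50]
    assert fano.mean() > 2.0


def test_realized_fold_change_matches_configuration():
    """Across many simulated pairs the planted RPKM log2 ratio averages log2fc."""
    diffs = []
    for seed in range(50):
        cfg = SimulationConfig(
            n_genes=500, conditions=(("A", 1), ("B", 1)), n_de=20, log2fc=2.0,
            de_conditions=("B",), module_size=0, planted_term_size=0, n_terms=1,
            library_size_mean=10**5, seed=seed,
        )
        genes, libs, _, truth = simulate_experiment(cfg)
        lengths = {g.gene_id: g.length_bp for g in genes}
        a, b = libs
        for g, lfc in truth.de_genes.items():
            ra = max(a.counts[g], 0.5) / a.total_tags
            rb = max(b.counts[g], 0.5) / b.total_tags
            diffs.append(np.log2(rb / ra) * np.sign(lfc))
    assert abs(np.mean(diffs) - 2.0) <= 0.2


def test_null_experiment_rarely_calls_genes():
    for seed in (1, 2, 3):
        cfg = SimulationConfig(
            n_genes=2000, conditions=(("A", 1), ("B", 1)), n_de=0, de_conditions=(),
            module_size=0, planted_term_size=0, seed=seed,
        )
        genes, libs, _, _ = simulate_experiment(cfg)
        recs = screen_pairwise(libs[0], libs[1], genes)
        frac = np.mean([r.direction != "ns" for r in recs])
        assert frac <= 0.005


def test_null_pair_totals_near_library_size():
    l1, l2 = simulate_null_pair(10_000, 10**6, seed=7)
    for lib in (l1, l2):
        assert abs(lib.total_tags - 10**6) <= 5 * np.sqrt(10**6)


def test_null_pair_single_gene():
    l1, l2 = simulate_null_pair(1, 1000, seed=1)
    assert l1.total_tags == sum(l1.counts.values())
    assert len(l1.counts) == 1


def test_truth_round_trip(tmp_path):
    _, _, _, truth = simulate_experiment(_small(seed=4))
    write_truth(truth, tmp_path)
    back = read_truth(tmp_path)
    assert back == truth
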