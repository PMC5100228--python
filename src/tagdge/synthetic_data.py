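"""Synthetic tag-count experiments with planted ground truth.

Emulates the statistical structure of a two-genotype x three-treatment
tag-sequencing design (two oilseed-rape cultivars under control, chromium,
and chromium + glutathione): replicated libraries of tag counts over a
shared gene catalog, with

* a log-normal baseline abundance profile over genes,
* Poisson tag sampling per library (negative-binomial when an
  overdispersion parameter is set, for robustness experiments),
* planted differentially expressed genes whose expected proportions are
  scaled by 2^(+-log2fc) in designated conditions,
* one annotation term concentrated on the planted DE genes (plus random
  terms across GO/KEGG namespaces), and
* a planted co-expression module sharing a latent per-library profile.

Everything is reproducible from a single integer seed. Default sizes are a
desk-scale stand-in for production tag libraries: 5,000 genes at 10^6 tags
per library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    AnnotationMap,
    ConfigurationError,
    GeneModel,
    QpcrMeasurement,
    TagLibrary,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_experiment",
    "simulate_null_pair",
    "simulate_qpcr",
    "write_truth",
    "read_truth",
]

DEFAULT_CONDITIONS: tuple[tuple[str, int], ...] = (
    ("ZS758_Ck", 2),
    ("ZS758_Cr", 2),
    ("ZS758_CrGSH", 2),
    ("Zheda622_Ck", 2),
    ("Zheda622_Cr", 2),
    ("Zheda622_CrGSH", 2),
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the emulated study design.

    ``dispersion`` is negative-binomial overdispersion (variance =
    mu + dispersion * mu^2); 0 gives pure Poisson tag sampling, the model
    the exact pairwise test assumes. ``de_conditions`` names the conditions
    in which planted DE genes are perturbed (the chromium treatments by
    default). The module's latent profile has standard deviation
    ``module_profile_sd`` in log2 units per library; ``module_noise_sd`` is
    the per-gene departure from that shared profile.
    """

    n_genes: int = 5000
    conditions: tuple[tuple[str, int], ...] = DEFAULT_CONDITIONS
    library_size_mean: int = 1_000_000
    seed: int = 0
    n_de: int = 200
    log2fc: float = 2.0
    dispersion: float = 0.0
    gene_length_range: tuple[int, int] = (200, 3000)
    planted_term_size: int = 50
    n_terms: int = 100
    module_size: int = 5
    module_noise_sd: float = 0.05
    module_profile_sd: float = 2.0
    de_conditions: tuple[str, ...] = ("ZS758_Cr", "Zheda622_Cr")
    abundance_sigma: float = 1.0  # log-normal spread of baseline abundances
    # DE is planted only in genes above this baseline-abundance quantile: a
    # fold change at an undetectable baseline is biologically meaningless
    # and no screen could (or should) recover it
    de_abundance_quantile: float = 0.25
    # module genes sit at this abundance quantile: high enough that counting
    # noise is small next to the shared latent profile, low enough that the
    # module's library share (hence compositional common-mode) is negligible
    module_abundance_quantile: float = 0.75

    def validate(self) -> None:
        labels = [c for c, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate condition labels")
        if self.n_genes < 1 or self.library_size_mean < 1:
            raise ConfigurationError("n_genes and library_size_mean must be >= 1")
        for name, v in (
            ("n_de", self.n_de),
            ("planted_term_size", self.planted_term_size),
            ("module_size", self.module_size),
        ):
            if not (0 <= v <= self.n_genes):
                raise ConfigurationError(f"{name}={v} must lie in [0, n_genes]")
        if self.n_de + self.module_size > self.n_genes:
            raise ConfigurationError("n_de + module_size exceeds n_genes")
        if self.dispersion < 0 or self.module_noise_sd < 0:
            raise ConfigurationError("dispersion and module_noise_sd must be >= 0")
        unknown = set(self.de_conditions) - set(labels)
        if self.n_de and unknown:
            raise ConfigurationError(f"de_conditions not in design: {sorted(unknown)}")
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("gene_length_range must satisfy 1 <= min <= max")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2fc
    enriched_term: str = ""
    module_genes: set[str] = field(default_factory=set)
    seed: int = 0


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def _random_terms(
    rng: np.random.Generator,
    namespace: str,
    prefix: str,
    n_terms: int,
    gene_ids: list[str],
    levels: dict[str, tuple[str, str]] | None = None,
) -> AnnotationMap:
    amap = AnnotationMap(namespace=namespace)
    n_genes = len(gene_ids)
    level1_pool = ("Metabolism", "Genetic Information Processing", "Environmental Information Processing")
    level2_pool = ("Carbohydrate metabolism", "Amino acid metabolism", "Translation", "Signal transduction")
    for i in range(n_terms):
        term = f"{prefix}{i:04d}"
        size = int(rng.integers(10, 61))
        size = min(size, n_genes)
        members = rng.choice(n_genes, size=size, replace=False)
        amap.term_genes[term] = {gene_ids[j] for j in members}
        amap.labels[term] = f"{prefix.lower()} term {i}"
        if namespace == "KEGG":
            amap.levels[term] = (
                level1_pool[int(rng.integers(len(level1_pool)))],
                level2_pool[int(rng.integers(len(level2_pool)))],
            )
    return amap


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[TagLibrary], dict[str, AnnotationMap], SyntheticTruth]:
    """Simulate one full experiment from ``config`` (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_ids(config.n_genes)

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    genes = [GeneModel(g, int(l)) for g, l in zip(gene_ids, lengths)]

    base = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_genes)
    de_floor = np.quantile(base, config.de_abundance_quantile)

    perm = rng.permutation(config.n_genes)
    module_idx = perm[: config.module_size]
    eligible = [i for i in perm[config.module_size :] if base[i] >= de_floor]
    if len(eligible) < config.n_de:
        raise ConfigurationError(
            f"only {len(eligible)} genes above the DE abundance floor; need {config.n_de}"
        )
    de_idx = np.array(eligible[: config.n_de], dtype=int)
    de_signs = rng.choice([-1.0, 1.0], size=config.n_de)

    if config.module_size:
        base[module_idx] = np.quantile(base, config.module_abundance_quantile)

    truth = SyntheticTruth(
        de_genes={gene_ids[i]: float(s * config.log2fc) for i, s in zip(de_idx, de_signs)},
        module_genes={gene_ids[i] for i in module_idx},
        seed=config.seed,
    )

    libraries: list[TagLibrary] = []
    for label, n_rep in config.conditions:
        parts = label.split("_", 1)
        genotype, treatment = (parts[0], parts[1]) if len(parts) == 2 else ("", label)
        cond_weights = base.copy()
        if label in config.de_conditions and config.n_de:
            cond_weights[de_idx] *= 2.0 ** (de_signs * config.log2fc)
        for rep in range(1, n_rep + 1):
            w = cond_weights.copy()
            if config.module_size:
                latent = rng.normal(0.0, config.module_profile_sd)
                eps = rng.normal(0.0, config.module_noise_sd, size=config.module_size)
                w[module_idx] *= 2.0 ** (latent + eps)
            props = w / w.sum()
            mu = props * config.library_size_mean
            counts = _draw_counts(rng, mu, config.dispersion)
            libraries.append(
                TagLibrary(
                    sample_id=f"{label}_r{rep}",
                    counts={g: int(c) for g, c in zip(gene_ids, counts)},
                    genotype=genotype,
                    treatment=treatment,
                    replicate=rep,
                )
            )

    annotations: dict[str, AnnotationMap] = {}
    bp = _random_terms(rng, "GO_BP", "BP", config.n_terms, gene_ids)
    if config.planted_term_size:
        planted = "BP_planted"
        take = min(config.planted_term_size, config.n_de)
        members = {gene_ids[i] for i in de_idx[:take]}
        if len(members) < config.planted_term_size:  # top up when n_de is small
            pool = [g for g in gene_ids if g not in members]
            extra = rng.choice(len(pool), size=config.planted_term_size - len(members), replace=False)
            members |= {pool[j] for j in extra}
        bp.term_genes[planted] = members
        bp.labels[planted] = "planted stress-response term"
        truth.enriched_term = planted
    annotations["GO_BP"] = bp
    annotations["GO_CC"] = _random_terms(rng, "GO_CC", "CC", max(1, config.n_terms // 2), gene_ids)
    annotations["GO_MF"] = _random_terms(rng, "GO_MF", "MF", max(1, config.n_terms // 2), gene_ids)
    annotations["KEGG"] = _random_terms(rng, "KEGG", "ko", max(1, config.n_terms // 2), gene_ids)

    return genes, libraries, annotations, truth


def simulate_null_pair(
    n_genes: int, library_size: int, seed: int
) -> tuple[TagLibrary, TagLibrary]:
    """Two libraries drawn from identical expected proportions (Poisson).

    The calibration case: every gene is truly null, so pairwise-test
    p-values should be (conservatively) uniform.
    """
    if n_genes < 1 or library_size < 1:
        raise ConfigurationError("n_genes and library_size must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = _gene_ids(n_genes)
    w = rng.lognormal(0.0, 1.0, size=n_genes)
    mu = w / w.sum() * library_size
    libs = []
    for name in ("null_1", "null_2"):
        counts = rng.poisson(mu)
        libs.append(
            TagLibrary(sample_id=name, counts={g: int(c) for g, c in zip(gene_ids, counts)})
        )
    return libs[0], libs[1]


def simulate_qpcr(
    truth: SyntheticTruth,
    n_targets: int = 10,
    n_replicates: int = 3,
    seed: int = 0,
    ct_noise_sd: float = 0.05,
) -> list[QpcrMeasurement]:
    """qPCR well measurements consistent with the planted fold changes.

    For each selected planted DE gene the treatment target Ct is shifted by
    -log2fc cycles relative to control (one cycle per doubling), around a
    reference gene held constant — so 2^-ddCt recovers the planted fold
    change up to Ct noise.
    """
    if not truth.de_genes:
        raise ValueError("truth has no planted DE genes to validate")
    rng = np.random.default_rng(seed)
    targets = sorted(truth.de_genes)[: n_targets]
    out: list[QpcrMeasurement] = []
    for gene in targets:
        lfc = truth.de_genes[gene]
        for group, shift in (("control", 0.0), ("treatment", -lfc)):
            for rep in range(1, n_replicates + 1):
                out.append(
                    QpcrMeasurement(
                        sample_id=f"{group}_r{rep}",
                        target_gene=gene,
                        reference_gene="REF",
                        ct_target=24.0 + shift + rng.normal(0.0, ct_noise_sd),
                        ct_reference=18.0 + rng.normal(0.0, ct_noise_sd),
                        group=group,
                    )
                )
    return out


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write the ground truth as three small TSVs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth_de_genes.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlog2fc\n")
        for g in sorted(truth.de_genes):
            fh.write(f"{g}\t{truth.de_genes[g]!r}\n")
    with open(outdir / "truth_module.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_id\n")
        for g in sorted(truth.module_genes):
            fh.write(f"{g}\n")
    with open(outdir / "truth_meta.tsv", "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"enriched_term\t{truth.enriched_term}\n")
        fh.write(f"seed\t{truth.seed}\n")


def read_truth(outdir: str | Path) -> SyntheticTruth:
    outdir = Path(outdir)
    truth = SyntheticTruth()
    with open(outdir / "truth_de_genes.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            g, v = line.rstrip("\n").split("\t")
            truth.de_genes[g] = float(v)
    with open(outdir / "truth_module.tsv", encoding="utf-8") as fh:
        next(fh)
        truth.module_genes = {line.strip() for line in fh if line.strip()}
    with open(outdir / "truth_meta.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            k, v = line.rstrip("\n").split("\t")
            if k == "enriched_term":
                truth.enriched_term = v
            elif k == "seed":
                truth.seed = int(v)
    return truth
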