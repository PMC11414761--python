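"""Synthetic study inputs with known ground truth.

Everything the pipeline consumes can be generated here: competition-assay
colony counts, negative-binomial RNA-seq count matrices with planted
additive and epistatic log2-fold-change effects, block-structured
coexpression expression matrices with designated hubs, PPI edge lists,
and gene-set files.  Each generator is a pure function of (config, seed);
random streams are named substreams of one seed, so adding a generator
does not shift the draws of another.

Defaults emulate the study design this package targets: an ancestral
strain assayed at 37.0 and 42.2 degC, four rho and two rpoB single
mutants, six rho + rpoB double mutants, ~2 RNA-seq replicates per genotype
(29 libraries), ~10 fitness assays per genotype x temperature, Poisson
plating noise on colony counts plus a per-assay biological jitter of
0.10 on the fitness scale (matching published assay-level variances), and
negative-binomial counts with dispersion alpha = 0.05
(variance mu + alpha mu^2).
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import CountMatrix
from .fitness import CompetitionAssay

RHO_ALLELES = ("rho_A43T", "rho_T231A", "rho_I15N", "rho_I15F")
RPOB_ALLELES = ("rpoB_I572F", "rpoB_I572L")
# the six double mutants with expression data
DOUBLES = (
    ("rho_A43T", "rpoB_I572F"), ("rho_A43T", "rpoB_I572L"),
    ("rho_T231A", "rpoB_I572F"), ("rho_T231A", "rpoB_I572L"),
    ("rho_I15N", "rpoB_I572F"), ("rho_I15N", "rpoB_I572L"),
)
# all eight engineered double mutants carry fitness assays
ALL_DOUBLES = tuple((rho, rpob) for rho in RHO_ALLELES for rpob in RPOB_ALLELES)

__all__ = [
    "SimulationTruth",
    "substream",
    "simulate_competition",
    "simulate_counts",
    "simulate_coexpression",
    "simulate_ppi",
    "simulate_gene_sets",
    "default_fitness_config",
    "write_bundle",
]


@dataclass
class SimulationTruth:
    seed: int
    true_fitness: dict = field(default_factory=dict)
    true_epsilon_fitness: dict = field(default_factory=dict)
    true_lfc: dict = field(default_factory=dict)
    true_epsilon_exp: dict = field(default_factory=dict)
    module_assignment: dict = field(default_factory=dict)
    hub_genes: list = field(default_factory=list)
    ppi_degrees: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj
        with open(path, "w") as fh:
            json.dump(_clean(vars(self)), fh, indent=1)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a master seed (stable across generator additions)."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                                        spawn_key=(key,)))


# ---------------------------------------------------------------------------
# competition assays

def default_fitness_config() -> dict[tuple[str, float], float]:
    """Study-scale true relative fitness per genotype x temperature.

    Singles are beneficial at 42.2 degC (except the near-neutral I15 codon
    alleles) and mildly deleterious at 20.0/37.0 degC.  Each of the eight
    double mutants combines its singles multiplicatively plus the published
    per-pair epistatic deviation, so the planted epistasis reproduces the
    study's pattern: strong negative epistasis (diminishing returns) for
    the beneficial rho alleles at 42.2 degC, weak epistasis for the
    near-neutral ones and at the lower temperatures.
    """
    from .datasets import double_mutant_epistasis

    singles = {
        "rho_A43T": {42.2: 1.15, 37.0: 0.97, 20.0: 0.96},
        "rho_T231A": {42.2: 1.12, 37.0: 0.97, 20.0: 0.97},
        "rho_I15N": {42.2: 1.00, 37.0: 0.98, 20.0: 0.98},
        "rho_I15F": {42.2: 1.01, 37.0: 0.98, 20.0: 0.98},
        "rpoB_I572F": {42.2: 1.18, 37.0: 0.96, 20.0: 0.95},
        "rpoB_I572L": {42.2: 1.16, 37.0: 0.97, 20.0: 0.96},
    }
    eps_table = double_mutant_epistasis()
    eps = {(r.double_id, r.temperature): r.epsilon
           for r in eps_table.itertuples(index=False)}
    config: dict[tuple[str, float], float] = {}
    for g, temps in singles.items():
        for T, w in temps.items():
            config[(g, T)] = w
    for rho, rpob in ALL_DOUBLES:
        key = f"{rho.replace('rho_', 'rho')}+{rpob.replace('rpoB_', 'rpoB')}"
        for T in (42.2, 37.0, 20.0):
            config[(f"{rho}+{rpob}", T)] = (
                singles[rho][T] * singles[rpob][T] + eps[(key, T)])
    return config


def simulate_competition(
    true_w: Mapping[tuple[str, float], float] | None = None,
    n_replicates: int = 10,
    plating_mean: float = 250.0,
    bio_sd: float = 0.10,
    dilution: float = 100.0,
    poisson: bool = True,
    seed: int = 0,
) -> tuple[list[CompetitionAssay], SimulationTruth]:
    """Competition assays with Poisson plating noise around known fitness.

    Ancestor expands ``dilution``-fold per cycle so its expected plated
    final count equals its initial; the mutant's expected final count is
    initial x dilution^(w_eff − 1) with w_eff = w + N(0, bio_sd) per assay.
    ``poisson=False`` turns all noise off, making the estimator exact.
    """
    if plating_mean <= 0:
        raise ValueError("plating mean must be positive")
    true_w = dict(true_w) if true_w is not None else default_fitness_config()
    if any(w <= 0 for w in true_w.values()):
        raise ValueError("true fitness values must be positive")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = substream(seed, "competition")
    assays: list[CompetitionAssay] = []
    for (genotype, temp), w in sorted(true_w.items()):
        for rep in range(n_replicates):
            if poisson:
                w_eff = w + rng.normal(0.0, bio_sd) if bio_sd > 0 else w
                ni_m = max(1, int(rng.poisson(plating_mean)))
                ni_a = max(1, int(rng.poisson(plating_mean)))
                nf_a = max(1, int(rng.poisson(ni_a)))
                nf_m = max(1, int(rng.poisson(ni_m * dilution ** (w_eff - 1.0))))
            else:
                ni_m = ni_a = plating_mean
                nf_a = plating_mean
                nf_m = plating_mean * dilution ** (w - 1.0)
            assays.append(CompetitionAssay(
                genotype_id=genotype, temperature=temp,
                replicate_id=f"r{rep}", biological_replicate_id=f"b{rep % 3}",
                n_initial_mutant=ni_m, n_final_mutant=nf_m,
                n_initial_ancestor=ni_a, n_final_ancestor=nf_a,
                dilution_factor=dilution,
            ))
    truth = SimulationTruth(seed=seed, true_fitness={
        f"{g}@{T}": w for (g, T), w in true_w.items()})
    for (g, T), w in true_w.items():
        if "+" in g:
            rho, rpob = g.split("+")
            wx = true_w.get((rho, T))
            wy = true_w.get((rpob, T))
            if wx is not None and wy is not None:
                truth.true_epsilon_fitness[f"{g}@{T}"] = w - wx * wy
    return assays, truth


# ---------------------------------------------------------------------------
# RNA-seq counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha mu^2 (Poisson when alpha=0)."""
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def default_design(n_replicates: int = 2) -> pd.DataFrame:
    """The 29-library design: anc37 x2, anc42 x3, six singles and six
    doubles at 42.2 degC, two replicates each (with the default n)."""
    rows = []
    def add(genotype, temp, n):
        for i in range(n):
            rows.append({"sample": f"{genotype}_{int(temp)}_r{i}",
                         "genotype": genotype, "temperature": temp,
                         "replicate": f"r{i}"})
    add("ancestor", 37.0, n_replicates)
    add("ancestor", 42.2, n_replicates + 1)
    for g in list(RHO_ALLELES) + list(RPOB_ALLELES):
        add(g, 42.2, n_replicates)
    for rho, rpob in DOUBLES:
        add(f"{rho}+{rpob}", 42.2, n_replicates)
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(
    n_genes: int = 2000,
    design: pd.DataFrame | None = None,
    n_replicates: int = 2,
    baseline_mean: float = 200.0,
    dispersion: float = 0.05,
    frac_anc_response: float = 0.2,
    anc_lfc_sd: float = 1.5,
    frac_de: float = 0.1,
    de_lfc: float = 4.0,
    frac_epistatic: float = 0.05,
    epsilon_magnitude: float = 2.0,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """NB count matrix with planted additive and epistatic effects.

    Per gene, the ancestral stress response plants a log2 fold change
    (Anc42 vs Anc37) in ``frac_anc_response`` of genes; each single mutant
    perturbs ``frac_de`` of genes by ±``de_lfc`` (vs Anc42); double-mutant
    log2 fold changes are the sum of their singles' plus a planted
    epsilon of ±``epsilon_magnitude`` in ``frac_epistatic`` of genes
    (those genes also get the constituent rho single's DE effect so they
    pass downstream DE gates).  Counts are NB around
    baseline x 2^(lfc) x size_factor.
    """
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    design = design if design is not None else default_design(n_replicates)
    genotypes = design["genotype"].unique()
    if not (((design["genotype"] == "ancestor") & (design["temperature"] == 37.0)).any()
            and ((design["genotype"] == "ancestor") & (design["temperature"] == 42.2)).any()):
        raise ValueError("design must include the ancestor at both temperatures")
    rng = substream(seed, "counts")
    genes = [f"g{i:04d}" for i in range(n_genes)]
    baselines = baseline_mean * rng.lognormal(0.0, 0.6, size=n_genes)

    truth = SimulationTruth(seed=seed)
    lfc_anc = np.zeros(n_genes)
    anc_idx = rng.choice(n_genes, size=int(frac_anc_response * n_genes), replace=False)
    lfc_anc[anc_idx] = rng.normal(0.0, anc_lfc_sd, size=anc_idx.size)

    singles = [g for g in genotypes if g != "ancestor" and "+" not in g]
    doubles = [g for g in genotypes if "+" in g]
    lfc_single: dict[str, np.ndarray] = {}
    for g in singles:
        v = np.zeros(n_genes)
        idx = rng.choice(n_genes, size=int(frac_de * n_genes), replace=False)
        v[idx] = rng.choice([-de_lfc, de_lfc], size=idx.size)
        lfc_single[g] = v
    eps_exp: dict[str, np.ndarray] = {}
    lfc_double: dict[str, np.ndarray] = {}
    for d in doubles:
        rho, rpob = d.split("+")
        lx = lfc_single.get(rho, np.zeros(n_genes))
        ly = lfc_single.get(rpob, np.zeros(n_genes))
        e = np.zeros(n_genes)
        # epistasis is planted on genes the rho single already perturbs, so
        # epistatic genes are differentially expressed in >= 1 contrast
        pool = np.flatnonzero(lx != 0)
        n_eps = min(int(frac_epistatic * n_genes), pool.size)
        idx = rng.choice(pool, size=n_eps, replace=False)
        e[idx] = rng.choice([-epsilon_magnitude, epsilon_magnitude], size=idx.size)
        eps_exp[d] = e
        lfc_double[d] = lx + ly + e

    sf = rng.uniform(*size_factor_range, size=len(design))
    cols = {}
    for j, (sample, row) in enumerate(design.iterrows()):
        g, T = row["genotype"], row["temperature"]
        if g == "ancestor" and T == 37.0:
            lfc = np.zeros(n_genes)
        elif g == "ancestor":
            lfc = lfc_anc
        elif "+" in g:
            lfc = lfc_anc + lfc_double[g]
        else:
            lfc = lfc_anc + lfc_single[g]
        mu = baselines * 2.0**lfc * sf[j]
        cols[sample] = _nb_draw(rng, mu, dispersion)
    counts = pd.DataFrame(cols, index=genes)

    truth.true_lfc["anc42_vs_anc37"] = dict(zip(genes, lfc_anc))
    for g in singles:
        truth.true_lfc[f"{g}_vs_anc42"] = dict(zip(genes, lfc_single[g]))
    for d in doubles:
        truth.true_lfc[f"{d}_vs_anc42"] = dict(zip(genes, lfc_double[d]))
        truth.true_epsilon_exp[d] = dict(zip(genes, eps_exp[d]))
    truth.extras["size_factors"] = dict(zip(design.index, sf))
    return CountMatrix(counts, design.copy()), truth


# ---------------------------------------------------------------------------
# coexpression blocks

def simulate_coexpression(
    block_sizes: Sequence[int] = (120, 100, 80, 60, 40),
    loading: float = 0.9,
    hub_loading: float = 0.98,
    n_hubs_per_block: int = 3,
    n_samples: int = 29,
    cross_cor: float = 0.0,
    n_background: int = 0,
    loading_spread: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Block-correlated expression with designated hub genes.

    Each block has a latent factor; member genes are
    loading x factor + sqrt(1 − loading²) x noise, and the first
    ``n_hubs_per_block`` genes of each block get ``hub_loading`` (the
    highest loading, hence the highest intra-block connectivity).
    ``loading_spread`` > 0 draws member loadings uniformly from
    [loading − spread, loading], grading connectivity within blocks the
    way real coexpression data grades it.  Optional background genes are
    pure noise.
    """
    for lo in (loading, hub_loading):
        if not 0 < lo <= 1:
            raise ValueError("loadings must lie in (0, 1]")
    if loading_spread < 0 or loading_spread >= loading:
        if loading_spread != 0:
            raise ValueError("loading_spread must lie in [0, loading)")
    if not 0 <= cross_cor < 1:
        raise ValueError("cross-block correlation must lie in [0, 1)")
    if any(s < 2 for s in block_sizes):
        raise ValueError("block sizes must be >= 2")
    rng = substream(seed, "coexpression")
    shared = rng.standard_normal(n_samples)
    rows, names = [], []
    truth = SimulationTruth(seed=seed)
    for b, size in enumerate(block_sizes):
        factor = (math.sqrt(cross_cor) * shared
                  + math.sqrt(1.0 - cross_cor) * rng.standard_normal(n_samples))
        for i in range(size):
            if i < n_hubs_per_block:
                lo = hub_loading
            elif loading_spread > 0:
                lo = float(rng.uniform(loading - loading_spread, loading))
            else:
                lo = loading
            noise = rng.standard_normal(n_samples)
            profile = lo * factor + math.sqrt(1.0 - lo**2) * noise
            name = f"b{b}_g{i:03d}"
            names.append(name)
            rows.append(profile)
            truth.module_assignment[name] = f"block{b}"
            if i < n_hubs_per_block:
                truth.hub_genes.append(name)
    for i in range(n_background):
        name = f"bg_g{i:03d}"
        names.append(name)
        rows.append(rng.standard_normal(n_samples))
        truth.module_assignment[name] = "background"
    expr = pd.DataFrame(rows, index=names,
                        columns=[f"s{j:02d}" for j in range(n_samples)])
    return expr, truth


# ---------------------------------------------------------------------------
# PPI edge lists

def simulate_ppi(
    n_genes: int = 200,
    degrees: Sequence[int] | None = None,
    mean_degree: float = 4.0,
    cutoff: float = 0.9,
    n_decoy_edges: int = 0,
    gene_names: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Configuration-model PPI edge list with confidences around a cutoff.

    Planted degrees (geometric by default) seed a configuration model;
    self-loops and parallel edges are simplified away.  True edges get
    confidence >= cutoff, decoy edges < cutoff, and the truth records the
    realized degrees of the simplified graph at the cutoff.
    """
    import warnings

    import networkx as nx

    rng = substream(seed, "ppi")
    if degrees is None:
        degrees = rng.geometric(1.0 / mean_degree, size=n_genes) - 0
        degrees = np.minimum(degrees, n_genes - 1)
    degrees = list(int(d) for d in degrees)
    if sum(degrees) % 2 == 1:
        warnings.warn("odd degree sum; incrementing one node's degree")
        degrees[int(np.argmin(degrees))] += 1
    names = list(gene_names) if gene_names is not None else [
        f"g{i:04d}" for i in range(len(degrees))]
    try:
        # exact realization of a graphical sequence, randomized by
        # degree-preserving double-edge swaps
        g = nx.havel_hakimi_graph(degrees)
        if g.number_of_edges() > 2:
            try:
                nx.double_edge_swap(g, nswap=2 * g.number_of_edges(),
                                    max_tries=50 * g.number_of_edges(),
                                    seed=int(rng.integers(2**31 - 1)))
            except nx.NetworkXException:
                pass  # too constrained to swap (e.g. a star); keep as built
    except nx.NetworkXError:
        g = nx.configuration_model(degrees, seed=int(rng.integers(2**31 - 1)))
        g = nx.Graph(g)  # collapse parallel edges
        g.remove_edges_from(nx.selfloop_edges(g))
    rows = []
    for u, v in sorted(g.edges()):
        rows.append({"gene_a": names[u], "gene_b": names[v],
                     "confidence": float(rng.uniform(cutoff, 1.0))})
    for _ in range(n_decoy_edges):
        u, v = rng.choice(len(names), size=2, replace=False)
        rows.append({"gene_a": names[u], "gene_b": names[v],
                     "confidence": float(rng.uniform(0.1, cutoff - 1e-9))})
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])
    truth = SimulationTruth(seed=seed)
    truth.ppi_degrees = {names[i]: int(g.degree(i)) if i in g else 0
                         for i in range(len(names))}
    return edges, truth


# ---------------------------------------------------------------------------
# gene sets

def simulate_gene_sets(
    universe: Sequence[str],
    set_sizes: Mapping[str, int],
    flagged: Sequence[str] = (),
    enrichment_odds: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, list[str]], SimulationTruth]:
    """Gene sets drawn with configurable enrichment for flagged genes.

    Each member is drawn without replacement with weight
    ``enrichment_odds`` for flagged genes and 1 otherwise.
    """
    universe = list(universe)
    if enrichment_odds <= 0:
        raise ValueError("enrichment odds must be positive")
    flagged_set = set(flagged)
    rng = substream(seed, "gene_sets")
    weights = np.array([enrichment_odds if g in flagged_set else 1.0
                        for g in universe], dtype=float)
    sets: dict[str, list[str]] = {}
    for name, size in set_sizes.items():
        if size > len(universe):
            raise ValueError(f"set {name!r} larger than the universe")
        p = weights / weights.sum()
        idx = rng.choice(len(universe), size=size, replace=False, p=p)
        sets[name] = sorted(universe[i] for i in idx)
    truth = SimulationTruth(seed=seed)
    truth.extras["enrichment_odds"] = enrichment_odds
    truth.extras["sets"] = sets
    return sets, truth


# ---------------------------------------------------------------------------
# full input bundle

def write_bundle(outdir, seed: int = 0, n_genes: int = 2000) -> dict:
    """Write a complete synthetic input bundle (assays, counts, sample
    sheet, gene sets, PPI edges) plus the truth JSON; returns file paths."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    assays, fit_truth = simulate_competition(seed=seed)
    assay_rows = [{
        "genotype": a.genotype_id, "temperature": a.temperature,
        "replicate": a.replicate_id, "bio_replicate": a.biological_replicate_id,
        "ni_mut": a.n_initial_mutant, "nf_mut": a.n_final_mutant,
        "ni_anc": a.n_initial_ancestor, "nf_anc": a.n_final_ancestor,
        "dilution": a.dilution_factor,
    } for a in assays]
    pd.DataFrame(assay_rows).to_csv(out / "assays.tsv", sep="\t", index=False)

    cm, count_truth = simulate_counts(n_genes=n_genes, seed=seed)
    cm.counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
    cm.sample_meta.rename_axis("sample").to_csv(out / "samples.tsv", sep="\t")

    edges, ppi_truth = simulate_ppi(n_genes=n_genes, gene_names=cm.genes, seed=seed)
    edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)

    set_sizes = {"heat_shock": min(100, n_genes // 5),
                 "stress_response": min(65, n_genes // 8),
                 "rho_terminated": min(300, max(1, int(0.15 * n_genes)))}
    sets, set_truth = simulate_gene_sets(cm.genes, set_sizes, seed=seed)
    with open(out / "gene_sets.gmt", "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + members) + "\n")

    fit_truth.true_lfc = count_truth.true_lfc
    fit_truth.true_epsilon_exp = count_truth.true_epsilon_exp
    fit_truth.ppi_degrees = ppi_truth.ppi_degrees
    fit_truth.extras.update(count_truth.extras)
    fit_truth.extras["gene_sets"] = set_truth.extras["sets"]
    fit_truth.to_json(out / "truth.json")
    return {name: str(out / name) for name in
            ("assays.tsv", "counts.tsv", "samples.tsv", "ppi_edges.tsv",
             "gene_sets.gmt", "truth.json")}
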