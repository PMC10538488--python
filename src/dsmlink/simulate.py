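"""Seeded synthetic-data generators for end-to-end testing.

The generators emulate the statistical structure the linking models assume:
a haplotype reference panel with block LD, diploid individuals drawn from
the same Li–Stephens copying process used for inference (so the chain prior
is well-specified by construction), and gene expression linearly coupled to
eQTL dosages with Gaussian noise, including redundant multi-eGene signals.
A "misspecified" recombination mode (hotspots unknown to the model) is
available for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsm import EQTLMap, ExpressionProfile, GenotypeProfile
from .hmm import HaplotypePanel, Haplotype, build_hmm_params

__all__ = [
    "SimConfig",
    "LinkingFixture",
    "simulate_panel",
    "simulate_individuals",
    "simulate_eqtl_map",
    "simulate_expression",
    "make_linking_fixture",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixtures.

    Defaults describe the standard desk-scale fixture: a panel of 60
    haplotypes over 300 sites in 5-site LD blocks, 150 eQTLs with 3 eGenes
    each, per-(eQTL, eGene) effect magnitudes uniform on [0.5, 1.5] sd of
    dosage with random sign, unit expression noise, and a population-scaled
    recombination intensity giving a few crossovers per simulated haplotype.
    """

    K_panel: int = 60
    V_sites: int = 300
    n_individuals: int = 300
    n_eqtls: int = 150
    genes_per_eqtl: int = 3
    effect_low: float = 0.5
    effect_high: float = 1.5
    noise_sd: float = 1.0
    recomb_scale: float = 50.0
    ld_block_size: int = 5
    n_founders: int = 4
    n_noise_genes: int = 20
    copy_error: float = 0.01
    maf_low: float = 0.05
    maf_high: float = 0.95
    founder_freq_low: float = 0.2
    founder_freq_high: float = 0.8
    cm_per_site: float = 0.01
    hotspot_intensity: float = 0.0  # >0 simulates unmodelled hotspots
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("K_panel", "V_sites", "n_individuals", "n_eqtls",
                     "genes_per_eqtl", "ld_block_size", "n_founders"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_eqtls > self.V_sites:
            raise ValueError("cannot place more eQTLs than sites")


@dataclass
class LinkingFixture:
    """A complete linking experiment: training pairs, shuffled test pairs,
    and extra decoy genotypes drawn from the same (or a frequency-shifted)
    panel.  ``truth`` maps query expression IDs to matching genotype IDs."""

    panel: HaplotypePanel
    eqtl_map: EQTLMap
    train_pairs: list[tuple[GenotypeProfile, ExpressionProfile]]
    test_genotypes: list[GenotypeProfile]
    test_expressions: list[ExpressionProfile]
    decoys: list[GenotypeProfile]
    truth: dict[str, str]
    effects: dict[tuple[int, str], float]
    config: SimConfig


def simulate_panel(cfg: SimConfig, rng: np.random.Generator | None = None) -> HaplotypePanel:
    """Block-LD reference panel.

    Sites are generated in blocks of ``ld_block_size``; within a block every
    panel haplotype copies one of ``n_founders`` founder segments, making
    adjacent sites correlated.  Per-site allele frequencies are pushed into
    [maf_low, maf_high] by flipping entries at degenerate sites.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    K, V = cfg.K_panel, cfg.V_sites
    alleles = np.empty((K, V), dtype=np.int8)
    for start in range(0, V, cfg.ld_block_size):
        width = min(cfg.ld_block_size, V - start)
        freqs = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=width)
        founders = (rng.random((cfg.n_founders, width)) < freqs).astype(np.int8)
        assign = rng.integers(cfg.n_founders, size=K)
        block = founders[assign]
        flip = rng.random((K, width)) < 0.03  # mutation on top of founders
        alleles[:, start:start + width] = block ^ flip
    # enforce frequency bounds
    for s in range(V):
        freq = alleles[:, s].mean()
        if freq < cfg.maf_low:
            need = int(np.ceil((cfg.maf_low - freq) * K))
            zeros = np.flatnonzero(alleles[:, s] == 0)
            alleles[rng.choice(zeros, size=min(need, zeros.size), replace=False), s] = 1
        elif freq > cfg.maf_high:
            need = int(np.ceil((freq - cfg.maf_high) * K))
            ones = np.flatnonzero(alleles[:, s] == 1)
            alleles[rng.choice(ones, size=min(need, ones.size), replace=False), s] = 0
    positions = (np.arange(V, dtype=np.int64) + 1) * 1000
    genetic_pos = np.arange(V, dtype=np.float64) * cfg.cm_per_site
    ids = [f"var{s:05d}" for s in range(V)]
    return HaplotypePanel(alleles, ids, positions, genetic_pos)


def _sample_haplotypes(
    panel: HaplotypePanel, cfg: SimConfig, n_haps: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_haps, V) mosaic copies of panel rows with copy error."""
    params = build_hmm_params(
        panel, cfg.recomb_scale, max(cfg.copy_error, 1e-6)
    )
    switch = params.switch_prob.copy()
    if cfg.hotspot_intensity > 0:
        hot = rng.random(switch.shape[0]) < 0.05
        switch[hot] = np.minimum(1.0, switch[hot] + cfg.hotspot_intensity)
    K, V = panel.K, panel.V
    states = np.empty((n_haps, V), dtype=np.int64)
    states[:, 0] = rng.integers(K, size=n_haps)
    for s in range(1, V):
        jump = rng.random(n_haps) < switch[s - 1]
        states[:, s] = np.where(jump, rng.integers(K, size=n_haps), states[:, s - 1])
    haps = panel.alleles[states, np.arange(V)]
    if cfg.copy_error > 0:
        flips = rng.random((n_haps, V)) < cfg.copy_error
        haps = haps ^ flips
    return haps.astype(np.int8)


def simulate_individuals(
    panel: HaplotypePanel,
    cfg: SimConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "ind",
) -> list[GenotypeProfile]:
    """Diploid individuals as pairs of Li–Stephens mosaics of the panel."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_individuals if n is None else n
    haps = _sample_haplotypes(panel, cfg, 2 * n, rng)
    return [
        GenotypeProfile(
            Haplotype(haps[2 * i]), Haplotype(haps[2 * i + 1]), f"{id_prefix}{i:04d}"
        )
        for i in range(n)
    ]


def simulate_eqtl_map(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[EQTLMap, dict[tuple[int, str], float]]:
    """Random eQTL sites, their eGene sets, and true linear effect sizes.

    Each eQTL gets ``genes_per_eqtl`` private eGenes; effect magnitudes are
    uniform on [effect_low, effect_high] with random sign.  Map significance
    is the absolute effect of the first eGene (used for greedy pruning) and
    the direction hint is its sign.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    sites = np.sort(rng.choice(cfg.V_sites, size=cfg.n_eqtls, replace=False))
    effects: dict[tuple[int, str], float] = {}
    egene_sets = []
    significance = np.empty(cfg.n_eqtls)
    direction = np.empty(cfg.n_eqtls)
    g = 0
    for i, s in enumerate(sites):
        genes = [f"gene{g + k:04d}" for k in range(cfg.genes_per_eqtl)]
        g += cfg.genes_per_eqtl
        for gene in genes:
            mag = rng.uniform(cfg.effect_low, cfg.effect_high)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[(int(s), gene)] = sign * mag
        egene_sets.append(genes)
        significance[i] = abs(effects[(int(s), genes[0])])
        direction[i] = np.sign(effects[(int(s), genes[0])])
    eqtl_map = EQTLMap(sites, egene_sets, significance=significance, direction=direction)
    return eqtl_map, effects


def simulate_expression(
    genotypes: list[GenotypeProfile],
    eqtl_map: EQTLMap,
    cfg: SimConfig,
    effects: dict[tuple[int, str], float] | None = None,
    rng: np.random.Generator | None = None,
) -> list[ExpressionProfile]:
    """Expression linearly coupled to eQTL dosages plus Gaussian noise.

    ``e_g = sum_{s: g in Q(s)} effect_{s,g} * dosage_s + N(0, noise_sd)``;
    ``n_noise_genes`` extra genes carry pure noise.  Effects default to a
    fresh draw per (eQTL, eGene) from the config's distribution.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if effects is None:
        effects = {}
        for s, genes in zip(eqtl_map.site_indices, eqtl_map.egene_sets):
            for gene in genes:
                mag = rng.uniform(cfg.effect_low, cfg.effect_high)
                effects[(int(s), gene)] = mag * (1.0 if rng.random() < 0.5 else -1.0)
    gene_ids: list[str] = []
    for genes in eqtl_map.egene_sets:
        for gene in genes:
            if gene not in gene_ids:
                gene_ids.append(gene)
    gene_ids += [f"noise{k:04d}" for k in range(cfg.n_noise_genes)]
    pos = {gid: j for j, gid in enumerate(gene_ids)}
    n, G = len(genotypes), len(gene_ids)
    E = rng.normal(0.0, cfg.noise_sd, size=(n, G))
    D = np.stack([g.dosage for g in genotypes])
    for (s, gene), eff in effects.items():
        E[:, pos[gene]] += eff * D[:, s]
    return [
        ExpressionProfile(E[i], gene_ids, sample_id=genotypes[i].sample_id)
        for i in range(n)
    ]


def make_linking_fixture(
    cfg: SimConfig | None = None,
    n_train: int = 300,
    n_test: int = 50,
    n_decoys: int = 250,
    decoy_freq_shift: float = 0.0,
) -> LinkingFixture:
    """Complete seeded linking experiment with disjoint train/test/decoys.

    ``decoy_freq_shift`` > 0 draws decoys from a panel whose allele
    frequencies are perturbed, emulating an ancestry-mismatched candidate
    pool.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    panel = simulate_panel(cfg, rng)
    eqtl_map, effects = simulate_eqtl_map(cfg, rng)
    train = simulate_individuals(panel, cfg, n_train, rng, id_prefix="train")
    test = simulate_individuals(panel, cfg, n_test, rng, id_prefix="test")
    if n_decoys > 0:
        decoy_panel = panel
        if decoy_freq_shift > 0:
            shifted = panel.alleles.copy()
            flip = rng.random(shifted.shape) < decoy_freq_shift
            shifted = shifted ^ flip
            decoy_panel = HaplotypePanel(
                shifted, panel.variant_ids, panel.positions, panel.genetic_pos
            )
        decoys = simulate_individuals(decoy_panel, cfg, n_decoys, rng, id_prefix="decoy")
    else:
        decoys = []
    train_expr = simulate_expression(train, eqtl_map, cfg, effects, rng)
    test_expr = simulate_expression(test, eqtl_map, cfg, effects, rng)
    truth = {e.sample_id: g.sample_id for g, e in zip(test, test_expr)}
    return LinkingFixture(
        panel=panel,
        eqtl_map=eqtl_map,
        train_pairs=list(zip(train, train_expr)),
        test_genotypes=test,
        test_expressions=test_expr,
        decoys=decoys,
        truth=truth,
        effects=effects,
        config=cfg,
    )
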