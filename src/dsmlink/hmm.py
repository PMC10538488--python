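"""Li–Stephens haplotype-copying hidden Markov model.

A haplotype is modelled as an error-prone mosaic copy of the rows of a
reference panel.  The hidden state at each site is the index of the panel
haplotype currently being copied; recombination switches the copied source
between adjacent sites with a probability derived from the genetic map, and
the observed allele differs from the copied allele with a small symmetric
error probability.

The forward–backward routine here additionally accepts per-site external
evidence weights, which is how expression-driven eQTL factors are injected
into the chain by :mod:`dsmlink.dsm`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypePanel",
    "HMMParams",
    "Haplotype",
    "SiteEvidence",
    "InvalidGeneticMapError",
    "DegenerateEvidenceError",
    "build_hmm_params",
    "forward_backward",
    "hmm_loglik",
    "diploid_loglik",
    "brute_force_marginal",
]

_BRUTE_FORCE_LIMIT = 10**6


class InvalidGeneticMapError(ValueError):
    """Genetic-map coordinates are not usable (e.g. decreasing)."""


class DegenerateEvidenceError(ValueError):
    """External evidence assigns zero weight to both alleles at a site."""


@dataclass
class HaplotypePanel:
    """Reference panel of K phased haplotypes over V biallelic sites.

    Parameters
    ----------
    alleles
        (K, V) matrix of 0/1 alleles, one row per reference haplotype.
    variant_ids
        V unique variant identifiers.
    positions
        Physical coordinates in bp (1-based, strictly increasing).
    genetic_pos
        Genetic-map coordinates in cM (non-decreasing).
    """

    alleles: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray
    genetic_pos: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=np.float64)
        self.variant_ids = list(self.variant_ids)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 1 or self.alleles.shape[1] < 1:
            raise ValueError("panel must be a non-empty K x V matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel alleles must be 0/1")
        K, V = self.alleles.shape
        if len(self.variant_ids) != V or len(set(self.variant_ids)) != V:
            raise ValueError("variant_ids must be V unique identifiers")
        if self.positions.shape != (V,) or np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing, length V")
        if self.genetic_pos.shape != (V,):
            raise ValueError("genetic_pos must have length V")
        if np.any(np.diff(self.genetic_pos) < 0):
            raise InvalidGeneticMapError("genetic_pos must be non-decreasing")

    @property
    def K(self) -> int:
        return self.alleles.shape[0]

    @property
    def V(self) -> int:
        return self.alleles.shape[1]

    def restrict(self, site_slice: slice) -> "HaplotypePanel":
        """Panel restricted to a contiguous range of sites."""
        return HaplotypePanel(
            self.alleles[:, site_slice],
            self.variant_ids[site_slice],
            self.positions[site_slice],
            self.genetic_pos[site_slice],
        )


@dataclass
class HMMParams:
    """Transition/emission parameters of the copying chain.

    ``switch_prob[s]`` is the probability of a recombination-driven switch
    between sites s and s+1; conditional on a switch the new source is drawn
    uniformly over the K panel rows (self included).  ``emission_error`` is
    the symmetric copy-error probability and ``prior`` the distribution over
    the first hidden state.
    """

    switch_prob: np.ndarray
    emission_error: float
    prior: np.ndarray

    def __post_init__(self) -> None:
        self.switch_prob = np.asarray(self.switch_prob, dtype=np.float64)
        self.prior = np.asarray(self.prior, dtype=np.float64)
        if np.any(self.switch_prob < 0) or np.any(self.switch_prob > 1):
            raise ValueError("switch probabilities must lie in [0, 1]")
        if not (0.0 < self.emission_error < 0.5):
            raise ValueError("emission_error must lie in (0, 0.5)")
        if abs(self.prior.sum() - 1.0) > 1e-12 or np.any(self.prior < 0):
            raise ValueError("prior must be a probability distribution")

    @property
    def K(self) -> int:
        return self.prior.shape[0]


@dataclass
class Haplotype:
    """A single phased haplotype: a length-V vector of 0/1 alleles."""

    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 1 or not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be a 1-D 0/1 vector")

    def __len__(self) -> int:
        return self.alleles.shape[0]


@dataclass
class SiteEvidence:
    """Per-site non-negative weights on the two alleles.

    ``w0[s]`` / ``w1[s]`` multiply the emission probability of allele 0 / 1 at
    site s.  Both weights may not vanish simultaneously at a site.
    """

    w0: np.ndarray
    w1: np.ndarray

    def __post_init__(self) -> None:
        self.w0 = np.asarray(self.w0, dtype=np.float64)
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        if self.w0.shape != self.w1.shape or self.w0.ndim != 1:
            raise ValueError("evidence weights must be two equal-length vectors")
        if np.any(self.w0 < 0) or np.any(self.w1 < 0):
            raise ValueError("evidence weights must be non-negative")
        if np.any((self.w0 == 0) & (self.w1 == 0)):
            raise DegenerateEvidenceError("both alleles have zero weight at some site")

    def __len__(self) -> int:
        return self.w0.shape[0]


def build_hmm_params(
    panel: HaplotypePanel,
    recomb_scale: float = 1.0,
    emission_error: float = 0.01,
) -> HMMParams:
    """Derive chain parameters from the panel's genetic map.

    The switch probability across interval s is
    ``1 - exp(-recomb_scale * dg_s / K)`` with ``dg_s`` the genetic distance
    in cM; the prior over the first copied source is uniform.
    """
    if recomb_scale <= 0:
        raise ValueError("recomb_scale must be positive")
    dg = np.diff(panel.genetic_pos)
    if np.any(dg < 0):
        raise InvalidGeneticMapError("genetic map must be non-decreasing")
    switch = -np.expm1(-recomb_scale * dg / panel.K)
    prior = np.full(panel.K, 1.0 / panel.K)
    return HMMParams(switch, emission_error, prior)


def _emission_matrix(
    h: Haplotype,
    panel: HaplotypePanel,
    params: HMMParams,
    evidence: SiteEvidence | None,
) -> np.ndarray:
    """(V, K) matrix of per-site per-state emission weights."""
    if len(h) != panel.V:
        raise ValueError("haplotype length does not match panel")
    eps = params.emission_error
    match = panel.alleles.T == h.alleles[:, None]  # (V, K)
    emis = np.where(match, 1.0 - eps, eps)
    if evidence is not None:
        if len(evidence) != panel.V:
            raise ValueError("evidence length does not match panel")
        w = np.where(h.alleles == 1, evidence.w1, evidence.w0)
        emis = emis * w[:, None]
    return emis


def forward_backward(
    h: Haplotype,
    panel: HaplotypePanel,
    params: HMMParams,
    evidence: SiteEvidence | None = None,
) -> tuple[float, np.ndarray]:
    """Scaled forward–backward over the copying chain.

    Returns the log marginal probability of the observed haplotype (times any
    evidence weights) and the (V, K) matrix of hidden-state posteriors.  The
    per-site scaling keeps the recursion stable for chains up to V ~ 1e5.
    """
    emis = _emission_matrix(h, panel, params, evidence)
    V, K = emis.shape
    rho = params.switch_prob
    fwd = np.empty((V, K))
    scale = np.empty(V)

    a = params.prior * emis[0]
    c = a.sum()
    if c <= 0:
        raise DegenerateEvidenceError("zero total emission weight at site 0")
    fwd[0] = a / c
    scale[0] = c
    for s in range(1, V):
        pred = (1.0 - rho[s - 1]) * fwd[s - 1] + rho[s - 1] / K
        a = pred * emis[s]
        c = a.sum()
        if c <= 0:
            raise DegenerateEvidenceError(f"zero total emission weight at site {s}")
        fwd[s] = a / c
        scale[s] = c
    log_marginal = float(np.log(scale).sum())

    post = np.empty((V, K))
    beta = np.ones(K)
    post[V - 1] = fwd[V - 1]
    for s in range(V - 2, -1, -1):
        tmp = beta * emis[s + 1] / scale[s + 1]
        beta = (1.0 - rho[s]) * tmp + rho[s] * tmp.sum() / K
        g = fwd[s] * beta
        post[s] = g / g.sum()
    return log_marginal, post


def hmm_loglik(h: Haplotype, panel: HaplotypePanel, params: HMMParams) -> float:
    """log p_HMM(h): marginal likelihood of a haplotype with no evidence."""
    log_marginal, _ = forward_backward(h, panel, params, evidence=None)
    return log_marginal


def diploid_loglik(maternal: Haplotype, paternal: Haplotype, panel: HaplotypePanel, params: HMMParams) -> float:
    """log p_HMM(x) for a phased genotype: the two chains are independent."""
    return hmm_loglik(maternal, panel, params) + hmm_loglik(paternal, panel, params)


def brute_force_marginal(
    h: Haplotype,
    panel: HaplotypePanel,
    params: HMMParams,
    evidence: SiteEvidence | None = None,
) -> float:
    """Exhaustive log marginal over all K^V hidden-state paths.

    Test oracle for :func:`forward_backward`; refuses instances with more
    than 1e6 paths.
    """
    K, V = panel.K, panel.V
    if K**V > _BRUTE_FORCE_LIMIT:
        raise ValueError("instance too large for brute-force enumeration")
    emis = _emission_matrix(h, panel, params, evidence)
    rho = params.switch_prob
    total = 0.0
    for path in itertools.product(range(K), repeat=V):
        p = params.prior[path[0]] * emis[0, path[0]]
        for s in range(1, V):
            stay = path[s] == path[s - 1]
            trans = (1.0 - rho[s - 1]) * stay + rho[s - 1] / K
            p *= trans * emis[s, path[s]]
        total += p
    return float(np.log(total))
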