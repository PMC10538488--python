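"""Discriminative sequence model (DSM) over eQTL genotypes.

The DSM is a conditional random field over a phased genotype sequence given a
gene-expression profile.  It combines, per haplotype, a Li–Stephens copying
chain over a reference panel (capturing LD) with one logistic "QTL factor"
per eQTL site linking the allele to the expression of the eQTL's associated
genes (eGenes):

    phi_s(h_s, e) = h_s * sigmoid(alpha_s + beta_s . e_Q(s))
                    + (1 - h_s) * (1 - sigmoid(alpha_s + beta_s . e_Q(s)))

The unnormalized conditional over a diploid genotype x = (h_m, h_p)
factorizes across the two haplotypes, so inference runs two independent
chains (linear, not quadratic, in the panel size K).  The match score used
for linking is the expression-conditional probability normalized by the
haplotype prior,  log M(x, e) = log p~(x | e) - log p_HMM(x), which reduces
to the sum of the log QTL factors at the observed alleles.

Training maximizes the *normalized* conditional likelihood
sum_i [log p~(h_m | e) + log p~(h_p | e) - 2 log Z_h(e)] where Z_h(e) sums
the chain over both the hidden copying state and the free allele at every
site.  The partition function couples the sites through the panel's LD
structure, which is what calibrates redundant eQTL signals.  Its gradient
with respect to the logit at site s is simply
(observed dosage) - 2 * (model posterior allele probability), so the
optimizer needs no autodiff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hmm import (
    HaplotypePanel,
    HMMParams,
    Haplotype,
    SiteEvidence,
    build_hmm_params,
    forward_backward,
    hmm_loglik,
)

__all__ = [
    "ExpressionProfile",
    "GenotypeProfile",
    "EQTLMap",
    "QTLFactorParams",
    "DSMParams",
    "TrainConfig",
    "qtl_factor",
    "expression_matrix",
    "dosage_matrix",
    "evidence_from_expression",
    "dsm_haplotype_logmarginal",
    "dsm_logscore",
    "dsm_exact_diploid_logscore",
    "dsm_score_matrix",
    "factor_probs",
    "crf_site_posteriors",
    "predict_dosage",
    "conditional_loglik",
    "train_dsm",
    "windowed_training",
    "WindowedDSM",
]

PROB_FLOOR = 1e-12


@dataclass
class ExpressionProfile:
    """Normalized expression values for one sample, keyed by gene ID."""

    values: np.ndarray
    gene_ids: list[str]
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 1 or self.values.shape[0] != len(self.gene_ids):
            raise ValueError("values and gene_ids must have equal length")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")


@dataclass
class GenotypeProfile:
    """A phased pair of haplotypes over the model's sites."""

    maternal: Haplotype
    paternal: Haplotype
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.maternal) != len(self.paternal):
            raise ValueError("haplotypes must have equal length")

    @property
    def dosage(self) -> np.ndarray:
        return self.maternal.alleles.astype(np.int64) + self.paternal.alleles


@dataclass
class EQTLMap:
    """eQTL sites and their eGene sets.

    ``site_indices[s]`` indexes the panel's sites; ``egene_sets[s]`` is the
    non-empty list of gene IDs associated with eQTL s.  ``significance`` (for
    greedy pruning) and ``direction`` (sign of association, for EBL) are
    optional hints.  Site indices must be distinct: eQTL records sharing a
    variant are merged (one site, one factor) by :meth:`from_records`.
    """

    site_indices: np.ndarray
    egene_sets: list[list[str]]
    significance: np.ndarray | None = None
    direction: np.ndarray | None = None
    eqtl_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        self.egene_sets = [list(g) for g in self.egene_sets]
        if len(self.egene_sets) != self.site_indices.shape[0]:
            raise ValueError("one eGene set per eQTL site required")
        if any(len(g) == 0 for g in self.egene_sets):
            raise ValueError("every eQTL must have at least one eGene")
        if len(np.unique(self.site_indices)) != self.site_indices.shape[0]:
            raise ValueError("eQTL site indices must be distinct (merge duplicates first)")
        if self.significance is not None:
            self.significance = np.asarray(self.significance, dtype=np.float64)
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=np.float64)
        if self.eqtl_ids is None:
            self.eqtl_ids = [f"eqtl_{i}" for i in self.site_indices]

    @property
    def n_eqtls(self) -> int:
        return self.site_indices.shape[0]

    @classmethod
    def from_records(
        cls,
        site_indices,
        egene_sets,
        significance=None,
        direction=None,
        eqtl_ids=None,
    ) -> "EQTLMap":
        """Build a map, merging records that share a panel site.

        Merged records pool their eGene sets; significance takes the maximum
        and direction/ID follow the most significant record.
        """
        site_indices = np.asarray(site_indices, dtype=np.int64)
        n = site_indices.shape[0]
        sig = np.zeros(n) if significance is None else np.asarray(significance, float)
        merged: dict[int, dict] = {}
        for i in range(n):
            s = int(site_indices[i])
            rec = merged.setdefault(
                s, {"genes": [], "sig": -np.inf, "dir": None, "id": None}
            )
            for g in egene_sets[i]:
                if g not in rec["genes"]:
                    rec["genes"].append(g)
            if sig[i] >= rec["sig"]:
                rec["sig"] = sig[i]
                rec["dir"] = None if direction is None else direction[i]
                rec["id"] = None if eqtl_ids is None else eqtl_ids[i]
        order = sorted(merged)
        return cls(
            np.array(order, dtype=np.int64),
            [merged[s]["genes"] for s in order],
            significance=np.array([merged[s]["sig"] for s in order]),
            direction=(
                None
                if direction is None
                else np.array([merged[s]["dir"] for s in order], dtype=np.float64)
            ),
            eqtl_ids=(
                None if eqtl_ids is None else [merged[s]["id"] for s in order]
            ),
        )


@dataclass
class QTLFactorParams:
    """Per-eQTL intercepts and eGene weight vectors."""

    alphas: np.ndarray
    betas: list[np.ndarray]

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=np.float64)
        self.betas = [np.asarray(b, dtype=np.float64) for b in self.betas]
        if len(self.betas) != self.alphas.shape[0]:
            raise ValueError("one beta vector per eQTL required")
        if not np.isfinite(self.alphas).all() or any(
            not np.isfinite(b).all() for b in self.betas
        ):
            raise ValueError("factor parameters must be finite")


@dataclass
class DSMParams:
    """Trained DSM bundle: chain parameters, QTL factors, and the frozen
    expression standardization (per-gene mean/sd from the training data)."""

    hmm: HMMParams
    qtl: QTLFactorParams
    eqtl_map: EQTLMap
    panel: HaplotypePanel
    gene_ids: list[str] = field(default_factory=list)
    gene_means: np.ndarray | None = None
    gene_sds: np.ndarray | None = None
    train_loss: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.qtl.alphas.shape[0] != self.eqtl_map.n_eqtls:
            raise ValueError("one factor per eQTL required")
        for b, genes in zip(self.qtl.betas, self.eqtl_map.egene_sets):
            if b.shape[0] != len(genes):
                raise ValueError("beta length must match eGene set size")
        if np.any(self.eqtl_map.site_indices >= self.panel.V):
            raise ValueError("eQTL site index out of panel range")
        if not self.gene_ids:
            seen: list[str] = []
            for genes in self.eqtl_map.egene_sets:
                for g in genes:
                    if g not in seen:
                        seen.append(g)
            self.gene_ids = seen
        G = len(self.gene_ids)
        if self.gene_means is None:
            self.gene_means = np.zeros(G)
        if self.gene_sds is None:
            self.gene_sds = np.ones(G)
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        self._gene_idx = [
            np.array([self._gene_pos[g] for g in genes], dtype=np.int64)
            for genes in self.eqtl_map.egene_sets
        ]

    @classmethod
    def flat(
        cls,
        panel: HaplotypePanel,
        eqtl_map: EQTLMap,
        hmm: HMMParams | None = None,
        **kwargs,
    ) -> "DSMParams":
        """Untrained parameters: alpha = beta = 0 (uninformative factors)."""
        if hmm is None:
            hmm = build_hmm_params(panel)
        qtl = QTLFactorParams(
            np.zeros(eqtl_map.n_eqtls),
            [np.zeros(len(g)) for g in eqtl_map.egene_sets],
        )
        return cls(hmm, qtl, eqtl_map, panel, **kwargs)


@dataclass
class TrainConfig:
    """Optimizer and chain hyperparameters for factor learning.

    Defaults: Adam with learning rate 0.025 for 50 full-batch epochs, flat
    (zero) initialization, symmetric copy error 0.01 and recombination scale
    1.0 for the frozen chain.
    """

    learning_rate: float = 0.025
    epochs: int = 50
    emission_error: float = 0.01
    recomb_scale: float = 1.0
    standardize: bool = True
    seed: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def qtl_factor(h_allele: int, e_sub: np.ndarray, alpha: float, beta: np.ndarray) -> float:
    """Probability the QTL factor assigns to one allele given eGene expression."""
    e_sub = np.asarray(e_sub, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if e_sub.shape != beta.shape:
        raise ValueError("beta and expression subset must have equal length")
    p = float(_sigmoid(np.array([alpha + beta @ e_sub]))[0])
    p = min(max(p, PROB_FLOOR), 1.0 - PROB_FLOOR)
    return p if h_allele == 1 else 1.0 - p


def expression_matrix(profiles: list[ExpressionProfile], gene_ids: list[str]) -> np.ndarray:
    """(n, G) matrix of expression values in a fixed gene order."""
    out = np.empty((len(profiles), len(gene_ids)))
    for i, prof in enumerate(profiles):
        pos = {g: j for j, g in enumerate(prof.gene_ids)}
        try:
            idx = [pos[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene ID {exc.args[0]!r} missing from expression profile") from exc
        out[i] = prof.values[idx]
    return out


def dosage_matrix(profiles: list[GenotypeProfile], site_indices: np.ndarray) -> np.ndarray:
    """(n, S) dosage matrix at the given panel sites."""
    return np.stack([p.dosage[site_indices] for p in profiles])


def _standardized(params: DSMParams, E: np.ndarray) -> np.ndarray:
    return (E - params.gene_means) / params.gene_sds


def _logits(params: DSMParams, E_std: np.ndarray) -> np.ndarray:
    """(n, S) factor logits for standardized expression rows."""
    n = E_std.shape[0]
    L = np.tile(params.qtl.alphas, (n, 1))
    for s, idx in enumerate(params._gene_idx):
        if idx.size:
            L[:, s] += E_std[:, idx] @ params.qtl.betas[s]
    return L


def factor_probs(params: DSMParams, profiles: list[ExpressionProfile]) -> np.ndarray:
    """(n, S) clipped allele-1 factor probabilities sigma(alpha + beta.e)."""
    E = _standardized(params, expression_matrix(profiles, params.gene_ids))
    return np.clip(_sigmoid(_logits(params, E)), PROB_FLOOR, 1.0 - PROB_FLOOR)


def evidence_from_expression(params: DSMParams, e: ExpressionProfile) -> SiteEvidence:
    """Site evidence carrying the QTL factors (weight 1 at non-eQTL sites)."""
    p = factor_probs(params, [e])[0]
    w1 = np.ones(params.panel.V)
    w0 = np.ones(params.panel.V)
    w1[params.eqtl_map.site_indices] = p
    w0[params.eqtl_map.site_indices] = 1.0 - p
    return SiteEvidence(w0, w1)


def dsm_haplotype_logmarginal(h: Haplotype, e: ExpressionProfile, params: DSMParams) -> float:
    """log p~_DSM(h | e): copying-chain marginal with QTL-factor evidence."""
    evidence = evidence_from_expression(params, e)
    log_m, _ = forward_backward(h, params.panel, params.hmm, evidence)
    return log_m


def dsm_logscore(x: GenotypeProfile, e: ExpressionProfile, params: DSMParams) -> float:
    """log M(x, e) = log p~_DSM(x | e) - log p_HMM(x)."""
    num = dsm_haplotype_logmarginal(x.maternal, e, params) + dsm_haplotype_logmarginal(
        x.paternal, e, params
    )
    den = hmm_loglik(x.maternal, params.panel, params.hmm) + hmm_loglik(
        x.paternal, params.panel, params.hmm
    )
    return num - den


def dsm_score_matrix(
    queries: list[ExpressionProfile],
    candidates: list[GenotypeProfile],
    params: DSMParams,
) -> np.ndarray:
    """(n_queries, n_candidates) log match scores.

    Because the QTL factors enter the chain as per-site constants once the
    alleles are observed, the chain terms cancel in the score and
    log M = sum_s [h_m log p_s + h_p log p_s + ...] = D log p + (2 - D) log(1 - p),
    which vectorizes as two matrix products.
    """
    P = factor_probs(params, queries)
    D = dosage_matrix(candidates, params.eqtl_map.site_indices).astype(np.float64)
    return np.log(P) @ D.T + np.log1p(-P) @ (2.0 - D).T


def _genotype_factor(dosage: int, logit: float, kind: str, cutpoint: float) -> float:
    """Genotype-level factor phi_s(x_s, e) for the exact diploid model."""
    if kind == "product":
        p = float(np.clip(_sigmoid(np.array([logit]))[0], PROB_FLOOR, 1 - PROB_FLOOR))
        return {0: (1 - p) ** 2, 1: p * (1 - p), 2: p * p}[dosage]
    if kind == "ordinal":
        lo = float(_sigmoid(np.array([-cutpoint - logit]))[0])
        hi = float(_sigmoid(np.array([cutpoint - logit]))[0])
        probs = {0: lo, 1: hi - lo, 2: 1.0 - hi}
        return max(probs[dosage], PROB_FLOOR)
    raise ValueError(f"unknown genotype factor kind: {kind}")


def dsm_exact_diploid_logscore(
    x: GenotypeProfile,
    e: ExpressionProfile,
    params: DSMParams,
    factor: str = "product",
    cutpoint: float = 1.0,
) -> float:
    """Exact paired-chain log marginal with genotype-level QTL factors.

    Runs forward over the joint (z_m, z_p) state space (K^2 states), so it is
    only feasible for small panels; used to quantify what the haplotype
    decoupling changes.  With ``factor="product"`` the genotype factor is the
    product of the two haplotype factors and the result equals the sum of the
    two haplotype-level log marginals.  ``factor="ordinal"`` uses a 3-level
    ordinal-logistic factor over dosage, which does not decouple.

    Note the genotype-level phi of the product kind assigns p(1-p) to a
    heterozygote (one ordered configuration), matching the phased model.
    """
    panel, hmm = params.panel, params.hmm
    K, V = panel.K, panel.V
    if K * K > 10**6:
        raise ValueError("paired-chain state space too large")
    eps = hmm.emission_error
    rho = hmm.switch_prob
    logits = _logits(params, _standardized(params, expression_matrix([e], params.gene_ids)))[0]
    site_logit = {int(s): logits[i] for i, s in enumerate(params.eqtl_map.site_indices)}
    dose = x.dosage

    def site_weight(s: int) -> float:
        if s not in site_logit:
            return 1.0
        return _genotype_factor(int(dose[s]), site_logit[s], factor, cutpoint)

    def emis(s: int) -> np.ndarray:
        em = np.where(panel.alleles[:, s] == x.maternal.alleles[s], 1 - eps, eps)
        ep = np.where(panel.alleles[:, s] == x.paternal.alleles[s], 1 - eps, eps)
        return np.outer(em, ep) * site_weight(s)

    a = np.outer(hmm.prior, hmm.prior) * emis(0)
    c = a.sum()
    log_m = np.log(c)
    a /= c
    for s in range(1, V):
        r = rho[s - 1]
        # transition applied independently on each chain axis
        a = (1 - r) * a + r / K * a.sum(axis=0, keepdims=True)
        a = (1 - r) * a + r / K * a.sum(axis=1, keepdims=True)
        a *= emis(s)
        c = a.sum()
        log_m += np.log(c)
        a /= c
    return float(log_m)


# ---------------------------------------------------------------------------
# Batched chain computations used for training and posterior prediction
# ---------------------------------------------------------------------------


def _crf_forward_backward(
    panel_alleles: np.ndarray,
    rho: np.ndarray,
    eps: float,
    P: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition function and allele posteriors of the free-allele chain.

    At each site the allele is summed out together with the copy error, so
    the per-state weight is (1-eps)*phi(a_panel) + eps*phi(1-a_panel).

    Parameters
    ----------
    panel_alleles : (K, V) 0/1 panel matrix.
    rho : (V-1,) switch probabilities.
    P : (n, V) allele-1 factor probability per individual and site
        (0.5 at sites without an eQTL factor).

    Returns
    -------
    logZ : (n,) log partition function per individual.
    q : (n, V) posterior probability of allele 1 per site.
    """
    K, V = panel_alleles.shape
    n = P.shape[0]
    A = panel_alleles.astype(bool)
    U1 = (1 - eps) * P + eps * (1 - P)  # state copies allele 1
    U0 = (1 - eps) * (1 - P) + eps * P  # state copies allele 0
    # posterior numerator for allele 1 given the state
    N1_1 = (1 - eps) * P  # panel allele 1
    N1_0 = eps * P        # panel allele 0

    F = np.empty((V, n, K))
    logZ = np.zeros(n)
    xi = np.where(A[:, 0], U1[:, 0:1], U0[:, 0:1])
    f = xi / K
    c = f.sum(axis=1)
    logZ += np.log(c)
    f /= c[:, None]
    F[0] = f
    for s in range(1, V):
        r = rho[s - 1]
        pred = (1 - r) * f + r / K
        xi = np.where(A[:, s], U1[:, s:s + 1], U0[:, s:s + 1])
        f = pred * xi
        c = f.sum(axis=1)
        logZ += np.log(c)
        f /= c[:, None]
        F[s] = f

    q = np.empty((n, V))
    b = np.ones((n, K))

    def site_q(s: int, gamma: np.ndarray) -> np.ndarray:
        xi_s = np.where(A[:, s], U1[:, s:s + 1], U0[:, s:s + 1])
        nu = np.where(A[:, s], N1_1[:, s:s + 1], N1_0[:, s:s + 1])
        return (gamma * nu / xi_s).sum(axis=1)

    q[:, V - 1] = site_q(V - 1, F[V - 1])
    for s in range(V - 2, -1, -1):
        r = rho[s]
        xi_next = np.where(A[:, s + 1], U1[:, s + 1:s + 2], U0[:, s + 1:s + 2])
        tmp = b * xi_next
        tmp /= tmp.sum(axis=1, keepdims=True)
        b = (1 - r) * tmp + r / K * tmp.sum(axis=1, keepdims=True)
        g = F[s] * b
        g /= g.sum(axis=1, keepdims=True)
        q[:, s] = site_q(s, g)
    return logZ, q


def _batched_hmm_loglik(
    H: np.ndarray, panel_alleles: np.ndarray, rho: np.ndarray, eps: float
) -> np.ndarray:
    """(m,) log p_HMM for m observed haplotype rows (vectorized forward)."""
    K, V = panel_alleles.shape
    m = H.shape[0]
    logL = np.zeros(m)
    emis = np.where(panel_alleles[None, :, 0] == H[:, 0:1], 1 - eps, eps)
    f = emis / K
    c = f.sum(axis=1)
    logL += np.log(c)
    f /= c[:, None]
    for s in range(1, V):
        r = rho[s - 1]
        pred = (1 - r) * f + r / K
        emis = np.where(panel_alleles[None, :, s] == H[:, s:s + 1], 1 - eps, eps)
        f = pred * emis
        c = f.sum(axis=1)
        logL += np.log(c)
        f /= c[:, None]
    return logL


@dataclass
class _TrainingData:
    E_std: np.ndarray          # (n, G) standardized expression
    D: np.ndarray              # (n, S) dosage at eQTL sites
    gene_idx: list[np.ndarray]
    panel_alleles: np.ndarray
    rho: np.ndarray
    eps: float
    site_indices: np.ndarray
    const_hmm: float           # sum_i log p_HMM(h_m) + log p_HMM(h_p)


def _prepare_training(
    pairs: list[tuple[GenotypeProfile, ExpressionProfile]],
    panel: HaplotypePanel,
    eqtl_map: EQTLMap,
    cfg: TrainConfig,
) -> tuple[_TrainingData, DSMParams]:
    if len(pairs) < 2:
        raise ValueError("training requires at least two matched pairs")
    genos = [g for g, _ in pairs]
    exprs = [e for _, e in pairs]
    hmm = build_hmm_params(panel, cfg.recomb_scale, cfg.emission_error)
    params = DSMParams.flat(panel, eqtl_map, hmm)
    E = expression_matrix(exprs, params.gene_ids)
    if cfg.standardize:
        means = E.mean(axis=0)
        sds = E.std(axis=0)
        sds[sds == 0] = 1.0
    else:
        means = np.zeros(E.shape[1])
        sds = np.ones(E.shape[1])
    params.gene_means, params.gene_sds = means, sds
    E_std = (E - means) / sds
    D = dosage_matrix(genos, eqtl_map.site_indices).astype(np.float64)
    H = np.concatenate(
        [np.stack([g.maternal.alleles for g in genos]),
         np.stack([g.paternal.alleles for g in genos])]
    )
    const = float(_batched_hmm_loglik(H, panel.alleles, hmm.switch_prob, hmm.emission_error).sum())
    data = _TrainingData(
        E_std, D, params._gene_idx, panel.alleles, hmm.switch_prob,
        hmm.emission_error, eqtl_map.site_indices, const,
    )
    return data, params


def _objective_and_grad(
    alphas: np.ndarray,
    betas: list[np.ndarray],
    data: _TrainingData,
    want_grad: bool = True,
) -> tuple[float, np.ndarray | None, list[np.ndarray] | None]:
    """Mean per-pair normalized conditional log-likelihood and its gradient."""
    n, S = data.D.shape
    V = data.panel_alleles.shape[1]
    L = np.tile(alphas, (n, 1))
    for s, idx in enumerate(data.gene_idx):
        if idx.size:
            L[:, s] += data.E_std[:, idx] @ betas[s]
    p = np.clip(_sigmoid(L), PROB_FLOOR, 1.0 - PROB_FLOOR)
    P_full = np.full((n, V), 0.5)
    P_full[:, data.site_indices] = p
    logZ, q_full = _crf_forward_backward(data.panel_alleles, data.rho, data.eps, P_full)
    # the free-allele chain at non-eQTL sites carries flat 0.5 factors whose
    # weight also multiplies the observed-haplotype term, so both sides of the
    # objective include them consistently:
    flat_sites = V - S
    obs = (data.D * np.log(p) + (2.0 - data.D) * np.log1p(-p)).sum()
    obs += 2.0 * n * flat_sites * np.log(0.5)
    loglik = (data.const_hmm + obs - 2.0 * logZ.sum()) / n
    if not np.isfinite(loglik):
        raise RuntimeError("non-finite training objective (diverging factors?)")
    if not want_grad:
        return loglik, None, None
    q = q_full[:, data.site_indices]
    G_logit = (data.D - 2.0 * q) / n
    g_alpha = G_logit.sum(axis=0)
    g_betas = [
        data.E_std[:, idx].T @ G_logit[:, s] if idx.size else np.zeros(0)
        for s, idx in enumerate(data.gene_idx)
    ]
    return loglik, g_alpha, g_betas


def _data_from_params(
    pairs: list[tuple[GenotypeProfile, ExpressionProfile]],
    params: DSMParams,
) -> _TrainingData:
    """Assemble batched training arrays using a bundle's frozen chain and
    frozen expression standardization."""
    genos = [g for g, _ in pairs]
    E = expression_matrix([e for _, e in pairs], params.gene_ids)
    E_std = _standardized(params, E)
    D = dosage_matrix(genos, params.eqtl_map.site_indices).astype(np.float64)
    H = np.concatenate(
        [np.stack([g.maternal.alleles for g in genos]),
         np.stack([g.paternal.alleles for g in genos])]
    )
    const = float(
        _batched_hmm_loglik(
            H, params.panel.alleles, params.hmm.switch_prob, params.hmm.emission_error
        ).sum()
    )
    return _TrainingData(
        E_std, D, params._gene_idx, params.panel.alleles,
        params.hmm.switch_prob, params.hmm.emission_error,
        params.eqtl_map.site_indices, const,
    )


def conditional_loglik(
    pairs: list[tuple[GenotypeProfile, ExpressionProfile]],
    params: DSMParams,
) -> float:
    """Mean normalized per-pair conditional log-likelihood log p_DSM(x | e)."""
    data = _data_from_params(pairs, params)
    value, _, _ = _objective_and_grad(
        params.qtl.alphas, params.qtl.betas, data, want_grad=False
    )
    return value


def train_dsm(
    pairs: list[tuple[GenotypeProfile, ExpressionProfile]],
    panel: HaplotypePanel,
    eqtl_map: EQTLMap,
    cfg: TrainConfig | None = None,
) -> DSMParams:
    """Jointly fit all QTL factors by full-batch Adam ascent.

    The chain (HMM) parameters are frozen; only (alpha_s, beta_s) move.
    Returns the fitted :class:`DSMParams` with the per-epoch objective trace
    in ``train_loss`` (negative mean conditional log-likelihood).
    """
    cfg = cfg or TrainConfig()
    data, params = _prepare_training(pairs, panel, eqtl_map, cfg)
    alphas = params.qtl.alphas.copy()
    betas = [b.copy() for b in params.qtl.betas]

    # hand-coded Adam (maximization)
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    m_a = np.zeros_like(alphas)
    v_a = np.zeros_like(alphas)
    m_b = [np.zeros_like(b) for b in betas]
    v_b = [np.zeros_like(b) for b in betas]
    trace = np.empty(cfg.epochs)
    for t in range(1, cfg.epochs + 1):
        loglik, g_a, g_b = _objective_and_grad(alphas, betas, data)
        trace[t - 1] = -loglik
        m_a = b1 * m_a + (1 - b1) * g_a
        v_a = b2 * v_a + (1 - b2) * g_a**2
        alphas = alphas + cfg.learning_rate * (m_a / (1 - b1**t)) / (
            np.sqrt(v_a / (1 - b2**t)) + adam_eps
        )
        for s in range(len(betas)):
            if betas[s].size == 0:
                continue
            m_b[s] = b1 * m_b[s] + (1 - b1) * g_b[s]
            v_b[s] = b2 * v_b[s] + (1 - b2) * g_b[s] ** 2
            betas[s] = betas[s] + cfg.learning_rate * (m_b[s] / (1 - b1**t)) / (
                np.sqrt(v_b[s] / (1 - b2**t)) + adam_eps
            )
    params.qtl = QTLFactorParams(alphas, betas)
    params.train_loss = trace
    return params


def crf_site_posteriors(
    params: DSMParams, profiles: list[ExpressionProfile]
) -> np.ndarray:
    """(n, S) model posterior allele-1 probability at the eQTL sites.

    The posterior marginalizes the copying chain, so it blends the
    expression-driven factors with panel LD.
    """
    p = factor_probs(params, profiles)
    n = p.shape[0]
    V = params.panel.V
    P_full = np.full((n, V), 0.5)
    P_full[:, params.eqtl_map.site_indices] = p
    _, q = _crf_forward_backward(
        params.panel.alleles, params.hmm.switch_prob, params.hmm.emission_error, P_full
    )
    return q[:, params.eqtl_map.site_indices]


def predict_dosage(allele_probs: np.ndarray) -> np.ndarray:
    """MAP dosage under the binomial map [(1-p)^2, 2p(1-p), p^2]."""
    p = np.asarray(allele_probs)
    stacked = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    return np.argmax(stacked, axis=0)


@dataclass
class WindowedDSM:
    """A DSM per consecutive window of eQTLs; scores sum across windows."""

    models: list[DSMParams]

    def score_matrix(
        self,
        queries: list[ExpressionProfile],
        candidates: list[GenotypeProfile],
    ) -> np.ndarray:
        total = np.zeros((len(queries), len(candidates)))
        for m in self.models:
            total += dsm_score_matrix(queries, candidates, m)
        return total

    def logscore(self, x: GenotypeProfile, e: ExpressionProfile) -> float:
        return float(self.score_matrix([e], [x])[0, 0])


def windowed_training(
    pairs: list[tuple[GenotypeProfile, ExpressionProfile]],
    panel: HaplotypePanel,
    eqtl_map: EQTLMap,
    window_size: int = 750,
    cfg: TrainConfig | None = None,
) -> WindowedDSM:
    """Train one DSM per consecutive window of ``window_size`` eQTLs.

    Each window's panel is restricted to the contiguous span of sites from
    the window's first to last eQTL (non-eQTL sites in between are kept for
    LD fidelity).  Genotype profiles are sliced accordingly.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if eqtl_map.n_eqtls == 0:
        raise ValueError("empty eQTL map")
    order = np.argsort(eqtl_map.site_indices)
    sites = eqtl_map.site_indices[order]
    chunks = [order[i:i + window_size] for i in range(0, len(sites), window_size)]
    models = []
    prev_end = 0
    for w, chunk in enumerate(chunks):
        lo = prev_end
        hi = panel.V if w == len(chunks) - 1 else int(eqtl_map.site_indices[chunk].max()) + 1
        prev_end = hi
        sub_panel = panel.restrict(slice(lo, hi))
        sub_map = EQTLMap(
            eqtl_map.site_indices[chunk] - lo,
            [eqtl_map.egene_sets[i] for i in chunk],
            significance=(
                None if eqtl_map.significance is None else eqtl_map.significance[chunk]
            ),
            direction=(
                None if eqtl_map.direction is None else eqtl_map.direction[chunk]
            ),
            eqtl_ids=[eqtl_map.eqtl_ids[i] for i in chunk],
        )
        sub_pairs = [
            (
                GenotypeProfile(
                    Haplotype(g.maternal.alleles[lo:hi]),
                    Haplotype(g.paternal.alleles[lo:hi]),
                    g.sample_id,
                ),
                e,
            )
            for g, e in pairs
        ]
        models.append(train_dsm(sub_pairs, sub_panel, sub_map, cfg))
    return WindowedDSM(models)
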