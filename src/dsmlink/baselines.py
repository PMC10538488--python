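"""Published baseline linking scorers: Gaussian naive Bayes and
extremity-based linking, plus the greedy correlation pruning they rely on.

Both baselines treat eQTLs independently, so they operate on a pruned set of
mutually near-independent eQTLs, each with a single eGene.  Genotypes are
collapsed to dosage classes {0, 1, 2} (phase carries no expression signal in
these models).

GNB scores a candidate genotype by Bayes' rule with a per-dosage-class
Gaussian over the eGene's expression and a genotype-frequency prior:

    log score = sum_s [ log N(e_Q(s); mu_{s,x_s}, sigma_s) + log p(x_s) ].

EBL predicts the corresponding homozygote whenever the eGene's expression is
beyond an extremity quantile and the eQTL-eGene association is strong
enough; this hybrid variant falls back to the GNB term at all other sites,
and penalizes a candidate disagreeing with a predicted homozygote by a fixed
``penalty`` in log space (the hard-filtering original is the limit
penalty -> infinity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dsm import (
    EQTLMap,
    ExpressionProfile,
    GenotypeProfile,
    dosage_matrix,
    expression_matrix,
)

__all__ = [
    "GNBParams",
    "EBLParams",
    "prune_eqtls",
    "gnb_fit",
    "gnb_logscore",
    "gnb_score_matrix",
    "ebl_fit",
    "ebl_logscore",
    "ebl_score_matrix",
]

_SIGMA_FLOOR = 1e-6
_PRIOR_FLOOR = 1e-6


@dataclass
class GNBParams:
    """Fitted Gaussian naive Bayes scorer over a pruned eQTL set."""

    eqtl_map: EQTLMap            # pruned, singleton eGene per site
    gene_ids: list[str]          # the single eGene per retained eQTL
    means: np.ndarray            # (S, 3) class means per dosage
    sds: np.ndarray              # (S,) shared (pooled) within-class sd
    priors: np.ndarray           # (S, 3) dosage-class priors

    def __post_init__(self) -> None:
        if np.any(self.sds <= 0):
            raise ValueError("class sds must be positive")
        if np.any(np.abs(self.priors.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("priors must sum to 1 per site")


@dataclass
class EBLParams:
    """Extremity-based linking parameters (hybrid with a GNB fallback)."""

    gnb: GNBParams
    extremity_q: float           # upper-tail quantile in (0.5, 1)
    corr_min: float              # minimum |eQTL-eGene correlation| in (0, 1]
    penalty: float = 5.0         # log-space penalty for a contradicted homozygote
    direction: np.ndarray = field(default=None)  # (S,) sign of association
    lo_thresh: np.ndarray = field(default=None)  # (S,) lower extremity cutoffs
    hi_thresh: np.ndarray = field(default=None)  # (S,) upper extremity cutoffs
    active: np.ndarray = field(default=None)     # (S,) bool, passes corr_min

    def __post_init__(self) -> None:
        if not (0.5 < self.extremity_q < 1.0):
            raise ValueError("extremity quantile must lie in (0.5, 1)")
        if not (0.0 < self.corr_min <= 1.0):
            raise ValueError("correlation threshold must lie in (0, 1]")


def prune_eqtls(
    dosages: np.ndarray,
    eqtl_map: EQTLMap,
    corr_threshold: float = 0.1,
) -> EQTLMap:
    """Greedy significance-ordered pruning of correlated eQTLs.

    Repeatedly keeps the most significant remaining eQTL and drops every
    other eQTL whose training-dosage Pearson correlation with it exceeds
    ``corr_threshold`` in absolute value.  Constant-dosage sites (undefined
    correlation) are excluded with a warning.

    Parameters
    ----------
    dosages : (n_samples, S) training dosage matrix aligned to the map.
    """
    S = eqtl_map.n_eqtls
    if dosages.shape[1] != S:
        raise ValueError("dosage matrix does not align with the eQTL map")
    sig = (
        eqtl_map.significance
        if eqtl_map.significance is not None
        else np.zeros(S)
    )
    sds = dosages.std(axis=0)
    degenerate = sds == 0
    if degenerate.any():
        warnings.warn(
            f"excluding {int(degenerate.sum())} constant-dosage eQTL site(s) "
            "with undefined correlation"
        )
    order = np.argsort(-sig, kind="stable")
    kept: list[int] = []
    removed = degenerate.copy()
    X = dosages - dosages.mean(axis=0)
    denom = sds * np.sqrt(dosages.shape[0])
    for s in order:
        if removed[s]:
            continue
        kept.append(int(s))
        r = np.zeros(S)
        ok = ~degenerate
        r[ok] = (X[:, ok].T @ X[:, s]) / (denom[ok] * denom[s])
        removed |= np.abs(r) > corr_threshold
        removed[s] = True  # processed
    kept.sort()
    return EQTLMap(
        eqtl_map.site_indices[kept],
        [eqtl_map.egene_sets[i] for i in kept],
        significance=sig[kept],
        direction=(
            None if eqtl_map.direction is None else eqtl_map.direction[kept]
        ),
        eqtl_ids=[eqtl_map.eqtl_ids[i] for i in kept],
    )


def _top_gene_ids(eqtl_map: EQTLMap) -> list[str]:
    # singleton Q(s): the first (most significant) eGene of each eQTL
    return [genes[0] for genes in eqtl_map.egene_sets]


def gnb_fit(
    pairs: list[tuple[GenotypeProfile, ExpressionProfile]],
    pruned_map: EQTLMap,
) -> GNBParams:
    """Estimate per-dosage Gaussian means, pooled sds, and dosage priors."""
    genes = _top_gene_ids(pruned_map)
    E = expression_matrix([e for _, e in pairs], genes)  # (n, S)
    D = dosage_matrix([g for g, _ in pairs], pruned_map.site_indices)
    n, S = E.shape
    means = np.empty((S, 3))
    sds = np.empty(S)
    priors = np.empty((S, 3))
    for s in range(S):
        counts = np.array([(D[:, s] == d).sum() for d in range(3)])
        priors[s] = np.maximum(counts / n, _PRIOR_FLOOR)
        priors[s] /= priors[s].sum()
        # per-class means; empty or singleton classes fall back to the
        # linear regression of expression on dosage evaluated at that dosage
        slope, intercept = np.polyfit(D[:, s], E[:, s], 1) if np.ptp(D[:, s]) else (0.0, E[:, s].mean())
        resid_sq = 0.0
        n_resid = 0
        for d in range(3):
            mask = D[:, s] == d
            if counts[d] >= 2:
                means[s, d] = E[mask, s].mean()
                resid_sq += ((E[mask, s] - means[s, d]) ** 2).sum()
                n_resid += counts[d]
            elif counts[d] == 1:
                means[s, d] = E[mask, s][0]
            else:
                means[s, d] = intercept + slope * d
        sd = np.sqrt(resid_sq / max(n_resid, 1)) if n_resid else E[:, s].std()
        if sd <= _SIGMA_FLOOR:
            warnings.warn(f"zero within-class variance at eQTL {s}; flooring sigma")
            sd = _SIGMA_FLOOR
        sds[s] = sd
    return GNBParams(pruned_map, genes, means, sds, priors)


def _gnb_site_terms(params: GNBParams, e_values: np.ndarray) -> np.ndarray:
    """(S, 3) log N(e_s; mu_{s,d}, sigma_s) + log prior for one profile."""
    e = e_values[:, None]
    ll = (
        -0.5 * np.log(2 * np.pi)
        - np.log(params.sds)[:, None]
        - 0.5 * ((e - params.means) / params.sds[:, None]) ** 2
    )
    return ll + np.log(params.priors)


def gnb_logscore(
    x: GenotypeProfile, e: ExpressionProfile, params: GNBParams
) -> float:
    """GNB log match score of one candidate genotype for one query."""
    ev = expression_matrix([e], params.gene_ids)[0]
    d = x.dosage[params.eqtl_map.site_indices]
    terms = _gnb_site_terms(params, ev)
    return float(terms[np.arange(len(d)), d].sum())


def gnb_score_matrix(
    queries: list[ExpressionProfile],
    candidates: list[GenotypeProfile],
    params: GNBParams,
) -> np.ndarray:
    """(n_queries, n_candidates) GNB log match scores."""
    Ev = expression_matrix(queries, params.gene_ids)
    D = dosage_matrix(candidates, params.eqtl_map.site_indices)
    out = np.empty((len(queries), len(candidates)))
    cols = np.arange(D.shape[1])
    for j in range(len(queries)):
        terms = _gnb_site_terms(params, Ev[j])  # (S, 3)
        out[j] = terms[cols, D].sum(axis=1)
    return out


def ebl_fit(
    pairs: list[tuple[GenotypeProfile, ExpressionProfile]],
    pruned_map: EQTLMap,
    extremity_q: float = 0.95,
    corr_min: float = 0.3,
    penalty: float = 5.0,
) -> EBLParams:
    """Fit the hybrid EBL scorer.

    Extremity cutoffs are the (1 - q) and q empirical quantiles of each
    eGene's training expression; the direction of association and the
    eQTL-eGene correlation come from the training data unless the map
    provides direction hints.
    """
    if pruned_map.n_eqtls == 0:
        raise ValueError("empty eQTL map: no retained eQTLs to fit")
    gnb = gnb_fit(pairs, pruned_map)
    genes = gnb.gene_ids
    E = expression_matrix([e for _, e in pairs], genes)
    D = dosage_matrix([g for g, _ in pairs], pruned_map.site_indices)
    with np.errstate(invalid="ignore"):
        corr = np.array(
            [
                np.corrcoef(D[:, s], E[:, s])[0, 1] if D[:, s].std() > 0 else 0.0
                for s in range(E.shape[1])
            ]
        )
    corr = np.nan_to_num(corr)
    direction = np.sign(corr)
    if pruned_map.direction is not None:
        hinted = pruned_map.direction != 0
        direction[hinted] = np.sign(pruned_map.direction[hinted])
    direction[direction == 0] = 1.0
    return EBLParams(
        gnb=gnb,
        extremity_q=extremity_q,
        corr_min=corr_min,
        penalty=penalty,
        direction=direction,
        lo_thresh=np.quantile(E, 1.0 - extremity_q, axis=0),
        hi_thresh=np.quantile(E, extremity_q, axis=0),
        active=np.abs(corr) >= corr_min,
    )


def _ebl_predicted_dosage(params: EBLParams, e_values: np.ndarray) -> np.ndarray:
    """(S,) predicted homozygous dosage (0 or 2) or -1 where not extreme."""
    pred = np.full(e_values.shape[0], -1, dtype=np.int64)
    hi = params.active & (e_values > params.hi_thresh)
    lo = params.active & (e_values < params.lo_thresh)
    pred[hi] = np.where(params.direction[hi] > 0, 2, 0)
    pred[lo] = np.where(params.direction[lo] > 0, 0, 2)
    return pred


def ebl_logscore(
    x: GenotypeProfile, e: ExpressionProfile, params: EBLParams
) -> float:
    """Hybrid EBL log match score for one candidate/query pair."""
    ev = expression_matrix([e], params.gnb.gene_ids)[0]
    d = x.dosage[params.gnb.eqtl_map.site_indices]
    pred = _ebl_predicted_dosage(params, ev)
    terms = _gnb_site_terms(params.gnb, ev)
    score = 0.0
    for s in range(len(d)):
        if pred[s] < 0:
            score += terms[s, d[s]]
        else:
            score += 0.0 if d[s] == pred[s] else -params.penalty
    return float(score)


def ebl_score_matrix(
    queries: list[ExpressionProfile],
    candidates: list[GenotypeProfile],
    params: EBLParams,
) -> np.ndarray:
    """(n_queries, n_candidates) hybrid EBL log match scores."""
    Ev = expression_matrix(queries, params.gnb.gene_ids)
    D = dosage_matrix(candidates, params.gnb.eqtl_map.site_indices)
    out = np.empty((len(queries), len(candidates)))
    cols = np.arange(D.shape[1])
    for j in range(len(queries)):
        pred = _ebl_predicted_dosage(params, Ev[j])
        terms = _gnb_site_terms(params.gnb, Ev[j])  # (S, 3)
        contrib = terms[cols, D]                     # (n_cand, S)
        ext = np.nonzero(pred >= 0)[0]
        if ext.size:
            contrib[:, ext] = np.where(
                D[:, ext] == pred[ext], 0.0, -params.penalty
            )
        out[j] = contrib.sum(axis=1)
    return out
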