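"""Linking attacks and their evaluation.

Forward linking independently assigns each query expression profile the
best-scoring candidate genotype (row argmax, not a bipartite matching);
reverse linking matches a genotype against candidate expression profiles
with the same pairwise scores.  A per-query Gaussian fitted to the
mismatching-pair scores serves as the null model from which upper-tail
P-values quantify how strongly a match separates from impostors.  When the
target individual's membership in the candidate set is unknown, links are
called only above a score threshold; sweeping the threshold yields
linking-adapted ROC and precision-recall curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .baselines import EBLParams, GNBParams, ebl_score_matrix, gnb_score_matrix
from .dsm import DSMParams, ExpressionProfile, GenotypeProfile, WindowedDSM, dsm_score_matrix

__all__ = [
    "ScoreMatrix",
    "NullModel",
    "LinkResult",
    "ThresholdCurves",
    "score_all",
    "link_forward",
    "link_reverse",
    "fit_null",
    "match_pvalue",
    "thresholded_linking",
    "holdout_trials",
    "linking_accuracy",
]


@dataclass
class ScoreMatrix:
    """Log match scores: rows are queries, columns candidate genotypes."""

    scores: np.ndarray
    query_ids: list[str]
    candidate_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.query_ids), len(self.candidate_ids)):
            raise ValueError("score matrix shape does not match ID lists")
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix entries must be finite")
        if len(set(self.query_ids)) != len(self.query_ids):
            raise ValueError("query IDs must be unique")
        if len(set(self.candidate_ids)) != len(self.candidate_ids):
            raise ValueError("candidate IDs must be unique")

    def subset_candidates(self, keep: list[str]) -> "ScoreMatrix":
        idx = [self.candidate_ids.index(c) for c in keep]
        return ScoreMatrix(self.scores[:, idx], self.query_ids, list(keep))


@dataclass
class NullModel:
    """Gaussian null of mismatching-pair log scores for one query."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("null sd must be positive")


@dataclass
class LinkResult:
    """Per-query linking outcome."""

    query_id: str
    best_candidate: str
    log_score: float
    pvalue: float | None = None
    called: bool = True
    tied: bool = False


def _ids(profiles, prefix: str) -> list[str]:
    out = []
    for i, p in enumerate(profiles):
        sid = getattr(p, "sample_id", None)
        out.append(sid if sid is not None else f"{prefix}{i}")
    return out


def score_all(
    queries: list[ExpressionProfile],
    candidates: list[GenotypeProfile],
    model: DSMParams | WindowedDSM | GNBParams | EBLParams,
) -> ScoreMatrix:
    """Score every candidate genotype against every query expression profile.

    The scorer is dispatched on the fitted model type (DSM, windowed DSM,
    GNB, or hybrid EBL).
    """
    if not queries or not candidates:
        raise ValueError("queries and candidates must be non-empty")
    if isinstance(model, DSMParams):
        scores = dsm_score_matrix(queries, candidates, model)
    elif isinstance(model, WindowedDSM):
        scores = model.score_matrix(queries, candidates)
    elif isinstance(model, GNBParams):
        scores = gnb_score_matrix(queries, candidates, model)
    elif isinstance(model, EBLParams):
        scores = ebl_score_matrix(queries, candidates, model)
    else:
        raise TypeError(f"untrained or unsupported scorer: {type(model).__name__}")
    return ScoreMatrix(scores, _ids(queries, "E"), _ids(candidates, "X"))


def link_forward(
    scores: ScoreMatrix,
    nulls: list[NullModel] | None = None,
    threshold: float | None = None,
) -> list[LinkResult]:
    """Row-wise argmax assignment, one candidate per query independently.

    Ties break deterministically toward the lowest candidate-ID order and
    are flagged (a tie indicates zero identifying signal).
    """
    results = []
    for j, qid in enumerate(scores.query_ids):
        row = scores.scores[j]
        best = int(np.argmax(row))
        tied = bool((row == row[best]).sum() > 1)
        pval = None
        if nulls is not None:
            pval = match_pvalue(row[best], nulls[j])
        called = True if threshold is None else bool(row[best] >= threshold)
        results.append(
            LinkResult(qid, scores.candidate_ids[best], float(row[best]), pval, called, tied)
        )
    return results


def link_reverse(
    query: GenotypeProfile,
    candidates: list[ExpressionProfile],
    model,
) -> LinkResult:
    """Match one genotype against candidate expression profiles.

    Uses the same pairwise scores as forward linking, read transposed.
    """
    mat = score_all(candidates, [query], model)
    col = mat.scores[:, 0]
    best = int(np.argmax(col))
    tied = bool((col == col[best]).sum() > 1)
    qid = query.sample_id if query.sample_id is not None else "X0"
    return LinkResult(qid, mat.query_ids[best], float(col[best]), None, True, tied)


def fit_null(
    scores: ScoreMatrix,
    true_pairing: dict[str, str] | None = None,
    min_mismatches: int = 30,
    subsample: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[NullModel]:
    """Per-query Gaussian null over mismatching candidates' scores.

    ``true_pairing`` maps query IDs to their true candidate ID; those entries
    are excluded from the fit.  ``subsample`` caps the number of mismatching
    candidates used per query (the published analyses used 500).
    """
    cand_index = {c: i for i, c in enumerate(scores.candidate_ids)}
    rng = rng or np.random.default_rng(0)
    nulls = []
    for j, qid in enumerate(scores.query_ids):
        row = scores.scores[j]
        mask = np.ones(row.shape[0], dtype=bool)
        if true_pairing and qid in true_pairing and true_pairing[qid] in cand_index:
            mask[cand_index[true_pairing[qid]]] = False
        vals = row[mask]
        if subsample is not None and vals.shape[0] > subsample:
            vals = rng.choice(vals, size=subsample, replace=False)
        if vals.shape[0] < min_mismatches:
            raise ValueError(
                f"query {qid}: only {vals.shape[0]} mismatching candidates "
                f"(need >= {min_mismatches}) to fit a null"
            )
        sd = float(vals.std(ddof=1))
        if sd <= 0:
            raise ValueError(f"query {qid}: degenerate (constant) null scores")
        nulls.append(NullModel(float(vals.mean()), sd))
    return nulls


def match_pvalue(score: float, null: NullModel) -> float:
    """Upper-tail Gaussian P-value of a match score under the null."""
    p = float(stats.norm.sf(score, loc=null.mean, scale=null.sd))
    return max(p, np.finfo(float).tiny)


def linking_accuracy(scores: ScoreMatrix, truth: dict[str, str]) -> float:
    """Fraction of queries whose argmax candidate is their true match."""
    links = link_forward(scores)
    hits = sum(1 for r in links if truth.get(r.query_id) == r.best_candidate)
    return hits / len(links)


@dataclass
class ThresholdCurves:
    """Threshold sweep of linking-adapted classification metrics."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auroc: float
    auprc: float


def thresholded_linking(
    scores: ScoreMatrix,
    truth: dict[str, str | None],
    thresholds: np.ndarray | None = None,
) -> ThresholdCurves:
    """Sweep a call threshold over best match scores.

    ``truth[qid]`` is the true candidate ID for queries whose match is
    present in the candidate set and ``None`` for holdout queries (their
    genotype was removed).  At a threshold t a query is *called* if its best
    score is >= t.  TPR is the fraction of present-match queries called and
    linked to the correct candidate; FPR is the fraction of holdout queries
    called at all (any call for them is wrong); precision counts correct
    calls among all calls.  AUROC and AUPRC are trapezoidal areas over the
    sweep.
    """
    present = [q for q in scores.query_ids if truth.get(q) is not None]
    absent = [q for q in scores.query_ids if truth.get(q) is None]
    if not absent:
        raise ValueError("FPR undefined: no holdout queries without a true match")
    if not present:
        raise ValueError("no present-match queries")
    links = {r.query_id: r for r in link_forward(scores)}
    best = np.array([links[q].log_score for q in scores.query_ids])
    correct = np.array(
        [
            truth.get(q) is not None and links[q].best_candidate == truth[q]
            for q in scores.query_ids
        ]
    )
    is_present = np.array([truth.get(q) is not None for q in scores.query_ids])
    if thresholds is None:
        thresholds = np.concatenate(([np.inf], np.sort(np.unique(best))[::-1], [-np.inf]))
    tpr, fpr, prec, rec = [], [], [], []
    for t in thresholds:
        called = best >= t
        tp = int((called & is_present & correct).sum())
        n_called = int(called.sum())
        tpr.append(tp / len(present))
        fpr.append(int((called & ~is_present).sum()) / len(absent))
        prec.append(tp / n_called if n_called else 1.0)
        rec.append(tp / len(present))
    tpr, fpr = np.array(tpr), np.array(fpr)
    prec, rec = np.array(prec), np.array(rec)
    order = np.argsort(fpr, kind="stable")
    auroc = float(np.trapezoid(tpr[order], fpr[order]))
    order_r = np.argsort(rec, kind="stable")
    auprc = float(np.trapezoid(prec[order_r], rec[order_r]))
    return ThresholdCurves(np.asarray(thresholds), tpr, fpr, prec, rec, auroc, auprc)


def holdout_trials(
    scores: ScoreMatrix,
    truth: dict[str, str],
    n_trials: int = 100,
    holdout_frac: float = 0.5,
    seed: int = 0,
) -> tuple[float, float, list[ThresholdCurves]]:
    """Repeated unknown-membership experiments on one score matrix.

    Each trial removes the true candidates of a random ``holdout_frac`` of
    the queries from the candidate set, runs :func:`thresholded_linking`,
    and the mean AUROC/AUPRC over trials is returned.
    """
    rng = np.random.default_rng(seed)
    qids = list(scores.query_ids)
    n_hold = max(1, int(round(holdout_frac * len(qids))))
    cand_index = {c: i for i, c in enumerate(scores.candidate_ids)}
    curves = []
    for _ in range(n_trials):
        held = set(rng.choice(qids, size=n_hold, replace=False))
        drop_cols = {cand_index[truth[q]] for q in held if truth[q] in cand_index}
        keep = [i for i in range(len(scores.candidate_ids)) if i not in drop_cols]
        sub = ScoreMatrix(
            scores.scores[:, keep],
            scores.query_ids,
            [scores.candidate_ids[i] for i in keep],
        )
        trial_truth = {q: (None if q in held else truth.get(q)) for q in qids}
        curves.append(thresholded_linking(sub, trial_truth))
    auroc = float(np.mean([c.auroc for c in curves]))
    auprc = float(np.mean([c.auprc for c in curves]))
    return auroc, auprc, curves
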