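"""Signature validation: repeated 2-fold cross-validated predictability,
frozen-signature transfer to external cohorts, and the random-gene-set
resampling null.

Predictability asks whether a pathway's scoring rule, rebuilt from scratch
on half a cohort, stratifies the held-out half; it is summarized as the
count of significant log-rank results over many random 2-fold partitions
(both folds are evaluated, so 50 partitions give 100 evaluations).
Generalizability asks whether a signature frozen on one cohort stratifies
cohorts it never saw.  The resampling null calibrates an observed
cross-cohort significance count against signatures of randomly chosen
genes of the same size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCatalog
from .signature import (
    TrainedSignature,
    compute_risk_scores,
    filter_genes,
    map_to_pathways,
    score_group_labels,
    train_signature,
)
from .survival import logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "TransferResult",
    "ResamplingResult",
    "cv_predictability",
    "select_pathways",
    "transfer_signature",
    "resampling_test",
]


@dataclass
class TransferResult:
    """Outcome of applying a frozen signature to one cohort."""

    cohort: str
    p_value: float
    n_genes_available: int
    score_cutoff_used: float
    significant: bool
    alpha: float = 0.05
    cutoff_mode: str = "training"


@dataclass
class ResamplingResult:
    """Null distribution of cross-cohort significance counts for random
    same-size gene sets, and the resulting p-value for the observed count."""

    observed_count: int
    null_counts: np.ndarray
    p_value: float
    n_rep: int
    seed: int
    n_degenerate: int = 0


def _evaluate_fold(
    expr_train: pd.DataFrame,
    surv_train: pd.DataFrame,
    expr_test: pd.DataFrame,
    surv_test: pd.DataFrame,
    pathway_genes_by_name: dict[str, list[str]],
    p_threshold: float,
) -> dict[str, float]:
    """Train per pathway on one half, evaluate the log-rank p on the other.

    Returns pathway -> p (NaN where the evaluation could not be made).
    The gene filter is re-run inside the training half, so a pathway's gene
    content varies across folds.
    """
    out: dict[str, float] = {}
    if int(surv_train["event"].sum()) == 0 or int(surv_test["event"].sum()) == 0:
        logger.warning("fold skipped: a half has zero events")
        return {name: np.nan for name in pathway_genes_by_name}

    all_genes = sorted({g for genes in pathway_genes_by_name.values() for g in genes})
    filt = filter_genes(expr_train, surv_train, p_threshold=p_threshold, genes=all_genes)
    retained = set(filt.index[filt["retained"]])

    for name, genes in pathway_genes_by_name.items():
        hits = [g for g in genes if g in retained]
        p_val = np.nan
        if hits:
            try:
                sig = train_signature(expr_train, surv_train, hits, pathway_name=name)
                scores = compute_risk_scores(expr_test, sig, median_source="signature")
                labels = score_group_labels(scores.scores, sig.score_cutoff)
                if not labels.degenerate:
                    p_val = logrank_test(surv_test, labels).p_value
            except ValueError:
                pass
        out[name] = p_val
    return out


def cv_predictability(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    catalog: GeneSetCatalog,
    n_partitions: int = 50,
    alpha: float = 0.05,
    p_threshold: float = 0.1,
    seed: int = 0,
    bonferroni_k: int | None = None,
) -> pd.DataFrame:
    """Repeated 2-fold cross-validation significance counts per pathway.

    Each partition randomly halves the cohort (odd n: sizes differ by 1,
    the larger half is the training half first and the roles alternate
    across partitions); the full training procedure — gene filter, Cox
    signs, training medians, score cutoff at the training median score —
    is run on one half and the frozen rule scores the other half, which is
    split at the training cutoff and tested by log-rank.  Both directions
    are evaluated, so counts run over ``2 * n_partitions`` evaluations.
    Evaluations that cannot be made (zero-event half, untrainable pathway,
    all scores tied on one side) are skipped and the denominator reported.

    Returns one row per pathway: ``count_raw`` significant at ``alpha``,
    ``count_adj`` at ``alpha / K`` (K = catalog size, or ``bonferroni_k``
    when evaluating a subset of a larger screened family), ``n_evaluations``
    the non-skipped denominator, plus bookkeeping columns.
    """
    if not expr.columns.equals(surv.index):
        expr = expr.loc[:, surv.index]
    if len(catalog) == 0:
        raise ValueError("empty gene-set catalog")
    k = bonferroni_k if bonferroni_k is not None else len(catalog)
    pathway_genes = {
        name: [g for g in genes if g in expr.index] for name, genes in catalog.items()
    }

    rng = np.random.default_rng(seed)
    n = expr.shape[1]
    count_raw = {name: 0 for name in catalog.names()}
    count_adj = {name: 0 for name in catalog.names()}
    n_eval = {name: 0 for name in catalog.names()}

    for part in range(n_partitions):
        perm = rng.permutation(n)
        n_big = (n + 1) // 2
        big, small = perm[:n_big], perm[n_big:]
        # alternate which half trains first when n is odd
        first_train = big if part % 2 == 0 else small
        second_train = small if part % 2 == 0 else big
        for train_idx, test_idx in ((first_train, second_train), (second_train, first_train)):
            e_tr, e_te = expr.iloc[:, train_idx], expr.iloc[:, test_idx]
            s_tr, s_te = surv.iloc[train_idx], surv.iloc[test_idx]
            p_by_pathway = _evaluate_fold(e_tr, s_tr, e_te, s_te, pathway_genes, p_threshold)
            for name, p_val in p_by_pathway.items():
                if np.isfinite(p_val):
                    n_eval[name] += 1
                    if p_val <= alpha:
                        count_raw[name] += 1
                    if p_val <= alpha / k:
                        count_adj[name] += 1

    rows = [
        {
            "pathway": name,
            "count_adj": count_adj[name],
            "count_raw": count_raw[name],
            "n_evaluations": n_eval[name],
            "n_partitions": n_partitions,
            "alpha": alpha,
            "alpha_adj": alpha / k,
            "seed": seed,
        }
        for name in catalog.names()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["count_adj", "count_raw"], ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def select_pathways(
    reports: pd.DataFrame, min_adj: int = 10, min_raw: int = 30
) -> list[str]:
    """Pathways passing the dual cross-validation count thresholds.

    Keeps pathways with ``count_adj >= min_adj`` and ``count_raw >=
    min_raw``, ordered by ``count_adj`` descending.
    """
    if reports.empty:
        return []
    ok = reports[(reports["count_adj"] >= min_adj) & (reports["count_raw"] >= min_raw)]
    ok = ok.sort_values("count_adj", ascending=False, kind="stable")
    return list(ok["pathway"])


def transfer_signature(
    signature: TrainedSignature,
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    alpha: float = 0.05,
    cutoff_mode: str = "training",
    median_source: str = "cohort",
    cohort: str = "",
) -> TransferResult:
    """Apply a frozen signature to an external cohort and log-rank test it.

    ``cutoff_mode`` selects the High/Low score cutoff: ``"training"`` uses
    the stored training-cohort cutoff, ``"cohort"`` the scored cohort's own
    median score.  When signature genes are missing from the cohort's
    platform the training cutoff no longer matches the attainable score
    range, so training mode falls back to the cohort median (logged).
    Gene-level cut points follow ``median_source`` (cohort medians by
    default, the cross-platform mode).
    """
    if cutoff_mode not in ("training", "cohort"):
        raise ValueError("cutoff_mode must be 'training' or 'cohort'")
    if not expr.columns.equals(surv.index):
        expr = expr.loc[:, surv.index]
    risk = compute_risk_scores(expr, signature, median_source=median_source)
    if cutoff_mode == "cohort" or risk.n_genes_available < len(signature.genes):
        if cutoff_mode == "training" and risk.n_genes_available < len(signature.genes):
            logger.info(
                "cohort %r: %d/%d signature genes available; using cohort median cutoff",
                cohort, risk.n_genes_available, len(signature.genes),
            )
        cutoff = float(np.median(risk.scores))
    else:
        cutoff = float(signature.score_cutoff)
    labels = score_group_labels(risk.scores, cutoff)
    if labels.degenerate:
        logger.warning("cohort %r: all risk scores fall on one side of the cutoff", cohort)
        return TransferResult(
            cohort=cohort,
            p_value=np.nan,
            n_genes_available=risk.n_genes_available,
            score_cutoff_used=cutoff,
            significant=False,
            alpha=alpha,
            cutoff_mode=cutoff_mode,
        )
    res = logrank_test(surv, labels)
    return TransferResult(
        cohort=cohort,
        p_value=res.p_value,
        n_genes_available=risk.n_genes_available,
        score_cutoff_used=cutoff,
        significant=bool(res.p_value <= alpha),
        alpha=alpha,
        cutoff_mode=cutoff_mode,
    )


def resampling_test(
    signature_size: int,
    train_expr: pd.DataFrame,
    train_surv: pd.DataFrame,
    cohorts: list[tuple[str, pd.DataFrame, pd.DataFrame]],
    observed_count: int,
    n_rep: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    gene_pool: list[str] | None = None,
    cutoff_mode: str = "training",
) -> ResamplingResult:
    """Random-gene-set null for an observed cross-cohort significance count.

    Each replicate draws ``signature_size`` genes uniformly without
    replacement from the training cohort's full gene universe (or
    ``gene_pool`` if given — e.g. a pre-filtered pool), trains a signature
    on the training cohort (Cox signs, medians, median-score cutoff; no
    gene filtering), transfers it to every cohort, and counts cohorts with
    p <= ``alpha``.  The p-value is the proportion of replicates whose
    count is at least ``observed_count``.  Replicates whose training is
    fully degenerate count 0 significances and are tallied.
    """
    if not cohorts:
        raise ValueError("need at least one evaluation cohort")
    pool = list(train_expr.index if gene_pool is None else gene_pool)
    if signature_size > len(pool):
        raise ValueError("signature_size exceeds the gene pool")
    rng = np.random.default_rng(seed)
    null_counts = np.zeros(n_rep, dtype=int)
    n_degenerate = 0
    for r in range(n_rep):
        genes = list(rng.choice(pool, size=signature_size, replace=False))
        try:
            sig = train_signature(train_expr, train_surv, genes, pathway_name=f"null_{r}")
        except ValueError:
            n_degenerate += 1
            continue
        count = 0
        for label, expr_c, surv_c in cohorts:
            res = transfer_signature(
                sig, expr_c, surv_c, alpha=alpha, cutoff_mode=cutoff_mode, cohort=label
            )
            if res.significant:
                count += 1
        null_counts[r] = count
    p_value = float(np.mean(null_counts >= observed_count))
    if n_degenerate:
        logger.warning("%d resampling replicate(s) had degenerate training", n_degenerate)
    return ResamplingResult(
        observed_count=int(observed_count),
        null_counts=null_counts,
        p_value=p_value,
        n_rep=n_rep,
        seed=seed,
        n_degenerate=n_degenerate,
    )
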