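"""Pathway signature construction: gene filtering by log-rank tests, mapping
retained genes onto pathway gene sets, the integer risk score, and the
pathway-level screen with Bonferroni control.

The scoring rule is deliberately coarse.  For a trained signature each gene
carries the sign of its univariate Cox coefficient and a training median;
a patient gains one point per gene whose expression falls on the
hazard-increasing side of the median (at-or-above it for a positive
coefficient, below it for a negative one).  The per-patient score is the sum
over the signature's genes, an integer in [0, n_genes].  Patients are then
split at the median score into High and Low risk groups and compared by the
log-rank test.  The coarseness is the point: an integer count of
unfavorable genes with median cut points transfers across array platforms
without rescaling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import GeneSetCatalog
from .survival import (
    GroupLabels,
    _cox_batch,
    _logrank_batch,
    dichotomize_at_median,
    logrank_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainedSignature",
    "RiskScores",
    "filter_genes",
    "map_to_pathways",
    "train_signature",
    "compute_risk_scores",
    "score_group_labels",
    "screen_pathways",
    "load_example_signature",
]


@dataclass
class TrainedSignature:
    """A frozen pathway signature: genes, Cox-coefficient signs, training
    medians, and the training-cohort score cutoff.

    Genes whose Cox fit was degenerate (sign 0) are excluded at training
    time, so every stored sign is +1 or -1.
    """

    pathway_name: str
    genes: list[str]
    signs: np.ndarray          # (+1/-1) per gene
    gene_medians: np.ndarray   # training cut value per gene
    score_cutoff: float        # median of training risk scores
    training_n: int

    def __post_init__(self):
        self.signs = np.asarray(self.signs, dtype=int)
        self.gene_medians = np.asarray(self.gene_medians, dtype=float)
        if not (len(self.genes) == self.signs.size == self.gene_medians.size):
            raise ValueError("genes, signs and medians must align")
        if not np.isin(self.signs, (-1, 1)).all():
            raise ValueError("stored signs must be +1 or -1")

    def to_json(self, path) -> None:
        payload = {
            "pathway_name": self.pathway_name,
            "genes": list(self.genes),
            "signs": [int(s) for s in self.signs],
            "gene_medians": [float(m) for m in self.gene_medians],
            "score_cutoff": float(self.score_cutoff),
            "training_n": int(self.training_n),
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TrainedSignature":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            pathway_name=payload["pathway_name"],
            genes=list(payload["genes"]),
            signs=np.array(payload["signs"]),
            gene_medians=np.array(payload["gene_medians"]),
            score_cutoff=float(payload["score_cutoff"]),
            training_n=int(payload["training_n"]),
        )


@dataclass
class RiskScores:
    """Integer risk scores for one cohort under one signature."""

    scores: pd.Series                 # per-sample integer
    signature: TrainedSignature
    n_genes_available: int
    genes_used: list[str] = field(default_factory=list)


def filter_genes(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    p_threshold: float = 0.1,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene log-rank filtering after median dichotomization.

    Every gene is dichotomized at its within-cohort median (High = at or
    above) and tested by the two-group log-rank test; genes with p strictly
    below ``p_threshold`` are retained.  Degenerate genes — all samples in
    one group after the median cut — are never retained and come back with
    NaN p-values.

    Returns a DataFrame indexed by gene with ``p_value`` and ``retained``
    columns, in the input gene order (optionally restricted to ``genes``).
    """
    if not expr.columns.equals(surv.index):
        expr = expr.loc[:, surv.index]  # raises on mismatch
    gene_list = list(expr.index if genes is None else [g for g in genes if g in expr.index])
    if not gene_list:
        return pd.DataFrame(columns=["p_value", "retained"])

    X = expr.loc[gene_list].to_numpy(dtype=float)
    medians = np.median(X, axis=1, keepdims=True)
    high = X >= medians
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy()
    _, p = _logrank_batch(time, event, high)

    n_degenerate = int(np.isnan(p).sum())
    if n_degenerate:
        logger.warning("%d degenerate gene(s) skipped by the log-rank filter", n_degenerate)
    retained = np.where(np.isnan(p), False, p < p_threshold)
    return pd.DataFrame(
        {"p_value": p, "retained": retained.astype(bool)}, index=pd.Index(gene_list, name="gene")
    )


def map_to_pathways(
    retained_genes, catalog: GeneSetCatalog
) -> dict[str, list[str]]:
    """Intersect the retained gene list with each catalog set.

    Catalog gene order is preserved within each pathway; pathways with an
    empty intersection are included (empty list) and flagged in the log.
    """
    retained = set(retained_genes)
    out: dict[str, list[str]] = {}
    for name, genes in catalog.items():
        hits = [g for g in genes if g in retained]
        if not hits:
            logger.warning("pathway %r has no retained genes", name)
        out[name] = hits
    return out


def train_signature(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    pathway_genes,
    pathway_name: str = "",
) -> TrainedSignature:
    """Fit the per-gene Cox signs and medians for a pathway's gene list.

    For each gene present in the cohort the univariate Cox coefficient is
    fitted and only its sign is kept, alongside the gene's training-cohort
    median.  Degenerate genes (sign 0) are dropped with a warning.  Risk
    scores are then computed on the training cohort itself and their median
    becomes the frozen score cutoff.
    """
    genes = [g for g in pathway_genes if g in expr.index]
    if not genes:
        raise ValueError(f"no genes of pathway {pathway_name!r} present in the cohort")
    if not expr.columns.equals(surv.index):
        expr = expr.loc[:, surv.index]

    X = expr.loc[genes].to_numpy(dtype=float)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy()
    beta, _, _, degen = _cox_batch(time, event, X)
    signs = np.sign(beta).astype(int)
    signs[degen] = 0

    keep = signs != 0
    if not keep.any():
        raise ValueError(f"all genes of pathway {pathway_name!r} gave degenerate Cox fits")
    if (~keep).any():
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(f"dropping sign-0 genes from {pathway_name!r}: {dropped}", stacklevel=2)

    kept_genes = [g for g, k in zip(genes, keep) if k]
    medians = np.median(X[keep], axis=1)
    sig = TrainedSignature(
        pathway_name=pathway_name,
        genes=kept_genes,
        signs=signs[keep],
        gene_medians=medians,
        score_cutoff=0.0,
        training_n=expr.shape[1],
    )
    training_scores = compute_risk_scores(expr, sig, median_source="signature").scores
    sig.score_cutoff = float(np.median(training_scores))
    return sig


def compute_risk_scores(
    expr: pd.DataFrame,
    signature: TrainedSignature,
    median_source: str = "cohort",
) -> RiskScores:
    """Integer risk scores for a cohort under a frozen signature.

    A patient gains 1 point per signature gene g with either
    (sign_g = +1 and x_g >= m_g) or (sign_g = -1 and x_g < m_g), where the
    cut m_g comes from ``median_source``: ``"cohort"`` recomputes each
    gene's median within the scored cohort (the cross-platform mode),
    ``"signature"`` uses the stored training medians.  Genes absent from
    the cohort are skipped — scores sum over the available genes with no
    rescaling.
    """
    if median_source not in ("cohort", "signature"):
        raise ValueError("median_source must be 'cohort' or 'signature'")
    present = [i for i, g in enumerate(signature.genes) if g in expr.index]
    if not present:
        raise ValueError("no signature genes present in the cohort")
    genes = [signature.genes[i] for i in present]
    signs = signature.signs[present]
    X = expr.loc[genes].to_numpy(dtype=float)
    if median_source == "cohort":
        cuts = np.median(X, axis=1)
    else:
        cuts = signature.gene_medians[present]

    above = X >= cuts[:, None]
    contrib = np.where(signs[:, None] > 0, above, ~above)
    scores = contrib.sum(axis=0).astype(int)
    return RiskScores(
        scores=pd.Series(scores, index=expr.columns, name="risk_score"),
        signature=signature,
        n_genes_available=len(genes),
        genes_used=genes,
    )


def score_group_labels(scores: pd.Series, cutoff: float) -> GroupLabels:
    """High/Low split of integer risk scores at a cutoff (High = score >= cutoff)."""
    s = scores.to_numpy(dtype=float)
    high = s >= cutoff
    degenerate = bool(high.all() or (~high).all())
    return GroupLabels(high=high, cut=float(cutoff), degenerate=degenerate)


def screen_pathways(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    catalog: GeneSetCatalog,
    alpha: float = 0.05,
    p_threshold: float = 0.1,
    return_signatures: bool = False,
):
    """Screen every catalog pathway for survival stratification.

    Pipeline per pathway: log-rank gene filter (p < ``p_threshold``) →
    intersect with the pathway → train signs/medians/cutoff → score the
    cohort → split at the median score → log-rank test.  Significance is
    Bonferroni-controlled at ``alpha / K`` with K = number of catalog
    pathways.  Pathways that cannot be trained (no retained genes, or all
    degenerate) are reported with NaN p-values, never dropped.

    Returns a DataFrame sorted by p-value (NaN rows last) with columns
    pathway, n_genes_used, p_value, significant_bonferroni, alpha_used;
    with ``return_signatures`` also a dict pathway -> TrainedSignature.
    """
    if len(catalog) == 0:
        raise ValueError("empty gene-set catalog")
    k = len(catalog)
    threshold = alpha / k

    # filtering only the catalog's gene universe is equivalent to filtering
    # everything and intersecting afterwards
    universe = [g for g in catalog.gene_universe() if g in expr.index]
    filt = filter_genes(expr, surv, p_threshold=p_threshold, genes=universe)
    retained = list(filt.index[filt["retained"]])
    per_pathway = map_to_pathways(retained, catalog)

    rows = []
    signatures: dict[str, TrainedSignature] = {}
    for name in catalog.names():
        genes = per_pathway[name]
        p_val = np.nan
        n_used = 0
        if genes:
            try:
                sig = train_signature(expr, surv, genes, pathway_name=name)
                scores = compute_risk_scores(expr, sig, median_source="signature")
                labels = score_group_labels(scores.scores, sig.score_cutoff)
                if labels.degenerate:
                    logger.warning("pathway %r: all scores on one side of the cutoff", name)
                else:
                    p_val = logrank_test(surv, labels).p_value
                n_used = len(sig.genes)
                signatures[name] = sig
            except ValueError as err:
                logger.warning("pathway %r failed training: %s", name, err)
        rows.append(
            {
                "pathway": name,
                "n_genes_used": n_used,
                "p_value": p_val,
                "significant_bonferroni": bool(p_val <= threshold) if np.isfinite(p_val) else False,
                "alpha_used": threshold,
            }
        )
    result = pd.DataFrame(rows).sort_values("p_value", na_position="last", kind="stable")
    result = result.reset_index(drop=True)
    if return_signatures:
        return result, signatures
    return result


def load_example_signature() -> tuple[GeneSetCatalog, pd.DataFrame]:
    """The packaged 16-gene apoptotic-execution-phase example signature.

    Returns the single-set catalog (GMT) and a sidecar table of per-gene
    published association signs and gene-level log-rank p-values, for use
    in examples and as a realistic pathway fixture.
    """
    from .io import read_gmt

    data = resources.files("pathsurv") / "data"
    with resources.as_file(data / "apoptotic_execution_phase.gmt") as p:
        catalog = read_gmt(p)
    with resources.as_file(data / "apoptotic_execution_phase_genes.tsv") as p:
        table = pd.read_csv(p, sep="\t", index_col=0)
    return catalog, table
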