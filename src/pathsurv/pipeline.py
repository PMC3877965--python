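"""End-to-end pipeline orchestration.

Runs screen → cross-validation → selection → transfer → resampling →
(optional) drug association from file inputs, writing tab-delimited result
tables, serialized signatures, a run manifest and a log into an output
directory.  Every stochastic stage draws its own sub-seed from the master
seed via ``numpy.random.SeedSequence.spawn`` (order: cross-validation,
resampling), so partial re-runs reproduce exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_clinical, read_expression, read_gmt
from .signature import screen_pathways
from .validation import cv_predictability, resampling_test, select_pathways, transfer_signature

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """File paths and tuning parameters for a full pipeline run.

    ``external_cohorts`` is a list of ``{label, expression, clinical}``
    mappings; ``response`` is an optional per-sample drug-response table
    (samples x drugs) scored against the top selected pathway.
    """

    expression: str
    clinical: str
    gmt: str
    out_dir: str
    external_cohorts: list[dict] = field(default_factory=list)
    response: str | None = None
    alpha: float = 0.05
    filter_p: float = 0.1
    n_partitions: int = 50
    n_rep: int = 1000
    min_adj: int = 10
    min_raw: int = 30
    cutoff_mode: str = "training"
    median_source: str = "cohort"
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "filter_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("n_partitions", "n_rep"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("expression", "clinical", "gmt"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} input not found: {getattr(self, name)}")
        for cohort in self.external_cohorts:
            for key in ("expression", "clinical"):
                if not Path(cohort[key]).exists():
                    raise FileNotFoundError(f"external cohort input not found: {cohort[key]}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "expression": self.expression,
            "clinical": self.clinical,
            "gmt": self.gmt,
            "out_dir": self.out_dir,
            "external_cohorts": self.external_cohorts,
            "response": self.response,
            "alpha": self.alpha,
            "filter_p": self.filter_p,
            "n_partitions": self.n_partitions,
            "n_rep": self.n_rep,
            "min_adj": self.min_adj,
            "min_raw": self.min_raw,
            "cutoff_mode": self.cutoff_mode,
            "median_source": self.median_source,
            "seed": self.seed,
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# pathsurv {__version__} seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole discovery/validation pipeline and write results.

    Returns a bundle dict with the in-memory result tables.  Any stage
    failure aborts with the stage name; partial outputs are kept and a
    ``FAILED`` marker file names the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pathsurv")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    seeds = np.random.SeedSequence(config.seed).spawn(2)
    cv_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    resample_seed = int(seeds[1].generate_state(1)[0] % (2**31))

    stage = "load-inputs"
    bundle: dict = {}
    try:
        expr = read_expression(config.expression)
        surv = read_clinical(config.clinical)
        expr = expr.loc[:, surv.index]
        catalog = read_gmt(config.gmt)
        externals = []
        for cohort in config.external_cohorts:
            e = read_expression(cohort["expression"])
            s = read_clinical(cohort["clinical"])
            externals.append((cohort["label"], e.loc[:, s.index], s))

        stage = "screen"
        screen, signatures = screen_pathways(
            expr, surv, catalog, alpha=config.alpha,
            p_threshold=config.filter_p, return_signatures=True,
        )
        _write_table(screen, out / "screen.tsv", config.seed, cfg_hash)
        sig_dir = out / "signatures"
        sig_dir.mkdir(exist_ok=True)
        for name, sig in signatures.items():
            sig.to_json(sig_dir / f"{name}.json")
        bundle["screen"] = screen

        stage = "cv"
        cv = cv_predictability(
            expr, surv, catalog, n_partitions=config.n_partitions,
            alpha=config.alpha, p_threshold=config.filter_p, seed=cv_seed,
        )
        _write_table(cv, out / "cv.tsv", config.seed, cfg_hash)
        bundle["cv"] = cv

        stage = "select"
        selected = select_pathways(cv, min_adj=config.min_adj, min_raw=config.min_raw)
        selected = [p for p in selected if p in signatures]
        (out / "selected.txt").write_text("".join(f"{p}\n" for p in selected))
        bundle["selected"] = selected

        stage = "transfer"
        eval_cohorts = [("training", expr, surv)] + externals
        rows = []
        observed: dict[str, int] = {}
        for name in selected:
            sig = signatures[name]
            count = 0
            for label, e_c, s_c in eval_cohorts:
                res = transfer_signature(
                    sig, e_c, s_c, alpha=config.alpha,
                    cutoff_mode=config.cutoff_mode,
                    median_source=config.median_source, cohort=label,
                )
                count += int(res.significant)
                rows.append(
                    {
                        "pathway": name,
                        "cohort": label,
                        "p_value": res.p_value,
                        "n_genes_available": res.n_genes_available,
                        "score_cutoff_used": res.score_cutoff_used,
                        "significant": res.significant,
                    }
                )
            observed[name] = count
        transfer = pd.DataFrame(
            rows, columns=["pathway", "cohort", "p_value", "n_genes_available",
                           "score_cutoff_used", "significant"],
        )
        _write_table(transfer, out / "transfer.tsv", config.seed, cfg_hash)
        bundle["transfer"] = transfer

        stage = "resample"
        res_rows = []
        for i, name in enumerate(selected):
            sig = signatures[name]
            res = resampling_test(
                signature_size=len(sig.genes),
                train_expr=expr, train_surv=surv,
                cohorts=eval_cohorts,
                observed_count=observed[name],
                n_rep=config.n_rep, alpha=config.alpha,
                seed=resample_seed + i, cutoff_mode=config.cutoff_mode,
            )
            res_rows.append(
                {
                    "pathway": name,
                    "signature_size": len(sig.genes),
                    "observed_count": res.observed_count,
                    "p_value": res.p_value,
                    "n_rep": res.n_rep,
                }
            )
        resample = pd.DataFrame(
            res_rows, columns=["pathway", "signature_size", "observed_count", "p_value", "n_rep"],
        )
        _write_table(resample, out / "resampling.tsv", config.seed, cfg_hash)
        bundle["resampling"] = resample

        if config.response is not None and selected:
            stage = "associate"
            from .association import associate_drugs
            from .signature import compute_risk_scores

            responses = pd.read_csv(config.response, sep="\t", index_col=0)
            top = signatures[selected[0]]
            scores = compute_risk_scores(expr, top, median_source=config.median_source).scores
            shared = scores.index.intersection(responses.index)
            assoc = associate_drugs(scores.loc[shared], responses.loc[shared])
            _write_table(assoc, out / "association.tsv", config.seed, cfg_hash)
            bundle["association"] = assoc

        stage = "manifest"
        manifest = {
            "pathsurv_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": config.to_dict(),
            "config_hash": cfg_hash,
            "stage_seeds": {"cv": cv_seed, "resample": resample_seed},
        }
        with open(out / "manifest.yaml", "wt", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        bundle["manifest"] = manifest
    except Exception as err:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        root.removeHandler(handler)
        handler.close()
    return bundle
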