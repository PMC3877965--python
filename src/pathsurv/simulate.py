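"""Synthetic cohort generation for the signature pipeline.

The generator emulates the structure of multi-cohort microarray survival
studies: a few hundred patients per cohort, thousands of genes on a
continuous log-intensity scale, a planted subset of hazard-linked genes
with signed effects, right-censored survival, cohort-specific
location/scale shifts, and occasional genes missing from a cohort's
platform.

Expression is drawn i.i.d. standard normal per gene; survival follows an
exponential proportional-hazards model whose per-patient hazard is
``baseline_hazard * exp(sum_g beta_g * x_gi)`` over the planted genes.
Censoring is independent of risk (exponential competing censoring and/or
administrative cutoff), and cohort shifts are applied to expression after
survival is generated, so platform distortion never alters true risk.
Missing genes are emulated by deleting the rows from the emitted matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneSetCatalog

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_catalog",
    "generate_multi_cohorts",
    "generate_drug_response",
]


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic cohort.

    Parameters
    ----------
    n_patients, n_genes
        Cohort dimensions; genes are named ``G0001``… unless
        ``gene_names`` is given.
    planted_genes, betas
        The hazard-linked subset and its signed log-hazard-ratios per unit
        expression (per-gene entries of ``betas``; genes without an entry
        get beta 0).
    baseline_hazard
        Events per month for a patient at the expression origin.
    censoring_rate, admin_censor_time
        Independent exponential censoring hazard (per month; 0 disables)
        and an optional administrative cutoff in months.
    cohort_shift
        ``(offset, scale)`` applied to every expression value after
        survival generation.
    missing_genes
        Genes absent from this cohort's platform; their rows are dropped
        from the emitted matrix only.
    """

    n_patients: int = 200
    n_genes: int = 2000
    planted_genes: Sequence[str] = field(default_factory=tuple)
    betas: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.01
    admin_censor_time: float | None = None
    cohort_shift: tuple[float, float] = (0.0, 1.0)
    missing_genes: Sequence[str] = field(default_factory=tuple)
    gene_names: Sequence[str] | None = None
    seed: int = 0

    def gene_universe(self) -> list[str]:
        if self.gene_names is not None:
            if len(self.gene_names) != self.n_genes:
                raise ValueError("gene_names length must equal n_genes")
            return list(self.gene_names)
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.admin_censor_time is not None and self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")
        if self.cohort_shift[1] <= 0:
            raise ValueError("cohort scale shift must be positive")
        universe = set(self.gene_universe())
        for g in list(self.planted_genes) + list(self.betas):
            if g not in universe:
                raise ValueError(f"planted gene {g!r} not in the generated gene universe")


@dataclass
class SyntheticCohort:
    """One generated cohort plus the configuration that produced it."""

    expression: pd.DataFrame   # genes x samples (after shift, minus missing genes)
    survival: pd.DataFrame     # index sample, columns time/event
    truth: SyntheticConfig

    def __post_init__(self):
        if not self.expression.columns.equals(self.survival.index):
            raise ValueError("expression sample IDs must equal survival sample IDs")


def generate_cohort(config: SyntheticConfig, sample_prefix: str = "S") -> SyntheticCohort:
    """Draw one cohort from the exponential proportional-hazards model.

    Identical config + seed yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_universe()
    samples = [f"{sample_prefix}{i + 1:04d}" for i in range(config.n_patients)]

    X = rng.standard_normal((config.n_genes, config.n_patients))
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)

    eta = np.zeros(config.n_patients)
    for g in config.planted_genes:
        beta = config.betas.get(g, 0.0)
        if beta != 0.0:
            eta += beta * expr.loc[g].to_numpy()
    hazard = config.baseline_hazard * np.exp(eta)

    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.full(config.n_patients, np.inf)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, config.n_patients)
    if config.admin_censor_time is not None:
        censor_time = np.minimum(censor_time, config.admin_censor_time)

    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    surv = pd.DataFrame(
        {"time": observed, "event": event}, index=pd.Index(samples, name="sample")
    )

    offset, scale = config.cohort_shift
    shifted = expr * scale + offset
    if config.missing_genes:
        missing = set(config.missing_genes)
        shifted = shifted.loc[[g for g in genes if g not in missing]]
    return SyntheticCohort(expression=shifted, survival=surv, truth=config)


def generate_catalog(
    universe: Sequence[str],
    planted_genes: Sequence[str],
    n_decoy_sets: int,
    decoy_size: int,
    seed: int = 0,
    planted_name: str = "planted",
    exclude_planted_from_decoys: bool = False,
) -> GeneSetCatalog:
    """A catalog of one planted set plus random decoy sets.

    Decoy genes are sampled without replacement from the universe,
    independently per set; set names are unique.  By default decoys may
    overlap the planted set (real pathway catalogs overlap); with
    ``exclude_planted_from_decoys`` the decoys are guaranteed
    signal-free, which makes them a clean negative control.
    """
    universe = list(universe)
    uni = set(universe)
    for g in planted_genes:
        if g not in uni:
            raise ValueError(f"planted gene {g!r} not in the universe")
    decoy_pool = (
        [g for g in universe if g not in set(planted_genes)]
        if exclude_planted_from_decoys
        else universe
    )
    if decoy_size > len(decoy_pool):
        raise ValueError("decoy_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    catalog = GeneSetCatalog(source="synthetic")
    catalog.add(planted_name, list(planted_genes), "synthetic planted set")
    for i in range(n_decoy_sets):
        members = rng.choice(decoy_pool, size=decoy_size, replace=False)
        catalog.add(f"decoy_{i + 1:02d}", list(members), "synthetic decoy set")
    return catalog


def generate_multi_cohorts(
    base_config: SyntheticConfig,
    n_cohorts: int,
    shifts: Sequence[tuple[float, float]] | None = None,
    missing_spec: Sequence[Sequence[str]] | None = None,
    seed: int = 0,
) -> list[SyntheticCohort]:
    """Independent cohorts sharing one planted truth.

    Each cohort gets its own sub-seed (derived from ``seed`` via
    ``numpy.random.SeedSequence.spawn``), and optionally its own
    ``(offset, scale)`` shift and platform-missing gene list — emulating a
    multi-study design where platforms differ and some signature genes are
    simply absent from a platform.
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    if shifts is not None and len(shifts) != n_cohorts:
        raise ValueError("shifts must have one entry per cohort")
    if missing_spec is not None and len(missing_spec) != n_cohorts:
        raise ValueError("missing_spec must have one entry per cohort")
    children = np.random.SeedSequence(seed).spawn(n_cohorts)
    cohorts = []
    for i in range(n_cohorts):
        sub_seed = int(children[i].generate_state(1)[0] % (2**31))
        cfg = replace(
            base_config,
            seed=sub_seed,
            cohort_shift=tuple(shifts[i]) if shifts is not None else base_config.cohort_shift,
            missing_genes=tuple(missing_spec[i]) if missing_spec is not None else (),
        )
        cohorts.append(generate_cohort(cfg, sample_prefix=f"C{i + 1}_"))
    return cohorts


def generate_drug_response(
    scores, slope: float, noise_sd: float, seed: int = 0
) -> pd.Series:
    """A continuous drug-sensitivity readout ("activity area") per sample.

    ``activity = slope * score + N(0, noise_sd)``; reproducible under seed.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    s = pd.Series(scores)
    rng = np.random.default_rng(seed)
    activity = slope * s.to_numpy(dtype=float) + rng.normal(0.0, noise_sd, s.size)
    return pd.Series(activity, index=s.index, name="activity_area")
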