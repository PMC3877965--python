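"""Risk score vs continuous drug response: OLS slope, tertile grouping,
Kruskal–Wallis across the three groups, and Wilcoxon rank-sum between the
extreme groups.

This is the predictive-biomarker arm of the pipeline: given per-cell-line
integer risk scores and a drug-sensitivity readout ("activity area",
higher = more growth inhibition), it asks whether the score tracks
response.  A drug with more than half its responses missing is excluded
outright.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["DrugAssociation", "tertile_groups", "associate_response", "associate_drugs"]

HIGH, INTERMEDIATE, LOW = "High", "Intermediate", "Low"


@dataclass
class DrugAssociation:
    drug: str
    slope: float
    p_lm: float
    p_kw: float
    p_wx: float
    group_sizes: dict[str, int]
    n_used: int
    missing_fraction: float
    excluded: bool = False


def tertile_groups(scores) -> pd.Series:
    """Three-group split of scores at the empirical 1/3 and 2/3 quantiles.

    Label High if score >= upper cut, Low if score < lower cut, else
    Intermediate — the same at-or-above convention as the median rule, so
    heavy ties give deterministic (possibly unequal) groups.
    """
    s = pd.Series(scores)
    if s.size < 3:
        raise ValueError("need at least 3 samples for tertile grouping")
    vals = s.to_numpy(dtype=float)
    lower, upper = np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(vals >= upper, HIGH, np.where(vals < lower, LOW, INTERMEDIATE))
    if len(np.unique(labels)) < 3:
        warnings.warn("degenerate tertile grouping (ties collapse a group)", stacklevel=2)
    return pd.Series(labels, index=s.index, name="group")


def associate_response(
    scores, response, drug: str = "", max_missing: float = 0.5
) -> DrugAssociation:
    """Test association of a drug response with the integer risk score.

    Samples with missing response are dropped; a drug missing in more than
    ``max_missing`` of samples is excluded entirely (all p-values NaN,
    ``excluded`` True, the missing fraction logged).  Otherwise: OLS slope
    of response on score with a two-sided slope test; tertile grouping of
    the scores, Kruskal–Wallis over the three groups, and Wilcoxon
    rank-sum between the High and Low groups.
    """
    s = pd.Series(scores).astype(float)
    r = pd.Series(response).reindex(s.index).astype(float)
    missing = r.isna()
    missing_fraction = float(missing.mean())
    if missing_fraction > max_missing:
        logger.warning(
            "drug %r excluded: %.0f%% of responses missing", drug, 100 * missing_fraction
        )
        return DrugAssociation(
            drug=drug, slope=np.nan, p_lm=np.nan, p_kw=np.nan, p_wx=np.nan,
            group_sizes={}, n_used=0, missing_fraction=missing_fraction, excluded=True,
        )
    s, r = s[~missing], r[~missing]
    if s.size < 3:
        raise ValueError("need at least 3 non-missing pairs")
    if np.ptp(s.to_numpy()) == 0:
        raise ValueError("zero score variance")

    fit = stats.linregress(s.to_numpy(), r.to_numpy())
    groups = tertile_groups(s)
    sizes = groups.value_counts().to_dict()
    by_group = {name: r[groups == name].to_numpy() for name in (HIGH, INTERMEDIATE, LOW)}
    present = [g for g in by_group.values() if g.size > 0]
    p_kw = (
        float(stats.kruskal(*present).pvalue) if len(present) >= 2 else np.nan
    )
    if by_group[HIGH].size and by_group[LOW].size:
        p_wx = float(
            stats.mannwhitneyu(by_group[HIGH], by_group[LOW], alternative="two-sided").pvalue
        )
    else:
        p_wx = np.nan
    return DrugAssociation(
        drug=drug,
        slope=float(fit.slope),
        p_lm=float(fit.pvalue),
        p_kw=p_kw,
        p_wx=p_wx,
        group_sizes={k: int(sizes.get(k, 0)) for k in (HIGH, INTERMEDIATE, LOW)},
        n_used=int(s.size),
        missing_fraction=missing_fraction,
    )


def associate_drugs(
    scores, responses: pd.DataFrame, max_missing: float = 0.5
) -> pd.DataFrame:
    """Run :func:`associate_response` for each drug column independently."""
    rows = []
    for drug in responses.columns:
        res = associate_response(scores, responses[drug], drug=drug, max_missing=max_missing)
        rows.append(
            {
                "drug": res.drug,
                "slope": res.slope,
                "p_lm": res.p_lm,
                "p_kw": res.p_kw,
                "p_wx": res.p_wx,
                "n_used": res.n_used,
                "missing_fraction": res.missing_fraction,
                "excluded": res.excluded,
            }
        )
    return pd.DataFrame(rows)
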