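"""Reading, writing and preprocessing of expression data, clinical tables,
gene-set catalogs (GMT) and probe maps.

Expression matrices are pandas DataFrames with gene symbols as the index and
sample IDs as columns (continuous, log-scale intensities).  Clinical /
survival tables are DataFrames indexed by sample ID with at least ``time``
(months, positive) and ``event`` (0/1, 1 = death observed) columns; extra
columns are treated as covariates.

Two preprocessing computations live here because they are part of the
pipeline's contract rather than generic utilities: collapsing probe-level
rows to gene symbols by the per-gene mean (probes annotated with zero or
several genes are discarded), and quantile normalization across samples.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCatalog",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "collapse_probes",
    "quantile_normalize",
]


class GeneSetCatalog:
    """An ordered mapping of set name -> list of unique gene symbols.

    Mirrors the structure of a GMT file: each set has a name, an optional
    description (defaults to the source label), and an ordered gene list
    with no within-set duplicates.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]] | None = None,
        descriptions: Mapping[str, str] | None = None,
        source: str = "",
    ):
        self._sets: "OrderedDict[str, list[str]]" = OrderedDict()
        self.descriptions: dict[str, str] = {}
        self.source = source
        if sets:
            for name, genes in sets.items():
                desc = (descriptions or {}).get(name, source)
                self.add(name, genes, desc)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self._sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        seen: list[str] = []
        for g in genes:
            g = str(g).strip()
            if g and g not in seen:
                seen.append(g)
        self._sets[name] = seen
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def names(self) -> list[str]:
        return list(self._sets)

    def items(self):
        return ((k, list(v)) for k, v in self._sets.items())

    def gene_universe(self) -> list[str]:
        """Union of all member genes, first-appearance order."""
        seen: list[str] = []
        have = set()
        for genes in self._sets.values():
            for g in genes:
                if g not in have:
                    have.add(g)
                    seen.append(g)
        return seen

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCatalog):
            return NotImplemented
        return list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"GeneSetCatalog({len(self)} sets)"


# ---------------------------------------------------------------------------
# expression / clinical tables
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a tab-delimited genes-x-samples matrix.

    The header row holds sample IDs, the first column gene symbols.
    Duplicate gene symbols are rejected: probe-level files must first go
    through :func:`collapse_probes`.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        n_fields = None
        for lineno, line in enumerate(fh, start=1):
            count = line.rstrip("\n").count("\t") + 1
            if n_fields is None:
                n_fields = count
            elif count != n_fields:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({count} fields, expected {n_fields})"
                )
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(
            f"duplicate gene symbols in {path}: {list(dup[:5])!r}; "
            "collapse probe-level data with collapse_probes() first"
        )
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite expression values in {path}")
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path) -> pd.DataFrame:
    """Read a tab-delimited clinical table (sample, time_months, event, ...).

    Returns a DataFrame indexed by sample ID with ``time`` and ``event``
    columns plus any extra covariates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    cols = {c.lower(): c for c in df.columns}
    time_col = cols.get("time") or cols.get("time_months")
    event_col = cols.get("event")
    if time_col is None or event_col is None:
        raise ValueError(f"clinical table {path} needs 'time'/'time_months' and 'event' columns")
    df = df.rename(columns={time_col: "time", event_col: "event"})
    validate_survival(df)
    return df


def write_clinical(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"time": "time_months"})
    out.to_csv(path, sep="\t", index_label="sample")


def validate_survival(table: pd.DataFrame) -> None:
    if table.index.duplicated().any():
        raise ValueError("duplicate sample IDs in survival table")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy()
    if not np.all(t > 0):
        raise ValueError("survival times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")


# ---------------------------------------------------------------------------
# GMT gene-set catalogs
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCatalog:
    """Parse a GMT file: one set per line, ``name TAB description TAB genes...``.

    Within-set duplicate genes are dropped (first occurrence kept) with a
    logged warning.
    """
    catalog = GeneSetCatalog()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g.strip()]
            if len(set(genes)) < len(genes):
                logger.warning(
                    "GMT set %r (line %d): duplicate genes dropped", name, lineno
                )
            catalog.add(name, genes, desc)
    return catalog


def write_gmt(catalog: GeneSetCatalog, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, genes in catalog.items():
            desc = catalog.descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# probe maps and probe collapsing
# ---------------------------------------------------------------------------

def read_probe_map(path) -> dict[str, list[str]]:
    """Two-column tab-delimited probe map (probe, gene).

    A probe annotated with several genes appears on several rows; a probe
    with no annotation may appear with an empty gene field.
    """
    mapping: dict[str, list[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'probe TAB gene'")
            probe, gene = parts[0].strip(), parts[1].strip()
            mapping.setdefault(probe, [])
            if gene:
                mapping[probe].append(gene)
    return mapping


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_map: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Collapse a probes-x-samples matrix to genes-x-samples.

    Probes annotated with zero or multiple genes are discarded; only
    single-gene probes survive.  Each gene's row is the arithmetic mean of
    its probes' rows, per sample.  Output gene order follows first
    appearance among the kept probes.
    """
    missing = [p for p in probe_matrix.index if p not in probe_map]
    if missing:
        raise KeyError(f"probes absent from the probe map: {missing[:5]!r}")

    gene_for_probe: dict[str, str] = {}
    for probe in probe_matrix.index:
        genes = [g.strip() for g in probe_map[probe] if str(g).strip()]
        if len(set(genes)) == 1:
            gene_for_probe[probe] = genes[0]

    if not gene_for_probe:
        raise ValueError("no single-gene probes remain after annotation filtering")

    kept = probe_matrix.loc[list(gene_for_probe)]
    genes = pd.Index([gene_for_probe[p] for p in kept.index], name="gene")
    # first-appearance gene order, independent of how pandas groups
    order = list(dict.fromkeys(genes))
    collapsed = kept.groupby(genes, sort=False).mean().loc[order]
    return collapsed


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples (columns) of a genes-x-samples matrix.

    Each sample's sorted values are replaced by the across-sample mean of
    the sorted values at each rank, so that afterwards every sample shares
    one value multiset.  Ties within a sample receive the mean of the
    reference values over the tied rank span, preserving the tie (so a
    sample with ties deviates from the shared multiset exactly on those
    spans — the dominant convention).
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if values.shape[0] < 1:
        raise ValueError("quantile normalization needs at least 1 gene")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in expression matrix")

    sorted_cols = np.sort(values, axis=0)
    reference = sorted_cols.mean(axis=1)

    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            assigned[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
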