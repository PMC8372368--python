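"""In-memory containers for the multi-omic cohort.

The pipeline moves five kinds of data around: a gene x sample expression
matrix (raw, normalized or log2 scale), a per-sample clinical table with
FAB/ELN labels and survival endpoints, named gene-set collections, a binary
mutation matrix and a continuous protein (RPPA) matrix.  All matrices are
thin wrappers around pandas DataFrames so that downstream code can rely on
labelled, validated axes without re-checking invariants at every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "MutationMatrix",
    "ProteinMatrix",
    "FAB_LEVELS",
    "ELN_LEVELS",
]

FAB_LEVELS = ("M1", "M2", "M4", "M5")
ELN_LEVELS = ("favorable", "intermediate", "unfavorable")

#: FAB levels binned to the two myeloid lineages used throughout.
FAB_LINEAGE = {"M1": "M1/M2", "M2": "M1/M2", "M4": "M4/M5", "M5": "M4/M5"}

SURVIVAL_ENDPOINTS = ("os", "efs", "remdur")


class Scale(str, Enum):
    """Scale of an expression matrix."""

    raw_counts = "raw_counts"
    normalized_counts = "normalized_counts"
    log2 = "log2"


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate {what} ids: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with an explicit scale.

    Parameters
    ----------
    data:
        DataFrame with gene ids as index and sample ids as columns.
    scale:
        One of :class:`Scale`; raw counts must be non-negative.
    """

    data: pd.DataFrame
    scale: Scale = Scale.raw_counts

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if self.scale is Scale.raw_counts and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.scale)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations and survival endpoints.

    Expected columns (all optional except ``sample_id`` as the index):
    ``fab`` (M1/M2/M4/M5), ``eln``, ``age`` (years), ``sex``, ``ahd``
    (bool), ``treatment``, ``blast_pct`` and, per endpoint e in
    {os, efs, remdur}: ``e_time`` (weeks) and ``e_event`` (0/1).
    Missing values stay missing; analyses exclude them listwise.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        df = self.data
        if "fab" in df:
            bad = set(df["fab"].dropna()) - set(FAB_LEVELS)
            if bad:
                raise ValueError(
                    f"unknown FAB level(s) {sorted(bad)}; cohort is restricted "
                    f"to {FAB_LEVELS}"
                )
        if "eln" in df:
            bad = set(df["eln"].dropna()) - set(ELN_LEVELS)
            if bad:
                raise ValueError(f"unknown ELN level(s) {sorted(bad)}")
        for ep in SURVIVAL_ENDPOINTS:
            tcol, ecol = f"{ep}_time", f"{ep}_event"
            if tcol in df:
                t = pd.to_numeric(df[tcol], errors="raise")
                if (t.dropna() < 0).any():
                    raise ValueError(f"negative {ep} time")
            if ecol in df:
                ev = df[ecol].dropna()
                if not set(np.asarray(ev, dtype=float)) <= {0.0, 1.0}:
                    raise ValueError(f"{ep}_event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self) -> pd.Series:
        """FAB binned to the two-level lineage label (M1/M2 vs M4/M5)."""
        return self.data["fab"].map(FAB_LINEAGE)

    def endpoint(self, name: str) -> pd.DataFrame:
        """(time, event) for one endpoint, complete cases only."""
        if name not in SURVIVAL_ENDPOINTS:
            raise ValueError(f"unknown endpoint {name!r}; use {SURVIVAL_ENDPOINTS}")
        sub = self.data[[f"{name}_time", f"{name}_event"]].dropna()
        sub.columns = ["time", "event"]
        return sub.astype(float)

    def missingness_report(self) -> pd.Series:
        """Number of missing values per clinical column."""
        return self.data.isna().sum()


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. hallmark pathways, HOX clusters, signatures)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                seen: set[str] = set()
                deduped = [g for g in genes if not (g in seen or seen.add(g))]
                warnings.warn(
                    f"gene set {name!r} contains duplicate genes; deduplicated "
                    f"{len(genes)} -> {len(deduped)}"
                )
                self.sets[name] = deduped

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a gene universe; empty sets are dropped
        with a warning (they cannot be scored)."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            inside = [g for g in genes if g in uni]
            if inside:
                kept[name] = inside
            else:
                warnings.warn(f"gene set {name!r} is empty after restriction")
        return GeneSetCollection(kept, dict(self.descriptions))


@dataclass
class MutationMatrix:
    """Binary gene x sample mutation calls (1 = mutated)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        uniq = set(np.unique(vals[~pd.isna(vals)]).astype(float))
        if not uniq <= {0.0, 1.0}:
            raise ValueError(f"mutation calls must be binary; found {sorted(uniq - {0.0, 1.0})}")
        self.data = self.data.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def frequencies(self) -> pd.Series:
        return self.data.mean(axis=1)


@dataclass
class ProteinMatrix:
    """Continuous protein (RPPA antibody) x sample expression matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "protein")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            p, s = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite protein value at {self.data.index[p]!r}, "
                f"sample {self.data.columns[s]!r}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def check_sample_alignment(expr: ExpressionMatrix, clinical: ClinicalTable) -> list[str]:
    """Samples present in the expression matrix but missing from the clinical
    table (the clinical table may be a superset)."""
    return [s for s in expr.sample_ids if s not in set(clinical.sample_ids)]
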