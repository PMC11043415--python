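"""Reading, validating and summarising replicated multi-environment trials.

The central containers are :class:`TrialData` (long-format replicated
observations of one trait) and :class:`CellMeans` (the genotype x environment
matrix of replicate means with its margins).  Every downstream analysis --
combined ANOVA, AMMI, univariate stability statistics and GGE geometry --
consumes one of these two.

Only balanced designs are accepted: each (environment, genotype) cell must
carry the same number of replicates.  Imbalance and missing cells are
rejected rather than imputed, because all the stability estimators assume a
complete balanced table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    DuplicateKeyError,
    EmptyDataError,
    MissingColumnError,
    NonNumericValueError,
    UnbalancedDesignError,
    ValidationError,
)

#: default column names for long-format input files
DEFAULT_COLUMNS: dict[str, str] = {
    "env": "env",
    "gen": "gen",
    "rep": "rep",
    "value": "value",
}

_CANONICAL = ["env", "gen", "rep", "value"]


@dataclass(frozen=True)
class TrialData:
    """Long-format replicated observations of one trait.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``env``, ``gen``, ``rep`` (labels) and ``value`` (finite
        real trait measurement, e.g. kg ha^-1).  Label order of first
        appearance is preserved throughout.
    trait_name : str
        Name of the measured trait.
    """

    records: pd.DataFrame
    trait_name: str = "value"

    def __post_init__(self) -> None:
        _validate_records(self.records)

    # -- basic summaries ---------------------------------------------------
    @property
    def genotypes(self) -> list:
        return list(pd.unique(self.records["gen"]))

    @property
    def environments(self) -> list:
        return list(pd.unique(self.records["env"]))

    @property
    def g(self) -> int:
        return len(self.genotypes)

    @property
    def q(self) -> int:
        return len(self.environments)

    @property
    def r(self) -> int:
        """Replicate count per cell (constant by the balance invariant)."""
        return int(self.records.groupby(["env", "gen"], sort=False).size().iloc[0])

    def cell_means(self) -> "CellMeans":
        return cell_means(self)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _validate_records(df: pd.DataFrame) -> None:
    missing = [c for c in _CANONICAL if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required columns: {missing}")
    if len(df) == 0:
        raise EmptyDataError("trial contains no records")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.loc[values.isna() | ~np.isfinite(values)]
    if len(bad):
        row = bad.iloc[0]
        raise NonNumericValueError(
            f"non-numeric or non-finite value {row['value']!r} at "
            f"(env={row['env']!r}, gen={row['gen']!r}, rep={row['rep']!r})"
        )
    dup = df.duplicated(subset=["env", "gen", "rep"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise DuplicateKeyError(
            f"duplicated key (env={row['env']!r}, gen={row['gen']!r}, "
            f"rep={row['rep']!r})"
        )
    counts = df.groupby(["env", "gen"], sort=False).size()
    envs = pd.unique(df["env"])
    gens = pd.unique(df["gen"])
    if len(counts) != len(envs) * len(gens):
        present = set(counts.index)
        for e in envs:
            for gn in gens:
                if (e, gn) not in present:
                    raise UnbalancedDesignError(
                        f"cell (env={e!r}, gen={gn!r}) has no observations"
                    )
    if counts.nunique() != 1:
        r0 = counts.iloc[0]
        off = counts[counts != r0].index[0]
        raise UnbalancedDesignError(
            f"cell (env={off[0]!r}, gen={off[1]!r}) has {counts.loc[off]} "
            f"replicates where {r0} were expected"
        )


def read_trial(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    sep: str | None = None,
) -> TrialData:
    """Read a delimited long-format trial file.

    Parameters
    ----------
    path : path to a CSV/TSV file with a header row.
    columns : optional mapping from canonical names (``env``, ``gen``,
        ``rep``, ``value``) to the column names used in the file.
    trait_name : trait label; defaults to the mapped value-column name.
    sep : field separator; inferred from the extension when omitted
        (``.tsv`` -> tab, otherwise comma).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDataError(f"{path} is empty") from exc
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise MissingColumnError(
            f"{path} lacks mapped columns {missing}; found {list(df.columns)}"
        )
    out = df[[colmap[k] for k in _CANONICAL]].copy()
    out.columns = _CANONICAL
    return TrialData(out, trait_name=trait_name or colmap["value"])


def write_trial(data: TrialData, path: str | Path) -> None:
    """Write long-format records; inverse of :func:`read_trial`."""
    data.to_csv(path)


@dataclass(frozen=True)
class CellMeans:
    """Genotype x environment matrix of cell means with margins.

    ``r`` records how many replicates stand behind each cell; it is 1 when
    the matrix was supplied directly, in which case operations that need a
    replicate error stratum refuse to run.
    """

    values: pd.DataFrame
    r: int = 1
    trait_name: str = "value"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float, na_value=np.nan)
        if not np.all(np.isfinite(v)):
            raise NonNumericValueError("cell-means matrix contains non-finite cells")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise DegenerateInputError(
                f"cell-means matrix is {self.values.shape}; need at least 2x2"
            )
        if self.r < 1:
            raise ValidationError("replicate count must be >= 1")

    @classmethod
    def from_matrix(
        cls,
        matrix,
        genotypes=None,
        environments=None,
        trait_name: str = "value",
    ) -> "CellMeans":
        """Wrap a bare g x q array/DataFrame of means (no replicate info)."""
        if isinstance(matrix, pd.DataFrame):
            df = matrix.astype(float)
        else:
            a = np.asarray(matrix, dtype=float)
            gens = genotypes or [f"G{i + 1}" for i in range(a.shape[0])]
            envs = environments or [f"E{j + 1}" for j in range(a.shape[1])]
            df = pd.DataFrame(a, index=list(gens), columns=list(envs))
        return cls(df, r=1, trait_name=trait_name)

    # -- margins -----------------------------------------------------------
    @property
    def genotype_means(self) -> pd.Series:
        return self.values.mean(axis=1)

    @property
    def environment_means(self) -> pd.Series:
        return self.values.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.values.to_numpy().mean())

    @property
    def g(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @property
    def genotypes(self) -> list:
        return list(self.values.index)

    @property
    def environments(self) -> list:
        return list(self.values.columns)

    def interaction(self) -> pd.DataFrame:
        """Doubly-centered residual Z_ij = X_ij - Xi. - X.j + X.. ."""
        v = self.values
        return v.sub(v.mean(axis=1), axis=0).sub(v.mean(axis=0), axis=1) + self.grand_mean

    def to_csv(self, path: str | Path, float_format: str = "%.6g") -> None:
        """Write the matrix with a trailing ``mean`` row and column."""
        out = self.values.copy()
        out["mean"] = self.genotype_means
        bottom = pd.concat([self.environment_means, pd.Series({"mean": self.grand_mean})])
        out.loc["mean"] = bottom
        out.to_csv(path, float_format=float_format, index_label="genotype")


def cell_means(data: TrialData) -> CellMeans:
    """Average replicates into the g x q cell-means matrix."""
    wide = (
        data.records.groupby(["gen", "env"], sort=False)["value"]
        .mean()
        .unstack("env")
        .reindex(index=data.genotypes, columns=data.environments)
    )
    wide.index.name = None
    wide.columns.name = None
    return CellMeans(wide, r=data.r, trait_name=data.trait_name)


def percent_over_check(means: CellMeans, genotype, check) -> float:
    """Signed percent difference of a genotype's pooled mean over a check's.

    Computed as ``100 * (mean_g / mean_check - 1)``.
    """
    gm = means.genotype_means
    for label in (genotype, check):
        if label not in gm.index:
            raise ValidationError(f"unknown genotype label {label!r}")
    base = gm.loc[check]
    if base == 0:
        raise ZeroDivisionError(f"check {check!r} has zero pooled mean")
    return float(100.0 * (gm.loc[genotype] / base - 1.0))
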