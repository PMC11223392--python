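"""Shared in-memory containers for expression data and sample metadata.

Matrices are thin wrappers around a pandas DataFrame (features in rows,
samples in columns) tagged with the measurement scale, so downstream code
can refuse, e.g., to CPM-normalize log2 intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical exposure conditions, ordered by dose. CA (clean air) is the
#: reference; UT is the untreated control, contrasted against CA like a dose.
CONDITIONS = ("UT", "CA", "LD", "MD", "HD")
DOSE_CONDITIONS = ("LD", "MD", "HD")
REFERENCE_CONDITION = "CA"

MATRIX_KINDS = ("counts", "log2_intensity", "cpm", "log2_cpm")


class XplatError(Exception):
    """Base class for all package errors."""


class ConfigError(XplatError):
    """Invalid simulation or pipeline configuration."""


class InputError(XplatError):
    """Malformed or inconsistent user input."""


@dataclass
class ExpressionMatrix:
    """Feature-by-sample measurement matrix.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
    kind
        One of ``counts``, ``log2_intensity``, ``cpm``, ``log2_cpm``.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise InputError(f"unknown matrix kind {self.kind!r}; expected one of {MATRIX_KINDS}")
        if self.values.isna().any().any():
            raise InputError("expression matrix contains missing values")
        if self.kind == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise InputError("count matrix contains negative values")
            if not np.allclose(arr, np.round(arr)):
                raise InputError("count matrix contains non-integer values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.kind)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, kind)


@dataclass
class SampleDesign:
    """Maps sample ids to exposure condition and replicate index."""

    table: pd.DataFrame  # index: sample_id; columns: condition, replicate
    reference_condition: str = REFERENCE_CONDITION

    def __post_init__(self) -> None:
        required = {"condition", "replicate"}
        if not required.issubset(self.table.columns):
            raise InputError(f"sample design needs columns {sorted(required)}")
        unknown = set(self.table["condition"]) - set(CONDITIONS)
        if unknown:
            raise InputError(f"unknown conditions in design: {sorted(unknown)}")
        if self.reference_condition not in set(self.table["condition"]):
            raise InputError(
                f"reference condition {self.reference_condition!r} absent from design"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        present = set(self.table["condition"])
        return [c for c in CONDITIONS if c in present]

    def samples(self, condition: str) -> list[str]:
        return list(self.table.index[self.table["condition"] == condition])

    def condition_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "condition"])

    def require_replicates(self, condition: str, n: int = 2) -> None:
        have = len(self.samples(condition))
        if have < n:
            raise InputError(
                f"condition {condition!r} has {have} sample(s); at least {n} required"
            )

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, reference_condition: str = REFERENCE_CONDITION) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, reference_condition)

    @classmethod
    def from_conditions(
        cls,
        conditions=CONDITIONS,
        n_reps: int = 3,
        reference_condition: str = REFERENCE_CONDITION,
    ) -> "SampleDesign":
        rows = []
        for cond in conditions:
            for r in range(1, n_reps + 1):
                rows.append((f"{cond}_{r}", cond, r))
        df = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"]).set_index(
            "sample_id"
        )
        return cls(df, reference_condition)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in the printed tables)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)
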