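"""Core data containers for clonal-tracking experiments.

The universal substrate is a nonnegative barcode x sample abundance table
(:class:`CountMatrix`); a :class:`MetadataTable` declares which experimental
variable values (individual, cell type, organ, timepoint, duplicate label)
each sample carries. Both are thin wrappers around pandas DataFrames so that
downstream code can use ordinary DataFrame operations while the wrappers
enforce the invariants that make the analyses meaningful (nonnegativity,
unique identifiers, column sums for normalized data).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValueKind",
    "CountMatrix",
    "MetadataTable",
    "ValidationIssue",
    "ValidationReport",
]


class ValueKind(str, enum.Enum):
    """What the numbers in a :class:`CountMatrix` mean."""

    RAW_READS = "raw_reads"
    NORMALIZED = "normalized"      # each nonzero column sums to 1
    SCALED = "scaled"              # normalized columns times a scale factor
    TRANSFORMED = "transformed"    # arcsin / log values; no sum invariant
    CELL_COUNTS = "cell_counts"    # cells per barcode per cell type


@dataclass
class CountMatrix:
    """Barcode x sample abundance matrix.

    Parameters
    ----------
    data
        DataFrame with barcode identifiers as the index and sample
        identifiers as the columns.  Values must be nonnegative and finite.
    value_kind
        Semantic tag for the values; several operations check it to refuse
        meaningless compositions (e.g. arcsin on scaled counts).
    scale_factor
        Declared column sum for ``value_kind == SCALED``.
    """

    data: pd.DataFrame
    value_kind: ValueKind = ValueKind.RAW_READS
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        self.value_kind = ValueKind(self.value_kind)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("empty count matrix")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate barcode identifier {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier {dup}")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("count matrix values must be numeric")
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at ({df.index[r]}, {df.columns[c]})"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at ({df.index[r]}, {df.columns[c]})"
            )
        if self.value_kind is ValueKind.NORMALIZED:
            sums = vals.sum(axis=0)
            bad = np.abs(sums[sums > 0] - 1.0) > 1e-9
            if bad.any():
                raise ValueError("normalized columns must sum to 1 within 1e-9")
        if self.value_kind is ValueKind.SCALED:
            if self.scale_factor is None or self.scale_factor <= 0:
                raise ValueError("scaled matrix requires a positive scale_factor")
            sums = vals.sum(axis=0)
            nz = sums > 0
            rel = np.abs(sums[nz] - self.scale_factor) / self.scale_factor
            if (rel > 1e-6).any():
                raise ValueError(
                    "scaled columns must sum to the scale factor within 1e-6"
                )

    # -- accessors -------------------------------------------------------

    @property
    def barcode_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.data.copy(), self.value_kind, self.scale_factor)

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample(s): {missing}")
        return CountMatrix(self.data[samples].copy(), self.value_kind, self.scale_factor)


@dataclass
class MetadataTable:
    """Per-sample values of the experimental variables.

    ``data`` is indexed by sample id; each column is one variable
    (e.g. individual, cell_type, duplicate), ordered as declared.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate annotation for sample {dup}")
        if self.data.shape[1] == 0:
            raise ValueError("metadata table declares no variables")
        blank = self.data.isna() | (self.data.astype(str).apply(lambda c: c.str.strip()) == "")
        if blank.to_numpy().any():
            sample = self.data.index[blank.any(axis=1)][0]
            raise ValueError(f"blank variable value for sample {sample}")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def levels(self, variable: str) -> list[str]:
        """Observed values of ``variable``, in first-appearance order."""
        if variable not in self.data.columns:
            raise KeyError(f"unknown metadata variable {variable!r}")
        return list(pd.unique(self.data[variable]))

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids whose annotations match every ``variable=value`` pair."""
        mask = pd.Series(True, index=self.data.index)
        for var, value in conditions.items():
            if var not in self.data.columns:
                raise KeyError(f"unknown metadata variable {var!r}")
            mask &= self.data[var] == value
        return list(self.data.index[mask])

    @classmethod
    def from_sample_names(
        cls, sample_ids: list[str], variables: list[str]
    ) -> "MetadataTable":
        """Parse underscore-joined sample names into annotations.

        Sample ids are assumed to be the variable values joined by ``_`` in
        the declared variable order, e.g. ``m2_cDC1_dupA`` for variables
        ``(individual, cell_type, duplicate)``.  An explicit metadata file
        always takes precedence over this convention.
        """
        rows = {}
        for sid in sample_ids:
            tokens = sid.split("_")
            if len(tokens) != len(variables):
                raise ValueError(
                    f"sample id {sid!r} has {len(tokens)} tokens, "
                    f"expected {len(variables)} ({variables})"
                )
            rows[sid] = tokens
        df = pd.DataFrame.from_dict(rows, orient="index", columns=variables)
        df.index.name = "sample"
        return cls(df)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str          # "error" | "warning"
    subject: str           # sample or barcode id (or "" for global issues)
    message: str


@dataclass
class ValidationReport:
    """Outcome of a validation or QC pass; problems are reported, not thrown."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def add(self, severity: str, subject: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, subject, message))

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.severity, i.subject, i.message) for i in self.issues],
            columns=["severity", "subject", "message"],
        )
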