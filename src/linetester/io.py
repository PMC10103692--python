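"""Data containers and CSV I/O for plot-level and mean-level trial data.

Two table shapes are canonical:

* **plot table** — long (tidy) CSV with one row per plot observation:
  ``genotype, role, line, tester, replicate, condition, trait, value``.
  This is what the simulator writes and what the full RCBD ANOVA consumes.
* **means table** — wide CSV with one row per genotype × condition and one
  column per trait, the shape in which trial results are normally published.
  Means are a sufficient input for combining-ability effects, heterosis and
  the multivariate analyses.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CROSS_SEP, TrialDesign

PLOT_COLUMNS = [
    "genotype",
    "role",
    "line",
    "tester",
    "replicate",
    "condition",
    "trait",
    "value",
]

MEANS_META_COLUMNS = ["genotype", "role", "line", "tester", "condition"]

_ROLES = {"line_parent", "tester_parent", "cross"}


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema or balance."""


def _normalize_text(text: str) -> str:
    """Map typographic characters to ASCII: minus signs and multiplication sign."""
    return (
        text.replace("−", "-")  # minus sign
        .replace("–", "-")  # en dash
        .replace("×", "x")  # multiplication sign in cross labels
    )


def _read_csv(path: str | Path) -> pd.DataFrame:
    raw = Path(path).read_text(encoding="utf-8")
    return pd.read_csv(_io.StringIO(_normalize_text(raw)), dtype=str, keep_default_na=False)


def validate_plot_table(df: pd.DataFrame, design: TrialDesign) -> pd.DataFrame:
    """Validate a long plot table against a design; return it typed and sorted.

    Checks the header, role/parent consistency, label membership, numeric
    finite values, replicate range, and completeness: every
    (genotype, replicate, condition, trait) cell must appear exactly once.
    """
    missing_cols = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"plot table is missing columns {missing_cols}")
    df = df[PLOT_COLUMNS].copy()

    unknown = sorted(set(df["genotype"]) - set(design.genotype_labels))
    if unknown:
        raise SchemaError(f"unknown genotype labels: {unknown}")

    bad_role = df[~df["role"].isin(_ROLES)]
    if len(bad_role):
        raise SchemaError(f"invalid role values: {sorted(bad_role['role'].unique())}")
    is_cross = df["role"] == "cross"
    if ((df.loc[is_cross, "line"] == "") | (df.loc[is_cross, "tester"] == "")).any():
        raise SchemaError("cross rows must name both line and tester parents")
    par = df[~is_cross]
    if (((par["line"] == "") == (par["tester"] == ""))).any():
        raise SchemaError("parent rows must name exactly one of line/tester")

    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"non-integer replicate value: {exc}") from None
    out_of_range = df[(df["replicate"] < 1) | (df["replicate"] > design.r)]
    if len(out_of_range):
        row = out_of_range.iloc[0]
        raise SchemaError(
            f"replicate {row['replicate']} outside 1..{design.r} "
            f"(genotype {row['genotype']!r})"
        )

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df[~np.isfinite(values)]
    if len(bad):
        row = bad.iloc[0]
        raise SchemaError(
            f"non-numeric or non-finite value {row['value']!r} for genotype "
            f"{row['genotype']!r}, trait {row['trait']!r}, replicate {row['replicate']}"
        )
    df["value"] = values.astype(float)

    unknown_cond = sorted(set(df["condition"]) - set(design.conditions))
    if unknown_cond:
        raise SchemaError(f"unknown condition labels: {unknown_cond}")

    # Completeness: every cell exactly once per (condition, trait).
    key = ["condition", "trait", "genotype", "replicate"]
    dup = df[df.duplicated(key)]
    if len(dup):
        row = dup.iloc[0]
        raise SchemaError(
            f"duplicate cell: genotype {row['genotype']!r}, replicate "
            f"{row['replicate']}, trait {row['trait']!r}, condition {row['condition']!r}"
        )
    expect = design.n_genotypes * design.r
    for (cond, trait), sub in df.groupby(["condition", "trait"]):
        if len(sub) != expect:
            have = {(g, k) for g, k in zip(sub["genotype"], sub["replicate"])}
            want = {
                (g, k)
                for g in design.genotype_labels
                for k in range(1, design.r + 1)
            }
            missing = sorted(want - have)[:5]
            raise SchemaError(
                f"incomplete data for trait {trait!r}, condition {cond!r}: "
                f"missing (genotype, replicate) cells {missing}"
            )
    return df.sort_values(key).reset_index(drop=True)


def load_plot_table(path: str | Path, design: TrialDesign) -> pd.DataFrame:
    """Read and validate a long plot-level CSV (see module docstring for schema)."""
    return validate_plot_table(_read_csv(path), design)


def write_plot_table(df: pd.DataFrame, path: str | Path) -> None:
    df[PLOT_COLUMNS].to_csv(path, index=False)


@dataclass
class MeansTable:
    """Genotype × trait means per condition, with role metadata.

    ``data`` is a tidy frame with the :data:`MEANS_META_COLUMNS` metadata
    columns followed by one numeric column per trait.
    """

    data: pd.DataFrame
    design: TrialDesign

    def __post_init__(self) -> None:
        for c in MEANS_META_COLUMNS:
            if c not in self.data.columns:
                raise SchemaError(f"means table missing column {c!r}")
        unknown = sorted(set(self.data["genotype"]) - set(self.design.genotype_labels))
        if unknown:
            raise SchemaError(f"unknown genotype labels: {unknown}")
        for cond in self.conditions:
            n = (self.data["condition"] == cond).sum()
            if n != self.design.n_genotypes:
                raise SchemaError(
                    f"condition {cond!r} has {n} genotype rows, "
                    f"expected {self.design.n_genotypes}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in MEANS_META_COLUMNS]

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))

    def values_for(self, condition: str) -> pd.DataFrame:
        """Genotype × trait matrix (all entries) for one condition."""
        sub = self.data[self.data["condition"] == condition]
        if sub.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return sub.set_index("genotype")[self.traits].astype(float)

    def value(self, genotype: str, trait: str, condition: str) -> float:
        return float(self.values_for(condition).loc[genotype, trait])

    def cross_matrix(self, trait: str, condition: str) -> pd.DataFrame:
        """The l × t matrix of F1 cross means (lines as rows, testers as columns)."""
        sub = self.data[
            (self.data["condition"] == condition) & (self.data["role"] == "cross")
        ]
        mat = sub.pivot(index="line", columns="tester", values=trait).astype(float)
        mat = mat.reindex(
            index=list(self.design.line_labels), columns=list(self.design.tester_labels)
        )
        if mat.isna().any().any():
            raise SchemaError(f"incomplete cross means for trait {trait!r}")
        mat.index.name = "line"
        mat.columns.name = "tester"
        return mat

    def parent_means(self, trait: str, condition: str) -> pd.Series:
        sub = self.data[
            (self.data["condition"] == condition) & (self.data["role"] != "cross")
        ]
        return sub.set_index("genotype")[trait].astype(float)

    # -- constructors / round-trip -----------------------------------------
    @classmethod
    def from_plot_table(cls, plots: pd.DataFrame, design: TrialDesign) -> "MeansTable":
        """Average replicates of a validated plot table into a means table."""
        agg = (
            plots.groupby(["condition", "genotype", "role", "line", "tester", "trait"])[
                "value"
            ]
            .mean()
            .reset_index()
        )
        wide = agg.pivot(
            index=["genotype", "role", "line", "tester", "condition"],
            columns="trait",
            values="value",
        ).reset_index()
        wide.columns.name = None
        order = {g: i for i, g in enumerate(design.genotype_labels)}
        wide = wide.sort_values(
            ["condition", "genotype"], key=lambda s: s.map(order).fillna(s)
        ).reset_index(drop=True)
        return cls(wide, design)

    @classmethod
    def read_csv(cls, path: str | Path, design: TrialDesign) -> "MeansTable":
        return cls(_read_csv(path).pipe(_coerce_trait_columns), design)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _coerce_trait_columns(df: pd.DataFrame) -> pd.DataFrame:
    for c in df.columns:
        if c not in MEANS_META_COLUMNS:
            df[c] = pd.to_numeric(df[c])
    return df


@dataclass(frozen=True)
class MeanSquareSet:
    """The four mean squares of a line × tester analysis plus design sizes.

    Sufficient input for variance components: lines, testers, line × tester
    and error mean squares, with ``r`` replicates, ``l`` lines, ``t`` testers
    and the error degrees of freedom.
    """

    ms_lines: float
    ms_testers: float
    ms_lxt: float
    ms_error: float
    r: int
    l: int  # noqa: E741 - conventional symbol
    t: int
    df_error: int

    def __post_init__(self) -> None:
        for name in ("ms_lines", "ms_testers", "ms_lxt", "ms_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.r, self.l, self.t) < 2 or self.df_error < 1:
            raise ValueError("invalid design sizes")

    @property
    def df_lines(self) -> int:
        return self.l - 1

    @property
    def df_testers(self) -> int:
        return self.t - 1

    @property
    def df_lxt(self) -> int:
        return (self.l - 1) * (self.t - 1)


def cross_label(line: str, tester: str) -> str:
    """Canonical cross label from parent labels."""
    return f"{line}{CROSS_SEP}{tester}"
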