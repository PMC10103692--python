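"""Balanced RCBD ANOVA with the line × tester partition.

The genotype sum of squares is split twice: first into parents, crosses and
the 1-df parents-vs-crosses contrast; then the cross sum of squares into
lines, testers and line × tester.  All F tests use the pooled RCBD error mean
square as denominator — the convention under which a tester effect can be
significant even when its mean square is smaller than the interaction's.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .design import TrialDesign
from .io import MeansTable, SchemaError

#: Row order of a full ANOVA report.
SOURCE_ORDER = [
    "replications",
    "genotypes",
    "parents",
    "crosses",
    "parents_vs_crosses",
    "lines",
    "testers",
    "lines_x_testers",
    "error",
]

ANOVA_COLUMNS = ["source", "df", "ss", "ms", "F", "p", "stars"]


def _ss(values: np.ndarray, weight: float) -> float:
    v = np.asarray(values, dtype=float)
    return float(weight * np.sum((v - v.mean()) ** 2))


def partition_genotypes(
    means: MeansTable,
    design: TrialDesign,
    r: int,
    trait: str,
    condition: str,
) -> tuple[float, float, float]:
    """Split the genotype SS into (SS_parents, SS_crosses, SS_pvc).

    The parents-vs-crosses term is the 1-df contrast between the two group
    means, ``r * n_p*n_c/(n_p+n_c) * (mean_parents - mean_crosses)**2``; by
    construction the three pieces add up to the genotype SS.
    """
    vals = means.values_for(condition)[trait]
    parents = vals.loc[[g for g in vals.index if design.role_of(g) != "cross"]]
    crosses = vals.loc[[g for g in vals.index if design.role_of(g) == "cross"]]
    n_p, n_c = len(parents), len(crosses)
    if n_p != design.l + design.t or n_c != design.n_crosses:
        raise SchemaError("means table does not cover all parents and crosses")
    ss_parents = _ss(parents.values, r)
    ss_crosses = _ss(crosses.values, r)
    ss_pvc = float(
        r * (n_p * n_c / (n_p + n_c)) * (parents.mean() - crosses.mean()) ** 2
    )
    return ss_parents, ss_crosses, ss_pvc


def partition_crosses(cross_means: pd.DataFrame, r: int) -> tuple[float, float, float]:
    """Split the cross SS of an l × t mean matrix into (lines, testers, l × t)."""
    mat = np.asarray(cross_means, dtype=float)
    if not np.isfinite(mat).all():
        raise SchemaError("incomplete cross-mean matrix")
    l, t = mat.shape
    ss_crosses = _ss(mat.ravel(), r)
    ss_lines = _ss(mat.mean(axis=1), r * t)
    ss_testers = _ss(mat.mean(axis=0), r * l)
    ss_lxt = ss_crosses - ss_lines - ss_testers
    return ss_lines, ss_testers, max(ss_lxt, 0.0)


def f_tests(table: pd.DataFrame, alphas: tuple[float, float] = (0.05, 0.01)) -> pd.DataFrame:
    """Fill F, p and significance stars testing each source against the error MS.

    Stars: ``**`` when p <= 0.01, ``*`` when p <= 0.05, blank otherwise
    (boundary inclusive).  A zero error MS gives F = inf, p = 0 for any
    non-zero source MS, and F = 0, p = 1 when the source MS is zero too.
    """
    table = table.copy()
    err = table[table["source"] == "error"]
    if err.empty:
        raise ValueError("error row required for F tests")
    ms_error = float(err["ms"].iloc[0])
    df_error = int(err["df"].iloc[0])
    a_star, a_dstar = max(alphas), min(alphas)
    for i, row in table.iterrows():
        if row["source"] in ("error",):
            continue
        ms, dfn = float(row["ms"]), int(row["df"])
        if ms_error == 0.0:
            F, p = (math.inf, 0.0) if ms > 0 else (0.0, 1.0)
        else:
            F = ms / ms_error
            p = float(stats.f.sf(F, dfn, df_error)) if F > 0 else 1.0
        table.loc[i, "F"] = F
        table.loc[i, "p"] = p
        table.loc[i, "stars"] = "**" if p <= a_dstar else ("*" if p <= a_star else "")
    return table


def rcbd_anova(
    plots: pd.DataFrame,
    design: TrialDesign,
    trait: str,
    condition: str,
) -> pd.DataFrame:
    """Full RCBD ANOVA for one trait under one condition.

    ``plots`` must be a validated plot table (see
    :func:`linetester.io.load_plot_table`).  Returns a frame with columns
    ``source, df, ss, ms, F, p, stars`` in :data:`SOURCE_ORDER`.
    """
    sub = plots[(plots["trait"] == trait) & (plots["condition"] == condition)]
    if sub.empty:
        raise SchemaError(f"no data for trait {trait!r}, condition {condition!r}")
    cell = sub.pivot(index="genotype", columns="replicate", values="value")
    if cell.isna().any().any() or cell.shape != (design.n_genotypes, design.r):
        raise SchemaError("unbalanced data: every genotype needs every replicate")
    y = cell.values.astype(float)
    g, r = y.shape
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    ss_geno = _ss(y.mean(axis=1), r)
    ss_reps = _ss(y.mean(axis=0), g)
    ss_error = max(ss_total - ss_geno - ss_reps, 0.0)

    means = MeansTable.from_plot_table(sub.assign(trait=trait), design)
    ss_par, ss_cross, ss_pvc = partition_genotypes(means, design, r, trait, condition)
    cross_mat = means.cross_matrix(trait, condition)
    ss_lines, ss_testers, ss_lxt = partition_crosses(cross_mat, r)

    rows = {
        "replications": (r - 1, ss_reps),
        "genotypes": (g - 1, ss_geno),
        "parents": (design.l + design.t - 1, ss_par),
        "crosses": (design.n_crosses - 1, ss_cross),
        "parents_vs_crosses": (1, ss_pvc),
        "lines": (design.l - 1, ss_lines),
        "testers": (design.t - 1, ss_testers),
        "lines_x_testers": ((design.l - 1) * (design.t - 1), ss_lxt),
        "error": ((g - 1) * (r - 1), ss_error),
    }
    table = pd.DataFrame(
        [
            {
                "source": s,
                "df": df,
                "ss": ss,
                "ms": ss / df if df else 0.0,
                "F": np.nan,
                "p": np.nan,
                "stars": "",
            }
            for s, (df, ss) in rows.items()
        ],
        columns=ANOVA_COLUMNS,
    )
    return f_tests(table)


def anova_from_means(
    means: MeansTable,
    design: TrialDesign,
    trait: str,
    condition: str,
    ms_error: float,
    df_error: int,
) -> pd.DataFrame:
    """Reconstruct the genotype-level ANOVA from published means plus an error MS.

    This is the published-granularity mode: the replication and error sums of
    squares are not recoverable from means alone, so the supplied error mean
    square stands in as the test denominator (no replications row is emitted).
    """
    r = design.r
    ss_par, ss_cross, ss_pvc = partition_genotypes(means, design, r, trait, condition)
    cross_mat = means.cross_matrix(trait, condition)
    ss_lines, ss_testers, ss_lxt = partition_crosses(cross_mat, r)
    ss_geno = ss_par + ss_cross + ss_pvc
    rows = {
        "genotypes": (design.n_genotypes - 1, ss_geno),
        "parents": (design.l + design.t - 1, ss_par),
        "crosses": (design.n_crosses - 1, ss_cross),
        "parents_vs_crosses": (1, ss_pvc),
        "lines": (design.l - 1, ss_lines),
        "testers": (design.t - 1, ss_testers),
        "lines_x_testers": ((design.l - 1) * (design.t - 1), ss_lxt),
        "error": (df_error, ms_error * df_error),
    }
    table = pd.DataFrame(
        [
            {
                "source": s,
                "df": df,
                "ss": ss,
                "ms": ss / df if df else 0.0,
                "F": np.nan,
                "p": np.nan,
                "stars": "",
            }
            for s, (df, ss) in rows.items()
        ],
        columns=ANOVA_COLUMNS,
    )
    return f_tests(table)


def lsd_genotype_means(ms_error: float, r: int, df_error: int, alpha: float) -> float:
    """Least significant difference between two genotype means.

    ``LSD = t(alpha/2, df_error) * sqrt(2 * MSe / r)`` — the two-sided
    critical difference for entry means averaged over ``r`` replicates.
    """
    if alpha not in (0.05, 0.01):
        raise ValueError("alpha must be 0.05 or 0.01")
    if ms_error < 0:
        raise ValueError("ms_error must be non-negative")
    return float(stats.t.ppf(1 - alpha / 2, df_error) * math.sqrt(2 * ms_error / r))
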