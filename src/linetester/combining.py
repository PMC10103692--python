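"""General and specific combining ability from an l × t table of cross means.

With ``x_ij`` the mean of the cross line i × tester j and ``mu`` the grand
mean of all l*t crosses, the effects are

    g_i = xbar_i. - mu      (line GCA)
    g_j = xbar_.j - mu      (tester GCA)
    s_ij = x_ij - mu - g_i - g_j   (SCA)

so both GCA vectors and every row/column of the SCA matrix sum to zero, and
``mu + g_i + g_j + s_ij`` reconstructs the observed cross mean exactly.
Parents never enter effect estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SchemaError


@dataclass
class GcaTable:
    """Line and tester GCA effects, optionally annotated with SEs and stars."""

    grand_mean: float
    line_effects: pd.Series
    tester_effects: pd.Series
    se_lines: float | None = None
    se_testers: float | None = None
    lsd: dict[str, dict[float, float]] = field(default_factory=dict)
    line_stars: pd.Series | None = None
    tester_stars: pd.Series | None = None


@dataclass
class ScaTable:
    """SCA effect matrix (lines × testers), optionally annotated."""

    effects: pd.DataFrame
    se: float | None = None
    lsd: dict[float, float] = field(default_factory=dict)
    stars: pd.DataFrame | None = None


def _check_matrix(cross_means: pd.DataFrame) -> np.ndarray:
    mat = np.asarray(cross_means, dtype=float)
    if mat.ndim != 2 or min(mat.shape) < 2:
        raise SchemaError("cross-mean matrix must be at least 2 x 2")
    if not np.isfinite(mat).all():
        raise SchemaError("cross-mean matrix contains missing values")
    return mat


def gca_effects(cross_means: pd.DataFrame) -> GcaTable:
    """GCA effects of every line and tester from the cross-mean matrix."""
    mat = _check_matrix(cross_means)
    mu = float(mat.mean())
    lines = pd.Series(mat.mean(axis=1) - mu, index=cross_means.index, name="gca")
    testers = pd.Series(mat.mean(axis=0) - mu, index=cross_means.columns, name="gca")
    return GcaTable(grand_mean=mu, line_effects=lines, tester_effects=testers)


def sca_effects(cross_means: pd.DataFrame, gca: GcaTable) -> ScaTable:
    """SCA deviations of every cross given GCA effects from the same matrix."""
    mat = _check_matrix(cross_means)
    g_i = gca.line_effects.to_numpy()
    g_j = gca.tester_effects.to_numpy()
    if mat.shape != (g_i.size, g_j.size):
        raise SchemaError("GCA dimensions do not match the cross-mean matrix")
    s = mat - gca.grand_mean - g_i[:, None] - g_j[None, :]
    return ScaTable(
        effects=pd.DataFrame(s, index=cross_means.index, columns=cross_means.columns)
    )


def _stars_for(effect: float, se: float, df_error: int, alphas=(0.05, 0.01)) -> str:
    """Significance marks against zero, boundary inclusive (|effect| >= t*SE)."""
    if se == 0.0:
        return "**" if effect != 0.0 else ""
    if abs(effect) >= stats.t.ppf(1 - min(alphas) / 2, df_error) * se:
        return "**"
    if abs(effect) >= stats.t.ppf(1 - max(alphas) / 2, df_error) * se:
        return "*"
    return ""


def effect_tests(
    gca: GcaTable,
    sca: ScaTable,
    ms_error: float,
    r: int,
    l: int,  # noqa: E741
    t: int,
    df_error: int,
    alphas: tuple[float, float] = (0.05, 0.01),
) -> tuple[GcaTable, ScaTable]:
    """Annotate GCA/SCA tables with standard errors, LSDs and stars.

    Standard errors follow the balanced line × tester expectations::

        SE(g_line)   = sqrt(MSe / (r t))
        SE(g_tester) = sqrt(MSe / (r l))
        SE(s_ij)     = sqrt(MSe (l-1)(t-1) / (r l t))

    An effect is starred when its two-sided t test against zero reaches the
    corresponding level (boundary inclusive).  LSD rows (t * SE) are reported
    informationally alongside.
    """
    if ms_error < 0:
        raise ValueError("ms_error must be non-negative")
    se_l = math.sqrt(ms_error / (r * t))
    se_t = math.sqrt(ms_error / (r * l))
    se_s = math.sqrt(ms_error * (l - 1) * (t - 1) / (r * l * t))
    tcrit = {a: float(stats.t.ppf(1 - a / 2, df_error)) for a in alphas}

    gca = GcaTable(
        grand_mean=gca.grand_mean,
        line_effects=gca.line_effects,
        tester_effects=gca.tester_effects,
        se_lines=se_l,
        se_testers=se_t,
        lsd={
            "lines": {a: tcrit[a] * se_l for a in alphas},
            "testers": {a: tcrit[a] * se_t for a in alphas},
        },
        line_stars=gca.line_effects.map(lambda e: _stars_for(e, se_l, df_error, alphas)),
        tester_stars=gca.tester_effects.map(
            lambda e: _stars_for(e, se_t, df_error, alphas)
        ),
    )
    sca = ScaTable(
        effects=sca.effects,
        se=se_s,
        lsd={a: tcrit[a] * se_s for a in alphas},
        stars=sca.effects.map(lambda e: _stars_for(e, se_s, df_error, alphas)),
    )
    return gca, sca


def combining_ability(
    cross_means: pd.DataFrame,
    ms_error: float | None = None,
    r: int | None = None,
    df_error: int | None = None,
) -> tuple[GcaTable, ScaTable]:
    """One-call GCA + SCA estimation, with significance if an error MS is given."""
    gca = gca_effects(cross_means)
    sca = sca_effects(cross_means, gca)
    if ms_error is not None:
        if r is None or df_error is None:
            raise ValueError("r and df_error are required with ms_error")
        l, t = cross_means.shape
        gca, sca = effect_tests(gca, sca, ms_error, r, l, t, df_error)
    return gca, sca
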