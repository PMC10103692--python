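"""Better-parent heterosis (heterobeltiosis) with direction-aware parent choice.

Heterobeltiosis expresses hybrid vigor as the percentage deviation of an F1
from the *better* of its two parents.  "Better" is trait-direction aware:
for a lower-is-better trait (days to heading, plant height) the better parent
is the one with the smaller mean, so a negative percentage is the desirable
outcome for earliness and shortness.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy import stats

from .design import Direction, TrialDesign, trait_direction
from .io import MeansTable


def better_parent(line_mean: float, tester_mean: float, direction: Direction) -> float:
    """The better of two parent means under the trait's direction of merit."""
    if not (math.isfinite(line_mean) and math.isfinite(tester_mean)):
        raise ValueError("parent means must be finite")
    if direction == "lower_better":
        return min(line_mean, tester_mean)
    return max(line_mean, tester_mean)


def heterobeltiosis(f1_mean: float, bp_value: float) -> float:
    """Percent deviation of the F1 from the better parent: 100 (F1 - BP)/BP."""
    if bp_value == 0.0:
        raise ValueError("better-parent mean is zero; percentage undefined")
    return 100.0 * (f1_mean - bp_value) / bp_value


def heterosis_significance(
    f1_mean: float,
    bp_value: float,
    ms_error: float,
    r: int,
    df_error: int,
    alphas: tuple[float, float] = (0.05, 0.01),
) -> str:
    """Stars for the F1-vs-better-parent difference against an LSD.

    The critical difference is ``t(alpha/2, df) * sqrt(2 MSe / r)`` — the LSD
    for comparing two entry means — applied at the 5% (*) and 1% (**) levels,
    boundary inclusive.
    """
    if ms_error < 0:
        raise ValueError("ms_error must be non-negative")
    diff = abs(f1_mean - bp_value)
    se = math.sqrt(2.0 * ms_error / r)
    if se == 0.0:
        return "**" if diff > 0 else ""
    if diff >= stats.t.ppf(1 - min(alphas) / 2, df_error) * se:
        return "**"
    if diff >= stats.t.ppf(1 - max(alphas) / 2, df_error) * se:
        return "*"
    return ""


def heterosis_table(
    means: MeansTable,
    design: TrialDesign,
    trait: str,
    condition: str,
    ms_error: float | None = None,
    df_error: int | None = None,
) -> pd.DataFrame:
    """Heterobeltiosis of every cross for one trait under one condition.

    Returns a frame indexed by cross label with columns ``f1, better_parent,
    heterobeltiosis, stars`` (stars empty unless an error MS is supplied).
    """
    direction = trait_direction(trait)
    vals = means.values_for(condition)[trait]
    rows = []
    for cross in design.cross_labels:
        line, tester = design.parents_of(cross)
        bp = better_parent(float(vals[line]), float(vals[tester]), direction)
        f1 = float(vals[cross])
        stars = ""
        if ms_error is not None:
            if df_error is None:
                raise ValueError("df_error is required with ms_error")
            stars = heterosis_significance(f1, bp, ms_error, design.r, df_error)
        rows.append(
            {
                "cross": cross,
                "f1": f1,
                "better_parent": bp,
                "heterobeltiosis": heterobeltiosis(f1, bp),
                "stars": stars,
            }
        )
    return pd.DataFrame(rows).set_index("cross")
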