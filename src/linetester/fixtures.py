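"""Packaged reference data from the rice line × tester drought trial.

Three hand-transcribed, version-controlled CSVs ship with the package so that
every downstream module can be exercised without any download:

* ``table3_means`` — genotype × trait mean matrix (31 entries × 10 traits ×
  2 irrigation conditions).
* ``table2_ms`` — the published ANOVA mean squares per trait and condition,
  including the combining-ability variance rows.
* ``table7_params`` — the published genetic-parameter table (additive,
  dominance and environmental variances, heritabilities, contributions).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .design import RICE_DESIGN
from .io import MeansTable, MeanSquareSet

FIXTURE_NAMES = ("table3_means", "table2_ms", "table2_full", "table7_params")

_FILES = {
    "table3_means": "table3_means.csv",
    "table2_ms": "table2_mean_squares.csv",
    "table2_full": "table2_mean_squares.csv",
    "table7_params": "table7_genetic_params.csv",
}


def fixture_path(name: str) -> Path:
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return Path(str(resources.files("linetester.data") / _FILES[name]))


def load_fixture(name: str):
    """Load a packaged fixture.

    Returns
    -------
    ``table3_means``
        A :class:`~linetester.io.MeansTable` for the 7 × 3 rice design.
    ``table2_ms``
        ``dict[(trait, condition), MeanSquareSet]`` built from the published
        lines / testers / line × tester / error mean squares.
    ``table2_full``
        The raw tidy frame of every published ANOVA row, including the
        genotype-level partition and the σ²GCA / σ²SCA rows.
    ``table7_params``
        Tidy frame of the published genetic parameters
        (columns ``trait, condition, parameter, value``).
    """
    path = fixture_path(name)
    if name == "table3_means":
        return MeansTable.read_csv(path, RICE_DESIGN)
    df = pd.read_csv(path)
    if name in ("table2_full", "table7_params"):
        return df
    if name == "table2_ms":
        out: dict[tuple[str, str], MeanSquareSet] = {}
        design = RICE_DESIGN
        for (trait, cond), sub in df.groupby(["trait", "condition"]):
            ms = sub.set_index("source")["value"]
            df_err = int(sub.set_index("source").loc["error", "df"])
            out[(trait, cond)] = MeanSquareSet(
                ms_lines=float(ms["lines"]),
                ms_testers=float(ms["testers"]),
                ms_lxt=float(ms["lines_x_testers"]),
                ms_error=float(ms["error"]),
                r=design.r,
                l=design.l,
                t=design.t,
                df_error=df_err,
            )
        return out
    raise AssertionError("unreachable")
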