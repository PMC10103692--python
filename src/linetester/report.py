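"""Report writers and the end-to-end analysis pipeline.

Two entry modes mirror how line × tester trials are encountered in practice:

* **plots mode** — replicate-level data (e.g. the simulator's output): full
  RCBD ANOVA, then effects, variance components, heterosis and multivariate
  summaries all flow from the data itself.
* **means + mean-squares mode** — the granularity at which trials are
  published: genotype means and an ANOVA mean-square table.  Everything
  except the replication/error sums of squares is recomputed from the means;
  the error mean square is taken from the supplied table.

All tabular outputs are TSV (two decimals, mirroring how such tables are
printed) with full-precision JSON alongside where structure matters.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import anova as _anova
from . import combining as _combining
from . import genetics as _genetics
from . import heterosis as _heterosis
from . import multivariate as _mv
from .design import TrialDesign
from .io import MeansTable, MeanSquareSet


def _fmt(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(decimals)
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    _fmt(df).to_csv(path, sep="\t", index=index)


def gca_frame(gca: _combining.GcaTable) -> pd.DataFrame:
    """GCA effects as one frame: lines then testers, with stars."""
    rows = []
    for label, eff in gca.line_effects.items():
        rows.append(
            {
                "parent": label,
                "set": "line",
                "gca": eff,
                "stars": "" if gca.line_stars is None else gca.line_stars[label],
            }
        )
    for label, eff in gca.tester_effects.items():
        rows.append(
            {
                "parent": label,
                "set": "tester",
                "gca": eff,
                "stars": "" if gca.tester_stars is None else gca.tester_stars[label],
            }
        )
    return pd.DataFrame(rows).set_index("parent")


def sca_frame(sca: _combining.ScaTable, design: TrialDesign) -> pd.DataFrame:
    """SCA effects as a long frame indexed by cross label."""
    rows = []
    for li in sca.effects.index:
        for te in sca.effects.columns:
            rows.append(
                {
                    "cross": design.cross_label(li, te),
                    "sca": sca.effects.loc[li, te],
                    "stars": "" if sca.stars is None else sca.stars.loc[li, te],
                }
            )
    return pd.DataFrame(rows).set_index("cross")


def analyze_condition(
    means: MeansTable,
    ms_sets: dict[tuple[str, str], MeanSquareSet],
    design: TrialDesign,
    condition: str,
    traits: list[str] | None = None,
    inbreeding_F: float = 1.0,
) -> dict[str, object]:
    """Run the full published-granularity pipeline for one condition.

    Returns a dict with per-trait ANOVA tables, GCA/SCA frames, variance
    components, heterosis tables, the trait correlation matrix and a Ward
    cluster model with a two-cluster summary.
    """
    traits = traits or means.traits
    out: dict[str, object] = {
        "condition": condition,
        "anova": {},
        "gca": {},
        "sca": {},
        "varcomp": {},
        "heterosis": {},
        "lsd": {},
    }
    for trait in traits:
        ms = ms_sets[(trait, condition)]
        out["anova"][trait] = _anova.anova_from_means(
            means, design, trait, condition, ms.ms_error, ms.df_error
        )
        cross = means.cross_matrix(trait, condition)
        gca, sca = _combining.combining_ability(
            cross, ms.ms_error, design.r, ms.df_error
        )
        out["gca"][trait] = gca_frame(gca)
        out["sca"][trait] = sca_frame(sca, design)
        out["varcomp"][trait] = _genetics.variance_components(ms, inbreeding_F)
        out["heterosis"][trait] = _heterosis.heterosis_table(
            means, design, trait, condition, ms.ms_error, ms.df_error
        )
        out["lsd"][trait] = {
            alpha: _anova.lsd_genotype_means(ms.ms_error, design.r, ms.df_error, alpha)
            for alpha in (0.05, 0.01)
        }
    matrix = means.values_for(condition)[traits]
    out["correlation"] = _mv.pearson_matrix(matrix)
    z = _mv.standardize(matrix)
    model = _mv.hcluster(z, "ward")
    out["cluster_model"] = model
    out["cluster_assignments"] = model.cut(2)
    out["cluster_summary"] = _mv.cluster_summary(out["cluster_assignments"], matrix)
    return out


def varcomp_frame(
    varcomp: dict[str, _genetics.VarianceComponents]
) -> pd.DataFrame:
    rows = []
    for trait, vc in varcomp.items():
        d = asdict(vc)
        d.pop("negative_estimates")
        rows.append({"trait": trait, **d})
    return pd.DataFrame(rows).set_index("trait")


def write_condition_report(
    result: dict[str, object], outdir: str | Path, design: TrialDesign
) -> list[Path]:
    """Write every table of :func:`analyze_condition` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cond = result["condition"]
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / f"{name}.{cond}.tsv"
        write_tsv(df, path, index=index)
        written.append(path)

    for trait, table in result["anova"].items():
        save(table, f"anova.{trait}", index=False)
    for kind in ("gca", "sca", "heterosis"):
        for trait, table in result[kind].items():
            save(table, f"{kind}.{trait}")
    save(varcomp_frame(result["varcomp"]), "genetic_parameters")
    corr = result["correlation"]
    save(corr.r, "correlation_r")
    save(corr.p.round(4), "correlation_p")
    save(result["cluster_summary"], "cluster_summary")
    save(result["cluster_assignments"].to_frame(), "cluster_assignments")
    newick = outdir / f"dendrogram.{cond}.nwk"
    newick.write_text(result["cluster_model"].to_newick() + "\n")
    written.append(newick)
    lsd_path = outdir / f"lsd.{cond}.json"
    lsd_path.write_text(
        json.dumps(
            {t: {str(a): v for a, v in d.items()} for t, d in result["lsd"].items()},
            indent=1,
        )
    )
    written.append(lsd_path)
    return written
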