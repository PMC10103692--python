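"""Synthetic line × tester RCBD trials with known genetic architecture.

The simulator draws plot values under the additive model

    cross plots:   y_ijk = mu + b_k + g_i + g_j + s_ij + e_ijk
    parent plots:  y_pk  = mu_p + b_k + e_pk

with block effects b_k, line GCA g_i, tester GCA g_j, SCA s_ij and plot error
e, all normal with configurable variances.  Effects are re-centered exactly
after drawing so the zero-sum constraints of the line × tester model hold in
finite samples, which makes the simulator an exact oracle for the estimation
pipeline at zero error variance.  A water-deficit condition is simulated as
an additive per-trait shift plus optional error-variance inflation; the
default configuration mirrors the packaged rice trial (7 lines × 3 testers ×
3 replicates, 10 traits, two irrigation conditions) with means, shifts and
variance components taken from its published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, RICE_DESIGN, TrialDesign
from .io import PLOT_COLUMNS


@dataclass(frozen=True)
class TraitSim:
    """Per-trait simulation parameters, all in (trait units)^2 except means."""

    mu: float
    sigma2_block: float = 0.0
    sigma2_gca_line: float = 1.0
    sigma2_gca_tester: float = 1.0
    sigma2_sca: float = 1.0
    sigma2_error: float = 1.0
    #: spread of parent per-se means around mu
    sigma2_parent: float | None = None
    #: additive shift applied to every plot under the water-deficit condition
    deficit_shift: float = 0.0
    #: multiplier on sigma2_error under water deficit
    deficit_error_inflation: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "sigma2_block",
            "sigma2_gca_line",
            "sigma2_gca_tester",
            "sigma2_sca",
            "sigma2_error",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma2_parent is not None and self.sigma2_parent < 0:
            raise ValueError("sigma2_parent must be non-negative")
        if self.deficit_error_inflation < 0:
            raise ValueError("deficit_error_inflation must be non-negative")

    @property
    def parent_variance(self) -> float:
        if self.sigma2_parent is not None:
            return self.sigma2_parent
        return self.sigma2_gca_line + self.sigma2_gca_tester + self.sigma2_sca


@dataclass(frozen=True)
class SimulationConfig:
    """Design plus per-trait parameters and a mandatory seed."""

    seed: int
    design: TrialDesign = RICE_DESIGN
    traits: dict[str, TraitSim] = field(
        default_factory=lambda: {"trait1": TraitSim(mu=50.0)}
    )
    conditions: tuple[str, ...] = CONDITIONS


@dataclass
class SimulationTruth:
    """The effects actually drawn, keyed by trait."""

    block_effects: dict[str, np.ndarray]
    line_gca: dict[str, pd.Series]
    tester_gca: dict[str, pd.Series]
    sca: dict[str, pd.DataFrame]
    parent_means: dict[str, pd.Series]
    config: SimulationConfig


def _centered_normal(rng: np.random.Generator, sigma2: float, size) -> np.ndarray:
    draw = rng.normal(0.0, np.sqrt(sigma2), size=size)
    if draw.ndim == 1:
        return draw - draw.mean()
    # center rows and columns exactly (double-centering keeps both zero-sum)
    return draw - draw.mean(axis=0) - draw.mean(axis=1)[:, None] + draw.mean()


def simulate_trial(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw one complete trial; deterministic given the seed.

    Returns a validated-schema long plot table covering every genotype,
    replicate, condition and trait, together with the drawn truth.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    lines, testers = design.line_labels, design.tester_labels
    truth = SimulationTruth({}, {}, {}, {}, {}, config)
    records: list[dict] = []

    for trait, ts in config.traits.items():
        g_i = pd.Series(
            _centered_normal(rng, ts.sigma2_gca_line, design.l), index=lines
        )
        g_j = pd.Series(
            _centered_normal(rng, ts.sigma2_gca_tester, design.t), index=testers
        )
        s = pd.DataFrame(
            _centered_normal(rng, ts.sigma2_sca, (design.l, design.t)),
            index=lines,
            columns=testers,
        )
        p_means = pd.Series(
            ts.mu + rng.normal(0.0, np.sqrt(ts.parent_variance), design.l + design.t),
            index=list(lines) + list(testers),
        )
        blocks = rng.normal(0.0, np.sqrt(ts.sigma2_block), design.r)
        truth.block_effects[trait] = blocks
        truth.line_gca[trait] = g_i
        truth.tester_gca[trait] = g_j
        truth.sca[trait] = s
        truth.parent_means[trait] = p_means

        for cond in config.conditions:
            shift = ts.deficit_shift if cond == "water_deficit" else 0.0
            err_sd = np.sqrt(
                ts.sigma2_error
                * (ts.deficit_error_inflation if cond == "water_deficit" else 1.0)
            )
            for k in range(1, design.r + 1):
                b = blocks[k - 1]
                for p in p_means.index:
                    is_line = p in lines
                    records.append(
                        {
                            "genotype": p,
                            "role": "line_parent" if is_line else "tester_parent",
                            "line": p if is_line else "",
                            "tester": "" if is_line else p,
                            "replicate": k,
                            "condition": cond,
                            "trait": trait,
                            "value": p_means[p] + b + shift + rng.normal(0, err_sd),
                        }
                    )
                for li in lines:
                    for te in testers:
                        records.append(
                            {
                                "genotype": design.cross_label(li, te),
                                "role": "cross",
                                "line": li,
                                "tester": te,
                                "replicate": k,
                                "condition": cond,
                                "trait": trait,
                                "value": ts.mu
                                + g_i[li]
                                + g_j[te]
                                + s.loc[li, te]
                                + b
                                + shift
                                + rng.normal(0, err_sd),
                            }
                        )
    plots = pd.DataFrame.from_records(records, columns=PLOT_COLUMNS)
    return plots, truth


def recovery_report(
    truth: SimulationTruth,
    trait: str,
    line_gca_est: pd.Series,
    tester_gca_est: pd.Series,
    sca_est: pd.DataFrame,
    sigma2_sca_est: float | None = None,
) -> dict[str, float]:
    """Compare pipeline estimates for one trait with the simulated truth.

    Reports Pearson correlations between true and estimated effect vectors
    and, if given, the bias of the SCA variance estimate.  Degenerate (zero
    spread) vectors yield a correlation of 1.0 when identical, else 0.0.
    """
    if list(line_gca_est.index) != list(truth.line_gca[trait].index):
        raise ValueError("line labels of estimates do not match the simulated design")
    if list(tester_gca_est.index) != list(truth.tester_gca[trait].index):
        raise ValueError("tester labels of estimates do not match the simulated design")

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
        if a.std() == 0.0 or b.std() == 0.0:
            return 1.0 if np.allclose(a, b) else 0.0
        return float(np.corrcoef(a, b)[0, 1])

    out = {
        "corr_line_gca": corr(truth.line_gca[trait].values, line_gca_est.values),
        "corr_tester_gca": corr(truth.tester_gca[trait].values, tester_gca_est.values),
        "corr_sca": corr(truth.sca[trait].values, sca_est.values),
        "sca_sign_agreement": float(
            np.mean(np.sign(truth.sca[trait].values) == np.sign(sca_est.values))
        ),
    }
    if sigma2_sca_est is not None:
        out["sigma2_sca_bias"] = float(
            sigma2_sca_est - truth.config.traits[trait].sigma2_sca
        )
    return out


def rice_like_config(seed: int) -> SimulationConfig:
    """A configuration emulating the packaged rice drought trial.

    Ten traits at the 7 × 3 × 3 design size; per-trait grand means and
    water-deficit shifts are taken from the packaged mean table, combining
    ability and error variances from the packaged mean-square table (line and
    tester GCA variance both set to the published pooled sigma2_GCA, SCA and
    error variances to the published sigma2_SCA and error MS).  Block
    variance is set to half the error variance — blocks in well-managed
    trials typically absorb less spread than plot error.
    """
    from .fixtures import load_fixture  # local import to avoid cycles

    means = load_fixture("table3_means")
    t2 = load_fixture("table2_full").set_index(["trait", "condition", "source"])["value"]
    traits: dict[str, TraitSim] = {}
    for trait in means.traits:
        mu_n = float(means.cross_matrix(trait, "normal").values.mean())
        mu_wd = float(means.cross_matrix(trait, "water_deficit").values.mean())
        s2_gca = float(t2[(trait, "normal", "sigma2_gca")])
        s2_sca = float(t2[(trait, "normal", "sigma2_sca")])
        s2_err = float(t2[(trait, "normal", "error")])
        s2_err_wd = float(t2[(trait, "water_deficit", "error")])
        traits[trait] = TraitSim(
            mu=mu_n,
            sigma2_block=0.5 * s2_err,
            sigma2_gca_line=max(s2_gca, 0.0),
            sigma2_gca_tester=max(s2_gca, 0.0),
            sigma2_sca=max(s2_sca, 0.0),
            sigma2_error=s2_err,
            deficit_shift=mu_wd - mu_n,
            deficit_error_inflation=s2_err_wd / s2_err if s2_err > 0 else 1.0,
        )
    return SimulationConfig(seed=seed, design=RICE_DESIGN, traits=traits)


def single_trait_config(
    seed: int,
    design: TrialDesign = RICE_DESIGN,
    **trait_kwargs,
) -> SimulationConfig:
    """Convenience one-trait configuration (normal condition only)."""
    ts = TraitSim(**{"mu": 50.0, **trait_kwargs})
    return SimulationConfig(
        seed=seed, design=design, traits={"trait1": ts}, conditions=("normal",)
    )
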