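"""Variance components, heritabilities and contributions for line × tester data.

Method-of-moments estimators from the four mean squares of the combined
analysis.  With fully inbred parents (inbreeding coefficient F = 1) the
combining-ability variances translate into genetic variances as
``sigma2_A = 2 * sigma2_GCA`` and ``sigma2_D = sigma2_SCA``; the general-F
coefficients ``4/(1+F)`` and ``(2/(1+F))**2`` are exposed for reuse with
non-inbred parents.  Negative moment estimates are retained as computed and
flagged, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import MeanSquareSet


@dataclass
class VarianceComponents:
    """Genetic-parameter estimates for one trait under one condition."""

    sigma2_gca: float
    sigma2_gca_lines: float
    sigma2_gca_testers: float
    sigma2_sca: float
    sigma2_A: float
    sigma2_D: float
    sigma2_E: float
    gca_sca_ratio: float | None
    h2_broad: float
    h2_narrow: float
    contrib_lines: float
    contrib_testers: float
    contrib_lxt: float
    inbreeding_F: float = 1.0
    #: names of moment estimates that came out negative
    negative_estimates: list[str] = field(default_factory=list)

    @property
    def nonadditive_predominant(self) -> bool:
        """True when sigma2_GCA / sigma2_SCA < 1, i.e. dominance-type gene action."""
        return self.gca_sca_ratio is not None and self.gca_sca_ratio < 1.0


def sca_variance(ms: MeanSquareSet) -> float:
    """sigma2_SCA = (MS_LxT - MS_error) / r."""
    return (ms.ms_lxt - ms.ms_error) / ms.r


def gca_variance(ms: MeanSquareSet) -> tuple[float, float, float]:
    """Per-set and pooled GCA variance estimates.

    Returns ``(pooled, from_lines, from_testers)`` where
    ``from_lines = (MS_lines - MS_LxT)/(r t)``,
    ``from_testers = (MS_testers - MS_LxT)/(r l)`` and the pooled value is
    their unweighted mean.
    """
    v_lines = (ms.ms_lines - ms.ms_lxt) / (ms.r * ms.t)
    v_testers = (ms.ms_testers - ms.ms_lxt) / (ms.r * ms.l)
    return (v_lines + v_testers) / 2.0, v_lines, v_testers


def additive_dominance(
    sigma2_gca: float, sigma2_sca: float, inbreeding_F: float = 1.0
) -> tuple[float, float]:
    """Translate combining-ability variances into additive and dominance variance.

    ``sigma2_A = (4/(1+F)) * sigma2_GCA`` and
    ``sigma2_D = (2/(1+F))**2 * sigma2_SCA``; at F = 1 these reduce to
    ``2 * sigma2_GCA`` and ``sigma2_SCA``.
    """
    if not 0.0 <= inbreeding_F <= 1.0:
        raise ValueError("inbreeding_F must lie in [0, 1]")
    c = 2.0 / (1.0 + inbreeding_F)
    return 2.0 * c * sigma2_gca, c * c * sigma2_sca


def heritabilities(
    sigma2_A: float, sigma2_D: float, sigma2_E: float
) -> tuple[float, float]:
    """Broad- and narrow-sense heritability, in percent.

    ``h2_b = 100 (A + D)/(A + D + E)`` and ``h2_n = 100 A/(A + D + E)``.
    """
    total = sigma2_A + sigma2_D + sigma2_E
    if total <= 0:
        raise ValueError("total phenotypic variance must be positive")
    return 100.0 * (sigma2_A + sigma2_D) / total, 100.0 * sigma2_A / total


def contributions(
    ss_lines: float, ss_testers: float, ss_lxt: float
) -> tuple[float, float, float]:
    """Percent contribution of lines, testers and line × tester to the cross SS."""
    total = ss_lines + ss_testers + ss_lxt
    if total <= 0:
        raise ValueError("sums of squares are all zero")
    return (
        100.0 * ss_lines / total,
        100.0 * ss_testers / total,
        100.0 * ss_lxt / total,
    )


def gca_sca_ratio(sigma2_gca: float, sigma2_sca: float) -> float | None:
    """sigma2_GCA / sigma2_SCA; ``None`` when the denominator is zero."""
    if sigma2_sca == 0.0:
        return None
    return sigma2_gca / sigma2_sca


def variance_components(
    ms: MeanSquareSet,
    inbreeding_F: float = 1.0,
    sigma2_gca_override: float | None = None,
) -> VarianceComponents:
    """Full genetic-parameter set from a mean-square set.

    ``sigma2_gca_override`` lets a published sigma2_GCA value be carried
    through instead of the pooled moment estimate (useful when reproducing a
    printed genetic-parameter table whose GCA variance came from elsewhere).
    sigma2_E is the error mean square.
    """
    s2_sca = sca_variance(ms)
    pooled, v_lines, v_testers = gca_variance(ms)
    s2_gca = pooled if sigma2_gca_override is None else sigma2_gca_override
    s2_A, s2_D = additive_dominance(s2_gca, s2_sca, inbreeding_F)
    s2_E = ms.ms_error
    h2_b, h2_n = heritabilities(s2_A, s2_D, s2_E)
    c_l, c_t, c_lt = contributions(
        ms.ms_lines * ms.df_lines,
        ms.ms_testers * ms.df_testers,
        ms.ms_lxt * ms.df_lxt,
    )
    negatives = [
        name
        for name, v in (
            ("sigma2_sca", s2_sca),
            ("sigma2_gca_lines", v_lines),
            ("sigma2_gca_testers", v_testers),
            ("sigma2_gca", s2_gca),
        )
        if v < 0
    ]
    return VarianceComponents(
        sigma2_gca=s2_gca,
        sigma2_gca_lines=v_lines,
        sigma2_gca_testers=v_testers,
        sigma2_sca=s2_sca,
        sigma2_A=s2_A,
        sigma2_D=s2_D,
        sigma2_E=s2_E,
        gca_sca_ratio=gca_sca_ratio(s2_gca, s2_sca),
        h2_broad=h2_b,
        h2_narrow=h2_n,
        contrib_lines=c_l,
        contrib_testers=c_t,
        contrib_lxt=c_lt,
        inbreeding_F=inbreeding_F,
        negative_estimates=negatives,
    )
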