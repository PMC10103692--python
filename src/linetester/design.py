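"""Trial design and trait metadata for line × tester mating experiments.

A line × tester trial crosses each of ``l`` female lines with each of ``t``
male testers, giving ``l*t`` F1 hybrids.  The full entry list evaluated in the
field is lines + testers + hybrids, laid out as a randomized complete block
design (RCBD) with ``r`` replicates, optionally repeated under several
environmental conditions (here: normal irrigation vs. water deficit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

Direction = Literal["higher_better", "lower_better"]

#: Canonical condition labels for the packaged rice drought trial.
CONDITIONS = ("normal", "water_deficit")

#: Separator used in canonical cross labels, e.g. ``"Puebla x Sakha106"``.
CROSS_SEP = " x "


@dataclass(frozen=True)
class TraitSpec:
    """A measured trait: its name, units, and direction of merit.

    ``direction`` states which way is agronomically desirable: earliness
    (fewer days to heading) and short stature are improvements, so those
    traits are ``lower_better``; every other trait is ``higher_better``.
    The direction drives better-parent selection in heterosis and the sign
    convention of "desirable" effects.
    """

    name: str
    units: str = ""
    direction: Direction = "higher_better"


#: Registry of the ten traits scored in the packaged rice drought trial.
TRAIT_REGISTRY: dict[str, TraitSpec] = {
    s.name: s
    for s in (
        TraitSpec("RWC", "%"),  # leaf relative water content
        TraitSpec("Proline", "mg g-1 FW"),
        TraitSpec("CAT", "unit mg-1 protein"),  # catalase activity
        TraitSpec("APX", "unit mg-1 protein"),  # ascorbate peroxidase
        TraitSpec("TC", "mg g-1 FW"),  # total chlorophyll
        TraitSpec("DTH", "days", "lower_better"),  # days to 50% heading
        TraitSpec("PH", "cm", "lower_better"),  # plant height
        TraitSpec("GYPP", "g"),  # grain yield per plant
        TraitSpec("SpF", "%"),  # spikelet fertility
        TraitSpec("GI", "g"),  # 1,000-grain weight (grain index)
    )
}


def trait_direction(trait: str) -> Direction:
    """Direction of merit for ``trait``; unknown traits default to higher-is-better."""
    spec = TRAIT_REGISTRY.get(trait)
    return spec.direction if spec is not None else "higher_better"


@dataclass(frozen=True)
class TrialDesign:
    """A balanced line × tester RCBD layout.

    Parameters
    ----------
    line_labels, tester_labels
        Ordered, disjoint parent labels; ``l = len(line_labels)`` and
        ``t = len(tester_labels)``.
    n_reps
        Number of complete blocks ``r``.
    conditions
        Environment labels under which the whole trial is repeated.
    """

    line_labels: tuple[str, ...]
    tester_labels: tuple[str, ...]
    n_reps: int = 3
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.l < 2 or self.t < 2 or self.r < 2:
            raise ValueError("need at least 2 lines, 2 testers and 2 replicates")
        labels = list(self.line_labels) + list(self.tester_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("line and tester labels must be unique and disjoint")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ValueError("conditions must be non-empty and unique")

    @property
    def l(self) -> int:  # noqa: E743 - conventional symbol
        return len(self.line_labels)

    @property
    def t(self) -> int:
        return len(self.tester_labels)

    @property
    def r(self) -> int:
        return self.n_reps

    @property
    def n_crosses(self) -> int:
        return self.l * self.t

    @property
    def n_genotypes(self) -> int:
        """Total entries in the trial: parents plus hybrids."""
        return self.l + self.t + self.n_crosses

    def cross_label(self, line: str, tester: str) -> str:
        if line not in self.line_labels or tester not in self.tester_labels:
            raise KeyError(f"unknown parent pair ({line!r}, {tester!r})")
        return f"{line}{CROSS_SEP}{tester}"

    @property
    def cross_labels(self) -> tuple[str, ...]:
        return tuple(
            f"{li}{CROSS_SEP}{te}" for li in self.line_labels for te in self.tester_labels
        )

    @property
    def genotype_labels(self) -> tuple[str, ...]:
        """All entry labels in canonical order: lines, testers, crosses."""
        return self.line_labels + self.tester_labels + self.cross_labels

    def role_of(self, genotype: str) -> str:
        if genotype in self.line_labels:
            return "line_parent"
        if genotype in self.tester_labels:
            return "tester_parent"
        if genotype in self.cross_labels:
            return "cross"
        raise KeyError(f"unknown genotype {genotype!r}")

    def parents_of(self, cross: str) -> tuple[str, str]:
        """Split a canonical cross label into its (line, tester) parents."""
        if cross not in self.cross_labels:
            raise KeyError(f"unknown cross {cross!r}")
        line, tester = cross.split(CROSS_SEP)
        return line, tester


#: The packaged rice drought trial: 7 lines × 3 testers × 3 replicates.
RICE_DESIGN = TrialDesign(
    line_labels=(
        "Puebla",
        "Hispagran",
        "IET1444",
        "WAB1573",
        "Giza177",
        "Sakha101",
        "Sakha105",
    ),
    tester_labels=("Sakha106", "Sakha107", "Sakha108"),
    n_reps=3,
)
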