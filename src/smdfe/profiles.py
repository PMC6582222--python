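"""Free-energy profile composition for stepwise reaction pathways.

A stepwise mechanism is a chain of elementary steps, each described by the
height of its transition state above its own reactant level (``dG_TS``) and
the free-energy change of the step (``dG_step``).  Chaining n steps yields a
profile of 2n+1 alternating stationary/transition levels, cumulative relative
to the first reactant.  The profile answers the questions the per-step
numbers cannot: the global activation free energy (highest cumulative TS
level), the overall reaction free energy (final stationary level) and the
rate-determining transition state.

Processes (e.g. deamination, oxidation, amination of the adenine→guanine
transformation) are themselves composed into a pathway by offsetting each
process by the cumulative free energy reached before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import kinetics
from .kinetics import StepKinetics, T_DEFAULT

__all__ = [
    "ElementaryStep",
    "Level",
    "FreeEnergyProfile",
    "PathwayResult",
    "compose_profile",
    "process_summary",
    "rate_determining_step",
    "concat_profiles",
    "pathway_global",
    "profile_to_table",
    "profile_from_table",
]

STATIONARY = "stationary"
TRANSITION = "transition"


@dataclass(frozen=True)
class ElementaryStep:
    """One elementary step: TS height and net change, both from the step's reactant."""

    name: str
    dG_TS: float  # kcal/mol, TS above this step's reactant level
    dG_step: float  # kcal/mol, product minus reactant
    ts_label: str | None = None

    @property
    def transition_label(self) -> str:
        return self.ts_label if self.ts_label is not None else f"TS({self.name})"


@dataclass(frozen=True)
class Level:
    label: str
    kind: str  # STATIONARY or TRANSITION
    dG: float  # cumulative, kcal/mol, relative to the first stationary point


@dataclass
class FreeEnergyProfile:
    """Alternating stationary/transition cumulative levels along a pathway."""

    levels: list[Level]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lv = self.levels
        if not lv or len(lv) % 2 == 0:
            raise ValueError("profile needs an odd number of levels (2n+1 for n steps)")
        if lv[0].kind != STATIONARY or abs(lv[0].dG) > 1e-12:
            raise ValueError("profile must start at a stationary level with dG = 0")
        for i, level in enumerate(lv):
            want = STATIONARY if i % 2 == 0 else TRANSITION
            if level.kind != want:
                raise ValueError(
                    f"level {i} ({level.label!r}): expected kind {want!r}, got {level.kind!r}"
                )

    @property
    def n_steps(self) -> int:
        return (len(self.levels) - 1) // 2

    @property
    def transition_levels(self) -> list[Level]:
        return self.levels[1::2]

    @property
    def stationary_levels(self) -> list[Level]:
        return self.levels[0::2]

    @property
    def final_dG(self) -> float:
        return self.levels[-1].dG


@dataclass
class PathwayResult:
    """Global energetics and kinetics of a composed pathway."""

    dG_act_global: float
    dG_rxn_global: float
    rds_label: str
    kinetics: StepKinetics
    profile: FreeEnergyProfile = field(repr=False)


def compose_profile(
    steps: Sequence[ElementaryStep], start_label: str = "reactants"
) -> FreeEnergyProfile:
    """Chain elementary steps into a cumulative free-energy profile.

    For each step i, the TS level is (previous stationary) + dG_TS(i) and the
    next stationary level is (previous stationary) + dG_step(i).
    """
    steps = list(steps)
    if not steps:
        raise ValueError("cannot compose a profile from an empty step list")
    names = [s.name for s in steps]
    if len(set(names)) != len(names):
        raise ValueError("step names must be unique within a composition")
    levels = [Level(start_label, STATIONARY, 0.0)]
    base = 0.0
    for s in steps:
        levels.append(Level(s.transition_label, TRANSITION, base + s.dG_TS))
        base += s.dG_step
        levels.append(Level(s.name, STATIONARY, base))
    return FreeEnergyProfile(levels)


def process_summary(profile: FreeEnergyProfile) -> tuple[float, float]:
    """(activation, reaction) free energy of a profile: max TS level, final level."""
    return max(l.dG for l in profile.transition_levels), profile.final_dG


def rate_determining_step(profile: FreeEnergyProfile) -> str:
    """Label of the highest cumulative transition level (earliest wins ties)."""
    best = profile.transition_levels[0]
    for level in profile.transition_levels[1:]:
        if level.dG > best.dG:
            best = level
    return best.label


def concat_profiles(profiles: Sequence[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Concatenate process profiles, offsetting each by the level reached before it."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot concatenate an empty list of profiles")
    levels = list(profiles[0].levels)
    for prof in profiles[1:]:
        offset = levels[-1].dG
        # the incoming profile's first stationary level coincides with the
        # current endpoint; drop it to keep strict alternation
        levels.extend(
            Level(l.label, l.kind, l.dG + offset) for l in prof.levels[1:]
        )
    return FreeEnergyProfile(levels)


def pathway_global(
    processes: Sequence[FreeEnergyProfile], T: float = T_DEFAULT
) -> PathwayResult:
    """Global activation/reaction energetics and TST kinetics of a pathway.

    The global activation free energy is the maximum cumulative TS level of
    the concatenated profile, measured from the initial reactants; the global
    reaction free energy is the final level (= sum of process ΔG values).
    """
    full = concat_profiles(processes)
    dG_act, dG_rxn = process_summary(full)
    kin = kinetics.step_kinetics(
        kinetics.StepEnergetics(label="global", dG_act=dG_act, dG_rxn=dG_rxn, T=T)
    )
    return PathwayResult(
        dG_act_global=dG_act,
        dG_rxn_global=dG_rxn,
        rds_label=rate_determining_step(full),
        kinetics=kin,
        profile=full,
    )


def profile_to_table(profile: FreeEnergyProfile) -> pd.DataFrame:
    """Lossless tabular serialization: one row per level."""
    return pd.DataFrame(
        {
            "label": [l.label for l in profile.levels],
            "kind": [l.kind for l in profile.levels],
            "cumulative_dG": [l.dG for l in profile.levels],
        }
    )


def profile_from_table(df: pd.DataFrame) -> FreeEnergyProfile:
    """Inverse of :func:`profile_to_table`."""
    return FreeEnergyProfile(
        [
            Level(str(r["label"]), str(r["kind"]), float(r["cumulative_dG"]))
            for _, r in df.iterrows()
        ]
    )


def steps_from_energetics(
    rows: Iterable[tuple[str, float, float]], ts_labels: Iterable[str] | None = None
) -> list[ElementaryStep]:
    """Build steps from (name, dG_TS, dG_step) triples, with optional TS labels."""
    rows = list(rows)
    labels: list[str | None]
    labels = list(ts_labels) if ts_labels is not None else [None] * len(rows)
    if len(labels) != len(rows):
        raise ValueError("ts_labels must match rows in length")
    return [
        ElementaryStep(name=n, dG_TS=a, dG_step=r, ts_label=t)
        for (n, a, r), t in zip(rows, labels)
    ]
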