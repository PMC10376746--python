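"""Segment-length-ratio post-exploration.

The balance simulation suggests that the trunk/leg proportion (which sets
the whole-body COG height) and the relative arm length (which sets the
wrist-angle geometry) jointly determine how hard the Planche is for a body
type.  This module computes the candidate coach-friendly indicators — the
trunk/arm (TL/AL), trunk/leg (TL/LL) and arm/leg (AL/LL) length ratios and
the difference TL/AL − TL/LL — per body type, summarizes them as mean ± SD
over the 20 body types of each race–gender group, and ranks the groups by
the mean difference.

Ratios are reported in percent.  TL = L2 + L3; LL = L4 + L5 (the foot is
excluded by default — "leg length" conventionally ends at the ankle — but can
be included); AL is L7 + L8 either with or without the hand, since the arm
chain admits both definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .anthropometry import (
    AnthropometryProvider,
    BodyType,
    Gender,
    ProviderConfig,
    Race,
    SegmentTable,
    as_provider,
)
from .statics import DegenerateGeometryError

__all__ = [
    "ARM_DEFINITIONS",
    "LengthRatios",
    "RatioSummary",
    "length_ratios",
    "summarize_group",
    "summarize_grid",
    "ranking_from_diff",
    "summaries_to_frame",
]

ARM_DEFINITIONS = ("without_hand", "with_hand")


@dataclass(frozen=True)
class LengthRatios:
    """Length ratios of one body, in percent."""

    tl_al: float
    tl_ll: float
    al_ll: float
    diff: float  # tl_al − tl_ll


@dataclass(frozen=True)
class RatioSummary:
    """Mean ± SD of the length ratios over one race–gender group."""

    race: Race
    gender: Gender
    n: int
    tl_al_mean: float
    tl_al_sd: float
    tl_ll_mean: float
    tl_ll_sd: float
    al_ll_mean: float
    al_ll_sd: float
    diff_mean: float
    diff_sd: float

    @property
    def group_name(self) -> str:
        return f"{self.race.value}-{self.gender.value}"


def length_ratios(
    table: SegmentTable,
    arm_definition: str = "without_hand",
    leg_includes_foot: bool = False,
) -> LengthRatios:
    """TL/AL, TL/LL, AL/LL (percent) and the difference TL/AL − TL/LL."""
    if arm_definition not in ARM_DEFINITIONS:
        raise ValueError(f"arm_definition must be one of {ARM_DEFINITIONS}, got {arm_definition!r}")
    tl = table.length(2) + table.length(3)
    ll = table.length(4) + table.length(5)
    if leg_includes_foot:
        ll += table.length(6)
    al = table.arm_reach_m
    if arm_definition == "with_hand":
        al += table.hand_length_m
    if al <= 0 or ll <= 0:
        raise DegenerateGeometryError("arm and leg lengths must be positive for ratios")
    tl_al = 100.0 * tl / al
    tl_ll = 100.0 * tl / ll
    return LengthRatios(
        tl_al=tl_al,
        tl_ll=tl_ll,
        al_ll=100.0 * al / ll,
        diff=tl_al - tl_ll,
    )


def summarize_group(
    bodies: Sequence[BodyType],
    provider: Union[AnthropometryProvider, ProviderConfig, None] = None,
    arm_definition: str = "without_hand",
    leg_includes_foot: bool = False,
    ddof: int = 1,
) -> RatioSummary:
    """Body-wise ratios, then mean and SD per ratio over one group.

    ``ddof=1`` gives the sample SD (the default); ``ddof=0`` the population
    SD.  All bodies must belong to the same race–gender group.
    """
    if not bodies:
        raise ValueError("bodies must be non-empty")
    groups = {body.group for body in bodies}
    if len(groups) > 1:
        raise ValueError(f"bodies span multiple race-gender groups: {sorted(g[0].value + '-' + g[1].value for g in groups)}")
    prov = as_provider(provider)
    ratios = [
        length_ratios(prov.segment_table(b), arm_definition, leg_includes_foot) for b in bodies
    ]
    n = len(ratios)

    def _stats(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values)
        sd = float(arr.std(ddof=ddof)) if n > ddof else 0.0
        return float(arr.mean()), sd

    race, gender = bodies[0].group
    tl_al = _stats([r.tl_al for r in ratios])
    tl_ll = _stats([r.tl_ll for r in ratios])
    al_ll = _stats([r.al_ll for r in ratios])
    diff = _stats([r.diff for r in ratios])
    return RatioSummary(
        race=race,
        gender=gender,
        n=n,
        tl_al_mean=tl_al[0],
        tl_al_sd=tl_al[1],
        tl_ll_mean=tl_ll[0],
        tl_ll_sd=tl_ll[1],
        al_ll_mean=al_ll[0],
        al_ll_sd=al_ll[1],
        diff_mean=diff[0],
        diff_sd=diff[1],
    )


def summarize_grid(
    bodies: Iterable[BodyType],
    provider: Union[AnthropometryProvider, ProviderConfig, None] = None,
    arm_definition: str = "without_hand",
    leg_includes_foot: bool = False,
    ddof: int = 1,
) -> list[RatioSummary]:
    """Group the bodies by (race, gender) and summarize each group."""
    by_group: dict[tuple[Race, Gender], list[BodyType]] = {}
    for body in bodies:
        by_group.setdefault(body.group, []).append(body)
    return [
        summarize_group(members, provider, arm_definition, leg_includes_foot, ddof)
        for members in by_group.values()
    ]


def ranking_from_diff(summaries: Sequence[RatioSummary]) -> list[RatioSummary]:
    """Order groups by mean TL/AL − TL/LL, descending; ties break by name."""
    return sorted(summaries, key=lambda s: (-s.diff_mean, s.group_name))


def summaries_to_frame(summaries: Sequence[RatioSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "race": s.race.value,
                "gender": s.gender.value,
                "n": s.n,
                "tl_al_mean": s.tl_al_mean,
                "tl_al_sd": s.tl_al_sd,
                "tl_ll_mean": s.tl_ll_mean,
                "tl_ll_sd": s.tl_ll_sd,
                "al_ll_mean": s.al_ll_mean,
                "al_ll_sd": s.al_ll_sd,
                "diff_mean": s.diff_mean,
                "diff_sd": s.diff_sd,
            }
            for s in summaries
        ]
    )
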