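"""Body-type grid construction, β-sweep simulation, difficulty ranking.

The study design crosses five body-mass classes with four body-height groups
per gender (the common 12–20-year-old range of the Chinese and German norms)
and applies them to the four race–gender groups, giving 80 body types.  Each
body type is swept over the competition-legal body angle range β ∈ [0°, 20°]
(the FIG caps the body line at 20° above parallel); at each β the static
balance is solved and the wrist angle α recorded.  Smaller α means a harder
balance, so body types are ranked by α at a reference β, and body types with
no feasible β anywhere are flagged "Planche impossible".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .anthropometry import (
    GROUPS,
    AnthropometryProvider,
    BodyType,
    Gender,
    ProviderConfig,
    Race,
    as_provider,
)
from .statics import solve_equilibrium

__all__ = [
    "GridSpec",
    "BetaRecord",
    "SweepResult",
    "RankEntry",
    "DEFAULT_BETA_GRID",
    "OLYMPIC_REFERENCE_MALE",
    "OLYMPIC_REFERENCE_FEMALE",
    "build_grid",
    "sweep_beta",
    "sweep_grid",
    "results_to_frame",
    "rank_body_types",
    "ranking_to_frame",
    "compare_reference_athletes",
    "plot_alpha_curves",
    "load_grid_spec",
]

logger = logging.getLogger(__name__)

#: β sampled every degree over the FIG-legal range (the range is prescribed,
#: the 1° step is this package's default).
DEFAULT_BETA_GRID: np.ndarray = np.arange(0.0, 21.0, 1.0)

#: Olympic-average body types used in the race comparison: (height m, mass kg).
OLYMPIC_REFERENCE_MALE: tuple[float, float] = (1.66, 63.0)
OLYMPIC_REFERENCE_FEMALE: tuple[float, float] = (1.53, 48.0)

_DEFAULT_WEIGHTS: dict[Gender, tuple[float, ...]] = {
    Gender.MALE: (44.0, 54.0, 63.0, 73.0, 83.0),
    Gender.FEMALE: (39.0, 48.0, 56.0, 65.0, 74.0),
}
_DEFAULT_HEIGHTS: dict[Gender, tuple[float, ...]] = {
    Gender.MALE: (1.57, 1.66, 1.74, 1.82),
    Gender.FEMALE: (1.45, 1.53, 1.62, 1.70),
}


@dataclass(frozen=True)
class GridSpec:
    """Weight classes and height groups per gender, and the groups to cross."""

    weights: Mapping[Gender, Sequence[float]] = field(
        default_factory=lambda: {g: list(v) for g, v in _DEFAULT_WEIGHTS.items()}
    )
    heights: Mapping[Gender, Sequence[float]] = field(
        default_factory=lambda: {g: list(v) for g, v in _DEFAULT_HEIGHTS.items()}
    )
    groups: Sequence[tuple[Race, Gender]] = GROUPS

    def __post_init__(self):
        for race, gender in self.groups:
            if not self.weights.get(gender):
                raise ValueError(f"grid spec has no weight classes for {gender.value}")
            if not self.heights.get(gender):
                raise ValueError(f"grid spec has no height groups for {gender.value}")


def build_grid(spec: GridSpec | None = None) -> list[BodyType]:
    """Cartesian product weights × heights within each race–gender group.

    The default spec yields 4 groups × 5 weights × 4 heights = 80 body types.
    """
    spec = spec or GridSpec()
    bodies: list[BodyType] = []
    for race, gender in spec.groups:
        for mass in spec.weights[gender]:
            for height in spec.heights[gender]:
                bodies.append(
                    BodyType(race=race, gender=gender, mass_kg=float(mass), height_m=float(height))
                )
    return bodies


def load_grid_spec(path: Union[str, Path]) -> GridSpec:
    """Read a GridSpec from YAML ({weights: {male: [...], ...}, heights: ...})."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    weights = {
        Gender(k): [float(v) for v in vals]
        for k, vals in (raw.get("weights") or _DEFAULT_WEIGHTS).items()
    }
    heights = {
        Gender(k): [float(v) for v in vals]
        for k, vals in (raw.get("heights") or _DEFAULT_HEIGHTS).items()
    }
    groups = tuple(
        (Race(r), Gender(g))
        for r, g in (raw.get("groups") or [(r.value, g.value) for r, g in GROUPS])
    )
    return GridSpec(weights=weights, heights=heights, groups=groups)


@dataclass(frozen=True)
class BetaRecord:
    """The balance solution at one β grid point."""

    beta_deg: float
    feasible: bool
    x_m: float
    alpha_deg: float | None


@dataclass(frozen=True)
class SweepResult:
    """α(β) records for one body type over the β grid."""

    body: BodyType
    records: tuple[BetaRecord, ...]

    @property
    def planche_impossible(self) -> bool:
        """True when no β in the grid admits a feasible balance."""
        return not any(r.feasible for r in self.records)

    @property
    def feasible_alphas(self) -> list[float]:
        return [r.alpha_deg for r in self.records if r.feasible]

    @property
    def alpha_min(self) -> float | None:
        alphas = self.feasible_alphas
        return min(alphas) if alphas else None

    @property
    def alpha_max(self) -> float | None:
        alphas = self.feasible_alphas
        return max(alphas) if alphas else None

    def record_at(self, beta_deg: float) -> BetaRecord:
        for rec in self.records:
            if abs(rec.beta_deg - beta_deg) <= 1e-9:
                return rec
        raise KeyError(f"beta = {beta_deg} deg is not in the sweep grid of {self.body.label}")


def _validate_beta_grid(beta_grid) -> np.ndarray:
    grid = np.asarray(DEFAULT_BETA_GRID if beta_grid is None else beta_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("beta grid must be a non-empty 1-D sequence of degrees")
    if np.any(grid < 0) or np.any(grid > 20):
        raise ValueError("beta grid must lie within the FIG-legal range [0, 20] degrees")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("beta grid must be strictly increasing")
    return grid


def sweep_beta(
    body: BodyType,
    provider: Union[AnthropometryProvider, ProviderConfig, None] = None,
    beta_grid=None,
) -> SweepResult:
    """Solve the balance for one body type at every β grid point."""
    grid = _validate_beta_grid(beta_grid)
    prov = as_provider(provider)
    try:
        table = prov.segment_table(body)
        records = []
        for beta in grid:
            sol = solve_equilibrium(table, float(beta))
            records.append(
                BetaRecord(
                    beta_deg=float(beta),
                    feasible=sol.feasible,
                    x_m=sol.x_m,
                    alpha_deg=sol.alpha_deg,
                )
            )
    except Exception as exc:
        raise type(exc)(f"{body.label}: {exc}") from exc
    result = SweepResult(body=body, records=tuple(records))
    if result.planche_impossible:
        logger.warning("%s: Planche impossible (no feasible beta in the grid)", body.label)
    return result


def sweep_grid(
    bodies: Iterable[BodyType],
    provider: Union[AnthropometryProvider, ProviderConfig, None] = None,
    beta_grid=None,
) -> list[SweepResult]:
    """Sweep every body type; logs per-body progress."""
    prov = as_provider(provider)
    results = []
    for body in bodies:
        logger.info("simulating %s", body.label)
        results.append(sweep_beta(body, prov, beta_grid))
    return results


def results_to_frame(results: Iterable[SweepResult]) -> pd.DataFrame:
    """Long-format table: one row per (body type, β) grid point."""
    rows = []
    for res in results:
        for rec in res.records:
            rows.append(
                {
                    "race": res.body.race.value,
                    "gender": res.body.gender.value,
                    "mass_kg": res.body.mass_kg,
                    "height_m": res.body.height_m,
                    "beta_deg": rec.beta_deg,
                    "feasible": rec.feasible,
                    "x_m": rec.x_m,
                    "alpha_deg": rec.alpha_deg if rec.feasible else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RankEntry:
    """One body type's difficulty rank at the reference β."""

    rank: int
    body: BodyType
    feasible_at_ref: bool
    alpha_deg: float | None
    planche_impossible: bool


def rank_body_types(results: Sequence[SweepResult], beta_ref: float = 0.0) -> list[RankEntry]:
    """Rank body types by α at ``beta_ref``, descending (largest α = easiest).

    Bodies infeasible at the reference β rank after all feasible ones;
    bodies with no feasible β anywhere are additionally flagged.  Ties are
    broken by the body identifier so the ordering is deterministic.
    """
    keyed = []
    for res in results:
        rec = res.record_at(beta_ref)  # raises KeyError if beta_ref missing
        alpha = rec.alpha_deg if rec.feasible else None
        sort_key = (
            0 if rec.feasible else 1,
            -(alpha if alpha is not None else 0.0),
            res.body.label,
        )
        keyed.append((sort_key, res, rec))
    keyed.sort(key=lambda item: item[0])
    return [
        RankEntry(
            rank=i + 1,
            body=res.body,
            feasible_at_ref=rec.feasible,
            alpha_deg=rec.alpha_deg if rec.feasible else None,
            planche_impossible=res.planche_impossible,
        )
        for i, (_, res, rec) in enumerate(keyed)
    ]


def ranking_to_frame(ranking: Sequence[RankEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [e.rank for e in ranking],
            "race": [e.body.race.value for e in ranking],
            "gender": [e.body.gender.value for e in ranking],
            "mass_kg": [e.body.mass_kg for e in ranking],
            "height_m": [e.body.height_m for e in ranking],
            "feasible_at_ref": [e.feasible_at_ref for e in ranking],
            "alpha_deg": [e.alpha_deg for e in ranking],
            "planche_impossible": [e.planche_impossible for e in ranking],
        }
    )


def compare_reference_athletes(
    provider: Union[AnthropometryProvider, ProviderConfig, None] = None,
    beta_grid=None,
) -> dict[str, SweepResult]:
    """α(β) curves for the Olympic-average gymnast in each race–gender group.

    Both races share the gender-matched reference body — male (1.66 m, 63 kg),
    female (1.53 m, 48 kg) — so any difference between the four curves is
    purely the race–gender difference in segment proportions.
    """
    refs = {
        Gender.MALE: OLYMPIC_REFERENCE_MALE,
        Gender.FEMALE: OLYMPIC_REFERENCE_FEMALE,
    }
    curves: dict[str, SweepResult] = {}
    for race, gender in GROUPS:
        height, mass = refs[gender]
        body = BodyType(race=race, gender=gender, mass_kg=mass, height_m=height)
        curves[f"{race.value}-{gender.value}"] = sweep_beta(body, provider, beta_grid)
    return curves


def plot_alpha_curves(
    results: Sequence[SweepResult],
    path: Union[str, Path, None] = None,
    title: str | None = None,
):
    """Plot α(β) curves (one line per body type); optionally save to ``path``."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for res in results:
        betas = [r.beta_deg for r in res.records if r.feasible]
        alphas = [r.alpha_deg for r in res.records if r.feasible]
        if betas:
            ax.plot(betas, alphas, marker="o", ms=2.5, lw=1, label=res.body.label)
    ax.set_xlabel("body angle β (deg)")
    ax.set_ylabel("wrist angle α (deg)")
    if title:
        ax.set_title(title)
    if len(results) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
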