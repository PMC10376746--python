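"""Synthetic anthropometry with known ground truth.

The published group-mean proportions behind the default provider come from
regression equations (segment properties linear in body mass and body
height, with race- and gender-specific coefficients) that were never printed.
This module emulates that statistical structure so every pipeline stage can
be tested end-to-end without external data: relative chain lengths are

    fraction(group, chain) = base + offset(group, chain)
                             + bh_slope(chain) · (BH − BH₀)
                             + bm_slope(chain) · (BM − BM₀)
                             + ε,   ε ~ N(0, noise_sd²),

clipped to (0, 1).  Noise is applied to *proportions*, not absolute lengths,
so the scale invariance of the wrist angle α is preserved.  Every generated
dataset carries a ground-truth record of the injected offsets, slopes and
group orderings, so recovery tests never re-derive what was injected.

The per-body noise draw is keyed on (seed, group, BM, BH): the same seed
always reproduces the same dataset, independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anthropometry import (
    DEFAULT_RELATIVE_LENGTHS,
    DEFAULT_SPLITS,
    GROUPS,
    STANDARD_GRAVITY,
    BodyType,
    Gender,
    ProviderConfig,
    Race,
    SegmentTable,
    make_segment_table,
)
from .statics import solve_equilibrium

__all__ = [
    "CHAINS",
    "SyntheticSpec",
    "SyntheticProvider",
    "SyntheticDataset",
    "ToyBody",
    "generate_provider",
    "generate_toy_bodies",
]

CHAINS = ("trunk", "legs", "arms")

_FRACTION_EPS = 1e-6  # open-interval clip bound for generated fractions


def _zero_offsets() -> dict[tuple[Race, Gender], dict[str, float]]:
    return {group: {chain: 0.0 for chain in CHAINS} for group in GROUPS}


def _zero_slopes() -> dict[str, float]:
    return {chain: 0.0 for chain in CHAINS}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic anthropometry model.

    ``group_length_offsets`` are additive shifts (fraction of BH) on each
    group's base chain proportions; ``bh_slope``/``bm_slope`` make the
    proportions linear in BH (per metre) and BM (per kilogram), centred at
    the reference body; ``noise_sd`` is the Gaussian SD on each generated
    fraction; ``n_bodies`` is the number of reference-body fraction samples
    drawn per group into the dataset's sample table.
    """

    seed: int = 0
    group_length_offsets: Mapping[tuple[Race, Gender], Mapping[str, float]] = field(
        default_factory=_zero_offsets
    )
    bh_slope: Mapping[str, float] = field(default_factory=_zero_slopes)
    bm_slope: Mapping[str, float] = field(default_factory=_zero_slopes)
    noise_sd: float = 0.0
    n_bodies: int = 0
    reference_height_m: float = 1.60
    reference_mass_kg: float = 60.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_bodies < 0:
            raise ValueError("n_bodies must be non-negative")

    def offset(self, group: tuple[Race, Gender], chain: str) -> float:
        return float(self.group_length_offsets.get(group, {}).get(chain, 0.0))

    def noiseless(self) -> "SyntheticSpec":
        return replace(self, noise_sd=0.0)


_GROUP_INDEX = {group: i for i, group in enumerate(GROUPS)}


@dataclass(frozen=True)
class SyntheticProvider:
    """Anthropometry provider drawing from the synthetic linear model."""

    spec: SyntheticSpec
    name: str = "synthetic"

    def _body_rng(self, body: BodyType) -> np.random.Generator:
        # Keyed, order-independent stream: same (seed, body) => same draw.
        return np.random.default_rng(
            [
                int(self.spec.seed),
                _GROUP_INDEX[body.group],
                int(round(body.height_m * 1e6)),
                int(round(body.mass_kg * 1e6)),
            ]
        )

    def relative_lengths(self, body: BodyType) -> dict[str, float]:
        """Noise-free-or-noisy chain fractions of BH for this body."""
        spec = self.spec
        base = DEFAULT_RELATIVE_LENGTHS[body.group]
        dbh = body.height_m - spec.reference_height_m
        dbm = body.mass_kg - spec.reference_mass_kg
        noise = (
            self._body_rng(body).normal(0.0, spec.noise_sd, size=len(CHAINS))
            if spec.noise_sd > 0
            else np.zeros(len(CHAINS))
        )
        fractions = {}
        for k, chain in enumerate(CHAINS):
            value = (
                base[chain]
                + spec.offset(body.group, chain)
                + float(spec.bh_slope.get(chain, 0.0)) * dbh
                + float(spec.bm_slope.get(chain, 0.0)) * dbm
                + float(noise[k])
            )
            fractions[chain] = float(np.clip(value, _FRACTION_EPS, 1.0 - _FRACTION_EPS))
        return fractions

    def segment_table(self, body: BodyType) -> SegmentTable:
        cfg = ProviderConfig(
            relative_lengths={body.group: self.relative_lengths(body), **{
                g: dict(DEFAULT_RELATIVE_LENGTHS[g]) for g in GROUPS if g != body.group
            }},
        )
        return make_segment_table(body, cfg)

    def noiseless(self) -> "SyntheticProvider":
        return SyntheticProvider(spec=self.spec.noiseless(), name=f"{self.name}-noiseless")


def _noise_free_diff(provider: SyntheticProvider, bodies: Sequence[BodyType]) -> float:
    """Mean TL/AL − TL/LL (percent) over bodies, from the injected fractions.

    Plain arithmetic on the injected proportions (arm = shoulder-to-wrist
    share of the arm chain, leg = thigh + shank), kept separate from the
    ratios module so ground truth does not depend on the code under test.
    """
    arm_share = DEFAULT_SPLITS["upper_arm_of_arms"] + DEFAULT_SPLITS["lower_arm_of_arms"]
    noiseless = provider.noiseless()
    diffs = []
    for body in bodies:
        frac = noiseless.relative_lengths(body)
        t, l, a = frac["trunk"], frac["legs"], frac["arms"] * arm_share
        diffs.append(100.0 * (t / a - t / l))
    return float(np.mean(diffs))


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated provider plus its ground truth and sample table."""

    spec: SyntheticSpec
    provider: SyntheticProvider
    ground_truth: dict
    provider_config: ProviderConfig
    samples: pd.DataFrame | None = None


def generate_provider(spec: SyntheticSpec) -> SyntheticDataset:
    """Build a synthetic provider and record what was injected.

    The ground truth holds the injected offsets and slopes, the noise-free
    chain proportions of each group at the reference body, and the group
    ordering by mean TL/AL − TL/LL over the default 20-body grids (the
    ordering the ratio post-exploration should recover).  ``provider_config``
    is the noise-free, slope-free configuration at the reference body, usable
    with the static table provider and serializable to YAML.
    """
    from .simulation import GridSpec, build_grid  # deferred: avoids cycle at import

    provider = SyntheticProvider(spec=spec)
    noiseless = provider.noiseless()
    reference = {
        group: noiseless.relative_lengths(
            BodyType(
                race=group[0],
                gender=group[1],
                mass_kg=spec.reference_mass_kg,
                height_m=spec.reference_height_m,
            )
        )
        for group in GROUPS
    }
    grid = build_grid(GridSpec())
    by_group: dict[tuple[Race, Gender], list[BodyType]] = {}
    for body in grid:
        by_group.setdefault(body.group, []).append(body)
    group_diffs = {group: _noise_free_diff(provider, members) for group, members in by_group.items()}
    diff_order = sorted(
        group_diffs, key=lambda g: (-group_diffs[g], f"{g[0].value}-{g[1].value}")
    )
    ground_truth = {
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "offsets": {
            f"{r.value}-{g.value}": {c: spec.offset((r, g), c) for c in CHAINS}
            for r, g in GROUPS
        },
        "bh_slope": {c: float(spec.bh_slope.get(c, 0.0)) for c in CHAINS},
        "bm_slope": {c: float(spec.bm_slope.get(c, 0.0)) for c in CHAINS},
        "reference_proportions": {
            f"{r.value}-{g.value}": reference[(r, g)] for r, g in GROUPS
        },
        "group_diffs": {f"{r.value}-{g.value}": group_diffs[(r, g)] for r, g in GROUPS},
        "group_diff_order": [f"{r.value}-{g.value}" for r, g in diff_order],
    }
    config = ProviderConfig(relative_lengths=reference)

    samples = None
    if spec.n_bodies > 0:
        rows = []
        for gi, group in enumerate(GROUPS):
            rng = np.random.default_rng([int(spec.seed), 1000 + gi])
            base = reference[group]
            for draw in range(spec.n_bodies):
                noise = rng.normal(0.0, spec.noise_sd, size=len(CHAINS))
                row = {
                    "race": group[0].value,
                    "gender": group[1].value,
                    "draw": draw,
                }
                for k, chain in enumerate(CHAINS):
                    row[chain] = float(
                        np.clip(base[chain] + noise[k], _FRACTION_EPS, 1 - _FRACTION_EPS)
                    )
                rows.append(row)
        samples = pd.DataFrame(rows)

    return SyntheticDataset(
        spec=spec,
        provider=provider,
        ground_truth=ground_truth,
        provider_config=config,
        samples=samples,
    )


@dataclass(frozen=True)
class ToyBody:
    """A random valid segment table with its known balance solution at β = 0."""

    table: SegmentTable
    known_x_m: float
    known_alpha_deg: float
    beta_deg: float = 0.0


def generate_toy_bodies(seed: int, n: int, symmetric: bool = False) -> list[ToyBody]:
    """Random valid segment tables paired with their balance solution.

    With ``symmetric=True`` each toy is built so the head exactly
    counterweights the trunk (the net COG offset N vanishes), giving the
    known solution x = 0, α = 90°.  Otherwise tables are drawn uniformly
    (lengths 0.08–0.5 m, masses 0.5–12 kg, COGs 10–90 % along the segment)
    and resampled until the balance is feasible, so α is always defined.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    toys: list[ToyBody] = []
    while len(toys) < n:
        lengths = rng.uniform(0.08, 0.5, size=8)
        cog_fracs = rng.uniform(0.1, 0.9, size=8)
        cogs = lengths * cog_fracs
        if symmetric:
            # Only head (1) and upper trunk (2) carry mass, tuned so
            # −(L1−D1)·m1 + D2·m2 = 0 exactly.
            m1 = rng.uniform(1.0, 8.0)
            m2 = m1 * (lengths[0] - cogs[0]) / cogs[1]
            masses = np.zeros(8)
            masses[0], masses[1] = m1, m2
        else:
            masses = rng.uniform(0.5, 12.0, size=8)
        table = SegmentTable(
            masses_kg=masses,
            lengths_m=lengths,
            cogs_m=cogs,
            hand_length_m=float(rng.uniform(0.05, 0.2)),
            g=STANDARD_GRAVITY,
        )
        sol = solve_equilibrium(table, beta_deg=0.0)
        if not sol.feasible:
            continue
        toys.append(ToyBody(table=table, known_x_m=sol.x_m, known_alpha_deg=sol.alpha_deg))
    return toys
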