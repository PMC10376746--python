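"""Anthropometric scaling: turn a body type into per-segment parameters.

The planar Planche model treats the athlete as eight torque-bearing rigid
segments (head, upper trunk, lower trunk, thighs, shanks, feet, upper arms,
lower arms) plus massless hands acting as the support.  This module converts
a :class:`BodyType` (body mass BM, body height BH, gender, race) into a
:class:`SegmentTable` — the masses ``m_i``, lengths ``L_i`` and
centre-of-gravity locations ``D_i`` the statics module consumes.

The default provider scales whole-chain lengths (trunk, legs, arms) as fixed
race- and gender-specific fractions of BH taken from published group means,
splits each chain into its sub-segments with configurable fractions, assigns
segment masses as fractions of BM, and places each segment COG at a
configurable fraction of the segment length (midpoint by default).  Every
fraction is overridable through :class:`ProviderConfig`, so a user holding a
full anthropometric regression set can reproduce it exactly; the shipped
defaults are a documented approximation, not ground truth.

Units are fixed at kilograms, metres and degrees at every interface.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Protocol, Union, runtime_checkable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Gender",
    "Race",
    "GROUPS",
    "SEGMENT_NAMES",
    "BodyType",
    "SegmentTable",
    "ProviderConfig",
    "ConfigurationError",
    "AnthropometryProvider",
    "TableProvider",
    "as_provider",
    "default_config",
    "make_segment_table",
    "load_provider_config",
    "save_provider_config",
    "DEFAULT_RELATIVE_LENGTHS",
    "DEFAULT_SPLITS",
    "DEFAULT_MASS_FRACTIONS",
    "DEFAULT_COG_FRACTIONS",
    "STANDARD_GRAVITY",
]

STANDARD_GRAVITY = 9.81  # m/s^2


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Race(str, enum.Enum):
    ASIAN = "asian"
    EUROPEAN = "european"


#: The four race–gender groups the model distinguishes.
GROUPS: tuple[tuple[Race, Gender], ...] = (
    (Race.ASIAN, Gender.MALE),
    (Race.ASIAN, Gender.FEMALE),
    (Race.EUROPEAN, Gender.MALE),
    (Race.EUROPEAN, Gender.FEMALE),
)

#: Torque-bearing segments, indexed 1..8 in the model equations.
SEGMENT_NAMES: tuple[str, ...] = (
    "head",
    "upper_trunk",
    "lower_trunk",
    "thighs",
    "shanks",
    "feet",
    "upper_arms",
    "lower_arms",
)

# Relative whole-chain lengths as fractions of body height, by (race, gender).
# Group means for young Chinese and German adults; the race–gender ordering
# (European legs longer / trunks shorter than Asian at equal BH) is the
# anthropometric signal the whole analysis rests on.
DEFAULT_RELATIVE_LENGTHS: dict[tuple[Race, Gender], dict[str, float]] = {
    (Race.ASIAN, Gender.MALE): {"trunk": 0.3953, "legs": 0.4815, "arms": 0.4046},
    (Race.ASIAN, Gender.FEMALE): {"trunk": 0.4019, "legs": 0.4729, "arms": 0.3921},
    (Race.EUROPEAN, Gender.MALE): {"trunk": 0.3792, "legs": 0.4983, "arms": 0.4143},
    (Race.EUROPEAN, Gender.FEMALE): {"trunk": 0.3854, "legs": 0.4901, "arms": 0.4151},
}

# Sub-segment length splits.  The trunk splits into upper/lower halves, the
# legs into thigh/shank, the arm chain (shoulder to fingertip) into upper arm,
# lower arm and hand.  Head and foot lengths scale directly with BH.  Values
# follow the classical proportion tables of the BSP literature (Drillis &
# Contini style); they are configuration, not ground truth.
DEFAULT_SPLITS: dict[str, float] = {
    "upper_trunk_of_trunk": 0.50,
    "lower_trunk_of_trunk": 0.50,
    "thigh_of_legs": 0.53,
    "shank_of_legs": 0.47,
    "upper_arm_of_arms": 0.425,
    "lower_arm_of_arms": 0.330,
    "hand_of_arms": 0.245,
    "head_of_bh": 0.130,
    "foot_of_bh": 0.152,
}

# Segment masses as fractions of BM (Dempster-style cadaver fractions with
# limbs merged left+right; the 0.497 trunk mass split upper/lower ≈ 55/45,
# thorax heavier than pelvis, per the de Leva adjustments).  The hand mass
# (~1.2% BM) is deliberately unassigned: the hands are the massless support
# in the statics model, so the eight fractions sum to 0.988 < 1.
DEFAULT_MASS_FRACTIONS: dict[str, float] = {
    "head": 0.081,
    "upper_trunk": 0.274,
    "lower_trunk": 0.223,
    "thighs": 0.200,
    "shanks": 0.093,
    "feet": 0.029,
    "upper_arms": 0.056,
    "lower_arms": 0.032,
}

# COG location as a fraction of segment length, in the convention each torque
# equation uses (head distal-referenced, trunk proximal, legs distal via the
# cumulative-length-minus-D form, arms per the lever-ratio forms).  Midpoint
# COGs (0.5) are the neutral default, under which the conventions coincide.
DEFAULT_COG_FRACTIONS: dict[str, float] = {name: 0.5 for name in SEGMENT_NAMES}


class ConfigurationError(ValueError):
    """A provider configuration violates an invariant; names the field."""


def _coerce_gender(value) -> Gender:
    return value if isinstance(value, Gender) else Gender(str(value).lower())


def _coerce_race(value) -> Race:
    return value if isinstance(value, Race) else Race(str(value).lower())


@dataclass(frozen=True, order=True)
class BodyType:
    """One subject definition: body mass, body height, gender and race."""

    race: Race
    gender: Gender
    mass_kg: float
    height_m: float

    def __post_init__(self):
        object.__setattr__(self, "race", _coerce_race(self.race))
        object.__setattr__(self, "gender", _coerce_gender(self.gender))
        if not self.mass_kg > 0:
            raise ValueError(f"mass_kg must be positive, got {self.mass_kg}")
        if not self.height_m > 0:
            raise ValueError(f"height_m must be positive, got {self.height_m}")

    @property
    def group(self) -> tuple[Race, Gender]:
        return (self.race, self.gender)

    @property
    def label(self) -> str:
        return (
            f"{self.race.value}-{self.gender.value}-"
            f"{self.mass_kg:g}kg-{self.height_m:g}m"
        )


@dataclass(frozen=True)
class SegmentTable:
    """Per-segment mass, length and COG location for segments 1–8.

    Arrays are ordered as :data:`SEGMENT_NAMES` (index 0 = segment 1 = head).
    ``hand_length_m`` is metadata only: the hand is the ninth segment of the
    body model but bears no torque.
    """

    masses_kg: np.ndarray
    lengths_m: np.ndarray
    cogs_m: np.ndarray
    hand_length_m: float = 0.0
    g: float = STANDARD_GRAVITY

    def __post_init__(self):
        for name in ("masses_kg", "lengths_m", "cogs_m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (8,):
                raise ValueError(f"{name} must have shape (8,), got {arr.shape}")
            object.__setattr__(self, name, arr)
        if np.any(self.masses_kg < 0):
            raise ValueError("segment masses must be non-negative")
        if np.any(self.lengths_m <= 0):
            raise ValueError("segment lengths must be positive")
        if np.any(self.cogs_m < 0) or np.any(self.cogs_m > self.lengths_m):
            raise ValueError("each COG location D_i must satisfy 0 <= D_i <= L_i")
        if self.hand_length_m < 0:
            raise ValueError("hand_length_m must be non-negative")
        if not self.g > 0:
            raise ValueError("g must be positive")

    # 1-based accessors matching the model's segment numbering.
    def mass(self, i: int) -> float:
        return float(self.masses_kg[i - 1])

    def length(self, i: int) -> float:
        return float(self.lengths_m[i - 1])

    def cog(self, i: int) -> float:
        return float(self.cogs_m[i - 1])

    @property
    def total_mass_kg(self) -> float:
        return float(self.masses_kg.sum())

    @property
    def arm_reach_m(self) -> float:
        """Shoulder-to-wrist length L7 + L8 — the feasibility radius."""
        return float(self.lengths_m[6] + self.lengths_m[7])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_index": np.arange(1, 9),
                "name": SEGMENT_NAMES,
                "mass_kg": self.masses_kg,
                "length_m": self.lengths_m,
                "cog_m": self.cogs_m,
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_fraction(value: float, path: str, *, closed_low=False) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ConfigurationError(f"{path}: expected a number, got {value!r}")
    low_ok = value >= 0 if closed_low else value > 0
    if not (low_ok and value <= 1):
        bound = "[0, 1]" if closed_low else "(0, 1]"
        raise ConfigurationError(f"{path}: fraction {value} outside {bound}")
    return value


@dataclass(frozen=True)
class ProviderConfig:
    """All fractions of the default anthropometry provider.

    ``relative_lengths`` maps each (race, gender) group to whole-chain
    lengths {trunk, legs, arms} as fractions of BH; ``splits`` divides each
    chain into sub-segments (and sets head/foot length as fractions of BH);
    ``mass_fractions`` are per-segment fractions of BM; ``cog_fractions``
    place each D_i as a fraction of L_i.
    """

    relative_lengths: Mapping[tuple[Race, Gender], Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_RELATIVE_LENGTHS.items()}
    )
    splits: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SPLITS))
    mass_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MASS_FRACTIONS)
    )
    cog_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COG_FRACTIONS)
    )
    g: float = STANDARD_GRAVITY

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for group in GROUPS:
            if group not in self.relative_lengths:
                raise ConfigurationError(
                    f"relative_lengths: missing group {group[0].value}_{group[1].value}"
                )
            for chain in ("trunk", "legs", "arms"):
                if chain not in self.relative_lengths[group]:
                    raise ConfigurationError(
                        f"relative_lengths.{group[0].value}_{group[1].value}: "
                        f"missing chain '{chain}'"
                    )
                _validate_fraction(
                    self.relative_lengths[group][chain],
                    f"relative_lengths.{group[0].value}_{group[1].value}.{chain}",
                )
        for key in DEFAULT_SPLITS:
            if key not in self.splits:
                raise ConfigurationError(f"splits: missing '{key}'")
            _validate_fraction(self.splits[key], f"splits.{key}")
        for pair, total_of in (
            (("upper_trunk_of_trunk", "lower_trunk_of_trunk"), "trunk"),
            (("thigh_of_legs", "shank_of_legs"), "legs"),
            (("upper_arm_of_arms", "lower_arm_of_arms", "hand_of_arms"), "arms"),
        ):
            s = sum(self.splits[k] for k in pair)
            if abs(s - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"splits: {'+'.join(pair)} must sum to 1 (got {s:.6f}) "
                    f"so the {total_of} chain length is conserved"
                )
        total_mass = 0.0
        for name in SEGMENT_NAMES:
            if name not in self.mass_fractions:
                raise ConfigurationError(f"mass_fractions: missing segment '{name}'")
            total_mass += _validate_fraction(
                self.mass_fractions[name], f"mass_fractions.{name}", closed_low=True
            )
            if name not in self.cog_fractions:
                raise ConfigurationError(f"cog_fractions: missing segment '{name}'")
            _validate_fraction(
                self.cog_fractions[name], f"cog_fractions.{name}", closed_low=True
            )
        if total_mass > 1.0 + 1e-9:
            raise ConfigurationError(
                f"mass_fractions: sum {total_mass:.4f} exceeds 1 (more mass than BM)"
            )
        if not self.g > 0:
            raise ConfigurationError(f"g: must be positive, got {self.g}")

    def with_relative_lengths(
        self, relative_lengths: Mapping[tuple[Race, Gender], Mapping[str, float]]
    ) -> "ProviderConfig":
        return replace(self, relative_lengths={g: dict(v) for g, v in relative_lengths.items()})


def default_config() -> ProviderConfig:
    """The shipped default provider configuration."""
    return ProviderConfig()


def make_segment_table(body: BodyType, cfg: ProviderConfig | None = None) -> SegmentTable:
    """Scale a body type into the eight-segment parameter table.

    Whole-chain lengths come from the group's relative lengths × BH and are
    split into sub-segments; masses are BM × per-segment fractions; each COG
    sits at ``cog_fraction × L_i``.
    """
    if cfg is None:
        cfg = default_config()
    rel = cfg.relative_lengths[body.group]
    bh, bm = body.height_m, body.mass_kg
    trunk, legs, arms = rel["trunk"] * bh, rel["legs"] * bh, rel["arms"] * bh
    sp = cfg.splits
    lengths = np.array(
        [
            sp["head_of_bh"] * bh,
            sp["upper_trunk_of_trunk"] * trunk,
            sp["lower_trunk_of_trunk"] * trunk,
            sp["thigh_of_legs"] * legs,
            sp["shank_of_legs"] * legs,
            sp["foot_of_bh"] * bh,
            sp["upper_arm_of_arms"] * arms,
            sp["lower_arm_of_arms"] * arms,
        ]
    )
    masses = bm * np.array([cfg.mass_fractions[n] for n in SEGMENT_NAMES])
    cogs = lengths * np.array([cfg.cog_fractions[n] for n in SEGMENT_NAMES])
    return SegmentTable(
        masses_kg=masses,
        lengths_m=lengths,
        cogs_m=cogs,
        hand_length_m=sp["hand_of_arms"] * arms,
        g=cfg.g,
    )


@runtime_checkable
class AnthropometryProvider(Protocol):
    """Anything that can turn a BodyType into a SegmentTable."""

    def segment_table(self, body: BodyType) -> SegmentTable: ...


@dataclass(frozen=True)
class TableProvider:
    """Provider backed by a static :class:`ProviderConfig` (the default)."""

    config: ProviderConfig = field(default_factory=default_config)
    name: str = "default"

    def segment_table(self, body: BodyType) -> SegmentTable:
        return make_segment_table(body, self.config)


def as_provider(
    source: Union[AnthropometryProvider, ProviderConfig, None],
) -> AnthropometryProvider:
    """Normalize a ProviderConfig / provider / None into a provider object."""
    if source is None:
        return TableProvider()
    if isinstance(source, ProviderConfig):
        return TableProvider(source)
    if isinstance(source, AnthropometryProvider):
        return source
    raise TypeError(f"cannot interpret {type(source).__name__} as an anthropometry provider")


# -- config file I/O ---------------------------------------------------------

def _group_key(race: Race, gender: Gender) -> str:
    return f"{race.value}_{gender.value}"


def load_provider_config(path: Union[str, Path]) -> ProviderConfig:
    """Read a (possibly partial) YAML provider config; defaults fill gaps.

    An empty file yields the all-default configuration.  Any invariant
    violation raises :class:`ConfigurationError` naming the offending field.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    known = {"relative_lengths", "splits", "mass_fractions", "cog_fractions", "g"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")

    rel = {g: dict(v) for g, v in DEFAULT_RELATIVE_LENGTHS.items()}
    for key, chains in (raw.get("relative_lengths") or {}).items():
        try:
            race_s, gender_s = key.split("_")
            group = (_coerce_race(race_s), _coerce_gender(gender_s))
        except ValueError:
            raise ConfigurationError(
                f"relative_lengths: bad group key {key!r} "
                "(expected e.g. 'asian_male')"
            )
        rel[group].update(chains or {})
    splits = {**DEFAULT_SPLITS, **(raw.get("splits") or {})}
    mass = {**DEFAULT_MASS_FRACTIONS, **(raw.get("mass_fractions") or {})}
    cog = {**DEFAULT_COG_FRACTIONS, **(raw.get("cog_fractions") or {})}
    g = float(raw.get("g", STANDARD_GRAVITY))
    return ProviderConfig(
        relative_lengths=rel, splits=splits, mass_fractions=mass, cog_fractions=cog, g=g
    )


def save_provider_config(cfg: ProviderConfig, path: Union[str, Path]) -> None:
    """Write a provider config as YAML readable by :func:`load_provider_config`."""
    payload = {
        "g": cfg.g,
        "relative_lengths": {
            _group_key(*group): {k: float(v) for k, v in chains.items()}
            for group, chains in cfg.relative_lengths.items()
        },
        "splits": {k: float(v) for k, v in cfg.splits.items()},
        "mass_fractions": {k: float(v) for k, v in cfg.mass_fractions.items()},
        "cog_fractions": {k: float(v) for k, v in cfg.cog_fractions.items()},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
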