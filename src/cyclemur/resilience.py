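"""Trait-based cyclone-resilience scoring for lemur species.

Six traits hypothesised to buffer a species against cyclone disturbance are
binarised and summed into a 0-6 resilience score:

===============  ==========================================  =============
indicator        scores 1 when                                threshold
===============  ==========================================  =============
energy           torpor/hibernation or similar present        boolean flag
habitat          uses the ground (not strictly arboreal)      boolean flag
group            mean group size strictly below 5             5 individuals
fruit            fruit strictly below 50% of annual diet      50 %
homerange        home range strictly above 10 ha              10 ha
mass             mean body mass strictly below 898 g          898 g
===============  ==========================================  =============

All inequalities are strict, so a species sitting exactly on a threshold
scores 0 on that trait.  The home-range direction (a point for *large*
ranges) follows the published scoring table as printed; see the methods
note for discussion.

The published 26-species indicator table ships as a fixture
(``load_reference_table``); the observed scores there span 0-4.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import DomainError

#: binarisation thresholds (strict inequalities)
GROUP_SIZE_MAX = 5.0
FRUIT_PCT_MAX = 50.0
HOME_RANGE_MIN_HA = 10.0
BODY_MASS_MAX_G = 898.0

#: canonical indicator order
INDICATORS = ("energy", "habitat", "group", "fruit", "homerange", "mass")

#: diet studies shorter than this (months) are dropped before averaging
MIN_DIET_STUDY_MONTHS = 9.0


@dataclass
class TraitRecord:
    """Raw traits of one species; any field may be None (missing)."""

    species_id: str
    energy_conservation: bool | None = None
    terrestrial_use: bool | None = None
    group_size: float | None = None
    fruit_pct: float | None = None
    home_range_ha: float | None = None
    body_mass_g: float | None = None

    def __post_init__(self) -> None:
        if self.group_size is not None and self.group_size <= 0:
            raise DomainError(f"{self.species_id}: group_size must be > 0")
        if self.fruit_pct is not None and not 0 <= self.fruit_pct <= 100:
            raise DomainError(f"{self.species_id}: fruit_pct must be in [0, 100]")
        if self.home_range_ha is not None and self.home_range_ha <= 0:
            raise DomainError(f"{self.species_id}: home_range_ha must be > 0")
        if self.body_mass_g is not None and self.body_mass_g <= 0:
            raise DomainError(f"{self.species_id}: body_mass_g must be > 0")


@dataclass
class BinaryTraitVector:
    """Six 0/1 resilience indicators; None marks a missing source trait."""

    species_id: str
    energy: int | None
    habitat: int | None
    group: int | None
    fruit: int | None
    homerange: int | None
    mass: int | None

    def as_tuple(self) -> tuple[int | None, ...]:
        return tuple(getattr(self, k) for k in INDICATORS)

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.as_tuple())

    @property
    def missing(self) -> list[str]:
        return [k for k in INDICATORS if getattr(self, k) is None]


def binarize(record: TraitRecord) -> BinaryTraitVector:
    """Apply the six strict thresholds to one species' raw traits."""

    def flag(v: bool | None) -> int | None:
        return None if v is None else int(bool(v))

    def below(v: float | None, cut: float) -> int | None:
        return None if v is None else int(v < cut)

    def above(v: float | None, cut: float) -> int | None:
        return None if v is None else int(v > cut)

    return BinaryTraitVector(
        species_id=record.species_id,
        energy=flag(record.energy_conservation),
        habitat=flag(record.terrestrial_use),
        group=below(record.group_size, GROUP_SIZE_MAX),
        fruit=below(record.fruit_pct, FRUIT_PCT_MAX),
        homerange=above(record.home_range_ha, HOME_RANGE_MIN_HA),
        mass=below(record.body_mass_g, BODY_MASS_MAX_G),
    )


def resilience_score(vector: BinaryTraitVector) -> int:
    """Sum of the six indicators; raises if any indicator is missing."""
    if not vector.complete:
        raise DomainError(
            f"{vector.species_id}: cannot score, missing indicators {vector.missing}"
        )
    return int(sum(vector.as_tuple()))


def score_table(records: list[TraitRecord]) -> tuple[pd.DataFrame, list[str]]:
    """Binarise and score many species; incomplete species are set aside.

    Returns (scored DataFrame with indicator columns plus ``resilience_score``,
    list of excluded species ids with reasons logged in the ``reason`` index).
    """
    rows, excluded = [], []
    for rec in records:
        vec = binarize(rec)
        if not vec.complete:
            excluded.append(f"{rec.species_id}: missing {', '.join(vec.missing)}")
            continue
        rows.append(
            {"species": rec.species_id}
            | {k: getattr(vec, k) for k in INDICATORS}
            | {"resilience_score": resilience_score(vec)}
        )
    return pd.DataFrame(rows), excluded


def aggregate_studies(
    studies: pd.DataFrame,
    *,
    min_diet_months: float = MIN_DIET_STUDY_MONTHS,
) -> list[TraitRecord]:
    """Average per-study trait values within species before binarisation.

    Expects one row per species-study with the TraitRecord columns plus an
    optional ``study_months`` column; rows whose diet value comes from a
    study spanning ``min_diet_months`` or less have ``fruit_pct`` masked.
    """
    df = studies.copy()
    if "study_months" in df.columns:
        short = df["study_months"].notna() & (df["study_months"] <= min_diet_months)
        df.loc[short, "fruit_pct"] = None
    records = []
    for sp, grp in df.groupby("species_id", sort=True):

        def mean_of(col):
            if col not in grp.columns:
                return None
            v = grp[col].dropna()
            return None if v.empty else float(v.mean())

        def any_of(col):
            if col not in grp.columns:
                return None
            v = grp[col].dropna()
            return None if v.empty else bool(v.any())

        records.append(
            TraitRecord(
                species_id=str(sp),
                energy_conservation=any_of("energy_conservation"),
                terrestrial_use=any_of("terrestrial_use"),
                group_size=mean_of("group_size"),
                fruit_pct=mean_of("fruit_pct"),
                home_range_ha=mean_of("home_range_ha"),
                body_mass_g=mean_of("body_mass_g"),
            )
        )
    return records


def load_reference_table() -> pd.DataFrame:
    """The packaged 26-species published indicator table.

    Columns: species, common_name, the six indicators, geographic_range,
    and the published resilience_score.
    """
    with resources.files("cyclemur.data").joinpath("table1_traits.csv").open() as fh:
        return pd.read_csv(fh)


def reference_vector(row: pd.Series) -> BinaryTraitVector:
    """Indicator vector for one row of the reference table."""
    return BinaryTraitVector(
        species_id=row["species"], **{k: int(row[k]) for k in INDICATORS}
    )
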