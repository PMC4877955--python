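"""Cohort stratification: sex x ethnicity x 5-year age band.

The modelled population is a closed adult cohort (ages 35+) stratified by
sex (male/female), ethnicity (Maori / non-Maori) and thirteen 5-year age
bands 35-39 ... 95-99.  A stratum is identified by the band's start age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

SEXES: tuple[str, ...] = ("male", "female")
ETHNICITIES: tuple[str, ...] = ("maori", "non_maori")
AGE_BAND_STARTS: tuple[int, ...] = tuple(range(35, 100, 5))  # 13 bands
AGE_BAND_WIDTH = 5
MAX_AGE = 100  # simulation hard stop: death or age 100
N_STRATA = len(SEXES) * len(ETHNICITIES) * len(AGE_BAND_STARTS)

SEX_INDEX = {s: i for i, s in enumerate(SEXES)}
ETH_INDEX = {e: i for i, e in enumerate(ETHNICITIES)}
BAND_INDEX = {b: i for i, b in enumerate(AGE_BAND_STARTS)}


@dataclass(frozen=True, order=True)
class StratumKey:
    """One (sex, ethnicity, 5-year age band) cell of the cohort."""

    sex: str
    ethnicity: str
    age_band: int  # band start age: 35, 40, ..., 95

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.age_band not in AGE_BAND_STARTS:
            raise ValueError(f"age_band {self.age_band} is not a 5-year band start in 35..95")


def all_strata() -> Iterator[StratumKey]:
    """Enumerate all 2 x 2 x 13 strata in a fixed canonical order."""
    for sex in SEXES:
        for eth in ETHNICITIES:
            for band in AGE_BAND_STARTS:
                yield StratumKey(sex, eth, band)


def band_for_age(age: int) -> int:
    """Start age of the 5-year band containing ``age`` (clipped to 35..95).

    Ages above 99 map to the 95-99 band; the simulation never accrues
    anything for them (occupancy is fully absorbed in death states).
    """
    if age < AGE_BAND_STARTS[0]:
        raise ValueError(f"age {age} below modelled range (35+)")
    return min(AGE_BAND_STARTS[-1], AGE_BAND_STARTS[0] + (age - AGE_BAND_STARTS[0]) // 5 * 5)
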