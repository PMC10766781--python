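"""TAG species, oxidized variants, ESI adduct ions and stage-1 mass windows.

Oxidation adds n x 15.9949 Da (one oxygen per epoxide/aldehyde, two per
hydroperoxide) to the neutral TAG, so oxidized species shift to higher m/z in
regular oxygen steps. Positive-mode ESI of neutral lipids is observed through
protonated, ammoniated or sodiated adducts depending on the solvent additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from pyteomics import mass as pt_mass

__all__ = [
    "TagSpecies",
    "AdductSpec",
    "TargetIon",
    "MassWindow",
    "OOO",
    "OOL",
    "ADDUCTS",
    "DELTA_O_MONO",
    "DELTA_O_NOMINAL",
    "adduct_mz",
    "default_windows",
    "build_target_table",
    "target_table_frame",
]

#: mass added per oxygen atom
DELTA_O_MONO = 15.9949146221
DELTA_O_NOMINAL = 16.0

#: electron mass, subtracted when a cation is formed
_ELECTRON = 0.00054858


@dataclass(frozen=True)
class TagSpecies:
    """A triacylglycerol defined by name, neutral formula and acyl labels."""

    name: str
    formula: str
    acyls: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.acyls) != 3:
            raise ValueError("a TAG carries exactly three acyl chains")
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"formula {self.formula!r} has non-positive mass")

    @property
    def monoisotopic_mass(self) -> float:
        return float(pt_mass.calculate_mass(formula=self.formula))

    @property
    def nominal_mass(self) -> float:
        comp = pt_mass.Composition(formula=self.formula)
        return float(
            sum(round(pt_mass.nist_mass[el][0][0]) * n for el, n in comp.items())
        )


@dataclass(frozen=True)
class AdductSpec:
    """Cation adduct: label, mass added to the neutral molecule, charge."""

    label: str
    shift_mono: float
    shift_nominal: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.shift_mono <= 0 or self.shift_nominal <= 0:
            raise ValueError("adduct mass shift must be > 0")


# cation masses = neutral fragment + proton(s) - electron
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", 1.00728, 1.0),
    "[M+NH4]+": AdductSpec(
        "[M+NH4]+", pt_mass.calculate_mass(formula="NH4") - _ELECTRON, 18.0
    ),
    "[M+Na]+": AdductSpec(
        "[M+Na]+", pt_mass.calculate_mass(formula="Na") - _ELECTRON, 23.0
    ),
}

#: triolein — the dominant TAG of rapeseed oil
OOO = TagSpecies("OOO", "C57H104O6", ("18:1", "18:1", "18:1"))
#: dioleoyl-linoleoyl-glycerol
OOL = TagSpecies("OOL", "C57H102O6", ("18:1", "18:1", "18:2"))

SPECIES: dict[str, TagSpecies] = {"OOO": OOO, "OOL": OOL}

MassMode = Literal["monoisotopic", "nominal"]


@dataclass(frozen=True)
class TargetIon:
    """One monitored ion: a species at a given oxidation degree and adduct."""

    species: TagSpecies
    n_ox: int
    adduct: AdductSpec
    mz: float

    @property
    def label(self) -> str:
        ox = f"{self.n_ox}ox-" if self.n_ox else ""
        return f"{ox}{self.species.name} {self.adduct.label}"


@dataclass(frozen=True)
class MassWindow:
    """Half-open m/z interval [lo, hi) used for stage-1 area integration."""

    label: str
    lo: float
    hi: float
    role: Literal["nonox", "ox", "ox-subclass"]

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window {self.label}: lo must be < hi")

    def contains(self, mz: float) -> bool:
        return self.lo <= mz < self.hi


def adduct_mz(
    species: TagSpecies,
    n_ox: int,
    adduct: AdductSpec | str,
    mass_mode: MassMode = "monoisotopic",
) -> float:
    """m/z of a (species, oxidation degree, adduct) ion.

    Consecutive oxidation degrees are spaced by exactly one oxygen mass
    (15.9949 Da monoisotopic, 16 Da nominal).
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise KeyError(
                f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}"
            ) from None
    if not 0 <= n_ox <= 6:
        raise ValueError("n_ox must be in 0..6")
    if mass_mode == "monoisotopic":
        m = species.monoisotopic_mass + n_ox * DELTA_O_MONO + adduct.shift_mono
    elif mass_mode == "nominal":
        m = species.nominal_mass + n_ox * DELTA_O_NOMINAL + adduct.shift_nominal
    else:
        raise ValueError(f"unknown mass_mode {mass_mode!r}")
    return m / adduct.charge


def default_windows(sample_kind: str) -> list[MassWindow]:
    """Stage-1 integration windows for a sample type.

    ``oil`` additionally carries per-degree ox subclass windows; ``OOO_std``
    and ``OOL_std`` use the standard-specific non-ox/ox ranges.
    """
    if sample_kind == "oil":
        return [
            MassWindow("nonox", 880.0, 910.0, "nonox"),
            MassWindow("ox", 912.0, 970.0, "ox"),
            MassWindow("1ox", 914.0, 926.0, "ox-subclass"),
            MassWindow("2ox", 928.0, 942.0, "ox-subclass"),
            MassWindow("3ox", 944.0, 957.0, "ox-subclass"),
            MassWindow("4ox", 959.0, 970.0, "ox-subclass"),
        ]
    if sample_kind == "OOO_std":
        return [
            MassWindow("nonox", 884.0, 908.0, "nonox"),
            MassWindow("ox", 915.0, 970.0, "ox"),
        ]
    if sample_kind == "OOL_std":
        return [
            MassWindow("nonox", 883.0, 906.0, "nonox"),
            MassWindow("ox", 913.0, 968.0, "ox"),
        ]
    raise ValueError(
        f"unknown sample kind {sample_kind!r}; expected oil, OOO_std or OOL_std"
    )


def build_target_table(
    species: Iterable[TagSpecies],
    adducts: Iterable[AdductSpec | str],
    max_ox: int,
    mass_mode: MassMode = "monoisotopic",
) -> list[TargetIon]:
    """Cartesian (species x oxidation degree x adduct) ion list, sorted by m/z."""
    if not 0 <= max_ox <= 6:
        raise ValueError("max_ox must be in 0..6")
    resolved = [ADDUCTS[a] if isinstance(a, str) else a for a in adducts]
    ions = [
        TargetIon(sp, n, ad, adduct_mz(sp, n, ad, mass_mode))
        for sp, n, ad in product(species, range(max_ox + 1), resolved)
    ]
    return sorted(ions, key=lambda ion: ion.mz)


def target_table_frame(ions: Sequence[TargetIon]) -> pd.DataFrame:
    """Export a target-ion list as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "species": [i.species.name for i in ions],
            "n_ox": [i.n_ox for i in ions],
            "adduct": [i.adduct.label for i in ions],
            "mz": [i.mz for i in ions],
        }
    )
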