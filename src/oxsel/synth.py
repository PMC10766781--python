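"""Synthetic flow-injection ESI-MS campaigns with known ground truth.

The generator emulates centroided positive-mode spectra of an oxidized
rapeseed oil (or a TAG standard): adduct sticks of OOO/OOL and their 1..n-ox
products in the m/z 880-970 region. Per-ion intensity is

    scale * abundance(species) * composition[n_ox]
          * efficiency(species, n_ox | condition) * adduct_weight(additive)
          * lognormal noise,

so the stage-2 selectivity of a noise-free spectrum equals the planted
efficiency ratio exactly — the generator is the oracle for the analysis
pipeline. Optional in-source fragmentation leakage relocates a fraction f of
each oxidized stick to the species' non-oxidized m/z (intensity conserving),
reproducing the downward bias of window-based selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ConditionSet, DesignTable, resolve_conditions
from .nmr import TagOxDistribution
from .species import ADDUCTS, OOL, OOO, TagSpecies, adduct_mz
from .spectra import Spectrum, write_spectrum

__all__ = [
    "IonizationModel",
    "CampaignSpec",
    "default_model",
    "null_model",
    "simulate_spectrum",
    "simulate_campaign",
]

FACTOR_CODES = ("A", "B", "C", "D", "E")

#: per-additive adduct propensities: ammonium formate yields mostly
#: ammoniated ions with minor protonated/sodiated signal; sodium salts
#: yield sodiated ions.
DEFAULT_ADDUCT_WEIGHTS: dict[str, dict[str, float]] = {
    "NH4Fo": {"[M+NH4]+": 1.0, "[M+H]+": 0.06, "[M+Na]+": 0.08},
    "NaOAc": {"[M+Na]+": 1.0},
    "NaI": {"[M+Na]+": 1.0},
}

_UNIT_CURVE = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class IonizationModel:
    """Planted per-ion ionization efficiencies as a function of conditions.

    ``base`` multiplies specific (species, n_ox) pairs; ``ox_factor_effects``
    / ``nonox_factor_effects`` give multiplicative level curves per factor
    code, applied to oxidized (n_ox >= 1) and non-oxidized species
    respectively; ``ox_interactions`` adds two-way multipliers keyed by
    ((code1, level1), (code2, level2)). ``leakage`` is the in-source
    fragmentation fraction f; ``noise_cv`` the coefficient of variation of
    the multiplicative log-normal noise.
    """

    base: Mapping[tuple[str, int], float] = field(default_factory=dict)
    ox_factor_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    nonox_factor_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    ox_interactions: Mapping[
        tuple[tuple[str, int], tuple[str, int]], float
    ] = field(default_factory=dict)
    adduct_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_ADDUCT_WEIGHTS
    )
    leakage: float = 0.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(v <= 0 for v in self.base.values()):
            raise ValueError("base efficiencies must be > 0")

    def efficiency(self, species: str, n_ox: int, cond: ConditionSet) -> float:
        """Planted ionization efficiency of (species, n_ox) under ``cond``."""
        eff = float(self.base.get((species, n_ox), 1.0))
        curves = self.ox_factor_effects if n_ox >= 1 else self.nonox_factor_effects
        for code, level in zip(FACTOR_CODES, cond.levels):
            eff *= curves.get(code, _UNIT_CURVE)[level]
        if n_ox >= 1:
            for ((c1, l1), (c2, l2)), mult in self.ox_interactions.items():
                i1, i2 = FACTOR_CODES.index(c1), FACTOR_CODES.index(c2)
                if cond.levels[i1] == l1 and cond.levels[i2] == l2:
                    eff *= mult
        return eff

    def true_selectivity(self, species: str, n_ox: int, cond: ConditionSet) -> float:
        """Ground-truth stage-2 selectivity: efficiency ratio ox / non-ox."""
        return self.efficiency(species, n_ox, cond) / self.efficiency(
            species, 0, cond
        )


def default_model(noise_cv: float = 0.10, leakage: float = 0.0) -> IonizationModel:
    """Planted scenario mirroring the observed ionization behavior.

    Sodiated ionization of oxidized TAGs is strongly favored over ammoniated
    (additive effect dominates), and the high capillary-voltage level boosts
    oxidized-species efficiency about two-fold. The resulting optimum profile
    is (NaOAc, mid concentration, mid sheath temperature, high capillary
    voltage, high nozzle voltage).
    """
    return IonizationModel(
        ox_factor_effects={
            "A": (1.0, 8.0, 5.0),  # NH4Fo, NaOAc, NaI
            "B": (0.8, 1.2, 0.9),
            "C": (0.85, 1.25, 1.1),
            "D": (1.0, 1.4, 2.0),
            "E": (0.9, 1.0, 1.15),
        },
        noise_cv=noise_cv,
        leakage=leakage,
    )


def null_model(noise_cv: float = 0.10) -> IonizationModel:
    """No factor influences efficiency; only noise varies. For calibration."""
    return IonizationModel(noise_cv=noise_cv)


@dataclass(frozen=True)
class CampaignSpec:
    """A full factorial-design measurement campaign to simulate."""

    design: DesignTable
    composition: TagOxDistribution
    replicates: int = 2  # measurements performed in duplicate
    species: tuple[TagSpecies, ...] = (OOO, OOL)
    abundances: tuple[float, ...] = (0.55, 0.45)  # OOO/OOL share in rapeseed oil
    max_ox: int = 4
    scale: float = 1e5
    sample: str = "oil"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.abundances) != len(self.species):
            raise ValueError("one abundance per species required")


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n)


def simulate_spectrum(
    cond: ConditionSet,
    model: IonizationModel,
    composition: TagOxDistribution,
    seed: int | np.random.Generator = 0,
    species: Sequence[TagSpecies] = (OOO, OOL),
    abundances: Sequence[float] = (0.55, 0.45),
    max_ox: int = 4,
    scale: float = 1e5,
    replicate: int | None = None,
    sample: str | None = None,
) -> Spectrum:
    """One centroided spectrum under a condition set; deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = model.adduct_weights.get(cond.additive)
    if weights is None:
        raise ValueError(f"no adduct weights defined for additive {cond.additive!r}")

    sticks: dict[float, float] = {}
    entries = []  # (mz, nonox_mz_of_same_adduct, n_ox, raw_intensity)
    for sp, ab in zip(species, abundances):
        for adduct_label, w in weights.items():
            adduct = ADDUCTS[adduct_label]
            nonox_mz = adduct_mz(sp, 0, adduct)
            for n_ox in range(max_ox + 1):
                inten = (
                    scale
                    * ab
                    * composition[n_ox]
                    * model.efficiency(sp.name, n_ox, cond)
                    * w
                )
                if inten > 0:
                    entries.append((adduct_mz(sp, n_ox, adduct), nonox_mz, n_ox, inten))

    noise = _lognormal_factor(rng, model.noise_cv, len(entries))
    f = model.leakage
    for (mz, nonox_mz, n_ox, inten), nf in zip(entries, noise):
        inten *= nf
        if n_ox >= 1 and f > 0:
            # in-source fragmentation: part of the oxidized signal registers
            # at the non-oxidized mass; total intensity is conserved
            sticks[nonox_mz] = sticks.get(nonox_mz, 0.0) + f * inten
            inten *= 1 - f
        sticks[mz] = sticks.get(mz, 0.0) + inten

    mzs = np.array(sorted(sticks))
    intens = np.array([sticks[m] for m in mzs])
    return Spectrum(
        mzs,
        intens,
        condition_set_id=cond.run_id,
        replicate=replicate,
        sample=sample,
    )


def simulate_campaign(
    spec: CampaignSpec,
    model: IonizationModel,
    out_dir: str | Path | None = None,
    format: str = "csv",
) -> tuple[pd.DataFrame, dict[str, Spectrum]]:
    """Simulate all design runs x replicates.

    Returns (manifest, spectra) where the manifest has columns path,
    condition_set_id, replicate, sample and ``spectra`` maps path keys to the
    in-memory spectra. If ``out_dir`` is given the spectra are also written
    there (CSV or mzML); otherwise paths are virtual keys usable with
    ``batch_selectivity(..., spectra=...)``.
    """
    conditions = resolve_conditions(spec.design)
    rows = []
    spectra: dict[str, Spectrum] = {}
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(conditions) * spec.replicates)
    i = 0
    for cond in conditions:
        for rep in range(1, spec.replicates + 1):
            rng = np.random.default_rng(children[i])
            i += 1
            s = simulate_spectrum(
                cond,
                model,
                spec.composition,
                seed=rng,
                species=spec.species,
                abundances=spec.abundances,
                max_ox=spec.max_ox,
                scale=spec.scale,
                replicate=rep,
                sample=spec.sample,
            )
            name = f"{spec.sample}_c{cond.run_id:02d}_r{rep}.{format}"
            if out_dir is not None:
                path = Path(out_dir) / name
                path.parent.mkdir(parents=True, exist_ok=True)
                write_spectrum(s, path, format=format)
                key = str(path)
            else:
                key = name
            spectra[key] = s
            rows.append(
                {
                    "path": key,
                    "condition_set_id": cond.run_id,
                    "replicate": rep,
                    "sample": spec.sample,
                }
            )
    return pd.DataFrame(rows), spectra
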