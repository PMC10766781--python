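"""The normalized selectivity factor for oxidized versus non-oxidized TAGs.

The selectivity of ionization is the ratio of composition-normalized peak
areas:

    selectivity = (area_ox / frac_ox) / (area_nonox / frac_nonox)

where the fractions come from the NMR-derived TAG oxidation-degree
distribution. A value above 1 means ionization favors the oxidized species.
Stage 1 integrates mass windows (all oxidized species at once); stage 2
integrates extracted-ion currents of specific (species, ox degree, adduct)
ions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nmr import NormalizationUndefinedError, TagOxDistribution, normalization_fractions
from .species import MassWindow, TargetIon
from .spectra import Spectrum, average_replicates, eic_area, read_spectrum, window_area

__all__ = [
    "SelectivityRecord",
    "selectivity_factor",
    "stage1_selectivity",
    "stage2_selectivity",
    "batch_selectivity",
]

log = logging.getLogger(__name__)

#: sentinel for the no-non-ox-signal case; excluded from downstream statistics
INFINITE_SELECTIVITY = math.inf


@dataclass(frozen=True)
class SelectivityRecord:
    """Eq.-style selectivity for one (sample, species, ox degree, condition)."""

    sample: str
    species: str  # species name or "window-level"
    ox_degrees: tuple[int, ...]
    condition_set_id: int | None
    selectivity: float
    sd: float = 0.0
    n_replicates: int = 1
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isinf(self.selectivity) and self.selectivity < 0:
            raise ValueError("selectivity must be >= 0")


def selectivity_factor(
    area_ox: float, area_nonox: float, frac_ox: float, frac_nonox: float
) -> float:
    """Ratio of normalized peak areas; the core selectivity statistic.

    Returns the ``inf`` sentinel (with a warning) when the non-oxidized
    species yields no signal at all — selectivity is then unbounded and the
    record must be excluded from ANOVA.
    """
    if min(area_ox, area_nonox) < 0:
        raise ValueError("areas must be >= 0")
    if frac_ox <= 0 or frac_nonox <= 0:
        raise NormalizationUndefinedError(
            "composition fractions must be > 0 for normalization"
        )
    if area_nonox == 0:
        warnings.warn(
            "non-oxidized species yields no signal: infinite selectivity sentinel"
        )
        return INFINITE_SELECTIVITY
    return (area_ox / frac_ox) / (area_nonox / frac_nonox)


def stage1_selectivity(
    s: Spectrum,
    windows: Sequence[MassWindow],
    dist: TagOxDistribution,
    ox_degrees: Iterable[int] = (1, 2, 3, 4),
) -> SelectivityRecord:
    """Window-level (stage-1) selectivity from one nonox and one ox window."""
    nonox = [w for w in windows if w.role == "nonox"]
    ox = [w for w in windows if w.role == "ox"]
    if len(nonox) != 1 or len(ox) != 1:
        raise ValueError("need exactly one 'nonox' and one 'ox' window")
    degrees = tuple(sorted(set(ox_degrees)))
    frac_ox, frac_nonox = normalization_fractions(dist, degrees)
    area_nonox = window_area(s, nonox[0]).area
    area_ox = window_area(s, ox[0]).area
    sel = selectivity_factor(area_ox, area_nonox, frac_ox, frac_nonox)
    return SelectivityRecord(
        sample=s.sample or "",
        species="window-level",
        ox_degrees=degrees,
        condition_set_id=s.condition_set_id,
        selectivity=sel,
        flags=("infinite",) if math.isinf(sel) else (),
    )


def stage2_selectivity(
    s: Spectrum,
    ion_ox: TargetIon,
    ion_nonox: TargetIon,
    dist: TagOxDistribution,
    tol: float = 0.35,
) -> SelectivityRecord:
    """Selected-ion (stage-2) selectivity for one oxidized target ion.

    The two ions must share species and adduct; normalization uses the
    single-degree fraction prob[n_ox] against prob[0].
    """
    if ion_nonox.n_ox != 0:
        raise ValueError("ion_nonox must have n_ox = 0")
    if ion_ox.n_ox < 1:
        raise ValueError("ion_ox must have n_ox >= 1")
    if ion_ox.species.name != ion_nonox.species.name:
        raise ValueError("ions must share the TAG species")
    if ion_ox.adduct.label != ion_nonox.adduct.label:
        raise ValueError("ions must share the adduct")
    frac_ox, frac_nonox = normalization_fractions(dist, {ion_ox.n_ox})
    area_ox = eic_area(s, ion_ox, tol).area
    area_nonox = eic_area(s, ion_nonox, tol).area
    sel = selectivity_factor(area_ox, area_nonox, frac_ox, frac_nonox)
    return SelectivityRecord(
        sample=s.sample or "",
        species=ion_ox.species.name,
        ox_degrees=(ion_ox.n_ox,),
        condition_set_id=s.condition_set_id,
        selectivity=sel,
        flags=("infinite",) if math.isinf(sel) else (),
    )


def _per_replicate_records(
    spectra: Sequence[Spectrum],
    dist: TagOxDistribution,
    windows: Sequence[MassWindow] | None,
    targets: Sequence[tuple[TargetIon, TargetIon]] | None,
    ox_degrees: Iterable[int],
    tol: float,
) -> list[SelectivityRecord]:
    recs = []
    for s in spectra:
        if windows is not None:
            recs.append(stage1_selectivity(s, windows, dist, ox_degrees))
        if targets is not None:
            for ion_ox, ion_nonox in targets:
                recs.append(stage2_selectivity(s, ion_ox, ion_nonox, dist, tol))
    return recs


def batch_selectivity(
    manifest: pd.DataFrame,
    dist: TagOxDistribution,
    windows: Sequence[MassWindow] | None = None,
    targets: Sequence[tuple[TargetIon, TargetIon]] | None = None,
    ox_degrees: Iterable[int] = (1, 2, 3, 4),
    tol: float = 0.35,
    spectra: Mapping[str, Spectrum] | None = None,
    aggregate: bool = True,
) -> pd.DataFrame:
    """Selectivity over a measurement campaign, per replicate or averaged.

    ``manifest`` columns: path, condition_set_id, replicate, sample. Spectra
    are read from ``path`` unless an in-memory ``spectra`` mapping (keyed by
    path) is supplied. Selectivity is computed per replicate; with
    ``aggregate=True`` (default) replicates are then averaged, preserving the
    replicate-SD semantics of reported mean +- SD. ``aggregate=False``
    returns one row per replicate (the input the factorial ANOVA needs).
    Missing files or infinite sentinels yield flagged rows, never silent
    drops.

    Returns a tidy table: sample, species, ox_degree, condition_set,
    [replicate,] selectivity, [sd, n_replicates,] flags.
    """
    required = {"path", "condition_set_id", "replicate", "sample"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    if windows is None and targets is None:
        raise ValueError("provide stage-1 windows and/or stage-2 targets")

    rep_rows: list[dict] = []
    n_missing = n_inf = 0
    for _, row in manifest.iterrows():
        key = str(row["path"])
        sample, cond, rep = str(row["sample"]), int(row["condition_set_id"]), int(row["replicate"])
        try:
            s = (
                spectra[key]
                if spectra is not None and key in spectra
                else read_spectrum(key, condition_set_id=cond, replicate=rep, sample=sample)
            )
        except (OSError, ValueError):
            n_missing += 1
            rep_rows.append(
                {
                    "sample": sample,
                    "species": "*",
                    "ox_degree": "",
                    "condition_set": cond,
                    "replicate": rep,
                    "selectivity": math.nan,
                    "flags": "missing-replicate",
                }
            )
            continue
        with warnings.catch_warnings():
            # sentinel warnings are redundant here: batch rows carry the
            # 'infinite' flag and the total is logged below
            warnings.filterwarnings("ignore", message=".*infinite selectivity.*")
            recs = _per_replicate_records([s], dist, windows, targets, ox_degrees, tol)
        for rec in recs:
            flags = set(rec.flags)
            val = rec.selectivity
            if math.isinf(val):
                n_inf += 1
                val = math.nan
            rep_rows.append(
                {
                    "sample": sample,
                    "species": rec.species,
                    "ox_degree": ",".join(map(str, rec.ox_degrees)),
                    "condition_set": cond,
                    "replicate": rep,
                    "selectivity": val,
                    "flags": ";".join(sorted(flags)),
                }
            )
    log.info(
        "batch_selectivity: %d replicate rows, %d missing replicates, %d infinite sentinels",
        len(rep_rows),
        n_missing,
        n_inf,
    )
    per_rep = pd.DataFrame(rep_rows)
    if not aggregate or per_rep.empty:
        return per_rep

    rows: list[dict] = []
    grouped = per_rep.groupby(["sample", "species", "ox_degree", "condition_set"])
    for (sample, species, ox_degree, cond), g in grouped:
        flags = {f for fl in g["flags"] if fl for f in fl.split(";")}
        vals = g["selectivity"].dropna().tolist()
        if species == "*":  # placeholder rows from wholly missing replicates
            continue
        if vals:
            mean, sd, single = average_replicates(vals)
            if single:
                flags.add("single-replicate")
        else:
            mean, sd = math.nan, math.nan
            flags.add("no-valid-replicate")
        rows.append(
            {
                "sample": sample,
                "species": species,
                "ox_degree": ox_degree,
                "condition_set": cond,
                "selectivity": mean,
                "sd": sd,
                "n_replicates": len(vals),
                "flags": ";".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)
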