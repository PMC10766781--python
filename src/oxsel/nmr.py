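"""Combinatorial TAG oxidation model from NMR group quantification.

Bulk NMR yields concentrations of aldehyde, epoxide and hydroperoxide groups
per kg of triacylglycerol (TAG). Under two assumptions — (i) a fatty-acid (FA)
chain carries at most one oxidized group, so a chain has 0, 1 (aldehyde or
epoxide) or 2 (hydroperoxide) added oxygen atoms, and (ii) a mean TAG molar
mass (default 885 g/mol, triolein) — these translate into per-chain oxidation
fractions. Treating the three sn positions of the glycerol backbone as
independent draws from that per-chain distribution gives a trinomial model for
the probability that a whole TAG molecule carries k = 0..6 added oxygens.
These probabilities are the composition terms that normalize MS peak areas in
the selectivity factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "NmrGroupQuant",
    "FaOxidationProfile",
    "TagOxDistribution",
    "InfeasibleCompositionError",
    "NormalizationUndefinedError",
    "fa_profile_from_nmr",
    "tag_distribution",
    "normalization_fractions",
    "read_nmr_csv",
    "distribution_table",
]

#: number of acyl chains on a glycerol backbone (sn-1, sn-2, sn-3)
N_CHAINS = 3

#: maximum added oxygens per TAG: three chains x two oxygens (hydroperoxide)
MAX_OX = 6


class InfeasibleCompositionError(ValueError):
    """Oxidized-group concentrations exceed the available fatty-acid pool."""


class NormalizationUndefinedError(ZeroDivisionError):
    """A composition fraction needed for normalization is zero."""


@dataclass(frozen=True)
class NmrGroupQuant:
    """Oxidation-group concentrations of a TAG sample, in mol per kg TAG."""

    aldehyde: float
    epoxide: float
    hydroperoxide: float
    mean_tag_mass: float = 885.0  # g/mol; triolein, dominant TAG of rapeseed oil

    def __post_init__(self) -> None:
        for name in ("aldehyde", "epoxide", "hydroperoxide"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be finite and >= 0")
        if not self.mean_tag_mass > 0:
            raise ValueError("mean_tag_mass must be > 0")

    @property
    def mol_tag_per_kg(self) -> float:
        """mol TAG per kg of oil (1000 g / mean molar mass)."""
        return 1000.0 / self.mean_tag_mass

    @property
    def mol_fa_per_kg(self) -> float:
        """mol fatty-acid chains per kg of oil (three chains per TAG)."""
        return N_CHAINS * self.mol_tag_per_kg


@dataclass(frozen=True)
class FaOxidationProfile:
    """Per-chain oxidation-state fractions (0, 1 or 2 added oxygens)."""

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        ps = (self.p0, self.p1, self.p2)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in ps):
            raise ValueError(f"fractions must lie in [0, 1]: {ps}")
        if abs(sum(ps) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1: {ps}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p0, self.p1, self.p2)


@dataclass(frozen=True)
class TagOxDistribution:
    """Probability that a TAG carries k = 0..6 added oxygen atoms.

    ``negligible_below`` marks the reporting threshold (fraction) under which
    high oxidation degrees are flagged as negligible; it does not alter the
    probabilities.
    """

    prob: tuple[float, ...]
    negligible_below: float = 0.005

    def __post_init__(self) -> None:
        if len(self.prob) != MAX_OX + 1:
            raise ValueError(f"prob must have {MAX_OX + 1} entries (k = 0..{MAX_OX})")
        if any(p < -1e-12 or p > 1 + 1e-12 for p in self.prob):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.prob) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def __getitem__(self, k: int) -> float:
        return self.prob[k]

    def negligible_degrees(self) -> list[int]:
        """Oxidation degrees whose probability falls below the threshold."""
        return [k for k, p in enumerate(self.prob) if p < self.negligible_below]

    def as_percent(self, decimals: int = 2) -> tuple[float, ...]:
        """Presentation helper: probabilities as percentages."""
        return tuple(round(100.0 * p, decimals) for p in self.prob)


def fa_profile_from_nmr(
    q: NmrGroupQuant, round_decimals: int | None = None
) -> FaOxidationProfile:
    """Convert group concentrations into per-chain oxidation fractions.

    p1 = (aldehyde + epoxide) / mol FA per kg (one added oxygen per group),
    p2 = hydroperoxide / mol FA per kg (two added oxygens),
    p0 = 1 - p1 - p2.

    Parameters
    ----------
    q
        Measured group concentrations.
    round_decimals
        If given, round p1 and p2 to this many decimals before forming p0.
        Published intermediate fractions are typically reported at three
        decimals; ``round_decimals=3`` reproduces calculations that chain
        from those printed values. Default ``None`` keeps full precision.

    Raises
    ------
    InfeasibleCompositionError
        If the oxidized chains implied by the concentrations exceed the FA
        pool (p0 < 0).
    """
    mol_fa = q.mol_fa_per_kg
    p1 = (q.aldehyde + q.epoxide) / mol_fa
    p2 = q.hydroperoxide / mol_fa
    if round_decimals is not None:
        p1 = round(p1, round_decimals)
        p2 = round(p2, round_decimals)
    p0 = 1.0 - p1 - p2
    if p0 < 0:
        raise InfeasibleCompositionError(
            f"oxidized-group concentrations imply {p1 + p2:.3f} oxidized chain "
            "fraction > 1; check units (mol per kg TAG) or mean_tag_mass"
        )
    return FaOxidationProfile(p0=p0, p1=p1, p2=p2)


def tag_distribution(p: FaOxidationProfile) -> TagOxDistribution:
    """Trinomial TAG oxidation-degree distribution over three sn positions.

    prob[k] sums p_a * p_b * p_c over the 27 ordered chain-state triples
    (a, b, c) in {0, 1, 2}^3 with a + b + c = k.
    """
    ps = p.as_tuple()
    prob = [0.0] * (MAX_OX + 1)
    for triple in product(range(3), repeat=N_CHAINS):
        term = 1.0
        for state in triple:
            term *= ps[state]
        prob[sum(triple)] += term
    total = sum(prob)
    # guard against drift from repeated float summation
    prob = [x / total for x in prob]
    return TagOxDistribution(prob=tuple(prob))


def normalization_fractions(
    d: TagOxDistribution, ox_degrees: Iterable[int]
) -> tuple[float, float]:
    """Composition fractions entering the selectivity normalization.

    Returns ``(frac_ox, frac_nonox)`` where ``frac_ox`` sums the distribution
    over the requested oxidation degrees and ``frac_nonox`` is the k = 0 term.

    Raises
    ------
    NormalizationUndefinedError
        If either fraction is zero — e.g. a fresh oil with no measurable
        oxidation has frac_ox = 0 and its selectivity is undefined.
    """
    degrees = set(ox_degrees)
    if not degrees or not degrees <= set(range(1, MAX_OX + 1)):
        raise ValueError(f"ox_degrees must be a non-empty subset of 1..{MAX_OX}")
    frac_ox = float(sum(d[k] for k in degrees))
    frac_nonox = float(d[0])
    if frac_ox == 0.0 or frac_nonox == 0.0:
        raise NormalizationUndefinedError(
            f"composition fraction is zero (ox={frac_ox}, nonox={frac_nonox}); "
            "selectivity normalization undefined"
        )
    return frac_ox, frac_nonox


# ---------------------------------------------------------------------------
# CSV interfaces


def read_nmr_csv(path: str | Path) -> dict[str, NmrGroupQuant]:
    """Read per-sample NMR quantification from CSV.

    Expected columns: sample_id, aldehyde_mol_per_kg, epoxide_mol_per_kg,
    hydroperoxide_mol_per_kg and optionally mean_tag_mass (default 885).
    """
    df = pd.read_csv(path)
    required = {
        "sample_id",
        "aldehyde_mol_per_kg",
        "epoxide_mol_per_kg",
        "hydroperoxide_mol_per_kg",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"NMR CSV missing columns: {sorted(missing)}")
    out: dict[str, NmrGroupQuant] = {}
    for _, row in df.iterrows():
        out[str(row["sample_id"])] = NmrGroupQuant(
            aldehyde=float(row["aldehyde_mol_per_kg"]),
            epoxide=float(row["epoxide_mol_per_kg"]),
            hydroperoxide=float(row["hydroperoxide_mol_per_kg"]),
            mean_tag_mass=float(row.get("mean_tag_mass", 885.0))
            if "mean_tag_mass" in df.columns
            else 885.0,
        )
    if not out:
        raise ValueError(f"no samples found in {path}")
    return out


def distribution_table(
    quants: dict[str, NmrGroupQuant], round_decimals: int | None = None
) -> pd.DataFrame:
    """Tidy per-sample oxidation-degree distribution (columns p_0ox..p_6ox)."""
    rows = []
    for sample_id, q in quants.items():
        profile = fa_profile_from_nmr(q, round_decimals=round_decimals)
        dist = tag_distribution(profile)
        row: dict[str, object] = {"sample_id": sample_id}
        row.update({f"p_{k}ox": dist[k] for k in range(MAX_OX + 1)})
        row["negligible_degrees"] = ";".join(map(str, dist.negligible_degrees()))
        rows.append(row)
    return pd.DataFrame(rows)
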