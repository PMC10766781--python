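"""Regular 3^(5-1) fractional factorial design over GF(3).

Five ionization factors at three levels each: (A) solvent additive type,
(B) additive concentration, (C) sheath gas temperature, (D) capillary
voltage, (E) nozzle voltage. The 81-run regular fraction takes the full
3^4 factorial on A-D and computes E from a single defining relation
E = cA*A + cB*B + cC*C + cD*D (mod 3) with all coefficients nonzero, which
keeps main effects and two-way interactions estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignTable",
    "ConditionSet",
    "DEFAULT_FACTORS",
    "generate_design",
    "validate_design",
    "resolve_conditions",
    "read_design_csv",
]

FACTOR_CODES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class Factor:
    """One design factor with its three typed level values."""

    code: str
    name: str
    levels: tuple
    unit: str = ""
    categorical: bool = False

    def __post_init__(self) -> None:
        if len(set(self.levels)) != 3:
            raise ValueError(f"factor {self.code}: exactly 3 distinct levels required")


#: additive type is categorical; its level order carries no meaning
DEFAULT_FACTORS: tuple[Factor, ...] = (
    Factor("A", "additive", ("NH4Fo", "NaOAc", "NaI"), categorical=True),
    Factor("B", "conc_mM", (0.05, 0.1, 0.2), unit="mM"),
    Factor("C", "sheath_C", (150, 250, 350), unit="degC"),
    Factor("D", "capillary_V", (2000, 3500, 5000), unit="V"),
    Factor("E", "nozzle_V", (500, 1000, 1500), unit="V"),
)


@dataclass(frozen=True)
class ConditionSet:
    """One resolved run: physical factor values plus its design id."""

    run_id: int
    additive: str
    conc_mM: float
    sheath_C: float
    capillary_V: float
    nozzle_V: float
    levels: tuple[int, int, int, int, int]


@dataclass(frozen=True)
class DesignTable:
    """81 runs as level indices (0/1/2) per factor, run ids 1..81."""

    levels: np.ndarray  # (n_runs, 5) int
    generator: tuple[int, int, int, int]
    factors: tuple[Factor, ...] = DEFAULT_FACTORS

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=int)
        object.__setattr__(self, "levels", lv)
        if lv.ndim != 2 or lv.shape[1] != 5:
            raise ValueError("levels must be (n_runs, 5)")

    @property
    def n_runs(self) -> int:
        return int(self.levels.shape[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.levels, columns=[f"{c}_level" for c in FACTOR_CODES]
        )
        df.insert(0, "run_id", np.arange(1, self.n_runs + 1))
        for f, col in zip(self.factors, FACTOR_CODES):
            df[f.name] = [f.levels[i] for i in self.levels[:, FACTOR_CODES.index(col)]]
        return df


def generate_design(
    factors: Sequence[Factor] = DEFAULT_FACTORS,
    generator: Sequence[int] = (1, 1, 1, 1),
) -> DesignTable:
    """Build the 81-run regular 3^(5-1) fraction.

    ``generator`` gives the GF(3) coefficients (cA, cB, cC, cD) in the
    defining relation for E; every coefficient must be nonzero, otherwise a
    main effect would be aliased with another main effect.
    """
    factors = tuple(factors)
    if len(factors) != 5:
        raise ValueError("exactly five factors required")
    gen = tuple(int(g) % 3 for g in generator)
    if len(gen) != 4 or any(g == 0 for g in gen):
        raise ValueError(
            "generator must give four nonzero GF(3) coefficients for A..D; "
            "a zero coefficient confounds main effects with each other"
        )
    base = np.array(list(product(range(3), repeat=4)), dtype=int)  # lexicographic
    e = (base @ np.array(gen)) % 3
    levels = np.column_stack([base, e])
    return DesignTable(levels=levels, generator=gen, factors=factors)


@dataclass
class DesignReport:
    """Validation outcome for a design table."""

    n_runs_ok: bool
    unique_ok: bool
    one_factor_balance_ok: bool
    two_factor_balance_ok: bool
    messages: list[str] = field(default_factory=list)
    confounding: str = ""

    @property
    def ok(self) -> bool:
        return (
            self.n_runs_ok
            and self.unique_ok
            and self.one_factor_balance_ok
            and self.two_factor_balance_ok
        )


def validate_design(t: DesignTable) -> DesignReport:
    """Check run count (81), uniqueness, and one-/two-factor balance (27/9)."""
    msgs: list[str] = []
    n_ok = t.n_runs == 81
    if not n_ok:
        msgs.append(f"expected 81 runs for a 3^(5-1) fraction, found {t.n_runs}")
    uniq = len({tuple(r) for r in t.levels}) == t.n_runs
    if not uniq:
        msgs.append("duplicate runs present")
    one_ok = True
    for j, code in enumerate(FACTOR_CODES):
        counts = np.bincount(t.levels[:, j], minlength=3)
        if not np.all(counts == t.n_runs // 3):
            one_ok = False
            msgs.append(f"factor {code} level counts {counts.tolist()} != balanced")
    two_ok = True
    for j, k in combinations(range(5), 2):
        pair_counts = np.zeros((3, 3), dtype=int)
        np.add.at(pair_counts, (t.levels[:, j], t.levels[:, k]), 1)
        if not np.all(pair_counts == t.n_runs // 9):
            two_ok = False
            msgs.append(
                f"factor pair {FACTOR_CODES[j]}{FACTOR_CODES[k]} not orthogonal"
            )
    gen_terms = " + ".join(
        f"{c if c != 1 else ''}{code}".strip()
        for c, code in zip(t.generator, FACTOR_CODES[:4])
    )
    confounding = (
        f"defining relation E = {gen_terms} (mod 3); the defining word "
        "I = cA*A + cB*B + cC*C + cD*D + 2E has length 5, so two-way "
        "interactions are aliased only with three-way or higher terms"
    )
    return DesignReport(n_ok, uniq, one_ok, two_ok, msgs, confounding)


def resolve_conditions(t: DesignTable) -> list[ConditionSet]:
    """Materialize each run as physical factor values."""
    named = {f.name: f for f in t.factors}
    out = []
    for i, row in enumerate(t.levels, start=1):
        vals = {
            f.name: f.levels[row[j]] for j, f in enumerate(t.factors)
        }
        out.append(
            ConditionSet(
                run_id=i,
                additive=str(vals.get("additive")),
                conc_mM=float(vals.get("conc_mM")),
                sheath_C=float(vals.get("sheath_C")),
                capillary_V=float(vals.get("capillary_V")),
                nozzle_V=float(vals.get("nozzle_V")),
                levels=tuple(int(x) for x in row),
            )
        )
    return out


def read_design_csv(path: str | Path, factors: Sequence[Factor] = DEFAULT_FACTORS) -> DesignTable:
    """Re-import a design exported by :meth:`DesignTable.to_frame`."""
    df = pd.read_csv(path)
    cols = [f"{c}_level" for c in FACTOR_CODES]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"design CSV missing columns: {sorted(missing)}")
    levels = df[cols].to_numpy(int)
    # infer generator from the first rows: E = sum(c_j * level_j) mod 3
    # solved over GF(3) from the table itself; fall back to (1,1,1,1)
    gen = _infer_generator(levels)
    return DesignTable(levels=levels, generator=gen, factors=tuple(factors))


def _infer_generator(levels: np.ndarray) -> tuple[int, int, int, int]:
    base, e = levels[:, :4], levels[:, 4]
    for cand in product((1, 2), repeat=4):
        if np.all((base @ np.array(cand)) % 3 == e):
            return cand
    return (1, 1, 1, 1)
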