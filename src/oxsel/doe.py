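"""ANOVA and Tukey-based selection of optimal ionization conditions.

The selectivity factor measured over the 81-run fraction is decomposed into
the five main effects (2 df each) and the ten two-way interactions (4 df
each) by ordinary least squares; on the balanced orthogonal fraction the
sequential (type-I) sums of squares coincide with types II/III. Tukey's
studentized-range comparisons of factor-level means use the residual mean
square of the full factorial model as the error term. Condition ranking
standardizes selectivity within each response (species x oxidation degree)
before averaging, so responses with large absolute selectivities do not
dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .design import DesignTable, FACTOR_CODES

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "Recommendation",
    "fit_anova",
    "tukey_comparisons",
    "recommend_conditions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects decomposition of one selectivity response."""

    table: pd.DataFrame  # term, df, sum_sq, mean_sq, F, p
    residual_df: float
    residual_ss: float
    response: str
    transform: str | None
    data: pd.DataFrame = field(repr=False)  # y + factor levels actually fitted
    n_excluded: int = 0

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return t.loc[t["p"] < alpha, "term"].tolist()


@dataclass(frozen=True)
class TukeyResult:
    """Simultaneous pairwise level comparisons for one factor."""

    factor: str
    table: pd.DataFrame  # level_a, level_b, diff, lo, hi, p_adj, significant
    alpha: float

    def winners(self) -> list[int]:
        """Levels not significantly worse than the best level's mean."""
        means = self._level_means()
        best = max(means, key=means.get)
        losers = set()
        for _, row in self.table.iterrows():
            if row["significant"]:
                a, b = int(row["level_a"]), int(row["level_b"])
                losers.add(a if means[a] < means[b] else b)
        return [lv for lv in sorted(means) if lv not in losers or lv == best]

    def _level_means(self) -> dict[int, float]:
        means: dict[int, float] = {}
        for _, row in self.table.iterrows():
            means[int(row["level_a"])] = row["mean_a"]
            means[int(row["level_b"])] = row["mean_b"]
        return means


def _attach_levels(records: pd.DataFrame, design: DesignTable) -> pd.DataFrame:
    # factor columns are prefixed (fA..fE): a bare column named "C" would
    # shadow the categorical marker in the model formula
    levels = pd.DataFrame(
        design.levels, columns=[f"f{c}" for c in FACTOR_CODES]
    )
    levels.insert(0, "condition_set", np.arange(1, design.n_runs + 1))
    unknown = set(records["condition_set"]) - set(levels["condition_set"])
    if unknown:
        raise ValueError(f"records reference unknown condition sets: {sorted(unknown)}")
    return records.merge(levels, on="condition_set", how="left")


def fit_anova(
    records: pd.DataFrame,
    design: DesignTable,
    response: str = "selectivity",
    transform: str | None = None,
    include_interactions: bool = True,
) -> AnovaResult:
    """Fit the 5-main-effect + 10-two-way-interaction ANOVA for one response.

    ``records`` holds one row per replicate with columns ``condition_set``
    and the response (typically from ``batch_selectivity(aggregate=False)``
    filtered to a single species x ox degree). Non-finite responses (missing
    replicates, infinite-selectivity sentinels already recorded as NaN) are
    excluded with a logged count. ``transform='log'`` fits log selectivity.

    Raises if the model would be saturated (zero residual degrees of
    freedom): without replication the full two-way model leaves no error
    term, and either replicate data or ``include_interactions=False`` is
    required.
    """
    if "condition_set" not in records.columns or response not in records.columns:
        raise ValueError(f"records need 'condition_set' and {response!r} columns")
    df = _attach_levels(records[["condition_set", response]].copy(), design)
    y = df[response].to_numpy(float)
    keep = np.isfinite(y)
    n_excluded = int((~keep).sum())
    if n_excluded:
        log.info("fit_anova: excluding %d non-finite response values", n_excluded)
    df = df.loc[keep].copy()
    if transform == "log":
        if (df[response] <= 0).any():
            raise ValueError("log transform requires strictly positive selectivity")
        df["y"] = np.log(df[response])
    elif transform is None:
        df["y"] = df[response]
    else:
        raise ValueError(f"unknown transform {transform!r}")

    mains = [f"C(f{c})" for c in FACTOR_CODES]
    terms = list(mains)
    if include_interactions:
        terms += [f"C(f{a}):C(f{b})" for a, b in combinations(FACTOR_CODES, 2)]
    model_df = sum(2 for _ in mains) + (40 if include_interactions else 0)
    if len(df) - 1 - model_df <= 0:
        raise ValueError(
            "saturated model: no residual degrees of freedom; provide replicate "
            "measurements or set include_interactions=False"
        )
    for c in FACTOR_CODES:
        present = df[f"f{c}"].nunique()
        if present < 3:
            raise ValueError(
                f"factor {c} has only {present} level(s) left after exclusions; "
                "its effect is not estimable for this response"
            )
    fit = smf.ols("y ~ " + " + ".join(terms), data=df).fit()
    an = anova_lm(fit, typ=1)
    resid = an.loc["Residual"]
    rows = []
    for term in terms:
        r = an.loc[term]
        label = term.replace("C(f", "").replace(")", "").replace(":", "")
        rows.append(
            {
                "term": label,
                "df": float(r["df"]),
                "sum_sq": float(r["sum_sq"]),
                "mean_sq": float(r["sum_sq"]) / float(r["df"]),
                "F": float(r["F"]),
                "p": float(r["PR(>F)"]),
            }
        )
    return AnovaResult(
        table=pd.DataFrame(rows),
        residual_df=float(resid["df"]),
        residual_ss=float(resid["sum_sq"]),
        response=response,
        transform=transform,
        data=df,
        n_excluded=n_excluded,
    )


def tukey_comparisons(
    fit: AnovaResult, factor: str, alpha: float = 0.05
) -> TukeyResult:
    """Tukey(-Kramer) comparisons of the three level means of one factor.

    Uses the residual mean square of the fitted factorial model as error
    term and the studentized-range distribution for simultaneous coverage at
    family level ``alpha``.
    """
    if factor not in FACTOR_CODES:
        raise ValueError(f"factor must be one of {FACTOR_CODES}")
    if fit.residual_df <= 0:
        raise ValueError("Tukey comparisons require residual degrees of freedom")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    g = fit.data.groupby(f"f{factor}")["y"]
    means, counts = g.mean(), g.size()
    k = len(means)
    mse = fit.residual_ms
    qcrit = studentized_range.ppf(1 - alpha, k, fit.residual_df)
    rows = []
    for a, b in combinations(sorted(means.index), 2):
        diff = means[b] - means[a]
        se = np.sqrt(mse / 2 * (1 / counts[a] + 1 / counts[b]))
        half = qcrit * se
        if se == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            p_adj = float(studentized_range.sf(abs(diff) / se, k, fit.residual_df))
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_a": means[a],
                "mean_b": means[b],
                "diff": diff,
                "lo": diff - half,
                "hi": diff + half,
                "p_adj": min(1.0, p_adj),
                "significant": p_adj < alpha,
            }
        )
    return TukeyResult(factor=factor, table=pd.DataFrame(rows), alpha=alpha)


@dataclass(frozen=True)
class Recommendation:
    """Ranked condition sets and per-factor level advice."""

    ranking: pd.DataFrame  # condition_set, score, mean_sd, rank
    factor_levels: dict[str, list[int]]  # factor -> recommended level indices
    flags: tuple[str, ...] = ()

    @property
    def best_condition(self) -> int:
        return int(self.ranking.iloc[0]["condition_set"])


def recommend_conditions(
    fits: Mapping[str, AnovaResult],
    records: pd.DataFrame,
    alpha: float = 0.05,
    flat_tol: float = 1e-9,
) -> Recommendation:
    """Select optimal conditions across one or more selectivity responses.

    ``records`` is the replicate-averaged batch table (columns sample,
    species, ox_degree, condition_set, selectivity, sd). Selectivity is
    z-standardized within each response before averaging across responses;
    condition sets are ranked by that mean score with ties broken by lower
    mean replicate SD. Per-factor recommendations list the Tukey-winning
    levels (those not significantly below the best level) aggregated over
    responses by majority.
    """
    if not fits:
        raise ValueError("at least one fitted response required")
    df = records.copy()
    df["response"] = (
        df["sample"].astype(str)
        + "/"
        + df["species"].astype(str)
        + "/"
        + df["ox_degree"].astype(str)
    )
    flags: list[str] = []

    def _zscore(g: pd.Series) -> pd.Series:
        sd = g.std(ddof=0)
        if not np.isfinite(sd) or sd <= flat_tol:
            return pd.Series(np.zeros(len(g)), index=g.index)
        return (g - g.mean()) / sd

    df["z"] = df.groupby("response")["selectivity"].transform(_zscore)
    if np.allclose(df["z"], 0, atol=flat_tol):
        flags.append("no discrimination")
    ranking = (
        df.groupby("condition_set")
        .agg(score=("z", "mean"), mean_sd=("sd", "mean"))
        .reset_index()
        .sort_values(["score", "mean_sd"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    votes: dict[str, dict[int, int]] = {c: {} for c in FACTOR_CODES}
    for fit in fits.values():
        for code in FACTOR_CODES:
            try:
                tk = tukey_comparisons(fit, code, alpha=alpha)
            except ValueError:
                continue
            for lv in tk.winners():
                votes[code][lv] = votes[code].get(lv, 0) + 1
    factor_levels = {}
    for code, v in votes.items():
        if not v:
            factor_levels[code] = [0, 1, 2]
            continue
        top = max(v.values())
        factor_levels[code] = sorted(lv for lv, n in v.items() if n == top)
    return Recommendation(
        ranking=ranking, factor_levels=factor_levels, flags=tuple(flags)
    )
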