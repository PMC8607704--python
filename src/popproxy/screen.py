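"""Inter-population differentiation screen.

Traits enter the distance-matrix stage only if they differ significantly
between populations.  Per trait the screen checks ANOVA assumptions
(Shapiro-Wilk normality of residuals, Levene homogeneity of variances with
mean centring), log-transforms and retests on failure, and falls back to the
rank-based Kruskal-Wallis H test when the transformed data still violate
them.  Traits with p >= alpha are excluded from distance construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TraitScreenEntry:
    trait: str
    test: str              # "ANOVA" or "KW"
    statistic: float
    df: tuple
    p: float
    transformed: bool
    retained: bool


@dataclass
class ScreenResult:
    alpha: float
    entries: dict[str, TraitScreenEntry] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return [t for t, e in self.entries.items() if e.retained]

    def to_records(self) -> list[dict]:
        return [
            {
                "trait": e.trait, "test": e.test, "statistic": e.statistic,
                "df": list(e.df), "p": e.p, "transformed": e.transformed,
                "retained": e.retained,
            }
            for e in self.entries.values()
        ]


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA. Returns (F, df_between, df_within, p).

    All-identical values make the F ratio 0/0: raised as ValueError.  Zero
    within-group variance with distinct means returns the +inf sentinel with
    p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("ANOVA undefined: all values identical (0/0)")
        return math.inf, df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with ties correction. Returns (H, df, p).

    All-identical values give H = 0, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    df = len(groups) - 1
    concat = np.concatenate(groups)
    if np.all(concat == concat[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def _assumptions_ok(groups: list[np.ndarray], alpha: float) -> bool:
    residuals = np.concatenate([g - g.mean() for g in groups])
    if np.allclose(residuals, residuals[0]):
        return False
    sw_p = stats.shapiro(residuals).pvalue
    lev_p = stats.levene(*groups, center="mean").pvalue
    return sw_p >= alpha and lev_p >= alpha


def screen_traits(table: pd.DataFrame, alpha: float = 0.05) -> ScreenResult:
    """Screen every trait column of a (population, tank)-indexed table.

    Decision rule per trait: test assumptions on the raw values; on failure,
    natural-log transform and retest; if assumptions still fail (or values
    are non-positive so the log is unavailable) use Kruskal-Wallis, else
    ANOVA.  ``retained`` means p < alpha.
    """
    if table.index.nlevels < 1:
        raise ValueError("table must be indexed by (population, tank)")
    pops = table.index.get_level_values(0)
    if pops.nunique() < 2:
        raise ValueError("need >= 2 populations")
    result = ScreenResult(alpha=alpha)
    for trait in table.columns:
        values = table[trait].astype(float)
        if values.isna().any():
            raise ValueError(f"trait {trait!r} has missing values")
        groups = [values[pops == p].to_numpy() for p in pops.unique()]
        entry = _screen_one(trait, groups, alpha)
        result.entries[trait] = entry
        logger.info(
            "screen %s: %s stat=%.4g p=%.4g %s", trait, entry.test,
            entry.statistic, entry.p, "retained" if entry.retained else "excluded",
        )
    return result


def _screen_one(trait: str, groups: list[np.ndarray], alpha: float) -> TraitScreenEntry:
    concat = np.concatenate(groups)
    if np.all(concat == concat[0]):  # constant trait
        h, df, p = kruskal_wallis(groups)
        return TraitScreenEntry(trait, "KW", h, (df,), p, False, p < alpha)
    transformed = False
    use_kw = False
    if not _assumptions_ok(groups, alpha):
        if np.all(concat > 0):
            transformed = True
            log_groups = [np.log(g) for g in groups]
            if _assumptions_ok(log_groups, alpha):
                groups = log_groups
            else:
                use_kw = True
        else:
            logger.warning("trait %s: non-positive values, log transform unavailable; using Kruskal-Wallis", trait)
            use_kw = True
    if use_kw:
        h, df, p = kruskal_wallis(groups)
        return TraitScreenEntry(trait, "KW", h, (df,), p, transformed, p < alpha)
    try:
        f, df1, df2, p = one_way_anova(groups)
    except ValueError:
        h, df, p = kruskal_wallis(groups)
        return TraitScreenEntry(trait, "KW", h, (df,), p, transformed, p < alpha)
    return TraitScreenEntry(trait, "ANOVA", f, (df1, df2), p, transformed, p < alpha)
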