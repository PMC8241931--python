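"""Root colonization statistics from CFU plate counts.

Colony counts are converted to cfu per gram of root tissue, log10
transformed (with a +1 offset so zero counts remain finite), and analyzed
with a two-way ANOVA (genotype × strain) and Tukey HSD post-hoc tests.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .models import ConfigurationError, DataError

CFU_COLUMNS = (
    "genotype",
    "strain",
    "colonies",
    "plated_volume_ul",
    "homogenate_volume_ul",
    "dilution_factor",
    "root_mass_g",
)


def cfu_per_gram(
    colonies,
    plated_volume_ul: float,
    homogenate_volume_ul: float,
    dilution_factor: float,
    root_mass_g: float,
) -> float:
    """cfu g⁻¹ = mean(colonies) × (homogenate/plated volume) × dilution / mass.

    ``colonies`` may be a single plate count or a sequence of replicate
    plate counts (averaged).
    """
    if root_mass_g <= 0:
        raise DataError("root mass must be positive")
    if plated_volume_ul <= 0 or homogenate_volume_ul <= 0:
        raise DataError("volumes must be positive")
    if dilution_factor < 1:
        raise DataError("dilution_factor must be >= 1")
    mean_colonies = float(np.mean(np.asarray(colonies, dtype=float)))
    if mean_colonies < 0:
        raise DataError("negative colony count")
    return mean_colonies * (homogenate_volume_ul / plated_volume_ul) * dilution_factor / root_mass_g


def cfu_table_to_log10(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``cfu_per_g`` and ``log10_cfu_per_g`` columns to a CFU table."""
    missing = set(CFU_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"CFU table missing columns: {sorted(missing)}")
    out = table.copy()
    out["cfu_per_g"] = [
        cfu_per_gram(
            r["colonies"],
            r["plated_volume_ul"],
            r["homogenate_volume_ul"],
            r["dilution_factor"],
            r["root_mass_g"],
        )
        for _, r in table.iterrows()
    ]
    out["log10_cfu_per_g"] = np.log10(out["cfu_per_g"] + 1.0)
    return out


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
) -> pd.DataFrame:
    """Two-way ANOVA with interaction; sequential (Type I) sums of squares.

    Returns the table with rows ``factor_a``, ``factor_b``,
    ``factor_a:factor_b`` and ``Residual`` and columns
    ``df, sum_sq, mean_sq, F, p``. Unbalanced designs are accepted with a
    warning (Type I SS then depend on factor order).
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": list(factor_a), "b": list(factor_b)}
    )
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise DataError("each factor needs at least 2 levels")
    cells = df.groupby(["a", "b"], observed=True).size()
    if len(cells) < df["a"].nunique() * df["b"].nunique():
        raise DataError("empty factor cell; two-way ANOVA with interaction needs all cells")
    if (cells < 2).any():
        raise DataError("every factor cell needs at least 2 replicates")
    if cells.nunique() > 1:
        warnings.warn(
            "unbalanced design: sequential (Type I) sums of squares depend on "
            "factor order",
            stacklevel=2,
        )

    if np.ptp(df["y"].to_numpy()) == 0:
        # degenerate: no variance anywhere; guard the 0/0 F ratios
        n = len(df)
        a_lev, b_lev = df["a"].nunique(), df["b"].nunique()
        rows = {
            "factor_a": (a_lev - 1),
            "factor_b": (b_lev - 1),
            "factor_a:factor_b": (a_lev - 1) * (b_lev - 1),
            "Residual": n - a_lev * b_lev,
        }
        out = pd.DataFrame(
            {
                "df": list(rows.values()),
                "sum_sq": 0.0,
                "mean_sq": 0.0,
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=list(rows.keys()),
        )
        return out

    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        index={"C(a)": "factor_a", "C(b)": "factor_b", "C(a):C(b)": "factor_a:factor_b"},
        columns={"PR(>F)": "p"},
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]
    return table[["df", "sum_sq", "mean_sq", "F", "p"]]


def tukey_hsd(
    values: Sequence[float],
    groups: Sequence[str],
    ms_resid: Optional[float] = None,
    df_resid: Optional[int] = None,
) -> pd.DataFrame:
    """Tukey honest-significant-difference pairwise comparisons.

    By default the residual mean square is the pooled within-group variance
    (one-way); an ANOVA residual MS and df can be supplied instead. The
    studentized range statistic uses the Tukey–Kramer standard error for
    unequal group sizes. Returns one row per pair with ``q`` and adjusted
    ``p`` from the studentized range distribution.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(list(groups), dtype=object)
    levels = sorted(set(g), key=str)
    k = len(levels)
    if k < 2:
        raise DataError("Tukey HSD needs at least 2 groups")
    means = {lev: y[g == lev].mean() for lev in levels}
    ns = {lev: int((g == lev).sum()) for lev in levels}
    if ms_resid is None or df_resid is None:
        df_resid = len(y) - k
        if df_resid <= 0:
            raise DataError("no residual degrees of freedom")
        ms_resid = sum(((y[g == lev] - means[lev]) ** 2).sum() for lev in levels) / df_resid
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = means[b] - means[a]
            se = np.sqrt(ms_resid / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "mean_diff": diff,
                    "q": q,
                    "p_adj": min(1.0, p),
                    "significant_0.05": p < 0.05,
                }
            )
    return pd.DataFrame(rows)


def analyze_cfu(table: pd.DataFrame) -> dict:
    """Full colonization analysis: cfu/g, log transform, ANOVA, Tukey HSD."""
    log_table = cfu_table_to_log10(table)
    anova = two_way_anova(
        log_table["log10_cfu_per_g"], log_table["genotype"], log_table["strain"]
    )
    ms_resid = float(anova.loc["Residual", "mean_sq"])
    df_resid = int(anova.loc["Residual", "df"])
    tukey = tukey_hsd(
        log_table["log10_cfu_per_g"],
        log_table["genotype"],
        ms_resid=ms_resid if np.isfinite(ms_resid) and ms_resid > 0 else None,
        df_resid=df_resid if np.isfinite(ms_resid) and ms_resid > 0 else None,
    )
    return {"log_table": log_table, "anova": anova, "tukey_genotype": tukey}
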