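"""Between-stratum endpoint comparisons and box-plot summary statistics.

Each of the 30 signaling endpoints is compared between two strata with an
independent-samples t-test (Welch by default; a pooled-variance variant is
available), two-sided, significant at p < 0.05.  Two contrast families are
supported: epithelium vs stroma within a ratio group, and high vs low ratio
within a compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    endpoint: str
    stratum_a: str
    stratum_b: str
    mean_a: float
    mean_b: float
    t_statistic: float | None
    df: float | None
    p_value: float | None
    significant: bool


@dataclass(frozen=True)
class BoxplotSummary:
    endpoint: str
    stratum: str
    median: float
    mean: float
    q25: float
    q75: float
    minimum: float
    maximum: float
    n: int


def compare_endpoint(
    values_a,
    values_b,
    alpha: float = DEFAULT_ALPHA,
    endpoint: str = "",
    stratum_a: str = "a",
    stratum_b: str = "b",
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sided independent-samples t-test between two strata.

    Welch (unequal-variance) by default; ``equal_var=True`` for the pooled
    test.  Samples with fewer than two values, or with zero variance in both
    groups, are untestable and reported with p absent (``None``).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    mean_a = float(a.mean()) if a.size else float("nan")
    mean_b = float(b.mean()) if b.size else float("nan")
    if a.size < 2 or b.size < 2 or (a.std() == 0 and b.std() == 0):
        return ComparisonResult(
            endpoint, stratum_a, stratum_b, mean_a, mean_b, None, None, None, False
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    t = float(res.statistic)
    p = float(res.pvalue)
    return ComparisonResult(
        endpoint, stratum_a, stratum_b, mean_a, mean_b, t, df, p, bool(p < alpha)
    )


def compare_all(
    reduced_wide: pd.DataFrame,
    group_labels: dict[str, str],
    contrast: str,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = False,
    exclude_cases: set[str] | None = None,
) -> pd.DataFrame:
    """One ComparisonResult per endpoint per contrast.

    ``contrast`` is one of:

    * ``"compartment-within-group"`` — epithelium vs stroma, separately in the
      high- and low-ratio groups;
    * ``"compartment-overall"`` — epithelium vs stroma across all cases;
    * ``"group-within-compartment"`` — high vs low ratio, separately in each
      compartment.

    ``reduced_wide`` is indexed by (case_id, compartment).
    """
    known = {"compartment-within-group", "compartment-overall", "group-within-compartment"}
    if contrast not in known:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {sorted(known)}")
    exclude_cases = exclude_cases or set()
    bad = set(group_labels.values()) - {"high", "low"}
    if bad:
        raise ValueError(f"unknown stratum label(s): {sorted(bad)}")

    df = reduced_wide[~reduced_wide.index.get_level_values("case_id").isin(exclude_cases)]
    comps = sorted(df.index.get_level_values("compartment").unique())
    case_group = pd.Series(group_labels)

    def subset(group: str | None, comp: str | None) -> pd.DataFrame:
        sel = df
        if comp is not None:
            sel = sel.xs(comp, level="compartment")
        else:
            sel = sel.droplevel("compartment")
        if group is not None:
            keep = [c for c in sel.index if case_group.get(c) == group]
            sel = sel.loc[keep]
        return sel

    pairs: list[tuple[str, pd.DataFrame, str, pd.DataFrame]] = []
    if contrast == "compartment-within-group":
        for grp in ("high", "low"):
            a = df[df.index.get_level_values("case_id").map(case_group) == grp]
            pairs.append(
                (
                    f"{grp}-ratio {comps[0]}",
                    a.xs(comps[0], level="compartment"),
                    f"{grp}-ratio {comps[1]}",
                    a.xs(comps[1], level="compartment"),
                )
            )
    elif contrast == "compartment-overall":
        pairs.append(
            (
                comps[0],
                df.xs(comps[0], level="compartment"),
                comps[1],
                df.xs(comps[1], level="compartment"),
            )
        )
    else:  # group-within-compartment
        for comp in comps:
            sub = df.xs(comp, level="compartment")
            grp = sub.index.map(case_group)
            pairs.append(
                (
                    f"high-ratio {comp}",
                    sub[grp == "high"],
                    f"low-ratio {comp}",
                    sub[grp == "low"],
                )
            )

    rows = []
    for label_a, da, label_b, db in pairs:
        for endpoint in reduced_wide.columns:
            r = compare_endpoint(
                da[endpoint].to_numpy(),
                db[endpoint].to_numpy(),
                alpha=alpha,
                endpoint=endpoint,
                stratum_a=label_a,
                stratum_b=label_b,
                equal_var=equal_var,
            )
            rows.append(r.__dict__)
    return pd.DataFrame(rows)


def boxplot_summary(values, endpoint: str = "", stratum: str = "") -> BoxplotSummary:
    """Order statistics for one stratum (quartiles by linear interpolation)."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("boxplot_summary needs a non-empty sample")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return BoxplotSummary(
        endpoint=endpoint,
        stratum=stratum,
        median=float(med),
        mean=float(v.mean()),
        q25=float(q25),
        q75=float(q75),
        minimum=float(v.min()),
        maximum=float(v.max()),
        n=int(v.size),
    )


def boxplot_table(
    reduced_wide: pd.DataFrame,
    group_labels: dict[str, str],
    exclude_cases: set[str] | None = None,
) -> pd.DataFrame:
    """Box-plot summaries per endpoint per group x compartment stratum."""
    exclude_cases = exclude_cases or set()
    df = reduced_wide[~reduced_wide.index.get_level_values("case_id").isin(exclude_cases)]
    case_group = pd.Series(group_labels)
    rows = []
    for comp in sorted(df.index.get_level_values("compartment").unique()):
        sub = df.xs(comp, level="compartment")
        grp = sub.index.map(case_group)
        for g in ("high", "low"):
            part = sub[grp == g]
            for endpoint in part.columns:
                vals = part[endpoint].dropna()
                if vals.empty:
                    continue
                rows.append(
                    boxplot_summary(
                        vals, endpoint=endpoint, stratum=f"{g}-ratio {comp}"
                    ).__dict__
                )
    return pd.DataFrame(rows)
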