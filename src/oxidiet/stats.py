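"""Assumption-routed multi-group comparisons with Fisher LSD post-hoc.

The comparison engine used throughout the pipeline, mirroring the standard
workflow of diet-intervention studies:

1. **Assumption check** — per-group normality (Shapiro–Wilk) and
   homogeneity of variances (Brown–Forsythe, i.e. median-centred Levene),
   each at a routing level α.  Any failure routes the variable to the
   nonparametric branch.
2. **Omnibus test** — one-way ANOVA (parametric) or Kruskal–Wallis
   (nonparametric), missing values dropped.
3. **Pairwise post-hoc** — Fisher's least significant difference: pairwise
   t statistics using the pooled mean-square error and residual degrees of
   freedom of the full one-way model.  LSD is *unadjusted by definition*;
   no multiplicity correction is applied.  On the nonparametric branch the
   pairwise step is an unadjusted two-sided Mann–Whitney U test (midrank
   ties), mirroring LSD's unadjusted philosophy.
4. **Annotation** — star flags (``*`` p < 0.05, ``**`` p < 0.01, strict
   inequalities) against a reference group, and ``+``/``−`` direction
   marks for significant pairs, matching the sign of the group-mean
   difference.

The model/results split follows statsmodels: build a :class:`GroupComparison`
from data, call :meth:`~GroupComparison.fit`, and read estimates,
p-values and the annotation table off the returned
:class:`GroupComparisonResults`.

Pairwise tests are computed unconditionally rather than gated on omnibus
significance: the per-comparison operating level of unadjusted LSD is then
the nominal α, which is what null-calibration checks of the full route
measure.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "GroupComparisonResults",
    "check_assumptions",
    "omnibus_test",
    "fisher_lsd",
    "compare_variables",
    "render_group_table",
    "DEFAULT_GROUP_ORDER",
]

DEFAULT_GROUP_ORDER = ("STD", "HFHS", "HFHS+ω3")

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


def _clean_groups(
    data: Mapping[str, Iterable[float]],
) -> dict[str, np.ndarray]:
    """Drop missing values; keep insertion order of groups."""
    out: dict[str, np.ndarray] = {}
    for g, vals in data.items():
        arr = np.asarray(list(vals), dtype=float)
        out[str(g)] = arr[np.isfinite(arr)]
    return out


def check_assumptions(
    data: Mapping[str, Iterable[float]],
    alpha: float = 0.05,
) -> tuple[str, list[str]]:
    """Decide the test route for one variable.

    Returns ``(route, warnings)`` where route is ``"parametric"`` or
    ``"nonparametric"``.  Nonparametric is chosen when any per-group
    Shapiro–Wilk p < alpha, the Brown–Forsythe p < alpha, or an assumption
    is untestable (a group with fewer than 3 observations, or a constant
    group, where the normality statistic is undefined).
    """
    groups = _clean_groups(data)
    usable = {g: v for g, v in groups.items() if v.size >= 2}
    warns: list[str] = []
    route = PARAMETRIC
    for g, vals in usable.items():
        if vals.size < 3:
            warns.append(f"group {g!r}: <3 observations, normality untestable")
            route = NONPARAMETRIC
            continue
        if np.ptp(vals) == 0:
            warns.append(f"group {g!r}: constant values, normality untestable")
            route = NONPARAMETRIC
            continue
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            p_norm = sps.shapiro(vals).pvalue
        if p_norm < alpha:
            route = NONPARAMETRIC
    if len(usable) >= 2 and all(np.ptp(v) > 0 for v in usable.values()):
        p_var = sps.levene(*usable.values(), center="median").pvalue
        if not np.isfinite(p_var) or p_var < alpha:
            route = NONPARAMETRIC
    return route, warns


def omnibus_test(
    data: Mapping[str, Iterable[float]],
    route: str,
) -> tuple[float, float]:
    """Omnibus statistic and p-value: ANOVA F or Kruskal–Wallis H.

    Missing values are dropped; groups left with < 2 observations are
    excluded.  Raises ``ValueError`` with fewer than two usable groups.
    An all-ties configuration (every observation identical) gives H = 0,
    p = 1 on the nonparametric route.
    """
    groups = [v for v in _clean_groups(data).values() if v.size >= 2]
    if len(groups) < 2:
        raise ValueError("fewer than 2 groups with >=2 observations")
    if route == PARAMETRIC:
        res = sps.f_oneway(*groups)
        return float(res.statistic), float(res.pvalue)
    if route == NONPARAMETRIC:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.kruskal(*groups)
        except ValueError:
            # scipy rejects the all-identical case; no evidence against H0
            return 0.0, 1.0
        if not np.isfinite(res.pvalue):  # all ties: H = 0/0
            return 0.0, 1.0
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown route {route!r}")


def _direction(mean_a: float, mean_b: float) -> str:
    if mean_b > mean_a:
        return "up"
    if mean_b < mean_a:
        return "down"
    return "none"


def fisher_lsd(
    data: Mapping[str, Iterable[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Fisher least-significant-difference pairwise comparisons.

    For each pair (a, b): ``t = (mean_a − mean_b) / sqrt(MSE (1/n_a +
    1/n_b))`` with the mean-square error and residual degrees of freedom
    taken from the *full* one-way model over all groups, two-sided p from
    the t distribution.  No multiplicity adjustment.  A zero MSE leaves p
    undefined (NaN).

    Returns a DataFrame with columns ``group_a, group_b, n_a, n_b, mean_a,
    mean_b, statistic, p, direction``; ``direction`` is the sign of
    ``mean_b − mean_a`` (up/down/none).
    """
    groups = {g: v for g, v in _clean_groups(data).items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("fewer than 2 groups with >=2 observations")
    if pairs is None:
        names = list(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    n_tot = sum(v.size for v in groups.values())
    k = len(groups)
    df_resid = n_tot - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_resid
    rows = []
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise KeyError(f"pair ({a!r}, {b!r}) names an unusable group")
        va, vb = groups[a], groups[b]
        ma, mb = va.mean(), vb.mean()
        if mse > 0:
            t = (ma - mb) / np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
            p = 2.0 * sps.t.sf(abs(t), df_resid)
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": va.size,
                "n_b": vb.size,
                "mean_a": ma,
                "mean_b": mb,
                "statistic": float(t),
                "p": float(p),
                "direction": _direction(ma, mb),
            }
        )
    return pd.DataFrame(rows)


def _pairwise_mwu(
    groups: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise KeyError(f"pair ({a!r}, {b!r}) names an unusable group")
        va, vb = groups[a], groups[b]
        res = sps.mannwhitneyu(va, vb, alternative="two-sided")
        ma, mb = va.mean(), vb.mean()
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": va.size,
                "n_b": vb.size,
                "mean_a": ma,
                "mean_b": mb,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "direction": _direction(ma, mb),
            }
        )
    return pd.DataFrame(rows)


class GroupComparison:
    """Comparison model for one variable observed in several groups.

    Parameters
    ----------
    data
        Mapping group label -> observations (NaN = missing, dropped).
        At least two groups must retain >= 2 observations.
    name
        Variable name used in summaries.
    routing_alpha
        Level of the assumption tests that route between the parametric
        and nonparametric branches (default 0.05).

    Examples
    --------
    >>> gc = GroupComparison({"STD": [1.0, 1.2, 0.9], "HFHS": [2.0, 2.2, 1.9]})
    >>> res = gc.fit()
    >>> res.route
    'parametric'
    """

    def __init__(
        self,
        data: Mapping[str, Iterable[float]],
        *,
        name: str = "value",
        routing_alpha: float = 0.05,
    ) -> None:
        self.name = name
        self.routing_alpha = float(routing_alpha)
        self.groups = _clean_groups(data)
        usable = [g for g, v in self.groups.items() if v.size >= 2]
        if len(usable) < 2:
            raise ValueError(
                f"{name!r}: need >=2 groups with >=2 non-missing observations"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_col: str = "value",
        group_col: str = "group",
        group_order: Sequence[str] | None = None,
        **kwargs,
    ) -> "GroupComparison":
        """Build from a tidy table with one observation per row."""
        if group_order is None:
            group_order = list(dict.fromkeys(df[group_col]))
        data = {
            g: df.loc[df[group_col] == g, value_col].to_numpy(dtype=float)
            for g in group_order
        }
        return cls(data, **kwargs)

    def fit(
        self,
        route: str | None = None,
        alpha: float = 0.05,
        pairs: Sequence[tuple[str, str]] | None = None,
    ) -> "GroupComparisonResults":
        """Run the route check, omnibus test and pairwise post-hoc.

        ``route`` overrides the automatic assumption-based routing;
        ``alpha`` is the significance level used for star/arrow
        annotation (strict inequality).
        """
        if route is None:
            route, warns = check_assumptions(self.groups, self.routing_alpha)
        else:
            if route not in (PARAMETRIC, NONPARAMETRIC):
                raise ValueError(f"unknown route {route!r}")
            warns = []
        stat, p = omnibus_test(self.groups, route)
        usable = {g: v for g, v in self.groups.items() if v.size >= 2}
        if pairs is None:
            names = list(usable)
            pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        if route == PARAMETRIC:
            pairwise = fisher_lsd(usable, pairs)
        else:
            pairwise = _pairwise_mwu(usable, pairs)
        return GroupComparisonResults(
            model=self,
            route=route,
            route_warnings=warns,
            omnibus_stat=stat,
            omnibus_p=p,
            pairwise=pairwise,
            alpha=alpha,
        )


def _stars(p: float, alpha: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < alpha / 5.0:  # 0.01 at the conventional alpha = 0.05
        return "**"
    if p < alpha:
        return "*"
    return ""


@dataclass
class GroupComparisonResults:
    """Fitted group-comparison results.

    Attributes
    ----------
    route : chosen branch, ``"parametric"`` or ``"nonparametric"``.
    omnibus_stat, omnibus_p : ANOVA F (or Kruskal–Wallis H) and its p.
    pairwise : DataFrame of pairwise tests (see :func:`fisher_lsd`).
    alpha : annotation significance level (strict).
    """

    model: GroupComparison
    route: str
    route_warnings: list[str]
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame
    alpha: float = 0.05

    def _pair_row(self, a: str, b: str) -> pd.Series | None:
        pw = self.pairwise
        hit = pw[(pw.group_a == a) & (pw.group_b == b)]
        if hit.empty:
            hit = pw[(pw.group_a == b) & (pw.group_b == a)]
            if hit.empty:
                return None
            row = hit.iloc[0].copy()
            row["mean_a"], row["mean_b"] = row["mean_b"], row["mean_a"]
            row["group_a"], row["group_b"] = row["group_b"], row["group_a"]
            row["direction"] = _direction(row["mean_a"], row["mean_b"])
            return row
        return hit.iloc[0]

    def flags(self, reference: str) -> dict[str, str]:
        """Star flags per non-reference group (``*`` p<0.05, ``**`` p<0.01)."""
        out: dict[str, str] = {}
        for g in self.model.groups:
            if g == reference:
                continue
            row = self._pair_row(reference, g)
            if row is not None:
                out[g] = _stars(row["p"], self.alpha)
        return out

    def arrows(self, reference: str) -> dict[str, str]:
        """``+``/``−`` direction marks vs the reference, significant pairs only."""
        out: dict[str, str] = {}
        for g in self.model.groups:
            if g == reference:
                continue
            row = self._pair_row(reference, g)
            if row is None:
                continue
            significant = np.isfinite(row["p"]) and row["p"] < self.alpha
            if significant and row["direction"] == "up":
                out[g] = "+"
            elif significant and row["direction"] == "down":
                out[g] = "−"
            else:
                out[g] = ""
        return out

    def summary(self) -> str:
        """Human-readable summary in the spirit of statsmodels results."""
        lines = [
            f"Group comparison: {self.model.name}",
            "=" * 60,
            f"route:    {self.route}"
            + (f"   ({'; '.join(self.route_warnings)})" if self.route_warnings else ""),
            "omnibus:  "
            + ("ANOVA F" if self.route == PARAMETRIC else "Kruskal-Wallis H")
            + f" = {self.omnibus_stat:.4g}, p = {self.omnibus_p:.4g}",
            "",
            "groups:",
        ]
        for g, v in self.model.groups.items():
            lines.append(
                f"  {g:>10}  n = {v.size:<3d} mean = {v.mean():.4g}  "
                f"sd = {v.std(ddof=1):.4g}"
            )
        lines += ["", "pairwise (unadjusted):", self.pairwise.to_string(index=False)]
        return "\n".join(lines)


def compare_variables(
    df: pd.DataFrame,
    *,
    variable_col: str = "variable",
    value_col: str = "value",
    group_col: str = "group",
    group_order: Sequence[str] | None = None,
    routing_alpha: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full route for every variable of a tidy long table.

    Returns one row per (variable, pair) with route, omnibus p, pairwise p,
    direction, and star flag for pairs involving any group.
    """
    rows = []
    for var, sub in df.groupby(variable_col, sort=False):
        try:
            model = GroupComparison.from_dataframe(
                sub,
                value_col=value_col,
                group_col=group_col,
                group_order=group_order,
                name=str(var),
                routing_alpha=routing_alpha,
            )
        except ValueError:
            continue  # too few usable groups (e.g. all-undefined spot)
        res = model.fit(alpha=alpha)
        for _, pw in res.pairwise.iterrows():
            rows.append(
                {
                    "variable": var,
                    "route": res.route,
                    "omnibus_p": res.omnibus_p,
                    "group_a": pw["group_a"],
                    "group_b": pw["group_b"],
                    "mean_a": pw["mean_a"],
                    "mean_b": pw["mean_b"],
                    "p": pw["p"],
                    "direction": pw["direction"],
                    "stars": _stars(pw["p"], alpha),
                }
            )
    return pd.DataFrame(rows)


def render_group_table(
    df: pd.DataFrame,
    *,
    variable_col: str = "variable",
    value_col: str = "value",
    group_col: str = "group",
    group_order: Sequence[str] | None = None,
    reference: str = "STD",
    ndigits: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Publication-style summary: ``mean (sd)`` cells, stars and arrows.

    One row per variable; per non-reference group a ``mean (sd)`` cell plus
    star flags vs the reference and ``+``/``−`` arrows for significant
    changes (vs the reference for the first comparison group, and vs the
    preceding group for later ones, matching the two published contrast
    columns HFHS/STD and HFHS+ω3/HFHS).
    """
    if group_order is None:
        group_order = [g for g in DEFAULT_GROUP_ORDER if g in set(df[group_col])]
        if not group_order:
            group_order = list(dict.fromkeys(df[group_col]))
    rows = []
    for var, sub in df.groupby(variable_col, sort=False):
        row: dict[str, object] = {"variable": var}
        try:
            model = GroupComparison.from_dataframe(
                sub, value_col=value_col, group_col=group_col,
                group_order=group_order, name=str(var),
            )
            res = model.fit(alpha=alpha)
        except ValueError:
            for g in group_order:
                vals = sub.loc[sub[group_col] == g, value_col].dropna()
                row[g] = (
                    f"{vals.mean():.{ndigits}f} ({vals.std(ddof=1):.{ndigits}f})"
                    if len(vals) > 1 else "undefined"
                )
            rows.append(row)
            continue
        for g in group_order:
            v = model.groups.get(g, np.array([]))
            if v.size < 2:
                row[g] = "undefined"
                continue
            cell = f"{v.mean():.{ndigits}f} ({v.std(ddof=1):.{ndigits}f})"
            if g != reference:
                stars = res.flags(reference).get(g, "")
                cell += f" {stars}" if stars else ""
            row[g] = cell
        # contrast columns: consecutive pairs in group order
        for a, b in zip(group_order[:-1], group_order[1:]):
            pw = res._pair_row(a, b)
            label = f"{b}/{a}"
            if pw is None:
                row[label] = ""
                continue
            sig = np.isfinite(pw["p"]) and pw["p"] < alpha
            glyph = {"up": "+", "down": "−"}.get(pw["direction"], "") if sig else ""
            row[label] = (glyph + " " + _stars(pw["p"], alpha)).strip()
        row["route"] = res.route
        rows.append(row)
    return pd.DataFrame(rows)
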