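"""Monte-Carlo calibration of the statistical route and the generator.

Simulation studies that characterise the pipeline's operating behaviour at
the study's sample sizes (3 groups × n = 9):

* per-comparison type-I error of the full route (assumption check →
  omnibus → unadjusted pairwise post-hoc) under the global null;
* detection power for the between-diet carbonylation effects implied by the
  published per-spot (mean, sd), and agreement of direction marks with the
  sign of the mean difference;
* recovery of the generator's distribution means at large n.

These functions are the basis of the package's self-checks; they are slow
relative to the rest of the test suite (seconds, not milliseconds) and
scale linearly in the replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CohortConfig, generate_cohort, generate_index_draws, \
    truncated_mean
from .stats import GroupComparison

__all__ = [
    "null_type_one_error",
    "effect_detection_sweep",
    "recovery_fraction",
]


def null_type_one_error(
    n_replicates: int = 5000,
    n_per_group: int = 9,
    n_groups: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Per-pair rejection rate of the full route under the global null.

    All groups drawn from one standard normal; every pairwise p < alpha
    counts as a (false) rejection.  Unadjusted LSD is calibrated
    per-comparison, so the rate should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    labels = [f"g{i}" for i in range(n_groups)]
    rejections = 0
    total = 0
    for _ in range(n_replicates):
        data = {g: rng.normal(0.0, 1.0, n_per_group) for g in labels}
        res = GroupComparison(data).fit(alpha=alpha)
        p = res.pairwise["p"].to_numpy()
        rejections += int((p[np.isfinite(p)] < alpha).sum())
        total += len(p)
    return rejections / total


@dataclass
class DetectionSweep:
    """Outcome of the per-spot power sweep over replicate cohorts."""

    detection_rate: pd.Series  # spot_id -> fraction of replicates flagged
    effect_size: pd.Series  # spot_id -> |standardized HFHS-vs-STD effect|
    arrows_consistent: int  # significant pairs whose mark matched the mean sign
    arrows_total: int

    def rates_at_effect(self, min_effect: float) -> pd.Series:
        return self.detection_rate[self.effect_size >= min_effect]


def effect_detection_sweep(
    config: CohortConfig,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    pair: tuple[str, str] = ("STD", "HFHS"),
) -> DetectionSweep:
    """Replicate cohorts at the configured spot parameters; flag rates.

    For each spot and replicate, index values are drawn at the configured
    per-group (mean, sd) with the cohort's n, the full comparison route is
    run, and the ``pair`` contrast is tested at ``alpha``.  Direction marks
    of every significant pair are checked against the sign of the group
    mean difference.
    """
    a, b = pair
    eff = {}
    for spot, per_group in config.spots.items():
        pa, pb = per_group[a], per_group[b]
        pooled = np.sqrt((pa.sd**2 + pb.sd**2) / 2.0)
        eff[spot] = abs(pb.mean - pa.mean) / pooled if pooled > 0 else np.inf
    flagged = {spot: 0 for spot in config.spots}
    arrows_ok = 0
    arrows_tot = 0
    for rep in range(n_replicates):
        draws = generate_index_draws(config, seed + rep)
        for spot, sub in draws.groupby("spot_id", sort=False):
            data = {
                g: sub.loc[sub.group == g, "index"].to_numpy()
                for g in config.groups
            }
            res = GroupComparison(data).fit(alpha=alpha)
            pw = res.pairwise
            hit = pw[(pw.group_a == a) & (pw.group_b == b)]
            if not hit.empty and np.isfinite(hit.p.iloc[0]) and hit.p.iloc[0] < alpha:
                flagged[spot] += 1
            for _, row in pw.iterrows():
                if np.isfinite(row.p) and row.p < alpha:
                    arrows_tot += 1
                    expected = "up" if row.mean_b > row.mean_a else "down"
                    arrows_ok += row.direction == expected
    return DetectionSweep(
        detection_rate=pd.Series(flagged, dtype=float) / n_replicates,
        effect_size=pd.Series(eff),
        arrows_consistent=arrows_ok,
        arrows_total=arrows_tot,
    )


def recovery_fraction(
    config: CohortConfig | None = None,
    n_per_group: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Check sample means against the generator's distribution means.

    Draws one large cohort (plus per-spot index draws) and compares every
    configured variable's per-group sample mean to its exact expectation —
    the truncated-normal mean, rescaled by compositional closure for fatty
    acids — within 3 standard errors (configured sd / sqrt(n); sd = 0
    variables are checked for exactness, fatty acids within the closure's
    sub-2%-relative perturbation).

    Returns a DataFrame with one row per (variable, group) and an ``ok``
    flag; the criterion of interest is ``ok.mean()``.
    """
    from .simulate import default_config

    if config is None:
        config = default_config()
    config = config.model_copy(update={"n_per_group": n_per_group})
    cohort = generate_cohort(config, seed)
    draws = generate_index_draws(config, seed + 1)
    rows = []

    def check(section, var, group, values, mean, sd, target):
        se = sd / np.sqrt(n_per_group)
        observed = float(np.mean(values))
        if sd > 0:
            ok = abs(observed - target) <= 3 * se
        elif section == "fatty_acid":
            ok = abs(observed - target) <= 1e-9 + 0.02 * target
        else:
            ok = np.allclose(values, target)
        rows.append(
            {
                "section": section,
                "variable": var,
                "group": group,
                "target": target,
                "observed": observed,
                "se": se,
                "ok": bool(ok),
            }
        )

    for var, per_group in config.scalars.items():
        for g, p in per_group.items():
            vals = cohort.scalars.loc[cohort.scalars.group == g, var]
            check("scalar", var, g, vals, p.mean, p.sd, truncated_mean(p.mean, p.sd))
    mu = {
        fa: {g: truncated_mean(pg[g].mean, pg[g].sd) for g in config.groups}
        for fa, pg in config.fatty_acids.items()
    }
    fa_tab = cohort.fatty_acids
    for name, per_group in config.fatty_acids.items():
        for g, p in per_group.items():
            total = sum(mu[f][g] for f in mu)
            target = 100.0 * mu[name][g] / total
            vals = fa_tab[(fa_tab.group == g) & (fa_tab.fa_name == name)].percent
            check("fatty_acid", name, g, vals, p.mean, p.sd, target)
    for spot, per_group in config.spots.items():
        for g, p in per_group.items():
            vals = draws[(draws.group == g) & (draws.spot_id == spot)]["index"]
            check("spot", spot, g, vals, p.mean, p.sd, truncated_mean(p.mean, p.sd))
    return pd.DataFrame(rows)
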