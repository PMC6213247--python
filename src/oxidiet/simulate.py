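"""Synthetic per-animal cohorts with the statistical structure of the study.

The source study published only group-level summaries (three diet groups —
standard chow, high-fat high-sucrose, and HFHS supplemented with EPA/DHA
1:1 — with n = 9 animals per group).  This generator draws per-animal
cohorts whose group means and standard deviations match those summaries, so
every pipeline stage (index computation, routing statistics, report tables)
runs end-to-end on data with realistic location, spread and effect sizes.

Model choices
-------------
* Scalar variables (biometrics, enzyme activities, conjugated dienes,
  per-spot carbonylation indexes) are drawn from a normal truncated at 0
  with the configured (mean, sd).  Printed s.d. are small relative to
  means, so truncation bias is negligible; s.d. = 0 yields the mean
  exactly.
* Fatty-acid percentages are drawn per acid (no published covariance
  structure) and then renormalized to a 100% compositional total — the
  renormalization induces the only cross-acid dependence.
* 2-D densitometry is generated backwards from the quantity of interest:
  per spot, a Coomassie (protein-amount) intensity is drawn log-normal and
  the FTSC (carbonyl) intensity is the product of a truncated-normal
  carbonylation-index draw with that Coomassie intensity, so the raw-ratio
  index recovers the configured distribution exactly.  Designated
  low-abundance spots (analogues of the study's intensely fluorescent but
  Coomassie-undetectable spots A–E) are drawn below the Coomassie detection
  limit and therefore yield undefined indexes downstream.
* 1-D lanes are emulated with seven bands per animal; the band-level index
  parameters are invented (the study printed no lane numbers) and encode
  the qualitative pattern HFHS > STD ≈ HFHS+ω3.

Every draw flows from a single integer seed through one
``numpy.random.Generator``; a cohort is bit-reproducible from
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.stats import truncnorm

from . import tables
from .fatty_acids import FattyAcidProfile

__all__ = [
    "GroupParams",
    "CohortConfig",
    "SyntheticCohort",
    "default_config",
    "generate_cohort",
    "generate_densitometry",
    "generate_index_draws",
    "generate_lanes",
    "truncated_mean",
]


class GroupParams(BaseModel):
    """Per-group (mean, sd) of one variable."""

    mean: float
    sd: float = Field(ge=0)


#: Invented 1-D band-level index parameters (no printed lane numbers exist);
#: qualitative pattern: HFHS roughly 1.6x STD, fish-oil group back near STD.
DEFAULT_BAND_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    f"b{i}": {
        "STD": (base, 0.10),
        "HFHS": (round(base * 1.6, 2), 0.12),
        "HFHS+ω3": (round(base * 1.1, 2), 0.10),
    }
    for i, base in enumerate([0.45, 0.60, 0.75, 0.90, 0.70, 0.55, 0.40], start=1)
}


class CohortConfig(BaseModel):
    """Full parameterization of a synthetic cohort.

    Defaults (see :func:`default_config`) reproduce the study conditions:
    three diet groups, n = 9, printed (mean, sd) for every variable, and
    five low-abundance spot analogues below the Coomassie detection limit.
    """

    groups: tuple[str, ...] = tables.GROUPS
    n_per_group: int = Field(default=9, ge=2)
    scalars: dict[str, dict[str, GroupParams]] = Field(default_factory=dict)
    fatty_acids: dict[str, dict[str, GroupParams]] = Field(default_factory=dict)
    spots: dict[str, dict[str, GroupParams]] = Field(default_factory=dict)
    bands: dict[str, dict[str, GroupParams]] = Field(default_factory=dict)
    low_abundance_spots: tuple[str, ...] = ("A", "B", "C", "D", "E")
    coomassie_log_mean: float = 11.0  # ln of typical spot optical density
    coomassie_log_sd: float = Field(default=0.3, ge=0)
    coomassie_detection_limit: float = Field(default=5000.0, gt=0)
    ftsc_saturation: float = Field(default=5.0e5, gt=0)

    @field_validator("groups")
    @classmethod
    def _at_least_two_groups(cls, v):
        if len(v) < 2:
            raise ValueError("need at least two groups")
        if len(set(v)) != len(v):
            raise ValueError("duplicate group labels")
        return v

    @model_validator(mode="after")
    def _check_params(self):
        for section_name in ("scalars", "fatty_acids", "spots", "bands"):
            for var, per_group in getattr(self, section_name).items():
                missing = set(self.groups) - set(per_group)
                if missing:
                    raise ValueError(
                        f"{section_name}[{var!r}] missing groups {sorted(missing)}"
                    )
        for fa, per_group in self.fatty_acids.items():
            for g, p in per_group.items():
                if p.mean < 0:
                    raise ValueError(f"fatty acid {fa!r} mean < 0 in group {g!r}")
        return self

    def animal_ids(self, group: str) -> list[str]:
        safe = group.replace("+", "p").replace("ω", "w")
        return [f"{safe}_{i + 1:02d}" for i in range(self.n_per_group)]

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.model_dump(), ensure_ascii=False, **kwargs)


def default_config(**overrides) -> CohortConfig:
    """The study-condition configuration, parameterized from printed tables.

    Scalars cover biometrics, antioxidant enzymes and conjugated dienes
    (measured quantities; per-animal ratio panels are derived downstream,
    not drawn).  Fatty acids and carbonylation spots carry the printed
    per-group (mean, sd).
    """
    sp = tables.scalar_params()
    derived = {"ast_alt", "alt_ast", "gssg_gsh"}  # computed per animal, not drawn
    scalars: dict[str, dict[str, GroupParams]] = {}
    for (var,), sub in sp.groupby(["variable"]):
        if var in derived:
            continue
        scalars[var] = {
            row["group"]: GroupParams(mean=row["mean"], sd=row["sd"])
            for _, row in sub.iterrows()
        }
    fas = {
        fa: {g: GroupParams(mean=v[g][0], sd=v[g][1]) for g in tables.GROUPS}
        for fa, v in tables.printed()["fatty_acids"].items()
    }
    spots = {
        row["spot_id"]: {}
        for _, row in tables.spot_params().iterrows()
    }
    for _, row in tables.spot_params().iterrows():
        spots[row["spot_id"]][row["group"]] = GroupParams(
            mean=row["mean"], sd=row["sd"]
        )
    bands = {
        b: {g: GroupParams(mean=m, sd=s) for g, (m, s) in per_group.items()}
        for b, per_group in DEFAULT_BAND_PARAMS.items()
    }
    cfg = dict(scalars=scalars, fatty_acids=fas, spots=spots, bands=bands)
    cfg.update(overrides)
    return CohortConfig(**cfg)


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Draw from N(mean, sd) truncated at 0; sd = 0 gives the mean exactly."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_mean(mean: float, sd: float) -> float:
    """Expectation of N(mean, sd) truncated at 0 (closed form).

    The generator's true distribution mean.  For the parent parameters used
    here the truncation bias ``sd·φ(−mean/sd)/Φ(mean/sd)`` is almost always
    negligible (mean/sd mostly > 2), but it is the exact round-trip target
    when checking that sample means recover the configured distribution.
    """
    if sd == 0:
        return float(mean)
    a = (0.0 - mean) / sd
    return float(truncnorm.mean(a, np.inf, loc=mean, scale=sd))


@dataclass
class SyntheticCohort:
    """A generated cohort: per-animal scalar and fatty-acid tables.

    Attributes
    ----------
    scalars : wide DataFrame, one row per animal (``animal_id, group`` +
        one column per scalar variable).
    fatty_acids : long DataFrame ``animal_id, group, fa_name, percent``
        with per-animal profiles renormalized to 100%.
    """

    config: CohortConfig
    seed: int
    scalars: pd.DataFrame
    fatty_acids: pd.DataFrame

    def profile(self, animal_id: str) -> FattyAcidProfile:
        sub = self.fatty_acids[self.fatty_acids.animal_id == animal_id]
        if sub.empty:
            raise KeyError(f"unknown animal {animal_id!r}")
        return FattyAcidProfile(
            dict(zip(sub.fa_name, sub.percent)), tol=1e-6
        )

    def animal_ids(self) -> list[str]:
        return self.scalars["animal_id"].tolist()


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Draw one cohort (scalar variables + fatty-acid profiles).

    Iteration order (group, then variable) is fixed, so a given
    (config, seed) is bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    n = config.n_per_group

    scalar_rows: dict[str, list] = {"animal_id": [], "group": []}
    for var in config.scalars:
        scalar_rows[var] = []
    fa_rows = []
    for group in config.groups:
        ids = config.animal_ids(group)
        scalar_rows["animal_id"].extend(ids)
        scalar_rows["group"].extend([group] * n)
        for var, per_group in config.scalars.items():
            p = per_group[group]
            scalar_rows[var].extend(_truncnorm_draw(rng, p.mean, p.sd, n))
        if config.fatty_acids:
            draws = np.column_stack(
                [
                    _truncnorm_draw(rng, pg[group].mean, pg[group].sd, n)
                    for pg in config.fatty_acids.values()
                ]
            )
            totals = draws.sum(axis=1)
            if (totals <= 0).any():
                raise ValueError("an animal drew an all-zero fatty-acid profile")
            draws = 100.0 * draws / totals[:, None]
            for i, animal in enumerate(ids):
                for j, fa in enumerate(config.fatty_acids):
                    fa_rows.append(
                        {
                            "animal_id": animal,
                            "group": group,
                            "fa_name": fa,
                            "percent": draws[i, j],
                        }
                    )
    return SyntheticCohort(
        config=config,
        seed=seed,
        scalars=pd.DataFrame(scalar_rows),
        fatty_acids=pd.DataFrame(
            fa_rows, columns=["animal_id", "group", "fa_name", "percent"]
        ),
    )


def generate_index_draws(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Per-animal carbonylation-index draws at the configured spot params.

    The index-target stage of the densitometry generator, exposed on its
    own: columns ``animal_id, group, spot_id, index``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in config.groups:
        ids = config.animal_ids(group)
        for spot, per_group in config.spots.items():
            p = per_group[group]
            vals = _truncnorm_draw(rng, p.mean, p.sd, len(ids))
            for animal, v in zip(ids, vals):
                rows.append(
                    {"animal_id": animal, "group": group, "spot_id": spot, "index": v}
                )
    return pd.DataFrame(rows)


def generate_densitometry(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Two-channel 2-D spot densitometry for every animal (one gel each).

    Per quantifiable spot the Coomassie intensity is log-normal and FTSC =
    (index draw) × Coomassie; low-abundance spot analogues get a Coomassie
    intensity uniformly below the detection limit and a saturated FTSC
    signal.  Columns: ``gel_id, animal_id, group, channel, spot_id,
    intensity``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in config.groups:
        for animal in config.animal_ids(group):
            gel = f"gel_{animal}"
            for spot, per_group in config.spots.items():
                p = per_group[group]
                index = _truncnorm_draw(rng, p.mean, p.sd, 1)[0]
                coom = float(
                    rng.lognormal(config.coomassie_log_mean, config.coomassie_log_sd)
                )
                for channel, intensity in (
                    ("FTSC", index * coom),
                    ("Coomassie", coom),
                ):
                    rows.append(
                        {
                            "gel_id": gel,
                            "animal_id": animal,
                            "group": group,
                            "channel": channel,
                            "spot_id": spot,
                            "intensity": intensity,
                        }
                    )
            for spot in config.low_abundance_spots:
                coom = float(
                    rng.uniform(0.05, 0.5) * config.coomassie_detection_limit
                )
                ftsc = float(config.ftsc_saturation * rng.lognormal(0.0, 0.1))
                for channel, intensity in (("FTSC", ftsc), ("Coomassie", coom)):
                    rows.append(
                        {
                            "gel_id": gel,
                            "animal_id": animal,
                            "group": group,
                            "channel": channel,
                            "spot_id": spot,
                            "intensity": intensity,
                        }
                    )
    return pd.DataFrame(rows)


def generate_lanes(config: CohortConfig, seed: int) -> pd.DataFrame:
    """1-D band densitometry (one lane per animal, two channels).

    Columns ``gel_id, animal_id, group, channel, spot_id, intensity`` with
    band ids as spot ids, so the same index machinery applies at band and
    lane granularity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in config.groups:
        for animal in config.animal_ids(group):
            lane = f"lane_{animal}"
            for band, per_group in config.bands.items():
                p = per_group[group]
                index = _truncnorm_draw(rng, p.mean, p.sd, 1)[0]
                coom = float(
                    rng.lognormal(config.coomassie_log_mean, config.coomassie_log_sd)
                )
                for channel, intensity in (
                    ("FTSC", index * coom),
                    ("Coomassie", coom),
                ):
                    rows.append(
                        {
                            "gel_id": lane,
                            "animal_id": animal,
                            "group": group,
                            "channel": channel,
                            "spot_id": band,
                            "intensity": intensity,
                        }
                    )
    return pd.DataFrame(rows)
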