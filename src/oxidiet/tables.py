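"""Access to the packaged printed summary statistics of the source study.

The study deposited no per-animal data; what is public are group means and
standard deviations (three diet groups, n = 9) for biometrics, antioxidant
enzymes, the liver fatty-acid profile, desaturase indexes and per-spot
carbonylation indexes.  Those printed numbers serve two roles here:

* defaults for the synthetic-cohort generator (:mod:`oxidiet.simulate`);
* inputs to the printed-value reproduction checks
  (:func:`oxidiet.pipeline.reproduce_printed`).
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

from .fatty_acids import FattyAcidProfile

__all__ = [
    "GROUPS",
    "printed",
    "group_mean_profile",
    "spot_params",
    "scalar_params",
]

GROUPS = ("STD", "HFHS", "HFHS+ω3")


@lru_cache(maxsize=1)
def printed() -> dict:
    """The packaged printed-tables dictionary (means/s.d. per group)."""
    with resources.files("oxidiet.data").joinpath("printed_tables.json").open() as fh:
        return json.load(fh)


def group_mean_profile(group: str) -> FattyAcidProfile:
    """The printed group-mean fatty-acid profile of one diet group.

    Printed means of the 22 individual fatty acids; totals land on
    100 ± 0.02 thanks to rounding of the printed cells.
    """
    data = printed()["fatty_acids"]
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
    return FattyAcidProfile({fa: vals[group][0] for fa, vals in data.items()})


def spot_params() -> pd.DataFrame:
    """Per-spot carbonylation-index (mean, sd) parameters, long format."""
    rows = []
    for spot, entry in printed()["carbonylation_spots"].items():
        for g in GROUPS:
            mean, sd = entry[g]
            rows.append(
                {
                    "spot_id": spot,
                    "genes": "/".join(entry["genes"]),
                    "group": g,
                    "mean": mean,
                    "sd": sd,
                }
            )
    return pd.DataFrame(rows)


def scalar_params() -> pd.DataFrame:
    """All printed scalar (mean, sd) parameters, long format.

    Covers biometrics, antioxidant enzymes and conjugated dienes; rows
    whose s.d. was not printed carry sd = 0 (degenerate draws).
    """
    p = printed()
    sections = {
        "biometrics": p["biometrics"],
        "antioxidants": p["antioxidants"],
        "peroxidation": {"conjugated_dienes_mmol_kg": p["conjugated_dienes_mmol_kg"]},
    }
    rows = []
    for section, variables in sections.items():
        for var, groups in variables.items():
            for g in GROUPS:
                mean, sd = groups[g]
                rows.append(
                    {
                        "section": section,
                        "variable": var,
                        "group": g,
                        "mean": float(mean),
                        "sd": 0.0 if sd is None else float(sd),
                    }
                )
    return pd.DataFrame(rows)
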