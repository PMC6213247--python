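"""End-to-end orchestration: cohort → indexes → statistics → report tables.

:func:`run_all` drives every stage over a (synthetic or user-supplied)
cohort and emits publication-style group tables with star flags and
direction arrows, plus a manifest with content hashes so a run is
verifiable and reproducible from (config, seed).

:func:`reproduce_printed` is pure arithmetic on the packaged printed group
means: it recomputes every derived quantity that is recomputable from the
published summary tables (class sums, EPA/DHA, diet shifts, biometric
indexes, ratio-of-means desaturase cells) and reports match/mismatch at the
printed precision.  Cells that do not reproduce from group means (the
published desaturase panel was evidently averaged per animal) are reported
as mismatches, not errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, biometrics, carbonylation, tables
from .fatty_acids import (
    class_sums,
    desaturase_indexes,
    diet_shift,
    inflammation_index,
    round_half_up,
)
from .simulate import CohortConfig, default_config, generate_cohort, \
    generate_densitometry, generate_lanes
from .stats import compare_variables, render_group_table

__all__ = ["RunManifest", "run_all", "reproduce_printed"]

log = logging.getLogger("oxidiet")


@dataclass
class RunManifest:
    """Inventory of one pipeline run: provenance plus output hashes."""

    seed: int
    config: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256

    def save(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "version": self.version,
                    "config": self.config,
                    "outputs": self.outputs,
                },
                indent=2,
                ensure_ascii=False,
                sort_keys=True,
            )
        )

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            config=d["config"],
            version=d["version"],
            outputs=d["outputs"],
        )

    def verify(self, out_dir: Path) -> dict[str, bool]:
        """Recompute output hashes; True per file iff unchanged."""
        return {
            name: _sha256(Path(out_dir) / name) == digest
            for name, digest in self.outputs.items()
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write(df: pd.DataFrame, out_dir: Path, name: str, manifest: RunManifest) -> None:
    path = out_dir / name
    df.to_csv(path, index=False)
    manifest.outputs[name] = _sha256(path)
    log.info("wrote %s: %d rows x %d cols", name, len(df), df.shape[1])


def _fa_derived_table(cohort) -> pd.DataFrame:
    """Per-animal class sums, desaturase panel and inflammation index."""
    rows = []
    for animal in cohort.animal_ids():
        prof = cohort.profile(animal)
        group = cohort.scalars.loc[
            cohort.scalars.animal_id == animal, "group"
        ].iloc[0]
        cs = class_sums(prof)
        rec = {
            "animal_id": animal,
            "group": group,
            "SAT": cs.SAT,
            "MUFA": cs.MUFA,
            "PUFA": cs.PUFA,
            "omega3": cs.omega3,
            "omega6": cs.omega6,
            "omega6_omega3": inflammation_index(prof),
        }
        for k, v in desaturase_indexes(prof).as_dict().items():
            rec[k] = np.nan if v is None else v
        rows.append(rec)
    return pd.DataFrame(rows)


def _tidy(df: pd.DataFrame, id_cols=("animal_id", "group")) -> pd.DataFrame:
    """Wide per-animal table -> tidy (variable, animal_id, group, value)."""
    value_cols = [c for c in df.columns if c not in id_cols]
    long = df.melt(
        id_vars=list(id_cols), value_vars=value_cols,
        var_name="variable", value_name="value",
    )
    return long[["variable", "animal_id", "group", "value"]]


def run_all(
    config: CohortConfig | None,
    seed: int,
    out_dir: str | Path,
    *,
    reference: str = "STD",
    densitometry_mode: str = "ppm",
) -> RunManifest:
    """Run simulation, index computation, statistics and reporting.

    Writes input tables, derived-index tables, the tidy comparison CSV and
    publication-style group tables to ``out_dir``; returns (and writes) the
    manifest.  Deterministic for fixed (config, seed).
    """
    if config is None:
        config = default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=int(seed), config=json.loads(config.to_json()), version=__version__
    )

    log.info("stage simulate: %d groups x n=%d", len(config.groups), config.n_per_group)
    cohort = generate_cohort(config, seed)
    dens2d = generate_densitometry(config, seed + 1)
    dens1d = generate_lanes(config, seed + 2)
    _write(cohort.scalars, out, "scalars.csv", manifest)
    _write(cohort.fatty_acids, out, "fatty_acids.csv", manifest)
    _write(dens2d, out, "densitometry_2d.csv", manifest)
    _write(dens1d, out, "densitometry_1d.csv", manifest)

    log.info("stage biometrics: deriving index columns")
    bio = biometrics.augment_biometrics(cohort.scalars)
    _write(bio, out, "biometrics_derived.csv", manifest)

    log.info("stage fatty_acids: class sums and desaturase panel")
    if config.fatty_acids:
        fa_derived = _fa_derived_table(cohort)
    else:
        fa_derived = pd.DataFrame(columns=["animal_id", "group"])
    _write(fa_derived, out, "fa_indexes.csv", manifest)

    log.info("stage carbonylation: %s-mode spot indexes", densitometry_mode)
    if len(dens2d):
        spot_idx = carbonylation.index_table(
            dens2d,
            mode=densitometry_mode,
            detection_limit=config.coomassie_detection_limit,
        )
        spot_idx = spot_idx.merge(
            cohort.scalars[["animal_id", "group"]], on="animal_id", how="left"
        )
    else:
        spot_idx = pd.DataFrame(
            columns=["animal_id", "spot_id", "index", "defined", "group"]
        )
    _write(spot_idx, out, "carbonylation_indexes.csv", manifest)

    lane_rows = []
    if len(dens1d):
        for (gel, animal, group), sub in dens1d.groupby(
            ["gel_id", "animal_id", "group"], sort=False
        ):
            wide = sub.pivot(index="spot_id", columns="channel", values="intensity")
            lane_rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "lane_index": carbonylation.lane_index(
                        wide["FTSC"], wide["Coomassie"]
                    ),
                }
            )
    lanes = pd.DataFrame(lane_rows, columns=["animal_id", "group", "lane_index"])
    _write(lanes, out, "lane_indexes.csv", manifest)

    log.info("stage group_stats: assumption-routed comparisons")
    tidy_parts = [
        _tidy(bio),
        _tidy(fa_derived),
        _tidy(lanes),
        spot_idx.assign(variable=lambda d: "spot_" + d.spot_id.astype(str))[
            ["variable", "animal_id", "group", "index"]
        ].rename(columns={"index": "value"}),
    ]
    tidy = pd.concat([t for t in tidy_parts if len(t)], ignore_index=True)
    _write(tidy, out, "tidy_observations.csv", manifest)

    comparisons = compare_variables(tidy, group_order=list(config.groups))
    _write(comparisons, out, "comparisons.csv", manifest)

    log.info("stage report: publication-style group tables")
    group_order = list(config.groups)
    bio_vars = [c for c in bio.columns if c not in ("animal_id", "group")]
    renders = {
        "table_biometrics.csv": _tidy(bio[["animal_id", "group"] + bio_vars]),
        "table_fatty_acids.csv": cohort.fatty_acids.rename(
            columns={"fa_name": "variable", "percent": "value"}
        )[["variable", "animal_id", "group", "value"]],
        "table_desaturases.csv": _tidy(
            fa_derived[
                ["animal_id", "group"]
                + [c for c in fa_derived.columns if c.startswith(("scd", "d4", "d5", "d6"))]
            ]
        ),
        "table_carbonylation.csv": tidy[tidy.variable.str.startswith("spot_")],
    }
    for name, sub in renders.items():
        rendered = render_group_table(
            sub, group_order=group_order, reference=reference
        )
        _write(rendered, out, name, manifest)

    manifest.save(out / "manifest.json")
    log.info("run complete: %d outputs", len(manifest.outputs))
    return manifest


# ---------------------------------------------------------------------------
# reproduction of printed derived values


def _check(rows, table, quantity, group, printed_value, computed, ndigits):
    rounded = round_half_up(computed, ndigits)
    rows.append(
        {
            "table": table,
            "quantity": quantity,
            "group": group,
            "printed": printed_value,
            "computed": rounded,
            "computed_raw": computed,
            "match": bool(abs(rounded - printed_value) < 10 ** (-ndigits) / 2),
        }
    )


def reproduce_printed(out_dir: str | Path | None = None) -> pd.DataFrame:
    """Recompute printed derived quantities from printed group means.

    Pure arithmetic on packaged constants; returns a report DataFrame with
    a ``match`` flag at printed precision, and optionally writes it as
    ``reproduction_report.csv``.
    """
    p = tables.printed()
    rows: list[dict] = []
    profiles = {g: tables.group_mean_profile(g) for g in tables.GROUPS}

    for g, prof in profiles.items():
        cs = class_sums(prof)
        for row_name, value in (
            ("SAT", cs.SAT),
            ("MUFA", cs.MUFA),
            ("PUFA", cs.PUFA),
            ("omega3", cs.omega3),
            ("omega6", cs.omega6),
        ):
            printed_mean = p["fatty_acid_class_rows_printed"][row_name][g][0]
            _check(rows, "fatty_acid_classes", row_name, g, printed_mean, value, 2)
        epa_dha = desaturase_indexes(prof).epa_dha
        _check(
            rows, "fatty_acid_classes", "epa_dha", g,
            p["epa_dha_ratio_printed"][g], epa_dha, 3,
        )

    shifts = p["diet_shifts_printed"]
    for name, fas in (
        ("dha", ["22:6ω3"]),
        ("epa", ["20:5ω3"]),
        ("epa_plus_dha", ["20:5ω3", "22:6ω3"]),
    ):
        value = diet_shift(profiles["HFHS"], profiles["HFHS+ω3"], fas)
        _check(rows, "diet_shift", name, "HFHS+ω3 vs HFHS", shifts[name], value, 2)

    bio = p["biometrics"]
    for g in tables.GROUPS:
        adip = biometrics.adiposity_index(
            bio["perigonadal_fat_g"][g][0], bio["body_weight_g"][g][0]
        )
        _check(
            rows, "biometric_indexes", "adiposity_index_pct", g,
            p["biometric_indexes_printed"]["adiposity_index_pct"][g], adip, 1,
        )
        hep = biometrics.hepatosomatic_index(
            bio["liver_weight_g"][g][0], bio["body_weight_g"][g][0]
        )
        _check(
            rows, "biometric_indexes", "hepatosomatic_index_pct", g,
            p["biometric_indexes_printed"]["hepatosomatic_index_pct"][g], hep, 2,
        )

    # desaturase panel from ratio of printed group means; the printed cells
    # were evidently averaged per animal, so only some cells reproduce
    for g, prof in profiles.items():
        panel = desaturase_indexes(prof).as_dict()
        for name, printed_pair in p["desaturase_indexes_printed"].items():
            value = panel[name]
            if value is None:
                continue
            _check(rows, "desaturase_indexes", name, g, printed_pair[g][0], value, 2)

    report = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "reproduction_report.csv", index=False)
    return report
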