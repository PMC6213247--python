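"""Densitometry normalization and protein carbonylation indexes.

Protein carbonyls are derivatized with FTSC (a carbonyl-specific
fluorophore) and gels are counter-stained with Coomassie for total protein.
The carbonylation index of a spot, band or lane is the FTSC signal divided
by the Coomassie signal of the same feature — carbonylation normalized for
protein amount.  Because both channels of a feature are measured on the same
gel, the index cancels gel-to-gel loading and exposure differences.

Spot intensities from 2-D gel image analysis are first expressed as parts
per million of the gel's total integrated optical density (ppm
normalization), which removes whole-gel scale.  The index is then the ratio
of ppm values; a raw-intensity mode is also provided (1-D lane totals, or
when both channels are already on a common scale).

Intensely fluorescent spots whose Coomassie signal falls below the stain's
detection limit (~100 ng of protein) have an *undefined* index: the
denominator is not quantifiable.  Undefined indexes propagate as missing
values (NaN), never as zeros, so they cannot bias group means.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ppm_normalize",
    "carbonylation_index",
    "lane_index",
    "index_table",
]

PPM = 1_000_000.0


def ppm_normalize(intensities: Mapping[str, float]) -> dict[str, float]:
    """Express each spot intensity as ppm of the channel's total intensity.

    Parameters
    ----------
    intensities
        Mapping spot id -> non-negative integrated optical density for one
        (gel, channel).

    Returns
    -------
    dict mapping spot id -> ppm; the values sum to 1e6.

    Raises
    ------
    ValueError
        On negative intensities or an all-zero channel (no normalizable
        signal).
    """
    if not intensities:
        raise ValueError("empty channel: nothing to normalize")
    vals = {k: float(v) for k, v in intensities.items()}
    for k, v in vals.items():
        if v < 0:
            raise ValueError(f"negative intensity for spot {k!r}: {v}")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("all-zero channel: no normalizable signal")
    return {k: PPM * v / total for k, v in vals.items()}


def carbonylation_index(
    ftsc: float,
    coomassie: float,
    *,
    coomassie_raw: float | None = None,
    detection_limit: float = 0.0,
) -> float:
    """FTSC / Coomassie signal ratio for one spot, band or lane.

    ``ftsc`` and ``coomassie`` are matched signals (typically ppm values
    from :func:`ppm_normalize` of the two channels of the same gel).  The
    Coomassie *raw* intensity, when given, is checked against the stain's
    detection limit: below it the protein amount is not quantifiable and the
    index is undefined (returned as ``nan``), mirroring high-fluorescence /
    low-abundance spots.

    Raises
    ------
    ValueError
        On negative inputs.
    """
    if ftsc < 0 or coomassie < 0:
        raise ValueError("signals must be non-negative")
    if coomassie_raw is not None and coomassie_raw < 0:
        raise ValueError("raw Coomassie intensity must be non-negative")
    checked = coomassie if coomassie_raw is None else coomassie_raw
    if checked < detection_limit or coomassie == 0.0:
        return float("nan")
    return float(ftsc) / float(coomassie)


def lane_index(band_ftsc, band_coomassie) -> float:
    """Total-lane carbonylation index from per-band intensities.

    The index at lane granularity: summed FTSC lane intensity over summed
    Coomassie lane intensity.  Used for 1-D gels where one lane is one
    animal.

    Raises
    ------
    ValueError
        If either lane is empty, intensities are negative, or the Coomassie
        total is zero.
    """
    f = np.asarray(list(band_ftsc), dtype=float)
    c = np.asarray(list(band_coomassie), dtype=float)
    if f.size == 0 or c.size == 0:
        raise ValueError("lanes must be non-empty")
    if (f < 0).any() or (c < 0).any():
        raise ValueError("band intensities must be non-negative")
    if c.sum() <= 0:
        raise ValueError("zero Coomassie lane total")
    return float(f.sum() / c.sum())


def index_table(
    densitometry: pd.DataFrame,
    *,
    mode: str = "ppm",
    detection_limit: float = 0.0,
) -> pd.DataFrame:
    """Per-(animal, spot) carbonylation indexes from a densitometry table.

    Parameters
    ----------
    densitometry
        Long table with columns ``gel_id, animal_id, channel, spot_id,
        intensity``; ``channel`` is ``"FTSC"`` or ``"Coomassie"`` and each
        (gel, channel, spot) appears once.  One gel is assumed to hold one
        animal's spots.
    mode
        ``"ppm"`` (default): each channel is ppm-normalized per gel before
        the ratio.  ``"raw"``: the ratio of raw intensities.  Either way the
        Coomassie *raw* intensity is compared against ``detection_limit``.
    detection_limit
        Minimum quantifiable raw Coomassie intensity; spots below it get an
        undefined (NaN) index and ``defined = False``.

    Returns
    -------
    DataFrame with columns ``animal_id, spot_id, index, defined``.
    """
    if mode not in ("ppm", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    required = {"gel_id", "animal_id", "channel", "spot_id", "intensity"}
    missing = required - set(densitometry.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    dup = densitometry.duplicated(subset=["gel_id", "channel", "spot_id"])
    if dup.any():
        raise ValueError("duplicate (gel, channel, spot) records")

    rows = []
    for gel_id, gel in densitometry.groupby("gel_id", sort=False):
        wide = gel.pivot(index="spot_id", columns="channel", values="intensity")
        if "FTSC" not in wide.columns or "Coomassie" not in wide.columns:
            raise ValueError(f"gel {gel_id!r} lacks an FTSC or Coomassie channel")
        animals = gel["animal_id"].unique()
        if len(animals) != 1:
            raise ValueError(f"gel {gel_id!r} maps to multiple animals")
        animal = animals[0]
        ftsc_raw = wide["FTSC"].astype(float)
        coom_raw = wide["Coomassie"].astype(float)
        if mode == "ppm":
            ftsc = pd.Series(ppm_normalize(ftsc_raw.to_dict()))
            coom = pd.Series(ppm_normalize(coom_raw.to_dict()))
        else:
            ftsc, coom = ftsc_raw, coom_raw
        for spot in wide.index:
            idx = carbonylation_index(
                ftsc[spot],
                coom[spot],
                coomassie_raw=coom_raw[spot],
                detection_limit=detection_limit,
            )
            rows.append(
                {
                    "animal_id": animal,
                    "spot_id": spot,
                    "index": idx,
                    "defined": bool(np.isfinite(idx)),
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "spot_id", "index", "defined"])
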