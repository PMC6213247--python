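"""Scalar indexes from biometric and biochemical measurements.

Per-animal arithmetic only: the adiposity index, the hepatosomatic index,
and elementwise ratio panels (GSSG/GSH redox balance, AST/ALT and ALT/AST
transaminase ratios).  Ratios are computed per animal and then summarized —
a mean of per-animal ratios is not the ratio of group means, and published
redox-balance cells are consistent with the per-animal convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "adiposity_index",
    "hepatosomatic_index",
    "ratio_panel",
    "augment_biometrics",
]


def adiposity_index(abdominal_fat: float, body_weight: float) -> float:
    """(total abdominal fat × 100) / body weight, in %.

    ``abdominal_fat`` is the dissected visceral depot mass (g) —
    operationally the perigonadal depot; ``body_weight`` in g.
    """
    if body_weight <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight}")
    if abdominal_fat < 0:
        raise ValueError("abdominal fat mass must be non-negative")
    return 100.0 * abdominal_fat / body_weight


def hepatosomatic_index(liver_weight: float, body_weight: float) -> float:
    """(liver weight × 100) / body weight, in %."""
    if body_weight <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight}")
    if liver_weight < 0:
        raise ValueError("liver weight must be non-negative")
    return 100.0 * liver_weight / body_weight


def _safe_ratio(num: float, den: float) -> float:
    return float(num) / float(den) if den > 0 else float("nan")


def ratio_panel(
    gssg: float | None = None,
    gsh: float | None = None,
    ast: float | None = None,
    alt: float | None = None,
) -> dict[str, float]:
    """Per-animal ratio panel: GSSG/GSH, AST/ALT, ALT/AST.

    Zero (or missing) denominators yield NaN (undefined), never an
    exception.  Only ratios whose inputs were supplied are returned.
    """
    out: dict[str, float] = {}
    if gssg is not None and gsh is not None:
        out["gssg_gsh"] = _safe_ratio(gssg, gsh)
    if ast is not None and alt is not None:
        out["ast_alt"] = _safe_ratio(ast, alt)
        out["alt_ast"] = _safe_ratio(alt, ast)
    return out


def augment_biometrics(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived index columns to a wide per-animal biometrics table.

    Recognized input columns (all optional except those each index needs):
    ``body_weight_g, perigonadal_fat_g, liver_weight_g, gssg_umol_g,
    gsh_umol_g, ast_u_l, alt_u_l``.  Adds ``adiposity_index_pct,
    hepatosomatic_index_pct, gssg_gsh, ast_alt, alt_ast`` where computable.
    """
    out = df.copy()
    bw = out.get("body_weight_g")
    if bw is not None:
        if (bw <= 0).any():
            raise ValueError("body weight must be positive for every animal")
        if "perigonadal_fat_g" in out:
            out["adiposity_index_pct"] = 100.0 * out["perigonadal_fat_g"] / bw
        if "liver_weight_g" in out:
            out["hepatosomatic_index_pct"] = 100.0 * out["liver_weight_g"] / bw
    if {"gssg_umol_g", "gsh_umol_g"} <= set(out.columns):
        out["gssg_gsh"] = np.where(
            out["gsh_umol_g"] > 0, out["gssg_umol_g"] / out["gsh_umol_g"], np.nan
        )
    if {"ast_u_l", "alt_u_l"} <= set(out.columns):
        out["ast_alt"] = np.where(
            out["alt_u_l"] > 0, out["ast_u_l"] / out["alt_u_l"], np.nan
        )
        out["alt_ast"] = np.where(
            out["ast_u_l"] > 0, out["alt_u_l"] / out["ast_u_l"], np.nan
        )
    return out
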