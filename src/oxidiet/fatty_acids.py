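"""Fatty-acid nomenclature and profile-derived indexes.

Liver total fatty acids quantified by GC-FID are reported as percentages of
total fatty acids ("C:DωN" shorthand, e.g. ``20:5ω3`` for EPA).  This module
parses that shorthand, forms saturation-class sums (SAT / MUFA / PUFA and the
ω-3 / ω-6 PUFA families), and computes the derived indexes used in
diet-intervention lipidomics:

* the desaturase-index panel — product-to-substrate percentage ratios that
  proxy desaturase enzyme activity (SCD-16, SCD-18, Δ4D, Δ5D, Δ6D, Δ5/6D);
* the ω-6/ω-3 "inflammation index";
* the EPA/DHA ratio;
* percentage-point shifts of selected fatty acids between diets.

All ratios are plain percentage ratios, so they are invariant to rescaling a
profile by a positive constant; a zero denominator makes an index *undefined*
(``None``), never an exception, so downstream group statistics can treat it
as missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

__all__ = [
    "FattyAcidDescriptor",
    "FattyAcidProfile",
    "ClassSums",
    "DesaturaseIndexes",
    "FattyAcidNameError",
    "parse_fa_name",
    "class_sums",
    "desaturase_indexes",
    "inflammation_index",
    "diet_shift",
    "round_half_up",
]

FAMILIES = ("ω3", "ω6", "ω7", "ω9", "saturated")

# "20:5ω3", "16:1 ω - 7", "18:3n-3", "22:6w3" all normalize to the same acid.
_FA_RE = re.compile(
    r"""^\s*
        (?P<carbons>\d+)\s*:\s*(?P<bonds>\d+)
        (?:\s*(?P<fam>[ωwn])\s*[-−–]?\s*(?P<pos>\d+))?
        \s*$""",
    re.VERBOSE,
)


class FattyAcidNameError(ValueError):
    """Raised when a fatty-acid shorthand string cannot be interpreted."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching how printed tables round.

    Python's builtin ``round`` uses banker's rounding (0.125 -> 0.12); summary
    tables in this field round half up (0.125 -> 0.13).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """A parsed fatty acid: chain length, double bonds, ω family."""

    carbons: int
    double_bonds: int
    family: str  # one of FAMILIES

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise FattyAcidNameError(f"carbon count {self.carbons} < 2")
        if self.double_bonds < 0:
            raise FattyAcidNameError("negative double-bond count")
        if self.family not in FAMILIES:
            raise FattyAcidNameError(f"unknown family {self.family!r}")
        if (self.family == "saturated") != (self.double_bonds == 0):
            raise FattyAcidNameError(
                f"family {self.family!r} inconsistent with "
                f"{self.double_bonds} double bond(s)"
            )

    @property
    def is_saturated(self) -> bool:
        return self.double_bonds == 0

    @property
    def is_mufa(self) -> bool:
        return self.double_bonds == 1

    @property
    def is_pufa(self) -> bool:
        return self.double_bonds >= 2

    def __str__(self) -> str:
        if self.is_saturated:
            return f"{self.carbons}:0"
        return f"{self.carbons}:{self.double_bonds}{self.family}"


def parse_fa_name(name: str) -> FattyAcidDescriptor:
    """Parse ``C:D`` / ``C:DωN`` shorthand into a :class:`FattyAcidDescriptor`.

    Accepts the spacing and symbol dialects that occur in practice: ``ω``,
    ``w`` or ``n`` for the family marker, with or without a hyphen/minus and
    spaces (``"16:1ω7"``, ``"16:1 ω − 7"``, ``"18:3n-3"``).

    Raises
    ------
    FattyAcidNameError
        If the string does not match the shorthand, names an unknown ω
        family, or is internally inconsistent (e.g. ``"16:0ω7"``).
    """
    if not isinstance(name, str):
        raise FattyAcidNameError(f"expected a string, got {type(name).__name__}")
    m = _FA_RE.match(name)
    if m is None:
        raise FattyAcidNameError(f"cannot parse fatty-acid name {name!r}")
    carbons = int(m.group("carbons"))
    bonds = int(m.group("bonds"))
    if m.group("pos") is None:
        if bonds != 0:
            raise FattyAcidNameError(
                f"{name!r}: {bonds} double bond(s) but no ω family given"
            )
        family = "saturated"
    else:
        if bonds == 0:
            raise FattyAcidNameError(f"{name!r}: saturated acid with ω suffix")
        family = f"ω{m.group('pos')}"
        if family not in FAMILIES:
            raise FattyAcidNameError(f"{name!r}: unsupported family {family!r}")
    return FattyAcidDescriptor(carbons, bonds, family)


def canonical_fa_name(name: str) -> str:
    """Normalize any accepted shorthand dialect to ``C:DωN`` / ``C:0``."""
    return str(parse_fa_name(name))


class FattyAcidProfile:
    """One sample's fatty-acid composition, in % of total fatty acids.

    Parameters
    ----------
    values
        Mapping of FA shorthand to percentage.  Names are normalized at
        construction, so dialect spellings collapse onto one key.
    tol
        Allowed deviation of the total from 100 during :meth:`validate`
        (default 0.5, absorbing the rounding of printed tables).
    validate
        Validate on construction (set False for deliberately degenerate
        inputs in tests).
    """

    def __init__(
        self,
        values: Mapping[str, float],
        *,
        tol: float = 0.5,
        validate: bool = True,
    ) -> None:
        self.values: dict[str, float] = {
            canonical_fa_name(k): float(v) for k, v in values.items()
        }
        if len(self.values) != len(values):
            raise FattyAcidNameError("duplicate fatty acids after normalization")
        self.tol = float(tol)
        if validate:
            self.validate()

    def validate(self) -> None:
        for fa, pct in self.values.items():
            if pct < 0:
                raise ValueError(f"negative percentage for {fa}: {pct}")
        total = self.total()
        if abs(total - 100.0) > self.tol:
            raise ValueError(
                f"profile total {total:.3f}% outside 100 ± {self.tol}"
            )

    def total(self) -> float:
        return float(sum(self.values.values()))

    def get(self, name: str, default: float = 0.0) -> float:
        return self.values.get(canonical_fa_name(name), default)

    def __getitem__(self, name: str) -> float:
        return self.values[canonical_fa_name(name)]

    def __contains__(self, name: str) -> bool:
        return canonical_fa_name(name) in self.values

    def __len__(self) -> int:
        return len(self.values)

    def renormalized(self) -> "FattyAcidProfile":
        """Rescale so percentages sum to exactly 100."""
        total = self.total()
        if total <= 0:
            raise ValueError("cannot renormalize an all-zero profile")
        scaled = {fa: 100.0 * v / total for fa, v in self.values.items()}
        return FattyAcidProfile(scaled, tol=self.tol, validate=False)

    def scaled(self, c: float) -> "FattyAcidProfile":
        return FattyAcidProfile(
            {fa: c * v for fa, v in self.values.items()},
            tol=self.tol,
            validate=False,
        )

    def __repr__(self) -> str:
        return f"FattyAcidProfile({len(self.values)} acids, total={self.total():.2f}%)"


@dataclass(frozen=True)
class ClassSums:
    """Saturation-class sums, in % of total fatty acids.

    ω-3/ω-6 sums count only polyunsaturates (≥ 2 double bonds): the
    monounsaturated members of a family (e.g. 18:1ω7) belong to MUFA, not to
    the PUFA-family rows, which is what reproduces published class rows.
    """

    SAT: float
    MUFA: float
    PUFA: float
    omega3: float
    omega6: float


def class_sums(profile: FattyAcidProfile) -> ClassSums:
    """Sum a profile into SAT / MUFA / PUFA / ω-3 / ω-6 classes."""
    sat = mufa = pufa = w3 = w6 = 0.0
    for fa, pct in profile.values.items():
        d = parse_fa_name(fa)
        if d.is_saturated:
            sat += pct
        elif d.is_mufa:
            mufa += pct
        else:
            pufa += pct
            if d.family == "ω3":
                w3 += pct
            elif d.family == "ω6":
                w6 += pct
    return ClassSums(sat, mufa, pufa, w3, w6)


@dataclass(frozen=True)
class DesaturaseIndexes:
    """Product/substrate percentage ratios proxying desaturase activities.

    Each index is ``None`` (undefined) when its substrate percentage is zero.

    Attributes
    ----------
    scd16 : 16:1ω7 / 16:0 (Δ9 stearoyl-CoA desaturase, palmitic branch)
    scd18 : 18:1ω9 / 18:0 (Δ9 stearoyl-CoA desaturase, stearic branch)
    d4d : 22:6ω3 / 22:5ω3 (Δ4 desaturase)
    d5d : 20:4ω6 / 20:3ω6 (Δ5 desaturase)
    d6d_dgla : 20:3ω6 / 18:2ω6 (Δ6 desaturase, DGLA product)
    d6d_gla : 18:3ω6 / 18:2ω6 (Δ6 desaturase, γ-linolenic product)
    d5d6d : 20:5ω3 / 18:3ω3 (combined Δ5/Δ6 pathway, ALA -> EPA)
    epa_dha : 20:5ω3 / 22:6ω3 (selective-incorporation marker)
    """

    scd16: float | None
    scd18: float | None
    d4d: float | None
    d5d: float | None
    d6d_dgla: float | None
    d6d_gla: float | None
    d5d6d: float | None
    epa_dha: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "scd16": self.scd16,
            "scd18": self.scd18,
            "d4d": self.d4d,
            "d5d": self.d5d,
            "d6d_dgla": self.d6d_dgla,
            "d6d_gla": self.d6d_gla,
            "d5d6d": self.d5d6d,
            "epa_dha": self.epa_dha,
        }


#: (product, substrate) percentage ratios defining each desaturase index.
DESATURASE_DEFINITIONS: dict[str, tuple[str, str]] = {
    "scd16": ("16:1ω7", "16:0"),
    "scd18": ("18:1ω9", "18:0"),
    "d4d": ("22:6ω3", "22:5ω3"),
    "d5d": ("20:4ω6", "20:3ω6"),
    "d6d_dgla": ("20:3ω6", "18:2ω6"),
    "d6d_gla": ("18:3ω6", "18:2ω6"),
    "d5d6d": ("20:5ω3", "18:3ω3"),
    "epa_dha": ("20:5ω3", "22:6ω3"),
}


def _ratio(profile: FattyAcidProfile, product: str, substrate: str) -> float | None:
    denom = profile.get(substrate, 0.0)
    if denom == 0.0:
        return None
    return profile.get(product, 0.0) / denom


def desaturase_indexes(profile: FattyAcidProfile) -> DesaturaseIndexes:
    """Compute the desaturase-index panel (plus EPA/DHA) for one profile."""
    return DesaturaseIndexes(
        **{
            name: _ratio(profile, prod, sub)
            for name, (prod, sub) in DESATURASE_DEFINITIONS.items()
        }
    )


def inflammation_index(profile: FattyAcidProfile) -> float | None:
    """ω-6/ω-3 PUFA ratio; lower is more anti-inflammatory.

    Returns ``None`` when the ω-3 sum is zero (undefined ratio).
    """
    cs = class_sums(profile)
    if cs.omega3 == 0.0:
        return None
    return cs.omega6 / cs.omega3


def diet_shift(
    profile_a: FattyAcidProfile,
    profile_b: FattyAcidProfile,
    fas: Iterable[str],
) -> float:
    """Percentage-point change of Σ(fas) from profile_a to profile_b.

    Raises
    ------
    KeyError
        If a requested fatty acid appears in neither profile.
    ValueError
        If ``fas`` is empty.
    """
    names = [canonical_fa_name(f) for f in fas]
    if not names:
        raise ValueError("fas must be non-empty")
    for n in names:
        if n not in profile_a.values and n not in profile_b.values:
            raise KeyError(f"unknown fatty acid {n!r}")
    return float(
        sum(profile_b.get(n, 0.0) for n in names)
        - sum(profile_a.get(n, 0.0) for n in names)
    )
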