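"""Compositional model of methyl-/acetyl-substituted oligogalacturonides.

Pectin lyases release 4,5-unsaturated oligomers of galacturonic acid (GalA)
that may carry O-6 methyl esters and O-2/O-3 acetyl groups.  At unit
(iontrap) resolution such an oligomer is fully described by four numbers:
degree of polymerization (dp), methyl count, acetyl count, and whether the
non-reducing end carries the Δ4,5 unsaturation introduced by β-elimination.

Nominal integer masses are primary (they reproduce published unit-resolution
observations exactly); monoisotopic masses are provided for ppm-tolerance
matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

# Nominal building blocks (Da): anhydro-GalA residue, CH2 (methyl ester vs
# free acid), C2H2O (acetyl), H2O.
RESIDUE_NOMINAL = 176
METHYL_NOMINAL = 14
ACETYL_NOMINAL = 42
WATER_NOMINAL = 18

# Monoisotopic counterparts.
RESIDUE_MONO = 176.03209
METHYL_MONO = 14.01565
ACETYL_MONO = 42.01057
WATER_MONO = 18.01056

# Ion chemistry, nominal mode: proton ~ 1, NH4 ~ 18, formate ~ 45 (HCOOH
# adduct minus proton).  Monoisotopic mode distinguishes the proton mass.
PROTON_MONO = 1.00728
AMMONIUM_MONO = 18.03383
FORMATE_MONO = 44.99820


class CompositionError(ValueError):
    """Raised when a composition violates its structural constraints."""


@dataclass(frozen=True, order=True)
class OligoComposition:
    """An oligogalacturonide composition: x GalA, y methyls, z acetyls.

    ``unsaturated`` marks the Δ4,5 double bond at the non-reducing end that
    every lyase product carries.
    """

    dp: int
    n_methyl: int = 0
    n_acetyl: int = 0
    unsaturated: bool = True

    def __post_init__(self) -> None:
        if self.dp < 1:
            raise CompositionError(f"dp must be >= 1, got {self.dp}")
        if not 0 <= self.n_methyl <= self.dp:
            raise CompositionError(
                f"n_methyl must be in [0, dp={self.dp}], got {self.n_methyl}"
            )
        if not 0 <= self.n_acetyl <= 2 * self.dp:
            raise CompositionError(
                f"n_acetyl must be in [0, 2*dp={2 * self.dp}], got {self.n_acetyl}"
            )


def nominal_mass(comp: OligoComposition) -> int:
    """Nominal (integer) molecular weight in Da.

    Unsaturated oligomers: 176*dp + 14*m + 42*a.  Saturated oligomers gain
    one water (18 Da): the Δ4,5 unsaturation is formally a water loss from
    the hydrated chain end.
    """
    m = RESIDUE_NOMINAL * comp.dp + METHYL_NOMINAL * comp.n_methyl + ACETYL_NOMINAL * comp.n_acetyl
    if not comp.unsaturated:
        m += WATER_NOMINAL
    return m


def monoisotopic_mass(comp: OligoComposition) -> float:
    """Monoisotopic molecular weight in Da, same structural rule."""
    m = RESIDUE_MONO * comp.dp + METHYL_MONO * comp.n_methyl + ACETYL_MONO * comp.n_acetyl
    if not comp.unsaturated:
        m += WATER_MONO
    return m


@dataclass(frozen=True)
class AdductSpec:
    """An ionization mode: adduct name, polarity, and charge state."""

    name: str  # deprotonated | formate | ammonium
    polarity: str  # negative | positive
    charge: int = 1

    _NOMINAL_SHIFTS = {"deprotonated": -1, "formate": 45, "ammonium": 18}
    _POLARITY = {"deprotonated": "negative", "formate": "negative", "ammonium": "positive"}

    def __post_init__(self) -> None:
        if self.name not in self._NOMINAL_SHIFTS:
            raise CompositionError(f"unsupported adduct name: {self.name!r}")
        if self.polarity != self._POLARITY[self.name]:
            raise CompositionError(
                f"adduct {self.name!r} must be {self._POLARITY[self.name]} polarity"
            )
        if self.charge < 1:
            raise CompositionError(f"charge must be >= 1, got {self.charge}")

    @classmethod
    def deprotonated(cls, z: int = 1) -> "AdductSpec":
        return cls("deprotonated", "negative", z)

    @classmethod
    def formate(cls, z: int = 1) -> "AdductSpec":
        return cls("formate", "negative", z)

    @classmethod
    def ammonium(cls, z: int = 1) -> "AdductSpec":
        return cls("ammonium", "positive", z)

    @property
    def label(self) -> str:
        return f"{self.name}{self.charge:+d}" if False else f"{self.name}:z{self.charge}"


def adduct_mz(mass: float, adduct: AdductSpec, mode: str = "nominal") -> float:
    """m/z of ``mass`` under ``adduct``.

    Nominal contract: [M-H]- = M-1; [M+FA]- = M+45; [M+NH4]+ = M+18;
    z=2 ammonium = (M+36)/2.  The adduct shift is applied once per charge.
    """
    if mass <= 0:
        raise CompositionError(f"mass must be positive, got {mass}")
    if mode == "nominal":
        shift = AdductSpec._NOMINAL_SHIFTS[adduct.name]
    elif mode == "monoisotopic":
        shift = {
            "deprotonated": -PROTON_MONO,
            "formate": FORMATE_MONO,
            "ammonium": AMMONIUM_MONO,
        }[adduct.name]
    else:
        raise CompositionError(f"unknown mass mode {mode!r}")
    return (mass + adduct.charge * shift) / adduct.charge


# --- nomenclature -----------------------------------------------------------

_NAME_RE = re.compile(
    r"^gA_(?P<dp>\d+)_m_(?P<m>\d+)(?:_a_(?P<a>\d+))?_?(?:\s*#(?P<iso>\d+))?$"
)


def format_name(comp: OligoComposition, isomer_index: int = 1, explicit_isomer: bool = False) -> str:
    """Render the gA_x_m_y[_a_z][ #k] compound label.

    The isomer suffix is printed for indices above 1; ``explicit_isomer``
    also prints " #1" (used when a sibling #2 exists, as in published
    labels).
    """
    name = f"gA_{comp.dp}_m_{comp.n_methyl}"
    if comp.n_acetyl:
        name += f"_a_{comp.n_acetyl}"
    if isomer_index != 1 or explicit_isomer:
        name += f" #{isomer_index}"
    return name


def parse_name(name: str) -> tuple[OligoComposition, int]:
    """Parse a gA_x_m_y[_a_z][ #k] label into (composition, isomer_index).

    All library compounds carry the Δ4,5 unsaturation, so ``unsaturated`` is
    always True here.  A missing acetyl term means zero acetyls; a missing
    isomer suffix means isomer 1.
    """
    m = _NAME_RE.match(name.strip().rstrip("*").strip())
    if m is None:
        raise CompositionError(f"cannot parse compound name {name!r}")
    comp = OligoComposition(
        dp=int(m.group("dp")),
        n_methyl=int(m.group("m")),
        n_acetyl=int(m.group("a") or 0),
        unsaturated=True,
    )
    return comp, int(m.group("iso") or 1)


# --- library ----------------------------------------------------------------

DEFAULT_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec.deprotonated(1),
    AdductSpec.formate(1),
    AdductSpec.ammonium(1),
    AdductSpec.ammonium(2),
)


@dataclass(frozen=True)
class LibraryEntry:
    """One candidate compound: composition, isomer label, and expected m/z."""

    composition: OligoComposition
    isomer_index: int = 1
    adducts: tuple[AdductSpec, ...] = DEFAULT_ADDUCTS

    @property
    def name(self) -> str:
        return format_name(self.composition, self.isomer_index)

    @property
    def nominal_mw(self) -> int:
        return nominal_mass(self.composition)

    @property
    def monoisotopic_mw(self) -> float:
        return monoisotopic_mass(self.composition)

    def expected_mz(self, mode: str = "nominal") -> list[tuple[AdductSpec, float]]:
        mass = self.nominal_mw if mode == "nominal" else self.monoisotopic_mw
        return [(a, adduct_mz(mass, a, mode)) for a in self.adducts]


def enumerate_library(
    dp_range: tuple[int, int] = (2, 8),
    max_acetyl: int = 2,
    min_methyl: int = 1,
    adducts: Iterable[AdductSpec] = DEFAULT_ADDUCTS,
    require_unsaturated: bool = True,
) -> list[LibraryEntry]:
    """Enumerate all candidate compositions within the given bounds.

    Deterministic ordering (dp, n_methyl, n_acetyl).  An empty range yields
    an empty list.
    """
    lo, hi = dp_range
    if lo < 1 or hi > 12:
        raise CompositionError(f"dp_range must lie within [1, 12], got {dp_range}")
    adducts = tuple(adducts)
    entries = []
    for dp in range(lo, hi + 1):
        for m in range(min_methyl, dp + 1):
            for a in range(0, max_acetyl + 1):
                comp = OligoComposition(dp, m, a, unsaturated=require_unsaturated)
                entries.append(LibraryEntry(comp, 1, adducts))
    return entries


# Rows of the shipped reference inventory whose printed cells are internally
# inconsistent with the naming/mass rule.  They are preserved verbatim in the
# transcription and flagged here rather than silently corrected.
KNOWN_INCONSISTENCIES = {
    "gA_4_m_3": "printed observed m/z 746; the mass rule gives [M+NH4]+ = 764",
    "gA_7_m_6": "printed MW 1335; the mass rule and the printed z=2 m/z 676 imply 1316",
    "gA_8_m_7": "printed GalA/methyl cells read 9/6; the label and MW 1506 imply 8/7",
}


def reference_library_table() -> pd.DataFrame:
    """The transcribed reference compound inventory as a DataFrame.

    48 unsaturated oligogalacturonides reported from pectin lyase digests of
    apple, citrus, and sugar beet pectin, with printed MW, charge states and
    positive-mode observed m/z preserved verbatim (see KNOWN_INCONSISTENCIES).
    """
    import io

    text = resources.files("pectolyze.data").joinpath("reference_compounds.csv").read_text()
    # isomer labels contain '#', so only whole comment lines are stripped
    data = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    return pd.read_csv(io.StringIO(data))


def load_reference_library(adducts: Iterable[AdductSpec] = DEFAULT_ADDUCTS) -> list[LibraryEntry]:
    """Build LibraryEntry records from the shipped reference inventory.

    Compositions are derived from the compound label (the authoritative cell;
    two flagged rows have inconsistent numeric cells).
    """
    table = reference_library_table()
    adducts = tuple(adducts)
    entries = []
    for name in table["name"]:
        comp, iso = parse_name(name)
        entries.append(LibraryEntry(comp, iso, adducts))
    return entries
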