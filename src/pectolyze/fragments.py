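"""MS2 fragment prediction for labeled oligogalacturonides.

Glycosidic fragments follow Domon–Costello nomenclature: B/C ions retain the
non-reducing portion, Y/Z the reducing portion.  For 1,4-linked uronides at
unit resolution, a free saturated i-mer weighs 176*i + 18; C ions carry the
glycosidic water (C = B + 18), Z ions have lost it (Z = Y - 18).  The single
cross-ring series emitted is 0,2A (loss of the C1-C2 ring fragment, 60 Da,
from the corresponding C ion).

Two empirical behaviours of iontrap spectra of these compounds are modeled:
a methanol loss (-32 Da) available only when the reducing-end residue is
methyl-esterified, and a positive-mode series-wide -7 Da offset on B/C ions
(an unexplained but reproducible observation; it is applied as an opaque,
flagged offset, never folded into the underlying masses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .composition import (
    ACETYL_NOMINAL,
    METHYL_NOMINAL,
    RESIDUE_NOMINAL,
    WATER_NOMINAL,
    CompositionError,
    OligoComposition,
)

CROSS_RING_02A_LOSS = 60  # C2H4O2 from the C1-C2 ring fragment
METHANOL_LOSS = 32
POSITIVE_MODE_EMPIRICAL_OFFSET = -7
AMMONIUM_NOMINAL = 18


@dataclass(frozen=True)
class Residue:
    methyl: bool = False
    acetyl_count: int = 0

    def __post_init__(self):
        if not 0 <= self.acetyl_count <= 2:
            raise CompositionError("acetyl_count per residue must be 0..2")


@dataclass(frozen=True)
class LabeledOligomer:
    """Per-residue labeled oligomer, non-reducing end first."""

    residues: tuple[Residue, ...]
    unsaturated_nonreducing: bool = True

    @property
    def dp(self) -> int:
        return len(self.residues)

    def composition(self) -> OligoComposition:
        return OligoComposition(
            dp=self.dp,
            n_methyl=sum(r.methyl for r in self.residues),
            n_acetyl=sum(r.acetyl_count for r in self.residues),
            unsaturated=self.unsaturated_nonreducing,
        )

    @classmethod
    def from_flags(cls, methyls, acetyls=None, unsaturated=True) -> "LabeledOligomer":
        acetyls = acetyls or [0] * len(methyls)
        return cls(
            tuple(Residue(bool(m), int(a)) for m, a in zip(methyls, acetyls, strict=True)),
            unsaturated,
        )


@dataclass(frozen=True)
class FragmentIon:
    series: str  # B | C | Z | A02
    index: int
    polarity: str
    charge: int
    mz: float
    neutral_losses: tuple[str, ...] = ()
    empirical_offset: int = 0
    # residue count / substituent counts of the neutral fragment, for
    # bookkeeping checks
    n_residues: int = 0
    n_methyl: int = 0
    n_acetyl: int = 0


def _segment_counts(olig: LabeledOligomer, start: int, stop: int) -> tuple[int, int]:
    seg = olig.residues[start:stop]
    return sum(r.methyl for r in seg), sum(r.acetyl_count for r in seg)


def _neutral_c(olig: LabeledOligomer, i: int) -> int:
    """Neutral mass of the C_i fragment (residues 1..i, non-reducing side)."""
    m, a = _segment_counts(olig, 0, i)
    mass = RESIDUE_NOMINAL * i + METHYL_NOMINAL * m + ACETYL_NOMINAL * a + WATER_NOMINAL
    if olig.unsaturated_nonreducing:
        mass -= WATER_NOMINAL
    return mass


def _neutral_z(olig: LabeledOligomer, j: int) -> int:
    """Neutral mass of the Z_j fragment (last j residues, reducing side)."""
    m, a = _segment_counts(olig, olig.dp - j, olig.dp)
    return RESIDUE_NOMINAL * j + METHYL_NOMINAL * m + ACETYL_NOMINAL * a


def predict_fragments(
    olig: LabeledOligomer,
    polarity: str = "negative",
    charge: int = 1,
    include_losses: bool = True,
    positive_offset: bool = True,
) -> list[FragmentIon]:
    """Predict the glycosidic/cross-ring fragment ladder of ``olig``.

    Negative mode emits C_i, Z_j and 0,2A_i ions (deprotonated); methanol
    loss variants are added for ions containing a methylated reducing-end
    residue.  Positive mode emits B_i and C_i ions with NH4+ retained and the
    empirical -7 Da series offset (flagged per ion, on by default).

    A dp=1 oligomer has no glycosidic bonds: the result is empty.
    """
    if olig.dp < 2:
        return []
    out: list[FragmentIon] = []
    dp = olig.dp
    red_methyl = olig.residues[-1].methyl

    def emit(series, i, neutral, losses=(), offset=0, nres=0, nm=0, na=0):
        if polarity == "negative":
            mz = (neutral - charge * 1) / charge
        else:
            mz = (neutral + charge * AMMONIUM_NOMINAL) / charge + offset
        out.append(
            FragmentIon(series, i, polarity, charge, mz, tuple(losses), offset, nres, nm, na)
        )

    for i in range(1, dp):
        cm, ca = _segment_counts(olig, 0, i)
        zc_m, zc_a = _segment_counts(olig, dp - i, dp)
        if polarity == "negative":
            emit("C", i, _neutral_c(olig, i), nres=i, nm=cm, na=ca)
            zi = _neutral_z(olig, i)
            emit("Z", i, zi, nres=i, nm=zc_m, na=zc_a)
            emit("A02", i, _neutral_c(olig, i) - CROSS_RING_02A_LOSS, nres=i, nm=cm, na=ca)
            if include_losses and red_methyl:
                # Z ions contain the methylated reducing end; methanol loss.
                emit("Z", i, zi - METHANOL_LOSS, losses=("methanol",), nres=i, nm=zc_m, na=zc_a)
        else:
            off = POSITIVE_MODE_EMPIRICAL_OFFSET if positive_offset else 0
            ci = _neutral_c(olig, i)
            emit("B", i, ci - WATER_NOMINAL, offset=off, nres=i, nm=cm, na=ca)
            emit("C", i, ci, offset=off, nres=i, nm=cm, na=ca)
    return out


def complementary_compositions(
    olig: LabeledOligomer, i: int
) -> tuple[OligoComposition, OligoComposition]:
    """Neutral compositions of the complementary C_i / Z_(dp-i) pair."""
    if not 1 <= i <= olig.dp - 1:
        raise CompositionError(f"glycosidic index must be in [1, dp-1], got {i}")
    cm, ca = _segment_counts(olig, 0, i)
    zm, za = _segment_counts(olig, i, olig.dp)
    c = OligoComposition(i, cm, ca, unsaturated=olig.unsaturated_nonreducing)
    z = OligoComposition(olig.dp - i, zm, za, unsaturated=True)
    return c, z


def localize_acetyl(
    candidate: OligoComposition,
    observed_fragments: list[tuple[str, int, bool]],
) -> set[int]:
    """Feasible acetyl residue positions given retained/lost observations.

    Each observation is (series, index, acetyl_retained) for a B or C
    fragment, which contains residues 1..index counted from the non-reducing
    end.  Retention places the acetyl within 1..index; loss places it within
    index+1..dp.  Observations intersect; an empty set signals contradictory
    evidence.  With no evidence every position is feasible.
    """
    feasible = set(range(1, candidate.dp + 1))
    for series, i, retained in observed_fragments:
        if series not in ("B", "C"):
            raise CompositionError(f"acetyl localization expects B/C fragments, got {series}")
        if not 1 <= i <= candidate.dp - 1:
            raise CompositionError(f"fragment index {i} invalid for dp={candidate.dp}")
        window = set(range(1, i + 1)) if retained else set(range(i + 1, candidate.dp + 1))
        feasible &= window
    return feasible


def enumerate_labelings(dp: int, max_acetyl_total: int = 2):
    """All per-residue labelings of an unsaturated dp-mer (test oracle aid).

    Methylation: every boolean pattern.  Acetylation: up to
    ``max_acetyl_total`` acetyls distributed over the 2*dp O-2/O-3 sites
    (counted per residue, capped at 2).
    """
    sites = list(range(dp))
    acetyl_patterns = set()
    for k in range(max_acetyl_total + 1):
        for combo in combinations_with_replacement(sites, k):
            counts = [0] * dp
            ok = True
            for s in combo:
                counts[s] += 1
                if counts[s] > 2:
                    ok = False
                    break
            if ok:
                acetyl_patterns.add(tuple(counts))
    for mbits in range(2**dp):
        methyls = [(mbits >> r) & 1 for r in range(dp)]
        for counts in acetyl_patterns:
            yield LabeledOligomer.from_flags(methyls, list(counts))
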