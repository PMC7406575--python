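"""Peak-to-compound matching and per-sample profile assembly.

Inputs are already-integrated peak areas (m/z, retention time, XIC area,
polarity); matching is against a compound library at a mass tolerance, with
retention-time-based grouping of compositional isomers and assembly into
per-(enzyme, substrate, time) intensity profiles.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd

from .composition import (
    AdductSpec,
    CompositionError,
    LibraryEntry,
    format_name,
)

DEFAULT_TOLERANCE_DA = 0.5  # unit-resolution iontrap
DEFAULT_RT_GAP_MIN = 0.5


@dataclass(frozen=True)
class Peak:
    """One integrated extracted-ion-chromatogram peak."""

    mz: float
    rt: float  # minutes
    intensity: float
    polarity: str = "positive"
    charge_hint: int | None = None

    def __post_init__(self):
        if self.intensity < 0:
            raise CompositionError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Identification:
    entry: LibraryEntry
    adduct: AdductSpec
    mass_error: float  # observed - expected, Da (in m/z space)
    peak: Peak
    isomer_index: int = 1

    @property
    def compound_label(self) -> str:
        return format_name(self.entry.composition, self.isomer_index)


def match_peaks(
    peaks: list[Peak],
    library: list[LibraryEntry],
    tolerance: float = DEFAULT_TOLERANCE_DA,
    mode: str = "nominal",
    all_matches: bool = False,
) -> tuple[list[Identification], list[Peak]]:
    """Match peaks to library (entry, adduct) pairs within ``tolerance`` Da.

    Polarity must agree; a charge hint on the peak restricts candidate
    charge states.  Per peak the best match wins: smallest |mass error|,
    then lower charge, then library order-independent lexicographic name.
    With ``all_matches`` every in-tolerance candidate is returned (useful
    when isobaric compositions cannot be distinguished at unit resolution).
    Returns (identifications, unmatched peaks).
    """
    if not library:
        raise CompositionError("empty library")
    if tolerance <= 0:
        raise CompositionError(f"tolerance must be positive, got {tolerance}")

    # Precompute candidate (entry, adduct, mz) triples.
    candidates = []
    for entry in library:
        for adduct, mz in entry.expected_mz(mode):
            candidates.append((entry, adduct, mz))

    idents: list[Identification] = []
    unmatched: list[Peak] = []
    for peak in peaks:
        hits = []
        for entry, adduct, mz in candidates:
            if adduct.polarity != peak.polarity:
                continue
            if peak.charge_hint is not None and adduct.charge != peak.charge_hint:
                continue
            err = peak.mz - mz
            if abs(err) <= tolerance:
                hits.append(Identification(entry, adduct, err, peak))
        if not hits:
            unmatched.append(peak)
            continue
        hits.sort(key=lambda h: (abs(h.mass_error), h.adduct.charge, h.entry.name))
        idents.extend(hits if all_matches else hits[:1])
    return idents, unmatched


def group_isomers(
    idents: list[Identification], rt_gap: float = DEFAULT_RT_GAP_MIN
) -> list[Identification]:
    """Assign isomer indices by elution order within each composition.

    Peaks of one composition separated by >= ``rt_gap`` minutes become
    distinct isomers (#1 earliest); peaks closer than the gap are merged
    into one identification with summed intensity.
    """
    by_comp: dict = defaultdict(list)
    for ident in idents:
        by_comp[ident.entry.composition].append(ident)

    out: list[Identification] = []
    for comp, group in by_comp.items():
        group.sort(key=lambda h: h.peak.rt)
        clusters: list[list[Identification]] = []
        for ident in group:
            if clusters and ident.peak.rt - clusters[-1][-1].peak.rt < rt_gap:
                clusters[-1].append(ident)
            else:
                clusters.append([ident])
        for k, cluster in enumerate(clusters, start=1):
            head = cluster[0]
            if len(cluster) > 1:
                merged_peak = replace(
                    head.peak, intensity=sum(c.peak.intensity for c in cluster)
                )
                head = replace(head, peak=merged_peak)
            out.append(replace(head, isomer_index=k))
    out.sort(key=lambda h: (h.entry.name, h.isomer_index))
    return out


@dataclass
class SampleProfile:
    """Compound-intensity map for one (enzyme, substrate, time) sample."""

    enzyme: str
    substrate: str
    time_min: float
    intensities: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.enzyme, self.substrate, self.time_min)

    def total(self) -> float:
        return sum(self.intensities.values())


def build_profile(
    idents: list[Identification],
    enzyme: str,
    substrate: str,
    time_min: float,
    library: list[LibraryEntry] | None = None,
) -> SampleProfile:
    """Assemble a complete compound-intensity profile for one sample.

    Every library compound gets an entry (0 when absent); multiple adducts
    or duplicate identifications of one compound are summed.
    """
    intensities: dict[str, float] = {}
    if library is not None:
        for entry in library:
            intensities.setdefault(entry.name, 0.0)
    for ident in idents:
        label = ident.compound_label
        intensities[label] = intensities.get(label, 0.0) + ident.peak.intensity
    return SampleProfile(enzyme, substrate, time_min, intensities)


# --- CSV adapters -----------------------------------------------------------

PEAK_COLUMNS = ["sample_id", "enzyme", "substrate", "time_min", "polarity", "mz", "rt_min", "intensity", "charge"]


def read_csv_skip_comments(path) -> pd.DataFrame:
    """Read a CSV ignoring leading '#' comment lines.

    Compound labels legitimately contain '#' (isomer suffixes), so pandas'
    in-line comment handling cannot be used.
    """
    import io
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    start = next(i for i, l in enumerate(lines) if not l.startswith("#"))
    return pd.read_csv(io.StringIO("\n".join(lines[start:])))


def read_peak_table(path) -> pd.DataFrame:
    df = read_csv_skip_comments(path)
    missing = set(PEAK_COLUMNS) - {"charge"} - set(df.columns)
    if missing:
        raise CompositionError(f"peak table missing columns: {sorted(missing)}")
    return df


def peaks_from_frame(df: pd.DataFrame) -> list[Peak]:
    return [
        Peak(
            mz=row.mz,
            rt=row.rt_min,
            intensity=row.intensity,
            polarity=row.polarity,
            charge_hint=None if pd.isna(getattr(row, "charge", float("nan"))) else int(row.charge),
        )
        for row in df.itertuples(index=False)
    ]
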