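"""Stochastic pectin-lyase digestion of synthetic homogalacturonan.

Substrate chains are explicit residue sequences (methyl / O-2 / O-3 acetyl
marks).  Cleavage follows a subsite model: the enzyme spans subsites -4..+4
across the attacked bond, requires a methyl-esterified GalA in subsite +1,
strongly prefers one in +3 (bonds lacking it cleave at a reduced relative
rate rho, zero in strict mode), and is slowed by acetyl groups anywhere in
the subsite window.  Digestion is an exact Gillespie simulation: each event
cleaves one bond chosen proportionally to its relative rate, and the
reducing-side product gains a Delta-4,5 unsaturated non-reducing end.

Residue, methyl, and acetyl counts are conserved along any trajectory;
the number of unsaturated ends equals the number of cleavage events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .composition import CompositionError, LibraryEntry, OligoComposition, adduct_mz
from .composition import AdductSpec
from .identify import PEAK_COLUMNS


@dataclass
class ResidueChain:
    """One homogalacturonan chain, non-reducing end first."""

    methyl: np.ndarray  # bool per residue
    acetyl_o2: np.ndarray  # bool
    acetyl_o3: np.ndarray  # bool
    unsaturated_nonreducing: bool = False

    def __post_init__(self):
        n = len(self.methyl)
        if n < 1 or len(self.acetyl_o2) != n or len(self.acetyl_o3) != n:
            raise CompositionError("chain arrays must be nonempty and equal length")

    def __len__(self) -> int:
        return len(self.methyl)

    @property
    def acetyl_counts(self) -> np.ndarray:
        return self.acetyl_o2.astype(np.int64) + self.acetyl_o3.astype(np.int64)

    def composition(self) -> OligoComposition:
        return OligoComposition(
            dp=len(self),
            n_methyl=int(self.methyl.sum()),
            n_acetyl=int(self.acetyl_counts.sum()),
            unsaturated=self.unsaturated_nonreducing,
        )

    @classmethod
    def from_flags(cls, methyl, acetyl_o2=None, acetyl_o3=None, unsaturated=False):
        methyl = np.asarray(methyl, dtype=bool)
        z = np.zeros(len(methyl), dtype=bool)
        a2 = z if acetyl_o2 is None else np.asarray(acetyl_o2, dtype=bool)
        a3 = z.copy() if acetyl_o3 is None else np.asarray(acetyl_o3, dtype=bool)
        return cls(methyl, a2, a3, unsaturated)


@dataclass(frozen=True)
class CleavageRule:
    """Subsite requirements and rate multipliers for one enzyme.

    rho: relative rate of bonds with methyl in +1 but not +3 (0 = strict).
    acetyl_penalty: multiplicative factor per acetyl group on a residue in
    the -4..+4 window.  block_on_plus1_acetyl optionally vetoes bonds whose
    +1 residue is acetylated.
    """

    rho: float = 0.25
    acetyl_penalty: float = 0.5
    block_on_plus1_acetyl: bool = False

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise CompositionError("rho must be in [0, 1]")
        if not 0.0 < self.acetyl_penalty <= 1.0:
            raise CompositionError("acetyl_penalty must be in (0, 1]")

    @classmethod
    def strict(cls) -> "CleavageRule":
        return cls(rho=0.0)


def bond_rates(chain: ResidueChain, rule: CleavageRule) -> np.ndarray:
    """Relative cleavage rate of each glycosidic bond.

    Bond k (0-based, between residues k and k+1) places residue k+1 in
    subsite +1 and residue k+3 in subsite +3; the -side subsites are residue
    k and its non-reducing neighbours.  Required subsites must exist on the
    chain; tolerance subsites may be vacant without penalty.
    """
    n = len(chain)
    if n < 2:
        return np.zeros(0)
    methyl = chain.methyl
    plus1 = methyl[1:n]  # residue k+1 for bond k
    plus3_exists = np.zeros(n - 1, dtype=bool)
    plus3_methyl = np.zeros(n - 1, dtype=bool)
    if n >= 4:
        plus3_exists[: n - 3] = True
        plus3_methyl[: n - 3] = methyl[3:n]
    # The binding cleft must be filled through +3 for productive cleavage
    # (trimers are never substrates); rho only relaxes the methyl requirement
    # at +3, not the occupancy requirement.
    rates = np.where(
        plus1 & plus3_methyl, 1.0, np.where(plus1 & plus3_exists, rule.rho, 0.0)
    )
    if rule.acetyl_penalty < 1.0:
        ac = chain.acetyl_counts
        csum = np.concatenate([[0], np.cumsum(ac)])
        k = np.arange(n - 1)
        lo = np.maximum(0, k - 3)  # subsite -4 is residue k-3
        hi = np.minimum(n, k + 5)  # subsite +4 is residue k+4
        window = csum[hi] - csum[lo]
        rates = rates * rule.acetyl_penalty**window
    if rule.block_on_plus1_acetyl:
        rates = np.where(chain.acetyl_counts[1:n] > 0, 0.0, rates)
    return rates


def cleavable_bonds(chain: ResidueChain, rule: CleavageRule) -> list[tuple[int, float]]:
    """(1-based bond index, relative rate) for every bond with nonzero rate."""
    rates = bond_rates(chain, rule)
    return [(k + 1, float(r)) for k, r in enumerate(rates) if r > 0]


def cleave(chain: ResidueChain, bond_index: int) -> tuple[ResidueChain, ResidueChain]:
    """Split at 1-based bond index; the reducing-side product gains Delta-4,5."""
    k = bond_index  # residues 0..k-1 | k..n-1 in 0-based slicing
    left = ResidueChain(
        chain.methyl[:k].copy(),
        chain.acetyl_o2[:k].copy(),
        chain.acetyl_o3[:k].copy(),
        chain.unsaturated_nonreducing,
    )
    right = ResidueChain(
        chain.methyl[k:].copy(),
        chain.acetyl_o2[k:].copy(),
        chain.acetyl_o3[k:].copy(),
        True,
    )
    return left, right


# --- substrate generation ---------------------------------------------------


@dataclass(frozen=True)
class SubstrateSpec:
    """Synthetic homogalacturonan population parameters.

    DM/DAc are percentages of GalA residues carrying the substituent;
    methyl placement is random (Bernoulli) or blockwise (runs of
    ``block_length`` methylated residues).  ``inert_fraction`` marks a
    fraction of residues as lyase-inert (an RG-I / neutral-sugar stand-in):
    inert residues are never methylated, so no bond places them in a
    required subsite.
    """

    n_chains: int = 100
    chain_length: int = 100
    dm: float = 69.0
    dac: float = 2.0
    methyl_pattern: str = "random"  # random | blockwise
    block_length: int = 10
    inert_fraction: float = 0.0
    name: str = "custom"

    def __post_init__(self):
        if not 0 <= self.dm <= 100 or not 0 <= self.dac <= 100:
            raise CompositionError("DM and DAc must be in [0, 100]")
        if self.methyl_pattern not in ("random", "blockwise"):
            raise CompositionError(f"unknown methyl_pattern {self.methyl_pattern!r}")
        if self.n_chains < 1 or self.chain_length < 1 or self.block_length < 1:
            raise CompositionError("n_chains, chain_length, block_length must be >= 1")
        if not 0 <= self.inert_fraction < 1:
            raise CompositionError("inert_fraction must be in [0, 1)")


def load_presets() -> dict[str, dict]:
    with resources.files("pectolyze.data").joinpath("substrate_presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def preset_spec(name: str, n_chains: int = 100, chain_length: int = 100) -> SubstrateSpec:
    presets = load_presets()
    if name not in presets:
        raise CompositionError(f"unknown substrate preset {name!r}; have {sorted(presets)}")
    p = presets[name]
    return SubstrateSpec(
        n_chains=n_chains,
        chain_length=chain_length,
        dm=p["dm"],
        dac=p["dac"],
        methyl_pattern=p.get("methyl_pattern", "random"),
        block_length=p.get("block_length", 10),
        name=name,
    )


def generate_chains(spec: SubstrateSpec, seed: int | np.random.Generator = 0) -> list[ResidueChain]:
    """Realize a chain population; deterministic under a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chains = []
    p_m = spec.dm / 100.0
    p_a = spec.dac / 100.0
    for _ in range(spec.n_chains):
        n = spec.chain_length
        if spec.methyl_pattern == "random":
            methyl = rng.random(n) < p_m
        else:
            methyl = np.zeros(n, dtype=bool)
            target = int(round(p_m * n))
            # Lay blocks at random starts until the target count is reached,
            # then trim the overshoot so the realized count is exact.
            while int(methyl.sum()) < target:
                start = int(rng.integers(0, n))
                methyl[start : start + spec.block_length] = True
            excess = int(methyl.sum()) - target
            if excess > 0:
                idx = np.where(methyl)[0]
                methyl[idx[-excess:]] = False
        if spec.inert_fraction > 0:
            methyl &= rng.random(n) >= spec.inert_fraction
        acetyl = rng.random(n) < p_a
        on_o2 = rng.random(n) < 0.5
        chains.append(
            ResidueChain(methyl, acetyl & on_o2, acetyl & ~on_o2, unsaturated_nonreducing=False)
        )
    return chains


# --- Gillespie digestion ----------------------------------------------------


@dataclass
class DigestState:
    chains: list[ResidueChain]
    time_min: float
    cleavage_count: int

    def composition_counts(self) -> Counter:
        return Counter(c.composition() for c in self.chains)

    def totals(self) -> tuple[int, int, int, int]:
        """(residues, methyls, acetyls, unsaturated ends)."""
        res = sum(len(c) for c in self.chains)
        met = sum(int(c.methyl.sum()) for c in self.chains)
        ace = sum(int(c.acetyl_counts.sum()) for c in self.chains)
        uns = sum(c.unsaturated_nonreducing for c in self.chains)
        return res, met, ace, uns


def simulate_digest(
    chains: list[ResidueChain],
    rule: CleavageRule,
    rate_constant: float = 1.0,
    time_points: tuple[float, ...] = (0.0, 1.0, 5.0, 20.0),
    seed: int | np.random.Generator = 0,
) -> list[DigestState]:
    """Exact stochastic simulation of the digestion; snapshots at time_points.

    The propensity of bond b is ``rate_constant * relative_rate(b)`` per
    minute.  Snapshot times must be ascending; t=0 reproduces the input.
    """
    if rate_constant <= 0:
        raise CompositionError("rate_constant must be positive")
    time_points = tuple(time_points)
    if any(b < a for a, b in zip(time_points, time_points[1:])):
        raise CompositionError("time_points must be ascending")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pool = [replace(c) for c in chains]
    rates = [bond_rates(c, rule) for c in pool]
    totals = [float(r.sum()) for r in rates]

    t = 0.0
    cleavages = 0
    snapshots: list[DigestState] = []
    pending = list(time_points)

    def snapshot(at: float):
        snapshots.append(
            DigestState([replace(c) for c in pool], at, cleavages)
        )

    while pending:
        total_rate = rate_constant * sum(totals)
        if total_rate <= 0:
            for at in pending:
                snapshot(at)
            pending = []
            break
        dt = rng.exponential(1.0 / total_rate)
        while pending and t + dt > pending[0]:
            snapshot(pending.pop(0))
        if not pending:
            break
        t += dt
        # choose chain then bond, proportional to relative rate
        cum = np.cumsum(totals)
        ci = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        ci = min(ci, len(pool) - 1)
        r = rates[ci]
        rcum = np.cumsum(r)
        bi = int(np.searchsorted(rcum, rng.random() * rcum[-1], side="right"))
        bi = min(bi, len(r) - 1)
        left, right = cleave(pool[ci], bi + 1)
        cleavages += 1
        pool[ci] = left
        rates[ci] = bond_rates(left, rule)
        totals[ci] = float(rates[ci].sum())
        pool.append(right)
        rr = bond_rates(right, rule)
        rates.append(rr)
        totals.append(float(rr.sum()))
    return snapshots


def initial_total_rate(chains: list[ResidueChain], rule: CleavageRule) -> float:
    """Sum of relative cleavage rates over all bonds of the population."""
    return float(sum(bond_rates(c, rule).sum() for c in chains))


def enumerate_terminal_products(chain: ResidueChain, rule: CleavageRule) -> set[frozenset]:
    """All reachable terminal product multisets (exhaustive; small chains only).

    Each terminal state is a frozenset of (composition, multiplicity) pairs.
    """
    results: set[frozenset] = set()

    def recurse(chains: tuple):
        moves = []
        for idx, c in enumerate(chains):
            for bond, _rate in cleavable_bonds(c, rule):
                moves.append((idx, bond))
        if not moves:
            results.add(frozenset(Counter(c.composition() for c in chains).items()))
            return
        for idx, bond in moves:
            left, right = cleave(chains[idx], bond)
            recurse(chains[:idx] + chains[idx + 1 :] + (left, right))

    recurse((chain,))
    return results


# --- observables ------------------------------------------------------------


def absorbance_trace(
    states: list[DigestState],
    extinction: float = 5500.0,
    path_cm: float = 1.0,
    volume_l: float = 1e-3,
    mol_per_count: float = 1e-9,
) -> pd.DataFrame:
    """A235 versus time from new unsaturated ends (Beer-Lambert).

    Each cleavage creates one 4,5-unsaturated product; its molar
    concentration is cleavage_count * mol_per_count / volume_l.
    """
    if extinction <= 0 or path_cm <= 0 or volume_l <= 0:
        raise CompositionError("extinction, path and volume must be positive")
    rows = [
        {
            "time_min": s.time_min,
            "product_M": s.cleavage_count * mol_per_count / volume_l,
            "A235": extinction * path_cm * s.cleavage_count * mol_per_count / volume_l,
        }
        for s in states
    ]
    return pd.DataFrame(rows)


def synthesize_peak_table(
    state: DigestState,
    library: list[LibraryEntry],
    noise_cv: float = 0.09,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
    enzyme: str = "sim-enzyme",
    substrate: str = "sim-substrate",
    mz_jitter_sd: float = 0.0,
    z2_mass_threshold: float = 1100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a digest snapshot into an LC-MS-like peak list.

    Unsaturated products of dp <= 8 whose composition is in the library
    become positive-mode ammonium-adduct peaks (z=1 below
    ``z2_mass_threshold`` Da, z=2 above, mirroring the charge-state tendency
    of larger oligomers); intensity is molar count times lognormal noise of
    the requested CV (CV 0 means intensities exactly proportional to
    counts).  Saturated original-end fragments, dp > 8 products, and
    compositions outside the library are excluded and reported separately.
    Retention times are synthetic but composition-deterministic so isomer
    grouping has a stable axis.
    """
    if noise_cv < 0:
        raise CompositionError("noise_cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lib_comps = {e.composition for e in library}
    counts = state.composition_counts()
    rows, excluded = [], []
    for comp, count in sorted(counts.items()):
        reason = None
        if not comp.unsaturated:
            reason = "saturated"
        elif comp.dp > 8:
            reason = "dp>8"
        elif comp not in lib_comps:
            reason = "not-in-library"
        if reason:
            excluded.append(
                {"dp": comp.dp, "n_methyl": comp.n_methyl, "n_acetyl": comp.n_acetyl,
                 "unsaturated": comp.unsaturated, "count": count, "reason": reason}
            )
            continue
        from .composition import nominal_mass

        mw = nominal_mass(comp)
        z = 1 if mw <= z2_mass_threshold else 2
        mz = adduct_mz(mw, AdductSpec.ammonium(z))
        if mz_jitter_sd > 0:
            mz += rng.normal(0.0, mz_jitter_sd)
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            intensity = count * rng.lognormal(-0.5 * sigma**2, sigma)
        else:
            intensity = float(count)
        rt = 2.0 * comp.dp + 0.3 * comp.n_methyl + 0.7 * comp.n_acetyl
        rows.append(
            {
                "sample_id": sample_id,
                "enzyme": enzyme,
                "substrate": substrate,
                "time_min": state.time_min,
                "polarity": "positive",
                "mz": mz,
                "rt_min": rt,
                "intensity": intensity,
                "charge": z,
            }
        )
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    excluded_df = pd.DataFrame(
        excluded, columns=["dp", "n_methyl", "n_acetyl", "unsaturated", "count", "reason"]
    )
    return peaks, excluded_df
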