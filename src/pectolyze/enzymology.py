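"""Enzymology arithmetic: substituent degrees, bond molarity, activity,
and Michaelis-Menten fitting via the Hanes-Woolf linearization.

Pectin lyase activity is followed at 235 nm, where the 4,5-unsaturated
galacturonide product absorbs with extinction coefficient 5500 M^-1 cm^-1.
One unit (U) releases 1 umol of unsaturated product per minute; specific
activity is U per mg enzyme.  Substrate concentrations for kinetics are
expressed as molar GalA-GalA bond concentration derived from the measured
GalA content of the pectin (the (n-1)/n end correction is negligible for
polymeric substrates and is not applied).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .composition import CompositionError

DEFAULT_EXTINCTION = 5500.0  # M^-1 cm^-1, 4,5-unsaturated galacturonide at 235 nm


def substrate_composition_table() -> pd.DataFrame:
    """Shipped monosaccharide composition fixture (umol/g dry matter)."""
    with resources.files("pectolyze.data").joinpath("substrate_composition.csv").open() as fh:
        return pd.read_csv(fh, comment="#").set_index("source")


def dm_dac(methanol_umol_g: float, acetate_umol_g: float, gala_umol_g: float) -> tuple[float, float]:
    """Degrees of methoxylation and acetylation from released substituents.

    DM = 100 * methanol / GalA and DAc = 100 * acetate / GalA, both in
    percent of GalA moieties.
    """
    if gala_umol_g <= 0:
        raise CompositionError("GalA content must be positive")
    return 100.0 * methanol_umol_g / gala_umol_g, 100.0 * acetate_umol_g / gala_umol_g


def bond_concentration(substrate_g_per_l: float, gala_umol_g: float) -> float:
    """GalA-GalA bond concentration in mM for a pectin solution.

    Bonds are approximated by GalA moles: mM = g/L * umol/g / 1000.
    """
    if substrate_g_per_l < 0 or gala_umol_g < 0:
        raise CompositionError("concentrations must be nonnegative")
    return substrate_g_per_l * gala_umol_g / 1000.0


@dataclass(frozen=True)
class AbsorbanceAssayConfig:
    extinction: float = DEFAULT_EXTINCTION  # M^-1 cm^-1
    path_cm: float = 1.0
    enzyme_mg: float = 0.001
    volume_l: float = 1e-3

    def __post_init__(self):
        if min(self.extinction, self.path_cm, self.enzyme_mg, self.volume_l) <= 0:
            raise CompositionError("assay configuration values must be positive")


def rate_from_a235(slope_per_min: float, cfg: AbsorbanceAssayConfig) -> float:
    """Specific activity (U/mg) from an A235 slope (absorbance/min)."""
    if slope_per_min < 0:
        raise CompositionError("slope must be >= 0")
    molar_per_min = slope_per_min / (cfg.extinction * cfg.path_cm)  # M/min
    umol_per_min = molar_per_min * cfg.volume_l * 1e6
    return umol_per_min / cfg.enzyme_mg


@dataclass(frozen=True)
class KineticFit:
    km_mm: float
    vmax: float  # same units as the supplied rates
    r_squared: float
    kcat_s: float | None = None


def hanes_woolf(
    s_mm,
    v,
    enzyme_mw_g_mol: float | None = None,
    enzyme_mg: float | None = None,
) -> KineticFit:
    """Michaelis-Menten fit from linear regression of S/v on S.

    slope = 1/Vmax and intercept = Km/Vmax.  When ``v`` is specific activity
    (umol min^-1 mg^-1) and the enzyme molecular weight is given, kcat (s^-1)
    is derived as Vmax * MW / 60000.  Requires >= 3 points with S, v > 0;
    duplicate substrate levels are allowed and point order is immaterial.
    """
    s = np.asarray(s_mm, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.size < 3 or s.size != v.size:
        raise CompositionError("need >= 3 matched (S, v) points")
    if np.any(s <= 0) or np.any(v <= 0):
        raise CompositionError("S and v must be positive for the Hanes-Woolf transform")
    res = stats.linregress(s, s / v)
    if res.slope <= 0 or res.intercept <= 0:
        raise CompositionError("Hanes-Woolf regression gave nonpositive slope or intercept")
    vmax = 1.0 / res.slope
    km = res.intercept * vmax
    kcat = None
    if enzyme_mw_g_mol is not None:
        # U/mg -> mol product / mol enzyme / s
        kcat = vmax * enzyme_mw_g_mol / 60.0 / 1000.0
    return KineticFit(km_mm=km, vmax=vmax, r_squared=res.rvalue**2, kcat_s=kcat)


def michaelis_menten_nls(s_mm, v) -> KineticFit:
    """Nonlinear least-squares Michaelis-Menten fit (diagnostic cross-check).

    The Hanes-Woolf linearization is the primary estimator; this direct fit
    is provided to flag cases where the linearization distorts the error
    structure.
    """
    s = np.asarray(s_mm, dtype=float)
    v = np.asarray(v, dtype=float)
    mm = lambda s, vmax, km: vmax * s / (km + s)
    p0 = (float(v.max()), float(np.median(s)))
    popt, _ = optimize.curve_fit(mm, s, v, p0=p0, maxfev=10000)
    resid = v - mm(s, *popt)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return KineticFit(km_mm=float(popt[1]), vmax=float(popt[0]), r_squared=r2)


def michaelis_menten_rates(s_mm, km_mm: float, vmax: float) -> np.ndarray:
    """Noiseless Michaelis-Menten rates (synthetic-data helper)."""
    s = np.asarray(s_mm, dtype=float)
    return vmax * s / (km_mm + s)
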