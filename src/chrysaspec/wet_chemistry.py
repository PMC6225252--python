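"""Standard-curve mathematics of the colorimetric reference assays.

Total polysaccharides are referenced against a glucose standard curve
(phenol-sulfuric-acid reaction, absorbance at 488 nm) and total
flavonoids against a rutin curve (nitrite-aluminium reaction, 500 nm).
Only the curve mathematics is modeled: ordinary least-squares fitting
of absorbance vs concentration, inversion of the line, conversion of an
in-tube concentration to % w/w through the dilution chain, and
recovery / RSD summaries.  The bench protocol itself is out of scope.

Units: the glucose curve is absorbance vs mg/mL at the 1-mL calibrated
volume before reagent addition (a 103 ug/mL stock pipetted at 0.2-1.0
mL then made up to 1 mL spans ~0.02-0.10 mg/mL, keeping absorbance in
the photometric range for a slope of ~9.9 per mg/mL).  The rutin curve
is absorbance vs ug/mL at the 25-mL final volume (slope ~0.013 per
ug/mL).  :class:`AssayDesign.conc_unit_mg_per_ml` carries the unit of C
so the % w/w conversion stays explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "AssayDesign",
    "fit_standard_curve",
    "invert_curve",
    "content_percent",
    "recovery_rsd",
    "GLUCOSE_ASSAY",
    "RUTIN_ASSAY",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance-concentration calibration A = slope*C + intercept."""

    slope: float
    intercept: float
    r_squared: float
    analyte: str  # "glucose" or "rutin"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    def absorbance(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class AssayDesign:
    """Dilution chain linking in-tube concentration to % w/w.

    ``assay_volume_mL`` is the volume at which the curve's C is defined;
    ``aliquot_volume_mL`` is the extract volume pipetted into it;
    ``conc_unit_mg_per_ml`` converts C's unit to mg/mL (1.0 when C is
    already mg/mL, 1e-3 when C is ug/mL).
    """

    sample_mass_g: float
    extract_volume_mL: float
    aliquot_volume_mL: float
    assay_volume_mL: float
    replicates: int = 3
    conc_unit_mg_per_ml: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sample_mass_g", "extract_volume_mL",
                     "aliquot_volume_mL", "assay_volume_mL",
                     "replicates", "conc_unit_mg_per_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Polysaccharide assay: 0.25 g powder, 100 mL extract, 0.5 mL aliquot
#: made up to 1 mL before reagents; C in mg/mL.
GLUCOSE_ASSAY = AssayDesign(0.25, 100.0, 0.5, 1.0, 3, 1.0)
#: Flavonoid assay: 0.25 g powder, 50 mL extract, 2 mL aliquot into a
#: 25-mL flask; C in ug/mL.
RUTIN_ASSAY = AssayDesign(0.25, 50.0, 2.0, 25.0, 3, 1e-3)


def fit_standard_curve(concentrations, absorbances,
                       analyte: str = "glucose") -> StandardCurve:
    """Ordinary least-squares line through (C, A) standard points."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size or c.size < 3:
        raise ValueError("need >= 3 matched standard points")
    if np.ptp(c) == 0:
        raise ValueError("constant concentrations give a singular fit")
    res = stats.linregress(c, a)
    a_hat = res.slope * c + res.intercept
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    ss_res = float(np.sum((a - a_hat) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return StandardCurve(float(res.slope), float(res.intercept), r2, analyte)


def invert_curve(curve: StandardCurve, absorbance: float) -> float:
    """Concentration from measured absorbance: C = (A - intercept)/slope."""
    return (absorbance - curve.intercept) / curve.slope


def content_percent(concentration: float, design: AssayDesign) -> float:
    """Convert in-tube concentration to % w/w of the dry sample.

    mass in tube [mg] = C * unit * assay volume; scale by the
    aliquot-to-extract ratio, then divide by the sample mass::

        % = C * unit * assay_vol / aliquot_vol * extract_vol
            / (mass_g * 1000) * 100
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    mg_in_tube = concentration * design.conc_unit_mg_per_ml * design.assay_volume_mL
    mg_in_extract = mg_in_tube / design.aliquot_volume_mL * design.extract_volume_mL
    return mg_in_extract / (design.sample_mass_g * 1000.0) * 100.0


def recovery_rsd(replicates, true_pct: float) -> tuple[float, float]:
    """Mean recovery (%) and relative standard deviation (%) of spiked
    replicate measurements against the known true content."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 replicates")
    if true_pct <= 0:
        raise ValueError("true_pct must be positive")
    mean = float(x.mean())
    if mean == 0:
        raise ValueError("zero replicate mean: RSD undefined")
    recovery = mean / true_pct * 100.0
    rsd = float(x.std(ddof=1)) / mean * 100.0
    return recovery, rsd
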