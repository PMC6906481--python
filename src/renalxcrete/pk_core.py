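"""Renal-physiology primitives: clearance ratio, excretion-type banding, and
the mechanistic forward model of renal clearance.

Renal clearance (CLr) of unchanged drug is the net result of glomerular
filtration, tubular secretion and tubular reabsorption.  Only unbound drug is
filtered, so the filtration clearance is ``fu,p × GFR``.  The clearance ratio

    CR = CLr / (fu,p × GFR)

locates a compound relative to pure filtration: CR < 0.67 indicates net
reabsorption (R), 0.67 ≤ CR < 1.5 is the intermediate, filtration-dominated
regime (IM), and CR ≥ 1.5 indicates net secretion (S).  The forward model

    CLr = (1 − FR) (fu,p × GFR + CLs)

expresses CLr through the fraction reabsorbed from the lumen (FR) and the
transporter-mediated secretion clearance (CLs); the three excretion types
correspond to the special cases FR > 0, CLs = 0 (R), FR = CLs = 0 (IM, where
CLr = fu,p × GFR exactly) and FR = 0, CLs > 0 (S).

All clearances are per-body-weight, mL/min/kg; GFR defaults to 1.8 mL/min/kg
(126 mL/min in a 70 kg adult).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "PhysiologyConstants",
    "DEFAULT_CONSTANTS",
    "CRType",
    "MechanismParams",
    "FE_LOW",
    "FE_HIGH_MEDIUM",
    "compute_cr",
    "classify_cr_type",
    "binarize_fe",
    "forward_clr",
    "per_kg_to_absolute",
    "absolute_to_per_kg",
]

#: Label for compounds with a minor urinary contribution (fe below threshold).
FE_LOW = "low"
#: Label for compounds excreted unchanged to a medium/high extent (fe >= threshold).
FE_HIGH_MEDIUM = "high_medium"


class CRType(str, enum.Enum):
    """Excretion type from the clearance ratio: reabsorption, intermediate, secretion."""

    R = "R"
    IM = "IM"
    S = "S"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PhysiologyConstants:
    """Physiological constants and decision thresholds.

    Parameters
    ----------
    gfr : float
        Glomerular filtration rate, mL/min/kg.
    cr_low, cr_high : float
        Clearance-ratio band edges separating R / IM / S types.  The lower
        edge belongs to IM and the upper edge to S.
    fe_threshold : float
        Cut on the fraction excreted unchanged in urine separating the
        ``low`` from the ``high_medium`` class (boundary inclusive upward).
    clr_range_cut : float
        CLr value (mL/min/kg) splitting the reliable high range from the low
        range in two-step predictions; the mean IM-type CLr.
    """

    gfr: float = 1.8
    cr_low: float = 0.67
    cr_high: float = 1.5
    fe_threshold: float = 0.30
    clr_range_cut: float = 1.02

    def __post_init__(self) -> None:
        for name in ("gfr", "cr_low", "cr_high", "fe_threshold", "clr_range_cut"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not self.cr_low < self.cr_high:
            raise ValueError(
                f"cr_low must be below cr_high, got {self.cr_low} >= {self.cr_high}"
            )
        if not self.fe_threshold < 1:
            raise ValueError(f"fe_threshold must lie in (0, 1), got {self.fe_threshold}")


DEFAULT_CONSTANTS = PhysiologyConstants()


@dataclass(frozen=True)
class MechanismParams:
    """Mechanistic determinants of renal clearance for one compound.

    ``fup`` is the fraction unbound in plasma (only unbound drug is filtered),
    ``fr`` the fraction reabsorbed from the tubular lumen, and ``cls`` the
    tubular secretion clearance in mL/min/kg.
    """

    fup: float
    fr: float = 0.0
    cls: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.fup <= 1):
            raise ValueError(f"fup must lie in (0, 1], got {self.fup!r}")
        if not (0 <= self.fr < 1):
            raise ValueError(f"fr must lie in [0, 1), got {self.fr!r}")
        if not (self.cls >= 0):
            raise ValueError(f"cls must be non-negative, got {self.cls!r}")


def compute_cr(
    clr: float, fup: float, constants: PhysiologyConstants = DEFAULT_CONSTANTS
) -> float:
    """Clearance ratio CR = CLr / (fu,p × GFR).

    ``clr`` in mL/min/kg and ``fup`` dimensionless; the result is
    dimensionless.  ``fup`` must be strictly positive (CR is undefined for a
    fully bound drug) and ``clr`` non-negative.
    """
    if not (fup > 0):
        raise ValueError(f"fup must be strictly positive to compute CR, got {fup!r}")
    if not (clr >= 0):
        raise ValueError(f"clr must be non-negative, got {clr!r}")
    return clr / (fup * constants.gfr)


def classify_cr_type(
    cr: float, constants: PhysiologyConstants = DEFAULT_CONSTANTS
) -> CRType:
    """Band a clearance ratio into R / IM / S.

    R for CR < ``cr_low``; IM for ``cr_low`` ≤ CR < ``cr_high``; S for
    CR ≥ ``cr_high`` — band edges follow the defining inequalities, so the
    lower edge is IM and the upper edge is S.
    """
    if not (cr >= 0):
        raise ValueError(f"cr must be non-negative, got {cr!r}")
    if cr < constants.cr_low:
        return CRType.R
    if cr < constants.cr_high:
        return CRType.IM
    return CRType.S


def binarize_fe(
    fe: float, constants: PhysiologyConstants = DEFAULT_CONSTANTS
) -> str:
    """Binarize the fraction excreted unchanged in urine.

    Returns :data:`FE_HIGH_MEDIUM` iff ``fe`` ≥ the threshold (0.30 by
    default, boundary inclusive), else :data:`FE_LOW`.
    """
    if not (0 <= fe <= 1):
        raise ValueError(f"fe must lie in [0, 1], got {fe!r}")
    return FE_HIGH_MEDIUM if fe >= constants.fe_threshold else FE_LOW


def forward_clr(
    params: MechanismParams, constants: PhysiologyConstants = DEFAULT_CONSTANTS
) -> float:
    """Mechanistic renal clearance CLr = (1 − FR)(fu,p × GFR + CLs), mL/min/kg.

    With ``fr = 0`` and ``cls = 0`` this reduces to the filtration-only
    intermediate-type clearance ``fup × gfr``.  The result is strictly
    positive for valid parameters.
    """
    if not isinstance(params, MechanismParams):
        params = MechanismParams(**params) if isinstance(params, dict) else params
    return (1.0 - params.fr) * (params.fup * constants.gfr + params.cls)


def per_kg_to_absolute(value_per_kg: float, body_mass_kg: float) -> float:
    """Convert a per-body-weight clearance (mL/min/kg) to absolute mL/min."""
    if not (body_mass_kg > 0):
        raise ValueError(f"body_mass_kg must be positive, got {body_mass_kg!r}")
    return value_per_kg * body_mass_kg


def absolute_to_per_kg(value_ml_min: float, body_mass_kg: float) -> float:
    """Convert an absolute clearance (mL/min) to per-body-weight mL/min/kg."""
    if not (body_mass_kg > 0):
        raise ValueError(f"body_mass_kg must be positive, got {body_mass_kg!r}")
    return value_ml_min / body_mass_kg
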