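"""Published photophysical constants of common green FPs and StayGold variants.

Values are the printed characterization-table constants: absorbance and
emission maxima (nm), absolute molar extinction coefficients at the
absorbance maximum and at the 483-nm excitation reference (10³ M⁻¹cm⁻¹ as
printed; converted to M⁻¹cm⁻¹ here) and the fluorescence quantum yield.
Entries whose ε or QY were not measured are omitted (tdoxStayGold, QC2-6).
"""

from __future__ import annotations

from .spectra import FPPhotophysics

# name, λab, λem, ε(λab) ×10³, ε(483) ×10³, QY_f
_TABLE = [
    ("EGFP", 488, 509, 51.0, 51.0, 0.71),
    ("mEGFP", 488, 509, 56.5, 56.5, 0.70),
    ("mClover3", 505, 518, 99.0, 52.0, 0.84),
    ("mNeonGreen", 505, 518, 112.0, 64.0, 0.87),
    ("mGreenLantern", 501, 515, 117.0, 76.0, 0.74),
    ("StayGold", 496, 505, 159.0, 105.0, 0.93),
    ("tdStayGold", 496, 504, 162.0, 108.0, 0.90),
    ("td5StayGold", 496, 504, 155.0, 103.4, 0.91),
    ("td5oxStayGold", 496, 506, 156.0, 102.6, 0.93),
    ("td8oxStayGold", 496, 506, 157.0, 103.0, 0.93),
    ("td8ox2StayGold", 496, 506, 159.0, 105.0, 0.93),
    ("mStayGold", 499, 510, 164.0, 100.0, 0.83),
    ("mStayGold2", 499, 509, 175.0, 110.0, 0.79),
]


def reference_photophysics() -> list[FPPhotophysics]:
    """FPPhotophysics records for every FP with fully printed constants."""
    return [
        FPPhotophysics(
            name=name,
            lambda_ab=lab,
            lambda_em=lem,
            eps_peak=eps_peak * 1e3,
            eps_at_ex=eps_483 * 1e3,
            qy=qy,
        )
        for name, lab, lem, eps_peak, eps_483, qy in _TABLE
    ]


def get_fp(name: str) -> FPPhotophysics:
    for fp in reference_photophysics():
        if fp.name == name:
            return fp
    raise KeyError(f"no reference photophysics for {name!r}")
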