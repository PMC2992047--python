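"""Molar masses and yield unit conversions.

Product yields on glucose are reported either on a mass basis
(mg product per g glucose) or on a molar basis (mol product per mol
glucose); the conversions here move between the two.  Vanillin
beta-D-glucoside yields are conventionally expressed in vanillin
equivalents (the glucosyl moiety is recycled carrier, not product), so
the vanillin molar mass is the default product mass.
"""

from __future__ import annotations

#: Molar masses, g/mol.
MW_GLUCOSE = 180.16
MW_VANILLIN = 152.15
MW_VANILLIN_GLUCOSIDE = 314.29
MW_ETHANOL = 46.07


def mass_to_molar_yield(
    mass_yield_mg_per_g: float,
    mw_product: float = MW_VANILLIN,
    mw_substrate: float = MW_GLUCOSE,
) -> float:
    """Convert a mass yield (mg/g) to a molar yield (mol/mol)."""
    return mass_yield_mg_per_g / 1000.0 * mw_substrate / mw_product


def molar_to_mass_yield(
    molar_yield: float,
    mw_product: float = MW_VANILLIN,
    mw_substrate: float = MW_GLUCOSE,
) -> float:
    """Convert a molar yield (mol/mol) to a mass yield (mg/g)."""
    return molar_yield * 1000.0 * mw_product / mw_substrate
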