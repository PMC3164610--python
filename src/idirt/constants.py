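"""Single source of truth for physical constants and modification masses.

Residue monoisotopic masses come from :data:`pyteomics.mass.std_aa_mass`;
isotope masses and natural abundances from :data:`pyteomics.mass.nist_mass`.
The convenience constants below are rounded to 6 decimal places, the precision
used throughout the pipeline.
"""

from pyteomics import mass as _pmass

PROTON_MASS = 1.007276
"""Mass of a proton in Da (charge carrier for positive-mode m/z)."""

WATER_MASS = 18.010565
"""Monoisotopic mass of H2O in Da, added once per peptide."""

C13_C12_DELTA = 1.003355
"""Mass difference between 13C and 12C in Da; the isotopologue spacing."""

ARG_13C6_SHIFT = 6 * C13_C12_DELTA  # 6.020130 Da per heavy arginine
"""Mass shift of a fully 13C6-labeled arginine relative to light arginine."""

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES}

#: Built-in variable/fixed modifications (name -> monoisotopic delta, Da).
MODIFICATION_MASS = {
    "acetyl": 42.010565,
    "oxidation": 15.994915,
    "carbamidomethyl": 57.021464,
}

# Isotope patterns as (nominal mass offset, exact mass, abundance) per element,
# taken from pyteomics' NIST table. Offsets are relative to the lightest
# isotope; sulfur has no offset-3 isotope.
_NIST = _pmass.nist_mass


def _element_isotopes(symbol: str, lightest: int) -> list[tuple[int, float, float]]:
    out = []
    for a, (m, ab) in sorted(_NIST[symbol].items()):
        if a == 0 or ab == 0.0:
            continue
        out.append((a - lightest, m, ab))
    return out


ELEMENT_ISOTOPES = {
    "C": _element_isotopes("C", 12),
    "H": _element_isotopes("H", 1),
    "N": _element_isotopes("N", 14),
    "O": _element_isotopes("O", 16),
    "S": _element_isotopes("S", 32),
}

#: Averagine model: mean atom counts per 111.1254 Da of peptide mass.
AVERAGINE_UNIT = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_UNIT_MASS = 111.1254

#: Monoisotopic mass of each element's lightest isotope.
ELEMENT_MONO_MASS = {
    "C": _NIST["C"][12][0],
    "H": _NIST["H"][1][0],
    "N": _NIST["N"][14][0],
    "O": _NIST["O"][16][0],
    "S": _NIST["S"][32][0],
}
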