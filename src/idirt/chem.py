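"""Peptide chemistry: masses, m/z, label shifts, digestion, isotope envelopes.

This layer knows nothing about spectra or files. It provides the arithmetic
that places a light/heavy peptide pair on the m/z axis: monoisotopic masses
(residue table + water + modification deltas), the 13C6-arginine label shift,
in-silico tryptic digestion with missed cleavages, and averagine isotope
envelopes used both to render synthetic spectra and to correct the light
envelope's contamination of the heavy monoisotopic peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import parser as _pparser

from .constants import (
    AVERAGINE_UNIT,
    AVERAGINE_UNIT_MASS,
    C13_C12_DELTA,
    ELEMENT_ISOTOPES,
    ELEMENT_MONO_MASS,
    MODIFICATION_MASS,
    PROTON_MASS,
    RESIDUE_MASS,
    STANDARD_RESIDUES,
    WATER_MASS,
)

# Trypsin: cleave C-terminal to K or R unless the next residue is proline.
TRYPSIN_RULE = r"[KR](?=[^P])"


@dataclass(frozen=True)
class LabelScheme:
    """Metabolic labeling scheme: which residues carry the heavy isotopes.

    The default is SILAC-style 13C6-arginine: every arginine in the heavy
    channel is 6.020129 Da heavier than its light counterpart.
    """

    labeled_residues: frozenset[str] = frozenset({"R"})
    mass_shift_per_residue: float = 6.020129

    def __post_init__(self) -> None:
        if not self.labeled_residues:
            raise ValueError("labeled_residues must be non-empty")
        if not self.mass_shift_per_residue > 0:
            raise ValueError("mass_shift_per_residue must be positive")

    def count_labeled(self, sequence: str) -> int:
        return sum(1 for aa in sequence if aa in self.labeled_residues)


Modification = tuple[int, str, float]  # (1-based position in peptide, name, delta Da)


@dataclass(frozen=True)
class PeptideSpecies:
    """An identified peptidoform: sequence + modifications + charge.

    ``protein_start`` is the 1-based position of the peptide's first residue
    within its protein, so a modification at peptide position ``p`` sits at
    protein position ``protein_start + p - 1`` (the field's H3K9/H3K14
    coordinates).
    """

    sequence: str
    modifications: tuple[Modification, ...] = ()
    charge: int = 2
    protein_id: str = ""
    protein_start: int = 1
    scheme: LabelScheme = field(default=LabelScheme(), compare=False)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.protein_start < 1:
            raise ValueError("protein_start must be >= 1")
        for pos, name, _delta in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification {name!r} at position {pos} outside peptide "
                    f"of length {len(self.sequence)}"
                )

    @property
    def n_label_residues(self) -> int:
        return self.scheme.count_labeled(self.sequence)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.sequence, self.modifications)

    @property
    def mz(self) -> float:
        return mz_from_mass(self.mass, self.charge)

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive protein coordinates covered by the peptide."""
        return self.protein_start, self.protein_start + len(self.sequence) - 1

    def protein_modifications(self) -> tuple[tuple[int, str], ...]:
        """Modifications as (protein position, name) pairs."""
        return tuple(
            (self.protein_start + pos - 1, name) for pos, name, _ in self.modifications
        )

    @property
    def mod_string(self) -> str:
        """Canonical 'pos:name' peptide-coordinate form (sorted by position)."""
        return ";".join(
            f"{pos}:{name}" for pos, name, _ in sorted(self.modifications)
        )

    @property
    def peptidoform_key(self) -> tuple[str, str, str]:
        """Identity used to pool PSMs: charge states collapse together."""
        return (self.protein_id, self.sequence, self.mod_string)


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative isotopologue abundances M+0..M+k, normalized to sum 1."""

    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances):
            raise ValueError("abundances must be non-negative")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    def __len__(self) -> int:
        return len(self.abundances)

    def ratio_to_mono(self, k: int) -> float:
        """Abundance of M+k relative to the monoisotopic peak."""
        if k >= len(self.abundances):
            raise ValueError(
                f"envelope covers M+0..M+{len(self.abundances) - 1}, need M+{k}"
            )
        return self.abundances[k] / self.abundances[0]


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    start: int  # 1-based position in the protein
    missed_cleavages: int


def validate_sequence(sequence: str) -> None:
    """Reject empty sequences and non-standard residue codes (B, Z, X, U, O...)."""
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for i, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(
                f"unknown residue code {aa!r} at position {i} in {sequence!r}"
            )


def monoisotopic_mass(sequence: str, modifications: tuple[Modification, ...] | list = ()) -> float:
    """Neutral monoisotopic mass: residues + one water + modification deltas."""
    validate_sequence(sequence)
    mass = WATER_MASS + sum(RESIDUE_MASS[aa] for aa in sequence)
    for _pos, name, delta in modifications:
        if not np.isfinite(delta):
            raise ValueError(f"non-finite mass delta for modification {name!r}")
        mass += delta
    return mass


def mz_from_mass(mass: float, charge: int) -> float:
    """m/z of the [M + charge*H]^charge+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if not mass > 0:
        raise ValueError(f"mass must be positive, got {mass}")
    return (mass + charge * PROTON_MASS) / charge


def heavy_shift(peptide: PeptideSpecies, scheme: LabelScheme | None = None) -> tuple[float, float]:
    """(mass shift, m/z shift) between the heavy and light forms of a peptide.

    Peptides without labeled residues return (0, 0); they carry no light/heavy
    pair and are unquantifiable downstream.
    """
    scheme = scheme or peptide.scheme
    n = scheme.count_labeled(peptide.sequence)
    mass_shift = n * scheme.mass_shift_per_residue
    return mass_shift, mass_shift / peptide.charge


def tryptic_digest(protein_sequence: str, max_missed: int = 2) -> list[DigestPeptide]:
    """In-silico tryptic digest with up to ``max_missed`` missed cleavages.

    Cleaves C-terminal to K/R except before proline. Returns peptides ordered
    by start position, then length, each with its 1-based start coordinate.
    """
    validate_sequence(protein_sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    peptides = []
    for start0, pep in _pparser.icleave(
        protein_sequence, TRYPSIN_RULE, missed_cleavages=max_missed, regex=True
    ):
        mc = sum(
            1
            for i in range(len(pep) - 1)
            if pep[i] in "KR" and pep[i + 1] != "P"
        )
        peptides.append(DigestPeptide(pep, start0 + 1, mc))
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def averagine_composition(mass: float) -> dict[str, int]:
    """Estimated elemental composition of a peptide of the given mass.

    Scales the averagine unit, rounds C/N/O/S to the nearest integer, then
    sets the hydrogen count so the monoisotopic mass matches within one
    hydrogen.
    """
    if not mass > 0:
        raise ValueError(f"mass must be positive, got {mass}")
    scale = mass / AVERAGINE_UNIT_MASS
    counts = {
        el: max(0, round(scale * n)) for el, n in AVERAGINE_UNIT.items() if el != "H"
    }
    heavy_atoms_mass = sum(ELEMENT_MONO_MASS[el] * n for el, n in counts.items())
    counts["H"] = max(0, round((mass - heavy_atoms_mass) / ELEMENT_MONO_MASS["H"]))
    return counts


def _element_distribution(element: str, n_atoms: int, k_max: int) -> np.ndarray:
    """Isotopologue distribution (by nominal mass offset) of n atoms of one element.

    Binary exponentiation of the single-atom distribution; truncation at k_max
    is safe because convolution coefficients below k_max never depend on
    higher-order terms.
    """
    base = np.zeros(k_max + 1)
    for offset, _mass, abundance in ELEMENT_ISOTOPES[element]:
        if offset <= k_max:
            base[offset] += abundance
    result = np.zeros(k_max + 1)
    result[0] = 1.0
    power = base
    n = n_atoms
    while n:
        if n & 1:
            result = np.convolve(result, power)[: k_max + 1]
        n >>= 1
        if n:
            power = np.convolve(power, power)[: k_max + 1]
    return result


def averagine_envelope(mass: float, k_max: int = 10) -> IsotopeEnvelope:
    """Isotope envelope M+0..M+k_max of an averagine peptide of the given mass.

    Elemental isotope masses/abundances are the NIST values; the distribution
    is the convolution of per-element multinomials, renormalized to sum 1 over
    the retained isotopologues.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    counts = averagine_composition(mass)
    dist = np.zeros(k_max + 1)
    dist[0] = 1.0
    for element, n_atoms in counts.items():
        if n_atoms:
            dist = np.convolve(dist, _element_distribution(element, n_atoms, k_max))[
                : k_max + 1
            ]
    dist = dist / dist.sum()
    return IsotopeEnvelope(tuple(dist.tolist()))


def isotopologue_spacing(charge: int) -> float:
    """m/z spacing between adjacent isotopologues at the given charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return C13_C12_DELTA / charge
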