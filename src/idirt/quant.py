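"""Light/heavy monoisotopic pair extraction and the percent-light statistic.

For each PSM the light target m/z is computed from the peptidoform's
monoisotopic mass and the heavy target sits one label shift higher
(6.020129 Da per arginine, divided by charge). Intensities are read from the
MS1 scans around the PSM's retention time; percent light = I_L / (I_L + I_H).

Because a 6 x (13C-12C) label shift lands the heavy monoisotopic peak exactly
on the light peptide's M+6 isotopologue (both are six 13C substitutions), the
light envelope contaminates the heavy measurement for large peptides; the
overlap correction subtracts that contribution using the averagine envelope
of the light peptidoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import IsotopeEnvelope, averagine_envelope, heavy_shift
from .io import PsmRecord, SpectrumMS1


@dataclass(frozen=True)
class QuantParams:
    """Extraction settings.

    ppm_tolerance defaults to 10 ppm (the precursor tolerance reused for peak
    matching); rt_window is the half-width in seconds around the PSM retention
    time; xic_mode 'apex' reads both channels from the scan with the maximal
    light peak, 'summed' integrates over all window scans.
    """

    ppm_tolerance: float = 10.0
    rt_window: float = 15.0
    xic_mode: str = "apex"
    overlap_correction: bool = True
    same_scan_ratio: bool = True

    def __post_init__(self) -> None:
        if not self.ppm_tolerance > 0:
            raise ValueError("ppm_tolerance must be positive")
        if self.rt_window < 0:
            raise ValueError("rt_window must be >= 0")
        if self.xic_mode not in ("apex", "summed"):
            raise ValueError(f"xic_mode must be 'apex' or 'summed', got {self.xic_mode!r}")


@dataclass(frozen=True)
class PairQuant:
    """Extracted light/heavy intensities for one PSM or peptidoform."""

    protein_id: str
    sequence: str
    mod_string: str
    protein_start: int
    charges: tuple[int, ...]
    I_L: float
    I_H: float
    percent_light: float
    flags: frozenset[str] = frozenset()
    n_psms: int = 1
    psm: PsmRecord | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.I_L < 0 or self.I_H < 0:
            raise ValueError("intensities must be non-negative")
        if not 0.0 <= self.percent_light <= 1.0:
            raise ValueError("percent_light must be in [0, 1]")

    @property
    def peptidoform_key(self) -> tuple[str, str, str]:
        return (self.protein_id, self.sequence, self.mod_string)


@dataclass
class QuantReport:
    n_psms: int = 0
    n_quantified: int = 0
    n_excluded_no_scans: int = 0
    n_excluded_both_missing: int = 0
    excluded: list[str] = field(default_factory=list)


def percent_light(I_L: float, I_H: float) -> float:
    """Fraction of the pair intensity carried by the light channel."""
    if I_L < 0 or I_H < 0:
        raise ValueError("intensities must be non-negative")
    total = I_L + I_H
    if total == 0:
        raise ValueError("percent_light undefined when both intensities are zero")
    return I_L / total


def find_peak(spectrum: SpectrumMS1, target_mz: float, ppm_tolerance: float) -> float | None:
    """Intensity of the peak nearest to target_mz within the ppm window.

    Distance ties are broken toward the higher-intensity peak. Returns None
    when no peak lies in the window — absence is a value, not an error.
    """
    if not target_mz > 0:
        raise ValueError("target_mz must be positive")
    half_width = target_mz * ppm_tolerance * 1e-6
    lo = np.searchsorted(spectrum.mz, target_mz - half_width, side="left")
    hi = np.searchsorted(spectrum.mz, target_mz + half_width, side="right")
    if lo >= hi:
        return None
    window_mz = spectrum.mz[lo:hi]
    window_int = spectrum.intensity[lo:hi]
    dist = np.abs(window_mz - target_mz)
    best = np.lexsort((-window_int, dist))[0]
    return float(window_int[best])


def overlap_correct(
    I_H_raw: float,
    I_L: float,
    envelope: IsotopeEnvelope,
    shift_isotopologues: int,
) -> tuple[float, bool]:
    """Remove the light envelope's M+shift contribution from the heavy mono peak.

    Returns (corrected intensity, clamped flag). The correction subtracts
    I_L x abundance[shift]/abundance[0]; a negative result clamps to 0.
    """
    ratio = envelope.ratio_to_mono(shift_isotopologues)
    corrected = I_H_raw - I_L * ratio
    if corrected < 0:
        return 0.0, True
    return corrected, False


def _extract_channel(
    scans: list[SpectrumMS1], target_mz: float, params: QuantParams
) -> tuple[float | None, int | None]:
    """(apex intensity, apex scan index) or (summed intensity, None)."""
    found = [(i, find_peak(s, target_mz, params.ppm_tolerance)) for i, s in enumerate(scans)]
    found = [(i, v) for i, v in found if v is not None]
    if not found:
        return None, None
    if params.xic_mode == "summed":
        return sum(v for _i, v in found), None
    i_apex, v_apex = max(found, key=lambda iv: iv[1])
    return v_apex, i_apex


def extract_pair(
    spectra: list[SpectrumMS1], psm: PsmRecord, params: QuantParams | None = None
) -> tuple[PairQuant | None, str | None]:
    """Extract (I_L, I_H, percent_light) for one PSM.

    Returns (PairQuant, None) on success or (None, reason) when the record is
    excluded (no scans in the retention-time window, or both peaks missing).
    A missing heavy channel yields percent_light 1 with flag ``heavy_missing``
    — the bait-control situation, where absence of heavy signal is itself the
    measurement — and symmetrically for a missing light channel.
    """
    params = params or QuantParams()
    pep = psm.peptide
    light_mz = pep.mz
    _mass_shift, mz_shift = heavy_shift(pep)
    if mz_shift == 0:
        return None, f"{psm.psm_id}: no labeled residue; unquantifiable"
    heavy_mz = light_mz + mz_shift

    scans = [
        s for s in spectra if abs(s.retention_time - psm.retention_time) <= params.rt_window
    ]
    if not scans:
        return None, f"{psm.psm_id}: no MS1 scans within {params.rt_window} s"

    flags: set[str] = set()
    I_L, apex_idx = _extract_channel(scans, light_mz, params)
    if I_L is not None and params.xic_mode == "apex" and params.same_scan_ratio:
        I_H = find_peak(scans[apex_idx], heavy_mz, params.ppm_tolerance)
    else:
        I_H, _ = _extract_channel(scans, heavy_mz, params)

    if I_L is None and I_H is None:
        return None, f"{psm.psm_id}: both monoisotopic peaks missing"
    if I_L is None:
        I_L = 0.0
        flags.add("light_missing")
    if I_H is None:
        I_H = 0.0
        flags.add("heavy_missing")
    elif params.overlap_correction and I_L > 0:
        n_label = pep.n_label_residues
        shift = 6 * n_label
        envelope = averagine_envelope(pep.mass, k_max=shift + 2)
        I_H, clamped = overlap_correct(I_H, I_L, envelope, shift)
        flags.add("overlap_corrected")
        if clamped:
            flags.add("clamped")

    if I_L == 0.0 and I_H == 0.0:
        return None, f"{psm.psm_id}: both monoisotopic peaks missing"

    return (
        PairQuant(
            protein_id=pep.protein_id,
            sequence=pep.sequence,
            mod_string=pep.mod_string,
            protein_start=pep.protein_start,
            charges=(pep.charge,),
            I_L=I_L,
            I_H=I_H,
            percent_light=percent_light(I_L, I_H),
            flags=frozenset(flags),
            psm=psm,
        ),
        None,
    )


def collapse_peptidoforms(pairs: list[PairQuant]) -> list[PairQuant]:
    """Pool PSM-level quants so each peptidoform contributes one value.

    Charge states and repeat PSMs of the same (protein, sequence, mods) are
    combined by summing intensities, which makes the pooled percent light the
    (I_L + I_H)-weighted mean of the per-PSM values. Distinct modification
    sets never collapse together.
    """
    by_key: dict[tuple[str, str, str], list[PairQuant]] = {}
    for p in pairs:
        by_key.setdefault(p.peptidoform_key, []).append(p)
    collapsed = []
    for key in sorted(by_key):
        group = by_key[key]
        I_L = sum(p.I_L for p in group)
        I_H = sum(p.I_H for p in group)
        flags = frozenset().union(*(p.flags for p in group))
        collapsed.append(
            PairQuant(
                protein_id=group[0].protein_id,
                sequence=group[0].sequence,
                mod_string=group[0].mod_string,
                protein_start=group[0].protein_start,
                charges=tuple(sorted({c for p in group for c in p.charges})),
                I_L=I_L,
                I_H=I_H,
                percent_light=percent_light(I_L, I_H),
                flags=flags,
                n_psms=sum(p.n_psms for p in group),
            )
        )
    return collapsed


def quantify_all(
    spectra: list[SpectrumMS1],
    psms: list[PsmRecord],
    params: QuantParams | None = None,
) -> tuple[list[PairQuant], QuantReport]:
    """Extract one pair per PSM, then collapse to unique peptidoforms."""
    params = params or QuantParams()
    report = QuantReport(n_psms=len(psms))
    psm_pairs = []
    for psm in psms:
        pair, reason = extract_pair(spectra, psm, params)
        if pair is None:
            report.excluded.append(reason)
            if "no MS1 scans" in reason:
                report.n_excluded_no_scans += 1
            else:
                report.n_excluded_both_missing += 1
        else:
            psm_pairs.append(pair)
    collapsed = collapse_peptidoforms(psm_pairs)
    report.n_quantified = len(collapsed)
    return collapsed, report


def pair_to_row(pair: PairQuant, condition: str) -> dict:
    """Quant-table row (io.QUANT_COLUMNS) for one collapsed peptidoform."""
    return {
        "protein_id": pair.protein_id,
        "sequence": pair.sequence,
        "modifications": pair.mod_string,
        "protein_start": pair.protein_start,
        "charges": ",".join(str(c) for c in pair.charges),
        "condition": condition,
        "n_psms": pair.n_psms,
        "I_L": pair.I_L,
        "I_H": pair.I_H,
        "percent_light": pair.percent_light,
        "flags": pair.flags,
    }
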