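"""Ground-truth-bearing synthetic I-DIRT experiments.

Emulates the study design: a light-only bait protein (the TAP-tagged histone,
expressed only in the 12C6-Arg culture), non-specific proteins at the 1:1
light:heavy mixing ratio, and histone-like proteins whose light fraction
depends on the formaldehyde cross-linking condition — with acetylated
peptidoforms exchanging at least as fast as their bulk counterparts.

For each condition the generator digests the proteins, keeps Arg-containing
peptides, places each peptidoform in its own retention-time slot, and renders
light and heavy averagine envelopes on a shared isotopologue grid (heavy
monoisotopic peak at light + 6 x nArg x 1.003355/z, so the light M+6nArg /
heavy M+0 coincidence is physically reproduced). Noise: a shared lognormal
ionization factor per species-scan (both channels), a smaller independent
lognormal per channel, bounded uniform m/z calibration jitter, random baseline
peaks, and rare whole-channel dropout. Outputs are mzML + PSM/group/truth
TSVs, bit-reproducible for a fixed seed.

The bundled protein sequences are synthetic histone-like fixtures (H3-like
with the K9/K14 signature, H4-like with K12/K16), not real proteome entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import (
    LabelScheme,
    PeptideSpecies,
    averagine_envelope,
    isotopologue_spacing,
    monoisotopic_mass,
    mz_from_mass,
    tryptic_digest,
)
from .constants import MODIFICATION_MASS
from .io import (
    GroupDefinition,
    PsmRecord,
    SpectrumMS1,
    write_group_table,
    write_mzml,
    write_psm_table,
)

ACETYL = "acetyl"
ACETYL_DELTA = MODIFICATION_MASS[ACETYL]

# Synthetic histone-like fixtures. H3_SYN carries the K9/K14 signature inside
# the KSTGGKAPR tryptic peptide; H4_SYN carries K12/K16 (K12 is followed by
# proline so several distinct tryptic peptides span both sites within two
# missed cleavages). BAIT and NSP sequences are strings of distinct
# Arg-terminated tryptic units.
H3_SYN = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTELLIR"
H4_SYN = "SGRGKGGKGLGKPGAKRHRKVLRDNIQGITKAPIRRGGVKRISGLIYEETR"
BAIT_SYN = (
    "SDTAVLRGQEILSRNAGTFEHRVLDSMEGRTPQAYNIRGESDVFARHLTQSNGR"
    "AVEFDPLRSGMTQHYRDLNAVTESRQGIFEPSARTSHVLNDGRAEQMPFVSR"
)
NSP1_SYN = (
    "GADSLFTRHQEVNIARSTMPLDGRYVENAQSRFDGHLTVRQASEMNPRGTLIVDSR"
    "EHNFAQGRVDSPLMTRYAGQENLR"
)
NSP2_SYN = (
    "TDFMSLARGHQPEVIRNSDTLAGRVFEMQHSRLDGNAPTRYSEVHLMRQAGDFNIR"
    "ETPLSVGRHMDNAQFRVGSELPTR"
)
NSP3_SYN = (
    "SEQGLDVRAFHTMPNRGVDLESARHTQFNIGRMPSEDLVRYGANHQTRFLDVESMR"
    "QTGHPLARNVEFSDGRASMQLHTR"
)
NSP4_SYN = (
    "DLGTFSMRVHQENPARGSDAVLTRFMHQEGIRNPTLSDARYEVGHMQRSTDFLNVR"
    "AQEGMPSRHLVTNDFRGEASQMIR"
)


@dataclass(frozen=True)
class SimProtein:
    """One simulated protein. ``channel_mode`` 'light_only' models the bait.

    ``signature_class``/``signature_sites`` describe the acetylation signature
    (protein coordinates); peptides spanning every site additionally yield a
    fully acetylated peptidoform assigned to ``signature_class``.
    """

    protein_id: str
    sequence: str
    class_label: str
    channel_mode: str = "mixed"  # 'mixed' | 'light_only'
    signature_class: str | None = None
    signature_sites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.channel_mode not in ("mixed", "light_only"):
            raise ValueError(f"bad channel_mode {self.channel_mode!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Noise parameters; all can be zeroed for noise-free oracle runs.

    ``intensity_cv`` is a shared per-species-per-scan ionization factor (light
    and heavy co-elute, so spray fluctuations hit both channels together);
    ``channel_cv`` is the smaller channel-independent residual. ``mz_jitter_ppm``
    is the half-width of a uniform calibration error.
    """

    intensity_cv: float = 0.2
    channel_cv: float = 0.05
    mz_jitter_ppm: float = 5.0
    baseline_peaks_per_scan: int = 20
    baseline_mz_range: tuple[float, float] = (300.0, 1800.0)
    baseline_intensity_range: tuple[float, float] = (1e2, 1e4)
    missing_peak_prob: float = 0.005

    def __post_init__(self) -> None:
        if min(self.intensity_cv, self.channel_cv, self.mz_jitter_ppm) < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0.0 <= self.missing_peak_prob <= 1.0:
            raise ValueError("missing_peak_prob must be in [0, 1]")


NOISE_FREE = NoiseModel(
    intensity_cv=0.0, channel_cv=0.0, mz_jitter_ppm=0.0,
    baseline_peaks_per_scan=0, missing_peak_prob=0.0,
)


@dataclass(frozen=True)
class SimScenario:
    """Full description of a synthetic experiment; seed is mandatory."""

    proteins: tuple[SimProtein, ...]
    conditions: tuple[str, ...]
    light_fraction: tuple[tuple[str, str, float], ...]  # (class, condition, f)
    seed: int
    max_missed: int = 2
    min_peptide_len: int = 6
    max_peptide_len: int = 30
    max_peptidoforms_per_protein: int = 12
    charge_choices: tuple[int, ...] = (2, 3)
    charge_probs: tuple[float, ...] = (0.7, 0.3)
    second_charge_prob: float = 0.3
    base_intensity_range: tuple[float, float] = (1e5, 1e7)
    n_scans: int = 3
    scan_spacing: float = 2.0
    slot_spacing: float = 60.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    decoy_psm_rate: float = 0.1
    decoy_q_range: tuple[float, float] = (0.02, 0.5)
    unlabeled_psm_count: int = 2
    scheme: LabelScheme = field(default_factory=LabelScheme)

    def __post_init__(self) -> None:
        table = self.fraction_table()
        for (label, condition), f in table.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"light fraction for {(label, condition)} not in [0,1]")
        for p in self.proteins:
            for c in self.conditions:
                if p.channel_mode == "light_only":
                    if table.get((p.class_label, c), 1.0) != 1.0:
                        raise ValueError(
                            f"light_only class {p.class_label!r} must have f = 1"
                        )
                elif (p.class_label, c) not in table:
                    raise ValueError(
                        f"no light fraction for ({p.class_label!r}, {c!r})"
                    )
                if p.signature_class and (p.signature_class, c) not in table:
                    raise ValueError(
                        f"no light fraction for ({p.signature_class!r}, {c!r})"
                    )

    def fraction_table(self) -> dict[tuple[str, str], float]:
        return {(label, cond): f for label, cond, f in self.light_fraction}


@dataclass(frozen=True)
class SimSpecies:
    """One rendered (peptidoform, charge) with its slot and intensity share."""

    peptide: PeptideSpecies
    class_label: str
    slot: int
    weight: float  # share of the peptidoform's base intensity


@dataclass
class SimResult:
    scenario: SimScenario
    spectra: dict[str, list[SpectrumMS1]]
    psms: dict[str, list[PsmRecord]]
    groups: list[GroupDefinition]
    truth: pd.DataFrame

    def paths(self, outdir) -> dict[str, object]:
        from pathlib import Path

        outdir = Path(outdir)
        return {
            "mzml": {c: outdir / f"{c}.mzML" for c in self.scenario.conditions},
            "psms": {c: outdir / f"{c}_psms.tsv" for c in self.scenario.conditions},
            "groups": outdir / "groups.tsv",
            "truth": outdir / "truth.tsv",
        }

    def write(self, outdir) -> dict[str, object]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = self.paths(outdir)
        for c in self.scenario.conditions:
            write_mzml(self.spectra[c], paths["mzml"][c])
            write_psm_table(self.psms[c], paths["psms"][c])
        write_group_table(self.groups, paths["groups"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False,
                          float_format="%.10g")
        return paths


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with mean exactly 1 (sigma^2/2 mean correction)."""
    if cv == 0.0:
        return 1.0
    sigma = _lognormal_sigma(cv)
    return math.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma)


def group_definitions(proteins: tuple[SimProtein, ...]) -> list[GroupDefinition]:
    """Build the stratification table implied by the simulated proteins."""
    by_class: dict[str, list[SimProtein]] = {}
    for p in proteins:
        by_class.setdefault(p.class_label, []).append(p)
    groups = []
    for label, members in by_class.items():
        forbidden = frozenset(
            (pos, ACETYL) for p in members for pos in p.signature_sites
        )
        groups.append(
            GroupDefinition(
                class_label=label,
                protein_ids=frozenset(p.protein_id for p in members),
                forbidden_mods=forbidden,
            )
        )
    for p in proteins:
        if p.signature_class:
            groups.append(
                GroupDefinition(
                    class_label=p.signature_class,
                    protein_ids=frozenset({p.protein_id}),
                    required_mods=frozenset((pos, ACETYL) for pos in p.signature_sites),
                )
            )
    return groups


def _candidate_peptides(protein: SimProtein, scenario: SimScenario):
    """Arg-containing tryptic peptides within the configured length band."""
    out = []
    for dp in tryptic_digest(protein.sequence, scenario.max_missed):
        if not scenario.min_peptide_len <= len(dp.sequence) <= scenario.max_peptide_len:
            continue
        if scenario.scheme.count_labeled(dp.sequence) < 1:
            continue
        out.append(dp)
    return out


def enumerate_peptidoforms(
    protein: SimProtein, scenario: SimScenario, rng: np.random.Generator
) -> list[tuple[PeptideSpecies, str]]:
    """(peptidoform, class label) pairs for one protein.

    Unmodified Arg-containing peptides are capped at
    ``max_peptidoforms_per_protein`` (sampled without replacement when more
    exist); every peptide spanning the full acetylation signature also yields
    the fully acetylated peptidoform.
    """
    candidates = _candidate_peptides(protein, scenario)
    if not candidates:
        raise ValueError(
            f"protein {protein.protein_id!r} (class {protein.class_label!r}) "
            "yields no quantifiable Arg-containing peptides"
        )
    if len(candidates) > scenario.max_peptidoforms_per_protein:
        idx = sorted(
            rng.choice(len(candidates), scenario.max_peptidoforms_per_protein,
                       replace=False).tolist()
        )
        chosen = [candidates[i] for i in idx]
    else:
        chosen = candidates
    forms: list[tuple[PeptideSpecies, str]] = []
    for dp in chosen:
        forms.append(
            (
                PeptideSpecies(dp.sequence, (), 2, protein.protein_id, dp.start,
                               scenario.scheme),
                protein.class_label,
            )
        )
    if protein.signature_class:
        for dp in candidates:
            end = dp.start + len(dp.sequence) - 1
            if all(dp.start <= pos <= end for pos in protein.signature_sites):
                mods = tuple(
                    sorted(
                        (pos - dp.start + 1, ACETYL, ACETYL_DELTA)
                        for pos in protein.signature_sites
                    )
                )
                forms.append(
                    (
                        PeptideSpecies(dp.sequence, mods, 2, protein.protein_id,
                                       dp.start, scenario.scheme),
                        protein.signature_class,
                    )
                )
    return forms


def _render_species_scans(
    species: SimSpecies,
    I_L: float,
    I_H: float,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Peak lists (rt, mz, intensity) for one species' scans."""
    pep = species.peptide
    noise = scenario.noise
    n_label = pep.n_label_residues
    shift_iso = 6 * n_label
    z = pep.charge
    spacing = isotopologue_spacing(z)
    light_mass = pep.mass
    light_mz0 = mz_from_mass(light_mass, z)
    k_max = max(10, shift_iso + 2)
    env_light = averagine_envelope(light_mass, k_max)
    env_heavy = averagine_envelope(
        light_mass + n_label * scenario.scheme.mass_shift_per_residue, k_max
    )
    rt0 = _slot_rt(species.slot, scenario)
    scans = []
    for i in range(scenario.n_scans):
        rt = rt0 + (i - (scenario.n_scans - 1) / 2.0) * scenario.scan_spacing
        shared = _lognormal_factor(rng, noise.intensity_cv)
        grid: dict[int, float] = {}
        for channel_intensity, offset, env in (
            (I_L, 0, env_light),
            (I_H, shift_iso, env_heavy),
        ):
            drop = (
                noise.missing_peak_prob > 0
                and rng.random() < noise.missing_peak_prob
            )
            chf = _lognormal_factor(rng, noise.channel_cv)
            if channel_intensity <= 0 or drop:
                continue
            amp = channel_intensity * shared * chf
            for k in range(k_max + 1):
                grid[offset + k] = grid.get(offset + k, 0.0) + (
                    amp * env.abundances[k] / env.abundances[0]
                )
        mzs = []
        intensities = []
        for k in sorted(grid):
            mz = light_mz0 + k * spacing
            if noise.mz_jitter_ppm > 0:
                mz *= 1.0 + rng.uniform(-noise.mz_jitter_ppm, noise.mz_jitter_ppm) * 1e-6
            mzs.append(mz)
            intensities.append(grid[k])
        scans.append((rt, np.array(mzs), np.array(intensities)))
    return scans


def _slot_rt(slot: int, scenario: SimScenario) -> float:
    return 30.0 + slot * scenario.slot_spacing


def _assemble_scans(
    per_species: list[list[tuple[float, np.ndarray, np.ndarray]]],
    scenario: SimScenario,
    rng: np.random.Generator,
    condition: str,
) -> list[SpectrumMS1]:
    by_rt: dict[float, list[tuple[np.ndarray, np.ndarray]]] = {}
    for scans in per_species:
        for rt, mz, intensity in scans:
            by_rt.setdefault(rt, []).append((mz, intensity))
    noise = scenario.noise
    spectra = []
    for idx, rt in enumerate(sorted(by_rt), start=1):
        parts = by_rt[rt]
        mz = np.concatenate([p[0] for p in parts])
        intensity = np.concatenate([p[1] for p in parts])
        if noise.baseline_peaks_per_scan > 0:
            n_noise = noise.baseline_peaks_per_scan
            lo, hi = noise.baseline_mz_range
            noise_mz = rng.uniform(lo, hi, n_noise)
            ilo, ihi = noise.baseline_intensity_range
            noise_int = np.exp(rng.uniform(math.log(ilo), math.log(ihi), n_noise))
            mz = np.concatenate([mz, noise_mz])
            intensity = np.concatenate([intensity, noise_int])
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        # merge exact duplicates so the m/z axis is strictly increasing
        if mz.size > 1:
            keep = np.concatenate(([True], np.diff(mz) > 0))
            if not keep.all():
                merged_int = np.zeros(keep.sum())
                np.add.at(merged_int, np.cumsum(keep) - 1, intensity)
                mz, intensity = mz[keep], merged_int
        spectra.append(
            SpectrumMS1(f"{condition}_scan={idx}", rt, mz, intensity)
        )
    return spectra


def simulate(scenario: SimScenario, outdir=None) -> SimResult:
    """Generate the synthetic experiment; optionally write all files to outdir.

    Deterministic given the scenario seed: two runs yield byte-identical
    tables and identical peak lists. Decoy and unquantifiable PSMs are drawn
    from a separate random substream, so disabling them changes no spectrum.
    """
    rng = np.random.default_rng([scenario.seed, 0])
    rng_decoy = np.random.default_rng([scenario.seed, 1])
    fractions = scenario.fraction_table()

    # Enumerate species once; slots are shared across conditions.
    all_forms: list[tuple[PeptideSpecies, str]] = []
    for protein in scenario.proteins:
        all_forms.extend(enumerate_peptidoforms(protein, scenario, rng))
    light_only_classes = {
        p.class_label for p in scenario.proteins if p.channel_mode == "light_only"
    }

    species_list: list[SimSpecies] = []
    pepform_species: list[list[int]] = []  # indices into species_list per form
    probs = np.array(scenario.charge_probs) / sum(scenario.charge_probs)
    for slot, (pep, label) in enumerate(all_forms):
        z1 = int(rng.choice(scenario.charge_choices, p=probs))
        charges = [(z1, 1.0)]
        others = [z for z in scenario.charge_choices if z != z1]
        if others and rng.random() < scenario.second_charge_prob:
            z2 = int(others[0]) if len(others) == 1 else int(rng.choice(others))
            charges = [(z1, 0.7), (z2, 0.3)]
        idxs = []
        for z, w in charges:
            species_list.append(
                SimSpecies(replace(pep, charge=z), label, slot, w)
            )
            idxs.append(len(species_list) - 1)
        pepform_species.append(idxs)

    spectra_by_condition: dict[str, list[SpectrumMS1]] = {}
    psms_by_condition: dict[str, list[PsmRecord]] = {}
    truth_rows = []
    psm_counter = 0
    for condition in scenario.conditions:
        per_species_scans = []
        psms: list[PsmRecord] = []
        for form_idx, (pep, label) in enumerate(all_forms):
            if label in light_only_classes:
                f = 1.0
            else:
                f = fractions[(label, condition)]
            lo, hi = scenario.base_intensity_range
            base = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            I_L_total = f * base
            I_H_total = (1.0 - f) * base
            for sp_idx in pepform_species[form_idx]:
                sp = species_list[sp_idx]
                per_species_scans.append(
                    _render_species_scans(
                        sp, I_L_total * sp.weight, I_H_total * sp.weight,
                        scenario, rng,
                    )
                )
                psm_counter += 1
                psms.append(
                    PsmRecord(
                        psm_id=f"psm{psm_counter}",
                        peptide=sp.peptide,
                        retention_time=_slot_rt(sp.slot, scenario),
                        q_value=float(rng.uniform(0.0005, 0.009)),
                    )
                )
            truth_rows.append(
                {
                    "condition": condition,
                    "class_label": label,
                    "protein_id": pep.protein_id,
                    "sequence": pep.sequence,
                    "modifications": pep.mod_string,
                    "true_f": f,
                    "I_L": I_L_total,
                    "I_H": I_H_total,
                }
            )
        spectra_by_condition[condition] = _assemble_scans(
            per_species_scans, scenario, rng, condition
        )
        psms.extend(
            _nuisance_psms(scenario, all_forms, rng_decoy, len(psms), condition)
        )
        psms_by_condition[condition] = psms

    result = SimResult(
        scenario=scenario,
        spectra=spectra_by_condition,
        psms=psms_by_condition,
        groups=group_definitions(scenario.proteins),
        truth=pd.DataFrame(truth_rows),
    )
    if outdir is not None:
        result.write(outdir)
    return result


def _nuisance_psms(
    scenario: SimScenario,
    all_forms: list[tuple[PeptideSpecies, str]],
    rng: np.random.Generator,
    n_true: int,
    condition: str,
) -> list[PsmRecord]:
    """Decoy PSMs (q > threshold) and Arg-free PSMs to exercise the filters."""
    out = []
    n_decoys = round(scenario.decoy_psm_rate * n_true)
    max_rt = _slot_rt(len(all_forms), scenario)
    qlo, qhi = scenario.decoy_q_range
    for i in range(n_decoys):
        pep, _label = all_forms[int(rng.integers(len(all_forms)))]
        seq = list(pep.sequence)
        rng.shuffle(seq)
        out.append(
            PsmRecord(
                psm_id=f"{condition}_decoy{i + 1}",
                peptide=PeptideSpecies("".join(seq), (), 2, "DECOY", 1,
                                       scenario.scheme),
                retention_time=float(rng.uniform(0.0, max_rt)),
                q_value=float(rng.uniform(qlo, qhi)),
            )
        )
    # confidently identified but Arg-free peptides: removed by the label filter
    added = 0
    for protein in scenario.proteins:
        for dp in tryptic_digest(protein.sequence, scenario.max_missed):
            if added >= scenario.unlabeled_psm_count:
                break
            if (
                scenario.min_peptide_len <= len(dp.sequence)
                and scenario.scheme.count_labeled(dp.sequence) == 0
            ):
                out.append(
                    PsmRecord(
                        psm_id=f"{condition}_argfree{added + 1}",
                        peptide=PeptideSpecies(dp.sequence, (), 2,
                                               protein.protein_id, dp.start,
                                               scenario.scheme),
                        retention_time=float(rng.uniform(0.0, max_rt)),
                        q_value=0.005,
                    )
                )
                added += 1
        if added >= scenario.unlabeled_psm_count:
            break
    return out


# ---------------------------------------------------------------------------
# Default scenario: the study design with the reported anchor light fractions.

CONDITIONS = ("FA0", "FA0.05", "FA0.25", "FA1.25")

#: Per-class true light fractions across the four cross-linking conditions.
#: Anchors: bait 1.0 and non-specific 0.5 everywhere; bulk histones 0.90 at
#: 0% FA (~10% exchange); bulk H3 0.80 at 0.05% FA; ~0.98 at 1.25% FA.
#: Remaining cells encode the qualitative ordering (acetylated <= bulk,
#: convergence at the highest cross-linking) and are scenario parameters.
DEFAULT_LIGHT_FRACTIONS = {
    "bait": (1.0, 1.0, 1.0, 1.0),
    "non-specific": (0.5, 0.5, 0.5, 0.5),
    "bulk-H3": (0.90, 0.80, 0.93, 0.98),
    "H3K9acK14ac": (0.88, 0.55, 0.85, 0.98),
    "bulk-H4": (0.90, 0.70, 0.90, 0.98),
    "H4K12acK16ac": (0.88, 0.68, 0.80, 0.98),
}

DEFAULT_PROTEINS = (
    SimProtein("H2B_TAP_SYN", BAIT_SYN, "bait", channel_mode="light_only"),
    SimProtein("H3_SYN", H3_SYN, "bulk-H3",
               signature_class="H3K9acK14ac", signature_sites=(9, 14)),
    SimProtein("H4_SYN", H4_SYN, "bulk-H4",
               signature_class="H4K12acK16ac", signature_sites=(12, 16)),
    SimProtein("NSP1_SYN", NSP1_SYN, "non-specific"),
    SimProtein("NSP2_SYN", NSP2_SYN, "non-specific"),
    SimProtein("NSP3_SYN", NSP3_SYN, "non-specific"),
    SimProtein("NSP4_SYN", NSP4_SYN, "non-specific"),
)


def fractions_tuple(
    table: dict[str, tuple[float, ...]], conditions: tuple[str, ...] = CONDITIONS
) -> tuple[tuple[str, str, float], ...]:
    return tuple(
        (label, cond, f)
        for label, fs in table.items()
        for cond, f in zip(conditions, fs)
    )


def default_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The six-class, four-condition emulation of the study design."""
    kwargs = dict(
        proteins=DEFAULT_PROTEINS,
        conditions=CONDITIONS,
        light_fraction=fractions_tuple(DEFAULT_LIGHT_FRACTIONS),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimScenario(**kwargs)


def subset_scenario(
    scenario: SimScenario,
    classes: list[str] | None = None,
    conditions: list[str] | None = None,
) -> SimScenario:
    """Restrict a scenario to selected classes and/or conditions."""
    proteins = scenario.proteins
    if classes is not None:
        proteins = tuple(
            replace(
                p,
                signature_class=p.signature_class
                if p.signature_class in classes else None,
                signature_sites=p.signature_sites
                if p.signature_class in classes else (),
            )
            for p in scenario.proteins
            if p.class_label in classes or p.signature_class in classes
        )
        if not proteins:
            raise ValueError(f"no proteins left for classes {classes}")
    conds = tuple(conditions) if conditions is not None else scenario.conditions
    keep_classes = {p.class_label for p in proteins} | {
        p.signature_class for p in proteins if p.signature_class
    }
    fractions = tuple(
        (label, cond, f)
        for label, cond, f in scenario.light_fraction
        if label in keep_classes and cond in conds
    )
    return replace(
        scenario, proteins=proteins, conditions=conds, light_fraction=fractions
    )
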