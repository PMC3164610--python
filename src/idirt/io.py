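"""Spectrum and table I/O plus identification filters.

mzML support is deliberately narrow: centroided MS1 spectra with uncompressed
or zlib-compressed 32/64-bit float arrays, which covers everything this
pipeline reads and writes. Profile-mode spectra are rejected loudly. Tables
(PSMs, group definitions, quant output, summaries) are fixed TSV dialects so
every stage of the pipeline is testable bit-exactly.
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .chem import LabelScheme, PeptideSpecies
from .constants import MODIFICATION_MASS

MZML_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions used by the reader/writer.
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_SCAN_START = "MS:1000016"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_NO_COMPRESSION = "MS:1000576"
_CV_ZLIB = "MS:1000574"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"


@dataclass(frozen=True)
class SpectrumMS1:
    """One centroided MS1 scan: sorted m/z values with their intensities."""

    scan_id: str
    retention_time: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.retention_time < 0:
            raise ValueError("retention_time must be >= 0")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z array must be strictly increasing")


@dataclass(frozen=True)
class PsmRecord:
    psm_id: str
    peptide: PeptideSpecies
    retention_time: float  # seconds
    q_value: float
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value must be in [0, 1], got {self.q_value}")


@dataclass(frozen=True)
class GroupDefinition:
    """One stratification class (e.g. bulk-H3 vs H3K9acK14ac).

    ``required_mods`` / ``forbidden_mods`` are (protein position, mod name)
    pairs in 1-based protein coordinates — the H3K9/H3K14-style nomenclature.
    """

    class_label: str
    protein_ids: frozenset[str]
    required_mods: frozenset[tuple[int, str]] = frozenset()
    forbidden_mods: frozenset[tuple[int, str]] = frozenset()


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_q_removed: int = 0
    n_unlabeled_removed: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "kept": self.n_kept,
            "removed_by_q_value": self.n_q_removed,
            "removed_no_labeled_residue": self.n_unlabeled_removed,
        }


# ---------------------------------------------------------------------------
# mzML


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(spectra: list[SpectrumMS1], path, ms_levels: list[int] | None = None) -> None:
    """Write centroided spectra as plain (non-indexed) mzML 1.1.

    ``ms_levels`` optionally assigns a per-spectrum MS level (default: all 1);
    used by tests to exercise the reader's MS1 filter.
    """
    if ms_levels is None:
        ms_levels = [1] * len(spectra)
    if len(ms_levels) != len(spectra):
        raise ValueError("ms_levels must match spectra length")

    def cv(parent, accession, name, value="", unit=None):
        el = etree.SubElement(parent, "cvParam")
        el.set("cvRef", "MS")
        el.set("accession", accession)
        el.set("name", name)
        el.set("value", str(value))
        if unit is not None:
            el.set("unitCvRef", unit[0])
            el.set("unitAccession", unit[1])
            el.set("unitName", unit[2])
        return el

    root = etree.Element("mzML", nsmap={None: MZML_NS})
    root.set("version", "1.1.0")
    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cvlist, "cv", id="MS", fullName="PSI-MS",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cvlist, "cv", id="UO", fullName="UNIT-ONTOLOGY",
        URI="http://ontologies.berkeleybop.org/uo.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    cv(fcontent, "MS:1000579", "MS1 spectrum")
    cv(fcontent, _CV_CENTROID, "centroid spectrum")
    run = etree.SubElement(root, "run", id="run")
    slist = etree.SubElement(run, "spectrumList", count=str(len(spectra)))
    for i, (spec, level) in enumerate(zip(spectra, ms_levels)):
        sp = etree.SubElement(
            slist, "spectrum", index=str(i), id=spec.scan_id,
            defaultArrayLength=str(spec.mz.size),
        )
        cv(sp, _CV_MS_LEVEL, "ms level", level)
        cv(sp, _CV_CENTROID, "centroid spectrum")
        scan_list = etree.SubElement(sp, "scanList", count="1")
        scan = etree.SubElement(scan_list, "scan")
        cv(scan, _CV_SCAN_START, "scan start time", repr(spec.retention_time),
           unit=("UO", "UO:0000010", "second"))
        balist = etree.SubElement(sp, "binaryDataArrayList", count="2")
        for accession, name, unit, values in (
            (_CV_MZ_ARRAY, "m/z array", ("MS", "MS:1000040", "m/z"), spec.mz),
            (_CV_INTENSITY_ARRAY, "intensity array",
             ("MS", "MS:1000131", "number of detector counts"), spec.intensity),
        ):
            payload = _encode_array(values)
            ba = etree.SubElement(balist, "binaryDataArray",
                                  encodedLength=str(len(payload)))
            cv(ba, _CV_FLOAT64, "64-bit float")
            cv(ba, _CV_NO_COMPRESSION, "no compression")
            cv(ba, accession, name, unit=unit)
            etree.SubElement(ba, "binary").text = payload
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(ba_element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind accession, values)."""
    dtype = "<f8"
    compressed = False
    kind = None
    text = ""
    for child in ba_element:
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession")
            if acc == _CV_FLOAT32:
                dtype = "<f4"
            elif acc == _CV_FLOAT64:
                dtype = "<f8"
            elif acc == _CV_ZLIB:
                compressed = True
            elif acc in (_CV_MZ_ARRAY, _CV_INTENSITY_ARRAY):
                kind = acc
        elif tag == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(element) -> tuple[int, SpectrumMS1]:
    ms_level = 1
    centroided = None
    rt = 0.0
    mz = intensity = None
    for cvp in element.iter(f"{{{MZML_NS}}}cvParam"):
        acc = cvp.get("accession")
        if acc == _CV_MS_LEVEL:
            ms_level = int(cvp.get("value"))
        elif acc == _CV_PROFILE:
            centroided = False
        elif acc == _CV_CENTROID:
            centroided = True if centroided is None else centroided
        elif acc == _CV_SCAN_START:
            rt = float(cvp.get("value"))
            if cvp.get("unitName", "").startswith("minute"):
                rt *= 60.0
    if centroided is False:
        raise ValueError(
            f"spectrum {element.get('id')!r} is profile mode; only centroided "
            "spectra are supported"
        )
    for ba in element.iter(f"{{{MZML_NS}}}binaryDataArray"):
        kind, values = _decode_binary_array(ba)
        if kind == _CV_MZ_ARRAY:
            mz = values
        elif kind == _CV_INTENSITY_ARRAY:
            intensity = values
    if mz is None or intensity is None:
        raise ValueError(f"spectrum {element.get('id')!r} lacks m/z or intensity array")
    if mz.size > 1 and np.any(np.diff(mz) <= 0):
        warnings.warn(
            f"spectrum {element.get('id')!r}: m/z array not strictly increasing; sorting",
            stacklevel=3,
        )
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        keep = np.concatenate(([True], np.diff(mz) > 0))
        mz, intensity = mz[keep], intensity[keep]
    return ms_level, SpectrumMS1(element.get("id") or "", rt, mz, intensity)


def read_ms1(path) -> list[SpectrumMS1]:
    """Read all MS1 spectra from an mzML file, sorted by retention time.

    MS2+ scans are skipped; profile-mode spectra raise. Parse errors carry
    lxml's line/column position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra = []
    try:
        context = etree.iterparse(str(path), events=("end",),
                                  tag=f"{{{MZML_NS}}}spectrum")
        for _event, element in context:
            ms_level, spec = _parse_spectrum(element)
            if ms_level == 1:
                spectra.append(spec)
            element.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"not a readable mzML file: {path}: {exc}") from exc
    if not spectra and path.stat().st_size == 0:
        raise ValueError(f"not a readable mzML file: {path}: empty file")
    spectra.sort(key=lambda s: s.retention_time)
    return spectra


# ---------------------------------------------------------------------------
# PSM / group tables

PSM_COLUMNS = [
    "psm_id", "protein_id", "protein_start", "sequence", "modifications",
    "charge", "retention_time_s", "q_value",
]


def parse_mod_string(
    text: str, mod_masses: dict[str, float], context: str = ""
) -> tuple[tuple[int, str, float], ...]:
    """Parse the 'pos:name;pos:name' modification dialect (1-based, in-peptide)."""
    text = (text or "").strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            pos_str, name = token.split(":", 1)
            pos = int(pos_str)
        except ValueError as exc:
            raise ValueError(f"{context}malformed modification token {token!r}") from exc
        name = name.strip()
        if name not in mod_masses:
            raise ValueError(
                f"{context}unknown modification name {name!r}; supply its mass "
                "via the extension table"
            )
        mods.append((pos, name, mod_masses[name]))
    return tuple(sorted(mods))


def read_psm_table(
    path,
    extra_mod_masses: dict[str, float] | None = None,
    scheme: LabelScheme | None = None,
) -> list[PsmRecord]:
    """Read the fixed-dialect PSM TSV into records with resolved mod masses."""
    scheme = scheme or LabelScheme()
    mod_masses = dict(MODIFICATION_MASS)
    if extra_mod_masses:
        mod_masses.update(extra_mod_masses)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} missing column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        ctx = f"{path} row {i}: "
        try:
            mods = parse_mod_string(row.modifications, mod_masses, context=ctx)
            peptide = PeptideSpecies(
                sequence=row.sequence,
                modifications=mods,
                charge=int(row.charge),
                protein_id=row.protein_id,
                protein_start=int(row.protein_start),
                scheme=scheme,
            )
            records.append(
                PsmRecord(
                    psm_id=row.psm_id,
                    peptide=peptide,
                    retention_time=float(row.retention_time_s),
                    q_value=float(row.q_value),
                )
            )
        except ValueError as exc:
            msg = str(exc)
            raise ValueError(msg if msg.startswith(str(path)) else ctx + msg) from exc
    return records


def write_psm_table(records: list[PsmRecord], path) -> None:
    rows = [
        {
            "psm_id": r.psm_id,
            "protein_id": r.peptide.protein_id,
            "protein_start": r.peptide.protein_start,
            "sequence": r.peptide.sequence,
            "modifications": r.peptide.mod_string,
            "charge": r.peptide.charge,
            "retention_time_s": f"{r.retention_time:.6g}",
            "q_value": f"{r.q_value:.6g}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


GROUP_COLUMNS = ["class_label", "protein_ids", "required_mods", "forbidden_mods"]


def _parse_protein_mods(text: str, context: str) -> frozenset[tuple[int, str]]:
    text = (text or "").strip()
    if not text:
        return frozenset()
    out = set()
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            pos_str, name = token.split(":", 1)
            out.add((int(pos_str), name.strip()))
        except ValueError as exc:
            raise ValueError(f"{context}malformed mod token {token!r}") from exc
    return frozenset(out)


def read_group_table(path) -> list[GroupDefinition]:
    """Read class definitions (protein sets + required/forbidden PTM signatures)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"group table {path} missing column(s): {', '.join(missing)}")
    groups = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"{path} row {i}: "
        if row.class_label in seen:
            raise ValueError(f"{ctx}duplicate class label {row.class_label!r}")
        seen.add(row.class_label)
        groups.append(
            GroupDefinition(
                class_label=row.class_label,
                protein_ids=frozenset(
                    p.strip() for p in row.protein_ids.split(",") if p.strip()
                ),
                required_mods=_parse_protein_mods(row.required_mods, ctx),
                forbidden_mods=_parse_protein_mods(row.forbidden_mods, ctx),
            )
        )
    return groups


def write_group_table(groups: list[GroupDefinition], path) -> None:
    def fmt(mods):
        return ";".join(f"{p}:{n}" for p, n in sorted(mods))

    rows = [
        {
            "class_label": g.class_label,
            "protein_ids": ",".join(sorted(g.protein_ids)),
            "required_mods": fmt(g.required_mods),
            "forbidden_mods": fmt(g.forbidden_mods),
        }
        for g in groups
    ]
    pd.DataFrame(rows, columns=GROUP_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_psms(
    records: list[PsmRecord],
    q_max: float = 0.01,
    scheme: LabelScheme | None = None,
) -> tuple[list[PsmRecord], FilterReport]:
    """Apply the identification filters: q-value cutoff and >=1 labeled residue.

    Only peptides carrying at least one labeled residue (arginine under the
    default scheme) have a light/heavy pair and can be quantified.
    """
    if not 0.0 < q_max <= 1.0:
        raise ValueError(f"q_max must be in (0, 1], got {q_max}")
    scheme = scheme or LabelScheme()
    report = FilterReport(n_input=len(records))
    kept = []
    for rec in records:
        if rec.q_value > q_max:
            report.n_q_removed += 1
        elif scheme.count_labeled(rec.peptide.sequence) < 1:
            report.n_unlabeled_removed += 1
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# Quant / summary tables

QUANT_COLUMNS = [
    "protein_id", "sequence", "modifications", "protein_start", "charges",
    "condition", "n_psms", "I_L", "I_H", "percent_light", "flags",
]

SUMMARY_COLUMNS = [
    "class_label", "condition", "n_peptides", "mean_percent_light", "sem",
    "exchange_fraction", "normalized_exchange",
]


def _g6(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return f"{x:.6g}"


def write_quant_table(rows: list[dict], path) -> None:
    """Serialize per-peptidoform quant rows (6 significant digits)."""
    out = []
    for r in rows:
        r = dict(r)
        for col in ("I_L", "I_H", "percent_light"):
            r[col] = _g6(r.get(col))
        r["flags"] = ",".join(sorted(r.get("flags", []) or []))
        out.append({c: r.get(c, "") for c in QUANT_COLUMNS})
    pd.DataFrame(out, columns=QUANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_quant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"modifications": str, "flags": str, "condition": str})
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"quant table {path} missing column(s): {', '.join(missing)}")
    for col in ("I_L", "I_H", "percent_light"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_summary_table(rows: list[dict], path) -> None:
    out = []
    for r in rows:
        r = dict(r)
        for col in ("mean_percent_light", "sem", "exchange_fraction",
                    "normalized_exchange"):
            r[col] = _g6(r.get(col))
        out.append({c: r.get(c, "") for c in SUMMARY_COLUMNS})
    pd.DataFrame(out, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_summary_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"condition": str, "class_label": str})
    for col in ("mean_percent_light", "sem", "exchange_fraction",
                "normalized_exchange"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
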