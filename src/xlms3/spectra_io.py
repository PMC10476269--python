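"""Reading and writing of spectra and sequence databases.

This module owns the in-memory spectrum model (:class:`Spectrum`), mzML input
and output, FASTA input, and reversed-sequence decoy generation. MSn spectra
carry an explicit precursor reference so that the MS1 -> MS2 -> MS3 scan
hierarchy can be reconstructed; MGF input is rejected because it cannot
represent that hierarchy.
"""

from __future__ import annotations

import base64
import logging
import re
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from lxml import etree
from pyteomics import fasta as _pfasta

log = logging.getLogger(__name__)

#: Accession prefix that marks reversed decoy entries.
DECOY_PREFIX = "REV_"

#: Default accession prefix that marks entrapment (foreign-organism) entries.
ENTRAPMENT_PREFIX = "ENT_"


@dataclass(frozen=True)
class Peak:
    """A single centroided peak: m/z in Th, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PrecursorRef:
    """Link from an MSn scan to the parent scan and isolated ion."""

    parent_scan_id: str
    selected_mz: float
    selected_charge: int | None = None
    isolation_width: float | None = None

    def __post_init__(self) -> None:
        if self.selected_mz <= 0:
            raise ValueError("selected_mz must be positive")
        if self.selected_charge is not None and not (1 <= self.selected_charge <= 15):
            raise ValueError(f"implausible precursor charge {self.selected_charge}")


@dataclass
class Spectrum:
    """One MSn scan with its peak list and precursor linkage.

    ``ms1_precursor_mz`` is the selected m/z at the MS1 level that this scan
    chain descends from: for an MS2 scan it equals its own precursor selection,
    for an MS3 scan it is the grandparent MS1 selection inherited through the
    MS2 parent.
    """

    scan_id: str
    ms_level: int
    retention_time: float  # minutes
    peaks: list[Peak]
    precursor: PrecursorRef | None = None
    ms1_precursor_mz: float | None = None

    def __post_init__(self) -> None:
        if self.ms_level >= 2 and self.precursor is None:
            raise ValueError(f"MS{self.ms_level} scan {self.scan_id!r} lacks a precursor")
        self.peaks = _merge_and_sort(self.peaks)

    @property
    def mz_array(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensity_array(self) -> list[float]:
        return [p.intensity for p in self.peaks]


def _merge_and_sort(peaks: Iterable[Peak]) -> list[Peak]:
    """Sort peaks ascending in m/z and merge exact-duplicate m/z by summing."""
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda q: q.mz):
        if out and p.mz == out[-1].mz:
            out[-1] = Peak(p.mz, out[-1].intensity + p.intensity)
        else:
            out.append(p)
    return out


@dataclass(frozen=True)
class ProteinEntry:
    """One database protein with decoy / entrapment bookkeeping flags."""

    accession: str
    sequence: str
    is_decoy: bool = False
    is_entrapment: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z]+", self.sequence):
            raise ValueError(
                f"protein {self.accession!r}: sequence must match [A-Z]+"
            )


# ---------------------------------------------------------------------------
# mzML input


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read all MS1/MS2/MS3 spectra from an mzML file.

    MSn scans without a resolvable precursor element are skipped with a
    warning; the skip count is logged. Retention times are normalized to
    minutes. MGF files are rejected because they carry no MSn scan linkage.

    Returns the spectra in file order with ``ms1_precursor_mz`` populated by
    walking each scan's precursor chain up to MS1.
    """
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        raise ValueError(
            "MGF input is not supported: MS2-MS3 searching requires the MSn "
            "precursor scan linkage that only mzML provides"
        )
    if not path.exists():
        raise FileNotFoundError(path)

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as err:
        raise ValueError(f"unreadable mzML file {path}: {err}") from err

    spectra: list[Spectrum] = []
    n_skipped = 0
    elements = tree.iter("{%s}spectrum" % _NS)
    for idx, el in enumerate(elements):
        spec = _spectrum_from_element(el, ordinal=idx + 1)
        if spec is None:
            n_skipped += 1
            continue
        spectra.append(spec)
    if n_skipped:
        log.warning("%s: skipped %d MSn scan(s) without precursor reference", path, n_skipped)

    resolve_ms1_precursors(spectra)
    return spectra


def _cv_value(el, accession: str) -> str | None:
    for cv in el.iter("{%s}cvParam" % _NS):
        if cv.get("accession") == accession:
            return cv.get("value")
    return None


def _spectrum_from_element(el, ordinal: int) -> Spectrum | None:
    ms_level = int(_cv_value(el, "MS:1000511") or 1)
    scan_id = el.get("id") or str(ordinal)

    rt = 0.0
    scan = el.find("{%s}scanList/{%s}scan" % (_NS, _NS))
    if scan is not None:
        for cv in scan.iter("{%s}cvParam" % _NS):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second" or cv.get("unitAccession") == "UO:0000010":
                    rt /= 60.0

    precursor = None
    if ms_level >= 2:
        precursor = _parse_precursor_element(el)
        if precursor is None:
            log.warning("scan %s (MS%d) has no precursor reference; skipped", scan_id, ms_level)
            return None

    mzs, ints = _parse_binary_arrays(el)
    peaks = [Peak(float(m), float(i)) for m, i in zip(mzs, ints) if m > 0]
    return Spectrum(scan_id, ms_level, rt, peaks, precursor)


def _parse_precursor_element(el) -> PrecursorRef | None:
    prec = el.find("{%s}precursorList/{%s}precursor" % (_NS, _NS))
    if prec is None:
        return None
    parent = prec.get("spectrumRef")
    if not parent:
        return None
    ion = prec.find("{%s}selectedIonList/{%s}selectedIon" % (_NS, _NS))
    if ion is None:
        return None
    mz = _cv_value(ion, "MS:1000744")
    if mz is None:
        return None
    charge = _cv_value(ion, "MS:1000041")
    width = None
    iso = prec.find("{%s}isolationWindow" % _NS)
    if iso is not None:
        width = _cv_value(iso, "MS:1000827")
    return PrecursorRef(
        parent_scan_id=str(parent),
        selected_mz=float(mz),
        selected_charge=int(charge) if charge else None,
        isolation_width=float(width) if width else None,
    )


def _parse_binary_arrays(el) -> tuple[list[float], list[float]]:
    import zlib

    mzs: list[float] = []
    ints: list[float] = []
    for arr in el.iter("{%s}binaryDataArray" % _NS):
        accs = {cv.get("accession") for cv in arr.iter("{%s}cvParam" % _NS)}
        binary = arr.find("{%s}binary" % _NS)
        if binary is None or not (binary.text or "").strip():
            continue
        raw = base64.b64decode(binary.text)
        if "MS:1000574" in accs:  # zlib compression
            raw = zlib.decompress(raw)
        fmt = "f" if "MS:1000521" in accs else "d"  # 32- vs 64-bit float
        values = list(struct.unpack("<%d%s" % (len(raw) // (4 if fmt == "f" else 8), fmt), raw))
        if "MS:1000514" in accs:
            mzs = values
        elif "MS:1000515" in accs:
            ints = values
    return mzs, ints


def resolve_ms1_precursors(spectra: Sequence[Spectrum]) -> None:
    by_id = {s.scan_id: s for s in spectra}
    for s in spectra:
        if s.ms_level == 2:
            s.ms1_precursor_mz = s.precursor.selected_mz
    for s in spectra:
        if s.ms_level == 3:
            parent = by_id.get(s.precursor.parent_scan_id)
            if parent is not None and parent.ms1_precursor_mz is not None:
                s.ms1_precursor_mz = parent.ms1_precursor_mz


# ---------------------------------------------------------------------------
# mzML output (minimal writer, used for fixtures and the simulator)

_NS = "http://psi.hupo.org/ms/mzml"


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as minimal plain mzML 1.1 (64-bit floats, uncompressed).

    The output is limited to what the reader needs: ms level, scan start time
    in minutes, precursor linkage with selected ion m/z and charge, and the
    peak arrays. It round-trips through :func:`read_mzml`.
    """
    root = etree.Element("{%s}mzML" % _NS, nsmap={None: _NS}, version="1.1.0")
    run = etree.SubElement(root, "{%s}run" % _NS, id="run1")
    slist = etree.SubElement(
        run, "{%s}spectrumList" % _NS, count=str(len(spectra))
    )
    for index, s in enumerate(spectra):
        _write_spectrum(slist, s, index)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    etree.SubElement(
        parent, "{%s}cvParam" % _NS, cvRef="MS", accession=accession, name=name,
        value=value, **attrs,
    )


def _write_spectrum(slist, s: Spectrum, index: int) -> None:
    el = etree.SubElement(
        slist, "{%s}spectrum" % _NS, index=str(index), id=s.scan_id,
        defaultArrayLength=str(len(s.peaks)),
    )
    _cv(el, "MS:1000511", "ms level", str(s.ms_level))
    _cv(el, "MS:1000127", "centroid spectrum")
    scan_list = etree.SubElement(el, "{%s}scanList" % _NS, count="1")
    scan = etree.SubElement(scan_list, "{%s}scan" % _NS)
    _cv(
        scan, "MS:1000016", "scan start time", repr(s.retention_time),
        unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
    )
    if s.precursor is not None:
        plist = etree.SubElement(el, "{%s}precursorList" % _NS, count="1")
        prec = etree.SubElement(
            plist, "{%s}precursor" % _NS, spectrumRef=s.precursor.parent_scan_id
        )
        if s.precursor.isolation_width is not None:
            iso = etree.SubElement(prec, "{%s}isolationWindow" % _NS)
            _cv(
                iso, "MS:1000827", "isolation window target m/z",
                repr(s.precursor.selected_mz), unitCvRef="MS",
                unitAccession="MS:1000040", unitName="m/z",
            )
        ions = etree.SubElement(prec, "{%s}selectedIonList" % _NS, count="1")
        ion = etree.SubElement(ions, "{%s}selectedIon" % _NS)
        _cv(
            ion, "MS:1000744", "selected ion m/z", repr(s.precursor.selected_mz),
            unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z",
        )
        if s.precursor.selected_charge is not None:
            _cv(ion, "MS:1000041", "charge state", str(s.precursor.selected_charge))
    arrays = etree.SubElement(el, "{%s}binaryDataArrayList" % _NS, count="2")
    _write_array(arrays, s.mz_array, "MS:1000514", "m/z array")
    _write_array(arrays, s.intensity_array, "MS:1000515", "intensity array")


def _write_array(parent, values: Sequence[float], accession: str, name: str) -> None:
    raw = struct.pack("<%dd" % len(values), *values)
    b64 = base64.b64encode(raw).decode("ascii")
    arr = etree.SubElement(
        parent, "{%s}binaryDataArray" % _NS, encodedLength=str(len(b64))
    )
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    _cv(arr, accession, name)
    etree.SubElement(arr, "{%s}binary" % _NS).text = b64


# ---------------------------------------------------------------------------
# FASTA input and decoys


def read_fasta(
    path: str | Path,
    entrapment_predicate: Callable[[str, str], bool] | None = None,
) -> list[ProteinEntry]:
    """Read a FASTA protein database.

    The accession is the first whitespace-delimited token of the header.
    Sequences are uppercased on read; characters outside A-Z are a fatal
    error naming the offending record. ``entrapment_predicate`` receives
    (accession, description) and flags entrapment entries; the default flags
    accessions starting with ``ENT_``.
    """
    if entrapment_predicate is None:
        entrapment_predicate = lambda acc, desc: acc.startswith(ENTRAPMENT_PREFIX)
    entries: list[ProteinEntry] = []
    with _pfasta.FASTA(str(path)) as reader:
        for header, seq in reader:
            parts = header.split(None, 1)
            accession = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            seq = seq.upper().replace("*", "")
            if not re.fullmatch(r"[A-Z]+", seq):
                raise ValueError(
                    f"FASTA record {accession!r} contains characters outside A-Z"
                )
            entries.append(
                ProteinEntry(
                    accession=accession,
                    sequence=seq,
                    is_decoy=accession.startswith(DECOY_PREFIX),
                    is_entrapment=bool(entrapment_predicate(accession, description)),
                    description=description,
                )
            )
    if not entries:
        raise ValueError(f"FASTA file {path} contains no records")
    return entries


def write_fasta(entries: Sequence[ProteinEntry], path: str | Path) -> None:
    """Write protein entries as FASTA."""
    with open(path, "w") as fh:
        for e in entries:
            header = e.accession + ((" " + e.description) if e.description else "")
            fh.write(f">{header}\n{e.sequence}\n")


def generate_decoys(entries: Sequence[ProteinEntry]) -> list[ProteinEntry]:
    """Whole-protein reversed decoys, one per target.

    Reversal of the full protein sequence is an involution: reversing a decoy
    recovers its target. Accessions get the ``REV_`` prefix; entrapment flags
    are inherited so that decoy hits to entrapment proteins stay attributable.
    """
    decoys = []
    for e in entries:
        if e.is_decoy:
            raise ValueError(f"entry {e.accession!r} is already a decoy")
        decoys.append(
            replace(
                e,
                accession=DECOY_PREFIX + e.accession,
                sequence=e.sequence[::-1],
                is_decoy=True,
            )
        )
    return decoys
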