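"""Doublet detection in MS2 spectra and MS3-to-doublet mapping.

A cross-linked precursor fragments in MS2 into two peptides each carrying one
cross-linker arm, producing two *doublets*: peak pairs separated by the
arm mass difference divided by the fragment charge. The instrument then
isolates doublet peaks for MS3. This module finds the doublets, deisotopes
them to monoisotopic neutral masses, assigns MS3 scans to the doublet peaks
they were triggered on, and converts doublet masses to cross-linker-free
peptide masses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .constants import NEUTRON, PROTON, neutral_from_mz, ppm_width
from .crosslinker import CrosslinkerProduct, CrosslinkerSpec, doublet_delta
from .spectra_io import Spectrum

log = logging.getLogger(__name__)

#: Band of accepted light/heavy intensity ratios for a doublet pair.
DEFAULT_INTENSITY_RATIO_BAND = (0.1, 10.0)


@dataclass(frozen=True)
class DoubletAnnotation:
    """One arm of a detected doublet: a peak attributed to peptide + arm.

    ``mono_neutral_mass`` is the deisotoped neutral mass of the arm-carrying
    peptide (the quantity the precursor-adjustment arithmetic starts from).
    """

    ms2_scan_id: str
    role: str  # "alpha" | "beta"
    arm: str  # "light" | "heavy"
    peak_index: int
    charge: int
    mono_neutral_mass: float
    partner_index: int
    product_applied: CrosslinkerProduct | None = None

    def __post_init__(self) -> None:
        if self.role not in ("alpha", "beta"):
            raise ValueError(f"role must be alpha/beta, got {self.role!r}")
        if self.arm not in ("light", "heavy"):
            raise ValueError(f"arm must be light/heavy, got {self.arm!r}")
        if self.charge < 1:
            raise ValueError("doublet charge must be >= 1")
        if self.mono_neutral_mass <= 0:
            raise ValueError("mono_neutral_mass must be positive")


@dataclass(frozen=True)
class DoubletPair:
    """A light/heavy annotation pair for one peptide of a cross-link."""

    light: DoubletAnnotation
    heavy: DoubletAnnotation

    @property
    def role(self) -> str:
        return self.light.role

    @property
    def charge(self) -> int:
        return self.light.charge


@dataclass(frozen=True)
class MS3Assignment:
    """An MS3 scan mapped to the doublet peak it fragments."""

    ms3_scan_id: str
    doublet: DoubletAnnotation
    adjusted_precursor_mass: float  # neutral, cross-linker-free
    adjusted_charge: int

    def __post_init__(self) -> None:
        if self.adjusted_charge < 1:
            raise ValueError("adjusted charge must be >= 1")


# ---------------------------------------------------------------------------
# charge inference and deisotoping


def _find_peak(spectrum: Spectrum, mz: float, tol: float) -> int | None:
    """Index of the most intense peak within ``tol`` Th of ``mz``, or None."""
    best = None
    for i, p in enumerate(spectrum.peaks):
        if abs(p.mz - mz) <= tol:
            if best is None or p.intensity > spectrum.peaks[best].intensity:
                best = i
    return best


def _envelope_up(
    spectrum: Spectrum, peak_index: int, z: int, frag_tol_ppm: float
) -> list[int]:
    """Indices of consecutive envelope members walking up from the peak."""
    chain = [peak_index]
    mz = spectrum.peaks[peak_index].mz
    while True:
        nxt = _find_peak(spectrum, mz + NEUTRON / z, ppm_width(mz, frag_tol_ppm) * 2)
        if nxt is None:
            break
        chain.append(nxt)
        mz = spectrum.peaks[nxt].mz
        if len(chain) > 8:  # peptide envelopes are short; guard runaway walks
            break
    return chain


def infer_charge(
    spectrum: Spectrum, peak_index: int, max_charge: int = 4, frag_tol_ppm: float = 20.0
) -> int | None:
    """Infer a peak's charge from its isotope envelope spacing.

    A charge ``z`` is consistent if at least one further envelope member is
    found at spacing ``NEUTRON/z`` above the peak (>= 2 consecutive members
    counting the peak itself) with non-exploding intensities. The largest
    consistent charge is returned; with no envelope the result is ``None``
    (unknown), in which case downstream code enumerates 1..max_charge.
    """
    consistent = []
    base_int = spectrum.peaks[peak_index].intensity
    for z in range(1, max_charge + 1):
        chain = _envelope_up(spectrum, peak_index, z, frag_tol_ppm)
        if len(chain) < 2:
            continue
        # plausibility: the envelope should not grow without bound
        ints = [spectrum.peaks[i].intensity for i in chain]
        if max(ints) <= 5.0 * max(base_int, 1e-12):
            consistent.append(z)
    return max(consistent) if consistent else None


def charges_to_consider(
    spectrum: Spectrum, peak_index: int, max_charge: int = 4, frag_tol_ppm: float = 20.0
) -> list[int]:
    """Charge states searched for a peak: the inferred one, else 1..max_charge."""
    z = infer_charge(spectrum, peak_index, max_charge, frag_tol_ppm)
    return [z] if z is not None else list(range(1, max_charge + 1))


def deisotope_peak(
    spectrum: Spectrum, peak_index: int, charge: int, frag_tol_ppm: float = 20.0
) -> tuple[float, int]:
    """Walk down the isotope envelope to the monoisotopic member.

    The instrument often isolates a higher (e.g. 13C) envelope member; the
    monoisotopic peak sits ``NEUTRON/charge`` steps below. Returns the
    neutral monoisotopic mass ``charge * (mono_mz - PROTON)`` and the index
    of the monoisotopic peak. With no envelope the selected peak itself is
    taken as monoisotopic.

    The monoisotopic m/z is estimated by averaging ``mz_k - k * NEUTRON/z``
    over all envelope members, which reduces the centroiding error by about
    the square root of the envelope length compared to reading off a single
    peak.
    """
    idx = peak_index
    mz = spectrum.peaks[idx].mz
    for _ in range(8):
        below = _find_peak(spectrum, mz - NEUTRON / charge, ppm_width(mz, frag_tol_ppm) * 2)
        if below is None:
            break
        idx = below
        mz = spectrum.peaks[idx].mz
    chain = _envelope_up(spectrum, idx, charge, frag_tol_ppm)
    estimates = [
        spectrum.peaks[k_idx].mz - k * NEUTRON / charge
        for k, k_idx in enumerate(chain)
    ]
    mono_mz = sum(estimates) / len(estimates)
    return charge * (mono_mz - PROTON), idx


# ---------------------------------------------------------------------------
# doublet detection


def detect_doublets(
    ms2: Spectrum,
    spec: CrosslinkerSpec,
    frag_tol_ppm: float = 20.0,
    max_charge: int = 4,
    prec_tol_ppm: float = 10.0,
    intensity_ratio_band: tuple[float, float] = DEFAULT_INTENSITY_RATIO_BAND,
) -> list[DoubletPair]:
    """Find cross-linker doublet pairs in an MS2 spectrum.

    For every charge ``z`` in 1..max_charge and every allowed product-delta
    combination, peak pairs separated by ``(delta + product_delta)/z`` within
    the fragment tolerance and with a light/heavy intensity ratio inside the
    configured band are annotated as doublets. Both members are deisotoped to
    monoisotopic neutral masses.

    If the MS1 precursor charge is known, pairs of doublets whose
    cross-linker-free peptide masses cannot sum (with the intact linker) to
    the MS1 precursor mass within the precursor tolerance are filtered: a
    doublet is kept only if it is consistent with at least one partner, or if
    it is the only doublet found. Alpha/beta roles are assigned across the
    surviving doublets by ascending light-peak m/z (alpha = lowest).
    """
    if ms2.ms_level != 2:
        raise ValueError("detect_doublets expects an MS2 spectrum")
    delta = doublet_delta(spec)
    lo, hi = intensity_ratio_band

    found: list[dict] = []
    seen: set[tuple[int, int, int]] = set()
    for z in range(1, max_charge + 1):
        for product in _pair_products(spec):
            pdelta = product.delta_mass if product is not None else 0.0
            step = (delta + pdelta) / z
            if step <= 0:
                continue
            for i, light in enumerate(ms2.peaks):
                j = _find_peak(ms2, light.mz + step, ppm_width(light.mz + step, frag_tol_ppm))
                if j is None or j == i:
                    continue
                heavy = ms2.peaks[j]
                if heavy.intensity <= 0 or light.intensity <= 0:
                    continue
                ratio = light.intensity / heavy.intensity
                if not (lo <= ratio <= hi):
                    continue
                key = (i, j, z)
                if key in seen:
                    continue
                seen.add(key)
                mono_light, _ = deisotope_peak(ms2, i, z, frag_tol_ppm)
                mono_heavy, _ = deisotope_peak(ms2, j, z, frag_tol_ppm)
                found.append(
                    dict(
                        light_index=i, heavy_index=j, charge=z,
                        light_mz=light.mz,
                        mono_light=mono_light, mono_heavy=mono_heavy,
                        product=product,
                    )
                )

    if not found:
        return []

    found = _filter_by_precursor_sum(ms2, found, spec, prec_tol_ppm)
    found.sort(key=lambda d: d["light_mz"])

    pairs: list[DoubletPair] = []
    for rank, d in enumerate(found):
        role = "alpha" if rank == 0 else "beta"
        light = DoubletAnnotation(
            ms2_scan_id=ms2.scan_id, role=role, arm="light",
            peak_index=d["light_index"], charge=d["charge"],
            mono_neutral_mass=d["mono_light"], partner_index=d["heavy_index"],
            product_applied=d["product"],
        )
        heavy = DoubletAnnotation(
            ms2_scan_id=ms2.scan_id, role=role, arm="heavy",
            peak_index=d["heavy_index"], charge=d["charge"],
            mono_neutral_mass=d["mono_heavy"], partner_index=d["light_index"],
            product_applied=d["product"],
        )
        pairs.append(DoubletPair(light=light, heavy=heavy))
    return pairs


def _pair_products(spec: CrosslinkerSpec) -> list[CrosslinkerProduct | None]:
    # products that shift the doublet spacing itself (applied to one arm);
    # None = canonical spacing. Multi-product stacking is not enumerated.
    out: list[CrosslinkerProduct | None] = [None]
    out.extend(spec.products)
    return out


def _filter_by_precursor_sum(
    ms2: Spectrum, found: list[dict], spec: CrosslinkerSpec, prec_tol_ppm: float
) -> list[dict]:
    prec = ms2.precursor
    if prec is None or prec.selected_charge is None or len(found) < 2:
        return found
    precursor_neutral = neutral_from_mz(prec.selected_mz, prec.selected_charge)
    tol = precursor_neutral * prec_tol_ppm * 1e-6
    # peptide pair + intact linker should reconstruct the precursor:
    # (mono_light_A - short) + (mono_light_B - short) + intact = precursor
    short = spec.short_arm.mono_mass
    keep = [False] * len(found)
    for a in range(len(found)):
        for b in range(a + 1, len(found)):
            mass_a = found[a]["mono_light"] - short
            mass_b = found[b]["mono_light"] - short
            if abs(mass_a + mass_b + spec.intact_mass - precursor_neutral) <= 2 * tol:
                keep[a] = keep[b] = True
    if not any(keep):
        return found  # keep everything rather than discard all evidence
    return [d for d, k in zip(found, keep) if k]


# ---------------------------------------------------------------------------
# MS3 mapping and mass adjustment


def peptide_mass_from_doublet(
    mono_neutral_mass: float,
    arm: str,
    spec: CrosslinkerSpec,
    product: CrosslinkerProduct | None = None,
) -> float:
    """Cross-linker-free peptide mass from a deisotoped doublet mass.

    Subtracts the remnant arm mass and, if the doublet indicated an
    alternative cleavage product, its mass change. A non-positive result is
    a rejected assignment (``ValueError``).
    """
    mass = mono_neutral_mass - spec.arm_mass(arm)
    if product is not None:
        mass -= product.delta_mass
    if mass <= 0:
        raise ValueError(
            f"adjusted peptide mass {mass:.4f} <= 0 for arm {arm!r}; assignment rejected"
        )
    return mass


def map_ms3_to_doublets(
    ms2: Spectrum,
    doublets: list[DoubletPair],
    ms3_scans: list[Spectrum],
    spec: CrosslinkerSpec,
    prec_tol_ppm: float = 10.0,
    rt_window: float = 5.0,
) -> tuple[list[MS3Assignment], int]:
    """Assign MS3 scans to the doublet peaks they were triggered on.

    An MS3 scan is assigned iff (a) it was recorded within ``rt_window``
    minutes *after* the MS2 scan, (b) it descends from the same MS1 precursor
    m/z within the precursor tolerance, and (c) its selected precursor m/z
    matches a doublet peak or a member of that peak's isotope envelope. MS3
    scans triggered on co-isolated non-doublet peaks fail (c) and are
    excluded from the cross-link search.

    Ties (precursor matching two doublet peaks) go to the closer peak; an
    exact tie goes to the lower-m/z (alpha-first) doublet. Returns the
    assignments and the count of unassigned MS3 scans.
    """
    assignments: list[MS3Assignment] = []
    n_unassigned = 0
    for ms3 in ms3_scans:
        if ms3.ms_level != 3:
            raise ValueError(f"scan {ms3.scan_id} is not MS3")
        a = _assign_one(ms2, doublets, ms3, spec, prec_tol_ppm, rt_window)
        if a is None:
            n_unassigned += 1
        else:
            assignments.append(a)
    return assignments, n_unassigned


def _assign_one(
    ms2: Spectrum,
    doublets: list[DoubletPair],
    ms3: Spectrum,
    spec: CrosslinkerSpec,
    prec_tol_ppm: float,
    rt_window: float,
) -> MS3Assignment | None:
    dt = ms3.retention_time - ms2.retention_time
    if dt < 0 or dt > rt_window:
        return None
    if ms3.ms1_precursor_mz is None or ms2.ms1_precursor_mz is None:
        return None
    if abs(ms3.ms1_precursor_mz - ms2.ms1_precursor_mz) > ppm_width(
        ms2.ms1_precursor_mz, prec_tol_ppm
    ):
        return None

    sel = ms3.precursor.selected_mz
    best: tuple[float, float, DoubletAnnotation] | None = None
    for pair in doublets:
        for ann in (pair.light, pair.heavy):
            peak_mz = ms2.peaks[ann.peak_index].mz
            # the MS3 may have been triggered on any member of the envelope
            for k in range(0, 4):
                env_mz = peak_mz + k * (NEUTRON / ann.charge)
                d = abs(sel - env_mz)
                if d <= ppm_width(env_mz, prec_tol_ppm):
                    # closer match wins; exact tie -> lower peak m/z, then the
                    # earlier (alpha-first) doublet by iteration order
                    if best is None or (d, peak_mz) < (best[0], best[1]):
                        best = (d, peak_mz, ann)
    if best is None:
        return None
    ann = best[2]
    try:
        adjusted = peptide_mass_from_doublet(
            ann.mono_neutral_mass, ann.arm, spec, ann.product_applied
        )
    except ValueError as err:
        log.warning("MS3 %s: %s", ms3.scan_id, err)
        return None
    return MS3Assignment(
        ms3_scan_id=ms3.scan_id,
        doublet=ann,
        adjusted_precursor_mass=adjusted,
        adjusted_charge=ann.charge,
    )
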