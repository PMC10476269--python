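"""Synthetic groupwise cross-linked peptide libraries and simulated runs.

Benchmark libraries for cross-linking search engines are built from
synthesized peptides that are split into groups and cross-linked *within*
groups only, so every inter-group identification is a known false positive
(the experimentally validated FDR). This module generates such libraries at
configurable scale and simulates the MS2-MS3 acquisition they are measured
with: each sampled intra-group cross-link yields one MS2 scan containing the
two cross-linker doublets plus backbone fragments of both arm-modified
peptides, and 0-2 MS3 scans per doublet holding linear fragments of the
arm-carrying peptide.

The spectral model is deliberately simple: log-normal peak intensities, a
configurable fraction of theoretical fragment ions present, Gaussian m/z
jitter at a third of the analyzer tolerance, and uniform random noise peaks.
Chromatographic peak shapes, co-elution, and real intensity structure are
not modeled.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import NEUTRON, PROTON, mz_from_neutral
from .crosslinker import CrosslinkerSpec
from .peptide_search import (
    DEFAULT_FIXED_MODS,
    PeptideCandidate,
    peptide_mass,
    theoretical_fragments,
)
from .spectra_io import (
    Peak,
    PrecursorRef,
    ProteinEntry,
    Spectrum,
    resolve_ms1_precursors,
    write_fasta,
    write_mzml,
)

#: Residues drawn for random library peptides (no K/R/P to keep cleavage and
#: cross-link sites fully controlled; no C to avoid fixed-mod bookkeeping in
#: hand checks).
_BODY_ALPHABET = "ADEFGHILMNQSTVWY"


@dataclass
class SyntheticLibrary:
    """A groupwise cross-linkable peptide library with known ground truth."""

    peptides: list[str]
    groups: dict[str, str]  # peptide sequence -> group id
    true_crosslinks: set[tuple[tuple[str, int], tuple[str, int]]]
    seed: int

    def group_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pep in self.peptides:
            out.setdefault(self.groups[pep], []).append(pep)
        return out


@dataclass
class SimulatedSpectrumTruth:
    """Ground truth for one emitted MS2 scan chain."""

    ms2_scan_id: str
    kind: str  # "crosslink" | "linear" | "noise"
    peptide_a: tuple[str, int] | None = None
    peptide_b: tuple[str, int] | None = None
    linear_peptide: str | None = None
    doublet_peak_indices: dict[str, tuple[int, int]] = field(default_factory=dict)
    ms3_scan_ids: list[str] = field(default_factory=list)
    noise_peaks: int = 0
    doublet_charge: int = 2


@dataclass
class SimulatedGroundTruth:
    """Full ground truth for one simulated run."""

    library: SyntheticLibrary
    spectra: list[SimulatedSpectrumTruth]
    sampled_crosslinks: list[tuple[tuple[str, int], tuple[str, int]]]

    def crosslink_set(self) -> set[tuple[tuple[str, int], tuple[str, int]]]:
        return set(self.sampled_crosslinks)


def _site_of(peptide: str) -> int:
    """The designated cross-link site: the single internal lysine."""
    return peptide.index("K", 0, len(peptide) - 1) + 1


def make_library(
    n_peptides: int = 30,
    group_size_range: tuple[int, int] = (6, 10),
    seed: int = 0,
    length_range: tuple[int, int] = (8, 16),
) -> SyntheticLibrary:
    """Generate a groupwise library of tryptic-like cross-linkable peptides.

    Each peptide has exactly one internal lysine (the cross-link site), a
    C-terminal K or R, and no other K/R/P, so trypsin with one missed
    cleavage regenerates it from its mini-protein FASTA wrapper. Peptides are
    partitioned into groups whose sizes fall in ``group_size_range``; the
    admissible (true) cross-links are all intra-group site pairs, including
    self-links of distinct peptide copies excluded (a peptide is not paired
    with itself).
    """
    lo, hi = group_size_range
    if n_peptides < lo:
        raise ValueError("n_peptides must reach the lower group-size bound")
    rng = random.Random(seed)
    peptides: list[str] = []
    seen: set[str] = set()
    masses: set[int] = set()
    while len(peptides) < n_peptides:
        length = rng.randint(*length_range)
        body = [rng.choice(_BODY_ALPHABET) for _ in range(length - 2)]
        site_pos = rng.randrange(1, length - 1)  # internal, never first/last
        residues = body[: site_pos - 1] + ["K"] + body[site_pos - 1 :]
        residues = residues[: length - 1] + [rng.choice("KR")]
        pep = "".join(residues)
        # enforce exactly one internal K and unique (and mass-distinct at
        # 10 mDa, so candidate lookups stay unambiguous in tests)
        if pep[:-1].count("K") != 1 or pep in seen:
            continue
        mkey = round(peptide_mass(pep) * 100)
        if mkey in masses:
            continue
        seen.add(pep)
        masses.add(mkey)
        peptides.append(pep)

    groups: dict[str, str] = {}
    remaining = list(peptides)
    gidx = 0
    while remaining:
        size = rng.randint(lo, hi)
        if len(remaining) - size < lo:
            size = len(remaining)
        chunk, remaining = remaining[:size], remaining[size:]
        for pep in chunk:
            groups[pep] = f"G{gidx:02d}"
        gidx += 1

    true_links: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    members: dict[str, list[str]] = {}
    for pep in peptides:
        members.setdefault(groups[pep], []).append(pep)
    for group_peps in members.values():
        for i in range(len(group_peps)):
            for j in range(i + 1, len(group_peps)):
                a = (group_peps[i], _site_of(group_peps[i]))
                b = (group_peps[j], _site_of(group_peps[j]))
                true_links.add((a, b) if a <= b else (b, a))
    return SyntheticLibrary(peptides, groups, true_links, seed)


def library_fasta_entries(library: SyntheticLibrary) -> list[ProteinEntry]:
    """Wrap library peptides as mini-proteins for database search."""
    return [
        ProteinEntry(accession=f"SYN{idx:03d}", sequence=pep,
                     description=f"group={library.groups[pep]}")
        for idx, pep in enumerate(library.peptides)
    ]


def write_group_table(library: SyntheticLibrary, path: str | Path) -> None:
    """Tab-separated peptide -> group membership table."""
    with open(path, "w") as fh:
        fh.write("peptide\tgroup\tsite\n")
        for pep in library.peptides:
            fh.write(f"{pep}\t{library.groups[pep]}\t{_site_of(pep)}\n")


def read_group_table(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                groups[parts[0]] = parts[1]
    return groups


@dataclass
class SimulationParams:
    """Tunable knobs of the spectral simulator (defaults are the study
    conditions used throughout the tests)."""

    n_crosslinks: int = 20
    ms3_per_doublet: int = 2
    noise_peaks: int = 30
    fragment_sampling: float = 0.7  # fraction of theoretical ions emitted
    frag_tol_ppm: float = 20.0
    doublet_charge: int = 2
    precursor_charge: int = 4
    gradient_minutes: float = 60.0
    n_linear_baits: int = 0  # decoy-bait linear-peptide MS2 spectra
    coisolation_rate: float = 0.0  # fraction of MS3 triggered off-doublet
    mz_jitter: bool = True


def _jitter(rng: np.random.Generator, mz: float, ppm: float, enabled: bool) -> float:
    if not enabled:
        return mz
    return mz + rng.normal(0.0, mz * ppm * 1e-6 / 3.0)


def _candidate(pep: str, site: int, arm: str) -> PeptideCandidate:
    return PeptideCandidate(
        sequence=pep,
        protein_accessions=frozenset({"SYN"}),
        is_decoy=False,
        is_entrapment=False,
        missed_cleavages=1,
        crosslink_site=site,
        arm=arm,
        fixed_mods=tuple(sorted(DEFAULT_FIXED_MODS.items())),
        neutral_mass=peptide_mass(pep),
    )


def _fragment_peaks(
    rng: np.random.Generator,
    pep: str,
    site: int,
    arm: str,
    spec: CrosslinkerSpec,
    params: SimulationParams,
) -> list[Peak]:
    frags = theoretical_fragments(_candidate(pep, site, arm), spec, max_frag_charge=2)
    peaks = []
    for _, mz in frags:
        if rng.random() > params.fragment_sampling:
            continue
        inten = float(rng.lognormal(mean=10.0, sigma=0.7))
        peaks.append(Peak(_jitter(rng, mz, params.frag_tol_ppm, params.mz_jitter), inten))
    return peaks


def _envelope(
    rng: np.random.Generator,
    mono_mz: float,
    charge: int,
    base_intensity: float,
    params: SimulationParams,
    n_members: int = 3,
) -> list[Peak]:
    """2-3 member isotope envelope with decaying intensities."""
    ratios = [1.0, 0.7, 0.35][:n_members]
    return [
        Peak(
            _jitter(rng, mono_mz + k * NEUTRON / charge, params.frag_tol_ppm,
                    params.mz_jitter),
            base_intensity * r,
        )
        for k, r in enumerate(ratios)
    ]


def simulate_run(
    library: SyntheticLibrary,
    spec: CrosslinkerSpec,
    params: SimulationParams | None = None,
    seed: int = 0,
    mzml_path: str | Path | None = None,
) -> tuple[list[Spectrum], SimulatedGroundTruth]:
    """Simulate one MS2-MS3 acquisition of the library.

    For each sampled intra-group cross-link the run contains one MS1 scan,
    one MS2 scan with both doublets (light/heavy arm-modified peptide peaks
    with isotope envelopes) plus stub-modified backbone fragments of both
    peptides and uniform noise, and ``ms3_per_doublet`` MS3 scans per doublet
    pair with linear fragments of the arm-carrying peptide. With
    ``coisolation_rate`` > 0 the corresponding fraction of MS3 scans is
    triggered on a noise peak instead of a doublet peak (an acquisition
    artifact the mapper must reject). Optional linear-bait MS2 spectra
    exercise the linear prefilter.

    Deterministic for identical (library, params, seed). If ``mzml_path``
    is given the spectra are also written as mzML.
    """
    if params is None:
        params = SimulationParams()
    rng = np.random.default_rng(seed)
    pyrng = random.Random(seed + 1)

    links = sorted(library.true_crosslinks)
    if params.n_crosslinks > len(links):
        raise ValueError(
            f"library admits only {len(links)} cross-links, "
            f"{params.n_crosslinks} requested"
        )
    sampled_idx = sorted(pyrng.sample(range(len(links)), params.n_crosslinks))
    sampled = [links[i] for i in sampled_idx]

    spectra: list[Spectrum] = []
    truths: list[SimulatedSpectrumTruth] = []
    scan_no = 0

    def next_id(level: int) -> str:
        nonlocal scan_no
        scan_no += 1
        return f"scan={scan_no}"

    rts = sorted(rng.uniform(2.0, params.gradient_minutes, size=len(sampled)))
    for (pa, pb), rt in zip(sampled, rts):
        chain = _emit_crosslink_chain(
            rng, pa, pb, float(rt), spec, params, next_id
        )
        spectra.extend(chain[0])
        truths.append(chain[1])

    # linear bait spectra (confidently explainable by a linear peptide)
    for i in range(params.n_linear_baits):
        pep = library.peptides[int(rng.integers(0, len(library.peptides)))]
        rt = float(rng.uniform(2.0, params.gradient_minutes))
        ms1_id = next_id(1)
        mass = peptide_mass(pep)
        mz = mz_from_neutral(mass, 2)
        ms1 = Spectrum(ms1_id, 1, rt - 0.01, [Peak(mz, 1e6)])
        ms2_id = next_id(2)
        frags = theoretical_fragments(_candidate(pep, 1, "light"), None, 2)
        peaks = [
            Peak(_jitter(rng, f, params.frag_tol_ppm, params.mz_jitter),
                 float(rng.lognormal(10.0, 0.7)))
            for _, f in frags
        ]
        peaks += _noise_peaks(rng, params.noise_peaks, 150.0, 1400.0)
        ms2 = Spectrum(
            ms2_id, 2, rt, peaks,
            PrecursorRef(ms1_id, mz, 2, isolation_width=1.2),
        )
        spectra.extend([ms1, ms2])
        truths.append(
            SimulatedSpectrumTruth(ms2_id, "linear", linear_peptide=pep,
                                   noise_peaks=params.noise_peaks)
        )

    resolve_ms1_precursors(spectra)
    truth = SimulatedGroundTruth(library, truths, sampled)
    if mzml_path is not None:
        write_mzml(spectra, mzml_path)
    return spectra, truth


def _noise_peaks(
    rng: np.random.Generator, n: int, lo: float, hi: float
) -> list[Peak]:
    return [
        Peak(float(m), float(i))
        for m, i in zip(
            rng.uniform(lo, hi, size=n), rng.lognormal(8.0, 1.0, size=n)
        )
    ]


def _emit_crosslink_chain(rng, pa, pb, rt, spec, params, next_id):
    (seq_a, site_a), (seq_b, site_b) = pa, pb
    mass_a, mass_b = peptide_mass(seq_a), peptide_mass(seq_b)
    precursor_neutral = mass_a + mass_b + spec.intact_mass
    prec_mz = mz_from_neutral(precursor_neutral, params.precursor_charge)
    z = params.doublet_charge

    ms1_id = next_id(1)
    ms1 = Spectrum(ms1_id, 1, rt - 0.02, [Peak(prec_mz, 5e6)])

    # doublet peaks: peptide + short arm (light) and + long arm (heavy)
    doublet_defs = []
    for seq, site, which in ((seq_a, site_a, "a"), (seq_b, site_b, "b")):
        mass = peptide_mass(seq)
        light_mz = mz_from_neutral(mass + spec.short_arm.mono_mass, z)
        heavy_mz = mz_from_neutral(mass + spec.long_arm.mono_mass, z)
        doublet_defs.append((which, seq, site, light_mz, heavy_mz))

    peaks: list[Peak] = []
    doublet_mono_mzs: dict[str, tuple[float, float]] = {}
    for which, seq, site, light_mz, heavy_mz in doublet_defs:
        base = float(rng.lognormal(12.0, 0.5))
        ratio = float(rng.uniform(0.5, 2.0))
        peaks += _envelope(rng, light_mz, z, base, params)
        peaks += _envelope(rng, heavy_mz, z, base * ratio, params)
        doublet_mono_mzs[which] = (light_mz, heavy_mz)
    for which, seq, site, *_ in doublet_defs:
        for arm in ("light", "heavy"):
            peaks += _fragment_peaks(rng, seq, site, arm, spec, params)
    peaks += _noise_peaks(rng, params.noise_peaks, 150.0, 1600.0)

    ms2_id = next_id(2)
    ms2 = Spectrum(
        ms2_id, 2, rt, peaks,
        PrecursorRef(ms1_id, prec_mz, params.precursor_charge, isolation_width=1.2),
    )

    chain = [ms1, ms2]
    ms3_ids: list[str] = []
    for which, seq, site, light_mz, heavy_mz in doublet_defs:
        arms = [("light", light_mz), ("heavy", heavy_mz)]
        for k in range(params.ms3_per_doublet):
            arm, sel_mz = arms[k % 2]
            offset = float(rng.uniform(0.05, 2.0))
            coisolated = rng.random() < params.coisolation_rate
            if coisolated:
                sel_mz = float(rng.uniform(300.0, 1200.0))
                ms3_peaks = _noise_peaks(rng, max(params.noise_peaks, 10), 150.0, 1200.0)
            else:
                ms3_peaks = _fragment_peaks(rng, seq, site, arm, spec, params)
                ms3_peaks += _noise_peaks(rng, params.noise_peaks // 2, 150.0, 1400.0)
            ms3_id = next_id(3)
            chain.append(
                Spectrum(
                    ms3_id, 3, rt + offset, ms3_peaks,
                    PrecursorRef(ms2_id, sel_mz, None, isolation_width=2.0),
                )
            )
            ms3_ids.append(ms3_id)

    truth = SimulatedSpectrumTruth(
        ms2_scan_id=ms2_id,
        kind="crosslink",
        peptide_a=pa,
        peptide_b=pb,
        ms3_scan_ids=ms3_ids,
        noise_peaks=params.noise_peaks,
        doublet_charge=z,
    )
    return chain, truth


def write_ground_truth(truth: SimulatedGroundTruth, path: str | Path) -> None:
    """Tab-separated sidecar listing each emitted scan chain's origin."""
    with open(path, "w") as fh:
        fh.write("ms2_scan\tkind\tpeptide_a\tsite_a\tpeptide_b\tsite_b\tms3_scans\n")
        for t in truth.spectra:
            pa = t.peptide_a or ("", "")
            pb = t.peptide_b or ("", "")
            fh.write(
                f"{t.ms2_scan_id}\t{t.kind}\t{pa[0]}\t{pa[1]}\t{pb[0]}\t{pb[1]}\t"
                + ",".join(t.ms3_scan_ids)
                + "\n"
            )
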