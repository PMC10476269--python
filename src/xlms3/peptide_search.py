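"""In-silico digestion, candidate generation, and fragment-match scoring.

Cross-linked peptides are identified *in linear form*: after cleavage of the
cross-linker, each peptide carries only a small arm remnant, so it can be
searched like a linear peptide with a variable-position modification. The
scorer here is a deterministic binomial-tail fragment-match score: under a
null model where each theoretical ion matches a random spectrum peak with
probability p, the score is -10*log10 P(X >= k) for k matched out of n
theoretical ions. It is order-preserving in match quality, which is all the
downstream pooling / min / max score propagation relies on.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import CARBAMIDOMETHYL, PROTON, RESIDUE_MASS, WATER
from .crosslinker import CrosslinkerSpec
from .doublet_mapping import DoubletAnnotation
from .spectra_io import ProteinEntry, Spectrum

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Enzyme:
    """A cleavage rule: cut after ``cleave_after`` unless next residue blocks."""

    name: str
    cleave_after: frozenset[str]
    block_if_next: frozenset[str]


TRYPSIN = Enzyme("trypsin", frozenset("KR"), frozenset("P"))

#: Fixed modifications applied during mass computation (residue -> delta Da).
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL}


@dataclass(frozen=True)
class DigestPeptide:
    """A digestion product with its position in the parent protein (1-based)."""

    sequence: str
    start: int  # 1-based position of first residue in the protein
    missed_cleavages: int
    protein_nterm: bool
    protein_cterm: bool


@dataclass(frozen=True)
class PeptideCandidate:
    """A peptide with one admissible cross-link site, ready for scoring."""

    sequence: str
    protein_accessions: frozenset[str]
    is_decoy: bool
    is_entrapment: bool
    missed_cleavages: int
    crosslink_site: int  # 1-based residue position within the peptide
    arm: str  # "light" | "heavy"
    fixed_mods: tuple[tuple[str, float], ...]
    neutral_mass: float  # peptide alone, fixed mods included, linker excluded
    protein_start: int = 1  # 1-based peptide start within the (first) protein

    def __post_init__(self) -> None:
        if not (1 <= self.crosslink_site <= len(self.sequence)):
            raise ValueError("crosslink_site out of range")

    @property
    def key(self) -> tuple[str, int, str, bool]:
        """Identity used for pooling: sequence, site, arm, decoy status."""
        return (self.sequence, self.crosslink_site, self.arm, self.is_decoy)


@dataclass(frozen=True)
class PSM:
    """A peptide-spectrum match with the binomial-tail score."""

    candidate: PeptideCandidate
    scan_id: str
    ms_level: int
    raw_score: float
    matched_ions: int
    total_ions: int
    source_doublet: DoubletAnnotation | None = None

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("raw_score must be >= 0")
        if self.matched_ions > self.total_ions:
            raise ValueError("matched ions cannot exceed theoretical ions")


# ---------------------------------------------------------------------------
# digestion


def digest(
    protein: ProteinEntry | str,
    enzyme: Enzyme = TRYPSIN,
    missed_cleavages_max: int = 2,
    length_range: tuple[int, int] = (5, 30),
    mass_range: tuple[float, float] = (400.0, 6000.0),
    fixed_mods: dict[str, float] | None = None,
) -> list[DigestPeptide]:
    """Enzymatic digestion with positions, missed cleavages, and filters.

    Implemented as a character walk over the sequence (cut after a residue in
    ``cleave_after`` unless the next residue is in ``block_if_next``),
    then enumeration of runs of up to ``missed_cleavages_max + 1`` adjacent
    fragments, filtered by length and by mass with fixed modifications.
    """
    seq = protein.sequence if isinstance(protein, ProteinEntry) else protein
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    cuts = [0]
    for i, aa in enumerate(seq[:-1]):
        if aa in enzyme.cleave_after and seq[i + 1] not in enzyme.block_if_next:
            cuts.append(i + 1)
    cuts.append(len(seq))

    lo_len, hi_len = length_range
    lo_m, hi_m = mass_range
    out: list[DigestPeptide] = []
    nfrag = len(cuts) - 1
    for a in range(nfrag):
        for mc in range(missed_cleavages_max + 1):
            b = a + mc + 1
            if b > nfrag:
                break
            pep = seq[cuts[a]:cuts[b]]
            if not (lo_len <= len(pep) <= hi_len):
                continue
            try:
                m = peptide_mass(pep, fixed_mods)
            except KeyError:
                continue  # non-standard residue (B, X, Z ...): skip peptide
            if not (lo_m <= m <= hi_m):
                continue
            out.append(
                DigestPeptide(
                    sequence=pep,
                    start=cuts[a] + 1,
                    missed_cleavages=mc,
                    protein_nterm=cuts[a] == 0,
                    protein_cterm=cuts[b] == len(seq),
                )
            )
    return out


def peptide_mass(sequence: str, fixed_mods: dict[str, float] | None = None) -> float:
    """Monoisotopic neutral peptide mass with fixed modifications applied."""
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    m = WATER
    for aa in sequence:
        m += RESIDUE_MASS[aa]
        m += fixed_mods.get(aa, 0.0)
    return m


# ---------------------------------------------------------------------------
# candidate index and generation


class PeptideIndex:
    """Mass-sorted index of digested peptides for tolerance lookups."""

    def __init__(
        self,
        proteins: list[ProteinEntry],
        enzyme: Enzyme = TRYPSIN,
        missed_cleavages_max: int = 2,
        length_range: tuple[int, int] = (5, 30),
        mass_range: tuple[float, float] = (400.0, 6000.0),
        fixed_mods: dict[str, float] | None = None,
    ) -> None:
        self.fixed_mods = DEFAULT_FIXED_MODS if fixed_mods is None else fixed_mods
        records: dict[tuple[str, bool], dict] = {}
        for prot in proteins:
            for dp in digest(
                prot, enzyme, missed_cleavages_max, length_range, mass_range,
                self.fixed_mods,
            ):
                key = (dp.sequence, prot.is_decoy)
                rec = records.setdefault(
                    key,
                    dict(
                        peptide=dp, accessions=set(), entrapment=False,
                        nterm=False, cterm=False, start=dp.start,
                    ),
                )
                rec["accessions"].add(prot.accession)
                rec["entrapment"] = rec["entrapment"] or prot.is_entrapment
                rec["nterm"] = rec["nterm"] or dp.protein_nterm
                rec["cterm"] = rec["cterm"] or dp.protein_cterm
        entries = []
        for (seq, is_decoy), rec in sorted(records.items()):
            entries.append(
                dict(
                    sequence=seq,
                    mass=peptide_mass(seq, self.fixed_mods),
                    is_decoy=is_decoy,
                    is_entrapment=rec["entrapment"],
                    accessions=frozenset(rec["accessions"]),
                    missed_cleavages=rec["peptide"].missed_cleavages,
                    protein_nterm=rec["nterm"],
                    protein_cterm=rec["cterm"],
                    start=rec["start"],
                )
            )
        entries.sort(key=lambda e: e["mass"])
        self._entries = entries
        self._masses = [e["mass"] for e in entries]

    def __len__(self) -> int:
        return len(self._entries)

    def by_mass(self, target_mass: float, prec_tol_ppm: float) -> list[dict]:
        tol = target_mass * prec_tol_ppm * 1e-6
        lo = bisect.bisect_left(self._masses, target_mass - tol)
        hi = bisect.bisect_right(self._masses, target_mass + tol)
        return self._entries[lo:hi]

    def all_entries(self) -> list[dict]:
        return list(self._entries)


def crosslink_sites(
    sequence: str,
    spec: CrosslinkerSpec,
    protein_nterm: bool = False,
    protein_cterm: bool = False,
) -> list[int]:
    """Admissible cross-link positions (1-based) in a peptide.

    A C-terminal K of a tryptic peptide is excluded unless the peptide is
    protein C-terminal: a lysine blocked by the cross-linker would not have
    been cleaved by trypsin in the first place.
    """
    sites = []
    for pos, aa in enumerate(sequence, start=1):
        if aa in spec.reactive_residues:
            if (
                pos == len(sequence)
                and aa in "KR"  # tryptic C-terminus
                and not protein_cterm
            ):
                continue
            sites.append(pos)
    if spec.protein_nterm_reactive and protein_nterm and 1 not in sites:
        sites.insert(0, 1)
    return sites


def generate_candidates(
    index: PeptideIndex,
    target_mass: float,
    prec_tol_ppm: float,
    spec: CrosslinkerSpec,
    arm: str,
) -> list[PeptideCandidate]:
    """All peptide candidates matching a cross-linker-free target mass.

    One candidate per admissible cross-link site per matching peptide.
    """
    out: list[PeptideCandidate] = []
    for e in index.by_mass(target_mass, prec_tol_ppm):
        for site in crosslink_sites(
            e["sequence"], spec, e["protein_nterm"], e["protein_cterm"]
        ):
            out.append(
                PeptideCandidate(
                    sequence=e["sequence"],
                    protein_accessions=e["accessions"],
                    is_decoy=e["is_decoy"],
                    is_entrapment=e["is_entrapment"],
                    missed_cleavages=e["missed_cleavages"],
                    crosslink_site=site,
                    arm=arm,
                    fixed_mods=tuple(sorted(index.fixed_mods.items())),
                    neutral_mass=e["mass"],
                    protein_start=e["start"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# theoretical fragments and scoring


def theoretical_fragments(
    candidate: PeptideCandidate,
    spec: CrosslinkerSpec | None,
    max_frag_charge: int = 2,
) -> list[tuple[str, float]]:
    """b- and y-ion m/z values for a (possibly arm-modified) peptide.

    Ions containing the cross-link site are shifted by the remnant arm mass;
    pass ``spec=None`` for an unmodified linear peptide. Fragment charges run
    from 1 to ``max_frag_charge``.
    """
    seq = candidate.sequence
    n = len(seq)
    if n < 2:
        return []
    mods = dict(candidate.fixed_mods)
    res = [RESIDUE_MASS[aa] + mods.get(aa, 0.0) for aa in seq]
    arm_mass = spec.arm_mass(candidate.arm) if spec is not None else 0.0
    site = candidate.crosslink_site

    prefix = np.cumsum(res)  # prefix[i] = mass of residues 1..i+1
    total = prefix[-1]
    out: list[tuple[str, float]] = []
    for i in range(1, n):  # b_i / y_(n-i)
        b_neutral = prefix[i - 1]
        y_neutral = total - prefix[i - 1] + WATER
        if spec is not None:
            if site <= i:
                b_neutral += arm_mass
            else:
                y_neutral += arm_mass
        for z in range(1, max_frag_charge + 1):
            out.append((f"b{i}+{z}", b_neutral / z + PROTON))
            out.append((f"y{n - i}+{z}", y_neutral / z + PROTON))
    return out


def count_matches(
    spectrum: Spectrum, fragment_mzs: list[float], frag_tol: float, tol_unit: str
) -> int:
    """Number of theoretical ions with at least one matching spectrum peak."""
    mzs = spectrum.mz_array
    k = 0
    for f in fragment_mzs:
        tol = f * frag_tol * 1e-6 if tol_unit == "ppm" else frag_tol
        i = bisect.bisect_left(mzs, f - tol)
        if i < len(mzs) and mzs[i] <= f + tol:
            k += 1
    return k


def binomial_score(
    k: int, n: int, n_peaks: int, span: float, tol_width: float
) -> float:
    """-10*log10 of the binomial tail P(X >= k) for k of n ions matched.

    The per-ion random-match probability is ``2 * tol_width * n_peaks / span``
    where ``span`` is the m/z range of the spectrum. Zero matches score 0.
    """
    if k <= 0 or n <= 0:
        return 0.0
    p = min(max(2.0 * tol_width * n_peaks / max(span, 1e-9), 1e-12), 0.999999)
    logsf = stats.binom.logsf(k - 1, n, p)
    return float(max(0.0, -10.0 * logsf / np.log(10.0)))


def score_psm(
    spectrum: Spectrum,
    candidate: PeptideCandidate,
    spec: CrosslinkerSpec | None,
    frag_tol: float = 20.0,
    tol_unit: str = "ppm",
    max_frag_charge: int = 2,
    source_doublet: DoubletAnnotation | None = None,
) -> PSM:
    """Score one candidate against one spectrum with the binomial-tail score."""
    frags = theoretical_fragments(candidate, spec, max_frag_charge)
    n = len(frags)
    mzs = spectrum.mz_array
    if n == 0 or not mzs:
        return PSM(candidate, spectrum.scan_id, spectrum.ms_level, 0.0, 0, n,
                   source_doublet)
    k = count_matches(spectrum, [f for _, f in frags], frag_tol, tol_unit)
    span = max(mzs[-1] - mzs[0], 1.0)
    mid = 0.5 * (mzs[0] + mzs[-1])
    tol_width = mid * frag_tol * 1e-6 if tol_unit == "ppm" else frag_tol
    score = binomial_score(k, n, len(mzs), span, tol_width)
    return PSM(candidate, spectrum.scan_id, spectrum.ms_level, score, k, n,
               source_doublet)


# ---------------------------------------------------------------------------
# linear prefilter


def linear_prefilter(
    spectra: list[Spectrum],
    index: PeptideIndex,
    threshold: float = 0.01,
    prec_tol_ppm: float = 10.0,
    frag_tol: float = 20.0,
    tol_unit: str = "ppm",
    max_charge: int = 4,
) -> set[str]:
    """Scan ids of MS2 spectra confidently explained by a *linear* peptide.

    Each MS2 spectrum is scored against unmodified linear peptides whose mass
    matches the precursor (at the declared charge, or 1..max_charge when
    unknown). Best hits are ranked across spectra and a target-decoy q-value
    is computed; scans whose best hit is a target with q <= threshold are
    flagged for exclusion from the cross-link search.
    """
    best: list[tuple[str, float, bool]] = []  # scan, score, is_decoy
    for s in spectra:
        if s.ms_level != 2 or s.precursor is None:
            continue
        charges = (
            [s.precursor.selected_charge]
            if s.precursor.selected_charge is not None
            else list(range(1, max_charge + 1))
        )
        top: tuple[float, bool] | None = None
        for z in charges:
            target = z * (s.precursor.selected_mz - PROTON)
            for e in index.by_mass(target, prec_tol_ppm):
                cand = PeptideCandidate(
                    sequence=e["sequence"],
                    protein_accessions=e["accessions"],
                    is_decoy=e["is_decoy"],
                    is_entrapment=e["is_entrapment"],
                    missed_cleavages=e["missed_cleavages"],
                    crosslink_site=1,
                    arm="light",
                    fixed_mods=tuple(sorted(index.fixed_mods.items())),
                    neutral_mass=e["mass"],
                )
                psm = score_psm(s, cand, None, frag_tol, tol_unit)
                if psm.raw_score > 0 and (top is None or psm.raw_score > top[0]):
                    top = (psm.raw_score, e["is_decoy"])
        if top is not None:
            best.append((s.scan_id, top[0], top[1]))

    if not best:
        return set()
    best.sort(key=lambda t: -t[1])
    # q-value: running minimum of decoys/targets from the bottom up
    qs: list[float] = []
    n_t = n_d = 0
    fdrs = []
    for _, _, is_decoy in best:
        if is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append(n_d / max(n_t, 1))
    qmin = float("inf")
    for f in reversed(fdrs):
        qmin = min(qmin, f)
        qs.append(qmin)
    qs.reverse()
    flagged = {
        scan
        for (scan, _, is_decoy), q in zip(best, qs)
        if not is_decoy and q <= threshold
    }
    if flagged:
        log.info("linear prefilter removed %d MS2 scan(s)", len(flagged))
    return flagged
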