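"""Score pooling, boosting, CSM/cross-link assembly, and validation.

Score propagation follows the usual conservative convention for cleavable
cross-link searches: a peptide identified in several MSn scans of the same
precursor gains confidence (multiplicative boost per additional scan), a
cross-link spectrum match (CSM) is only as good as its weaker peptide
(min), and a cross-link is as good as its best supporting CSM (max).
Validation is a two-step target-decoy FDR (CSM level, then cross-link
level) with the paired-decoy estimator (TD - DD) / TT, followed optionally
by entrapment filtering and groupwise experimentally-validated FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .constants import neutral_from_mz
from .crosslinker import CrosslinkerSpec
from .peptide_search import PSM, PeptideCandidate
from .spectra_io import Spectrum

log = logging.getLogger(__name__)

#: Default boost parameter: each additional supporting MSn scan multiplies the
#: best score by (1 + p/100).
DEFAULT_BOOST_P = 20.0


@dataclass(frozen=True)
class PooledHit:
    """One peptide's evidence pooled across an MS2 scan and its MS3 scans."""

    candidate: PeptideCandidate
    scores_peptide: tuple[float, ...]
    scan_ids: tuple[str, ...]
    p: float
    boosted_score: float

    @property
    def n(self) -> int:
        """Number of unique MSn scans the peptide was identified in."""
        return len(set(self.scan_ids))


def boost_score(scores: tuple[float, ...] | list[float], n: int, p: float) -> float:
    """Boosted identification score: ``max(scores) * (1 + p/100) ** (n - 1)``.

    Anchors: p = 0 leaves the maximum score unchanged; p = 100 doubles it for
    every additional scan. n = 1 (single scan) is never boosted.
    """
    if not scores:
        raise ValueError("cannot boost an empty score list")
    if n < 1:
        raise ValueError("n must be >= 1")
    if p < 0:
        raise ValueError("boost parameter p must be >= 0")
    return max(scores) * (1.0 + p / 100.0) ** (n - 1)


def pool_and_boost(psms: list[PSM], p: float = DEFAULT_BOOST_P) -> PooledHit:
    """Pool PSMs of one candidate across one MS2 scan chain and boost.

    All PSMs must share candidate identity (sequence, site, arm, decoy
    status). ``n`` counts unique scan ids.
    """
    if not psms:
        raise ValueError("cannot pool an empty PSM list")
    key = psms[0].candidate.key
    if any(m.candidate.key != key for m in psms):
        raise ValueError("pooled PSMs must share candidate identity")
    scores = tuple(m.raw_score for m in psms)
    scan_ids = tuple(m.scan_id for m in psms)
    n = len(set(scan_ids))
    return PooledHit(
        candidate=psms[0].candidate,
        scores_peptide=scores,
        scan_ids=scan_ids,
        p=p,
        boosted_score=boost_score(scores, n, p),
    )


# ---------------------------------------------------------------------------
# CSMs and cross-links


def _decoy_class(a: PeptideCandidate, b: PeptideCandidate) -> str:
    nd = int(a.is_decoy) + int(b.is_decoy)
    return ("TT", "TD", "DD")[nd]


@dataclass(frozen=True)
class CSM:
    """A cross-link spectrum match: two pooled peptides on one MS2 scan."""

    ms2_scan_id: str
    alpha: PooledHit
    beta: PooledHit
    score: float
    decoy_class: str

    def __post_init__(self) -> None:
        if self.decoy_class not in ("TT", "TD", "DD"):
            raise ValueError(f"bad decoy class {self.decoy_class!r}")

    @property
    def contains_entrapment(self) -> bool:
        return self.alpha.candidate.is_entrapment or self.beta.candidate.is_entrapment

    @property
    def pair_key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Unordered (sequence, site) pair key used for cross-link grouping."""
        a = (self.alpha.candidate.sequence, self.alpha.candidate.crosslink_site)
        b = (self.beta.candidate.sequence, self.beta.candidate.crosslink_site)
        return (a, b) if a <= b else (b, a)


def make_csm(ms2_scan_id: str, alpha: PooledHit, beta: PooledHit) -> CSM:
    """Combine the two peptides into a CSM; score = min of boosted scores."""
    return CSM(
        ms2_scan_id=ms2_scan_id,
        alpha=alpha,
        beta=beta,
        score=min(alpha.boosted_score, beta.boosted_score),
        decoy_class=_decoy_class(alpha.candidate, beta.candidate),
    )


def assemble_csms(
    ms2: Spectrum,
    pooled_alpha: list[PooledHit],
    pooled_beta: list[PooledHit],
    spec: CrosslinkerSpec | None = None,
    prec_tol_ppm: float = 10.0,
) -> list[CSM]:
    """Pair the best alpha hit with the best beta hit of one MS2 scan.

    If either side has no hit, no CSM is formed. When the MS1 precursor
    charge is known and a cross-linker spec is given, pairs whose peptide
    masses plus the intact linker mass disagree with the MS1 precursor mass
    beyond tolerance are dropped.
    """
    if not pooled_alpha or not pooled_beta:
        if pooled_alpha or pooled_beta:
            log.debug("scan %s: only one side identified, no CSM", ms2.scan_id)
        return []
    alpha = max(pooled_alpha, key=lambda h: (h.boosted_score, h.candidate.sequence))
    beta = max(pooled_beta, key=lambda h: (h.boosted_score, h.candidate.sequence))
    if spec is not None and ms2.precursor is not None and ms2.precursor.selected_charge:
        precursor_neutral = neutral_from_mz(
            ms2.precursor.selected_mz, ms2.precursor.selected_charge
        )
        total = alpha.candidate.neutral_mass + beta.candidate.neutral_mass + spec.intact_mass
        if abs(total - precursor_neutral) > 2 * precursor_neutral * prec_tol_ppm * 1e-6:
            log.debug("scan %s: precursor-sum check failed, CSM dropped", ms2.scan_id)
            return []
    return [make_csm(ms2.scan_id, alpha, beta)]


@dataclass
class Crosslink:
    """A grouped cross-link: one peptide pair aggregating its CSMs."""

    peptide_a: tuple[str, int]  # (sequence, 1-based site)
    peptide_b: tuple[str, int]
    csms: list[CSM]
    score: float
    decoy_class: str
    group_a: str | None = None
    group_b: str | None = None

    @property
    def contains_entrapment(self) -> bool:
        return any(c.contains_entrapment for c in self.csms)

    @property
    def best_csm(self) -> CSM:
        return max(self.csms, key=lambda c: c.score)


def group_crosslinks(csms: list[CSM]) -> list[Crosslink]:
    """Group CSMs of the same unordered (sequence, site) pair.

    The cross-link score is the maximum CSM score; its decoy class is taken
    from the maximum-scoring CSM.
    """
    by_key: dict[tuple, list[CSM]] = {}
    for c in csms:
        by_key.setdefault(c.pair_key, []).append(c)
    out = []
    for key in sorted(by_key):
        members = by_key[key]
        best = max(members, key=lambda c: c.score)
        out.append(
            Crosslink(
                peptide_a=key[0],
                peptide_b=key[1],
                csms=members,
                score=best.score,
                decoy_class=best.decoy_class,
            )
        )
    return out


# ---------------------------------------------------------------------------
# FDR estimation


@dataclass
class FDRResult:
    """Outcome of one target-decoy thresholding step."""

    level: str  # "CSM" | "crosslink"
    threshold_score: float
    n_tt: int
    n_td: int
    n_dd: int
    estimated_fdr: float
    accepted: list  # TT items at or above the threshold


def estimate_fdr(items: list, target: float, level: str = "CSM") -> FDRResult:
    """Target-decoy FDR thresholding with the paired estimator.

    Items (anything with ``score`` and ``decoy_class``) are sorted by
    descending score; at each candidate threshold the FDR among accepted
    target-target items is estimated as ``max(0, TD - DD) / TT``. The lowest
    threshold whose estimate is <= ``target`` is chosen and its TT items
    returned. Equal scores are treated as one block (all in or all out), so a
    decoy tied with targets keeps the targets out — the conservative choice.
    """
    if not 0 < target < 1:
        raise ValueError("FDR target must be in (0, 1)")
    if not items:
        return FDRResult(level, float("inf"), 0, 0, 0, 0.0, [])
    ranked = sorted(items, key=lambda it: -it.score)

    best: tuple[float, int, int, int, float] | None = None  # thr, tt, td, dd, fdr
    tt = td = dd = 0
    i = 0
    n = len(ranked)
    while i < n:
        j = i
        while j < n and ranked[j].score == ranked[i].score:
            c = ranked[j].decoy_class
            tt += c == "TT"
            td += c == "TD"
            dd += c == "DD"
            j += 1
        fdr = 0.0 if tt == 0 else max(0, td - dd) / tt
        if fdr <= target:
            best = (ranked[i].score, tt, td, dd, fdr)
        i = j
    if best is None:
        return FDRResult(level, float("inf"), 0, 0, 0, 0.0, [])
    thr, tt, td, dd, fdr = best
    accepted = [it for it in ranked if it.score >= thr and it.decoy_class == "TT"]
    return FDRResult(level, thr, tt, td, dd, fdr, accepted)


def two_step_validate(
    csms: list[CSM],
    target_csm: float = 0.01,
    target_xl: float = 0.01,
) -> tuple[FDRResult, FDRResult, list[Crosslink]]:
    """Two-step validation: CSM-level FDR, grouping, cross-link-level FDR.

    Decoy cross-links are removed from the final report (they only serve the
    estimation).
    """
    csm_result = estimate_fdr(csms, target_csm, level="CSM")
    # the CSM threshold applies to targets and decoys alike so that the
    # surviving decoys still calibrate the second estimation step
    surviving = [c for c in csms if c.score >= csm_result.threshold_score]
    if not csm_result.accepted:
        return csm_result, FDRResult("crosslink", float("inf"), 0, 0, 0, 0.0, []), []
    links = group_crosslinks(surviving)
    xl_result = estimate_fdr(links, target_xl, level="crosslink")
    final = [l for l in xl_result.accepted if l.decoy_class == "TT"]
    return csm_result, xl_result, final


# ---------------------------------------------------------------------------
# groupwise validated FDR and entrapment filtering


def validated_group_fdr(
    crosslinks: list[Crosslink],
    groups: dict[str, str],
) -> float:
    """Experimentally validated FDR for a groupwise-cross-linked library.

    ``groups`` maps peptide sequence to group label; peptides absent from the
    map are non-library. A cross-link is a false positive if its peptides are
    in different groups or if either peptide is non-library. Returns
    (#inter-group + #non-library) / #total; an empty input returns 0 with a
    warning.
    """
    if not crosslinks:
        log.warning("validated_group_fdr: empty cross-link list, returning 0")
        return 0.0
    false_positives = 0
    for xl in crosslinks:
        ga = groups.get(xl.peptide_a[0])
        gb = groups.get(xl.peptide_b[0])
        if ga is None or gb is None or ga != gb:
            false_positives += 1
    return false_positives / len(crosslinks)


def entrapment_filter(
    crosslinks: list[Crosslink],
    max_fraction: float = 0.01,
) -> list[Crosslink]:
    """Remove lowest-scoring cross-links until the entrapment fraction drops.

    Iteratively discards the lowest-scoring cross-link while the fraction of
    cross-links containing an entrapment peptide is >= ``max_fraction``.
    Operates on the already-validated accepted list.
    """
    remaining = sorted(crosslinks, key=lambda x: -x.score)
    while remaining:
        n_ent = sum(1 for x in remaining if x.contains_entrapment)
        if n_ent / len(remaining) < max_fraction:
            break
        remaining.pop()
    return remaining
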