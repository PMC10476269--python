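"""End-to-end MS2-MS3 cross-link search orchestration.

The search runs, per MS2 scan: linear prefilter -> doublet detection ->
MS3-to-doublet mapping -> candidate generation from the adjusted
cross-linker-free peptide masses -> fragment-match scoring on the assigned
MS3 scans (and, by default, also on the MS2 scan itself) -> pooling and
boosting -> CSM assembly. CSMs are then validated with the two-step
target-decoy FDR and grouped into cross-links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .crosslinker import CrosslinkerSpec, load_spec
from .doublet_mapping import (
    DoubletPair,
    detect_doublets,
    map_ms3_to_doublets,
    peptide_mass_from_doublet,
)
from .peptide_search import (
    PSM,
    PeptideIndex,
    generate_candidates,
    linear_prefilter,
    score_psm,
)
from .scoring_validation import (
    CSM,
    Crosslink,
    FDRResult,
    PooledHit,
    assemble_csms,
    pool_and_boost,
    two_step_validate,
)
from .spectra_io import ProteinEntry, Spectrum, generate_decoys

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one search run, with the package defaults."""

    crosslinker: str = "DSSO"
    prec_tol_ppm: float = 10.0
    frag_tol: float = 20.0
    frag_tol_unit: str = "ppm"  # "ppm" (Orbitrap-like) or "Da" (ion-trap-like)
    max_charge: int = 4
    max_frag_charge: int = 2
    rt_window: float = 5.0  # minutes, one-sided (MS3 after MS2)
    boost_p: float = 20.0
    fdr_csm: float = 0.01
    fdr_crosslink: float = 0.01
    prefilter_q: float = 0.01
    use_prefilter: bool = True
    use_ms2_supplement: bool = True  # also score candidates on the MS2 scan
    missed_cleavages: int = 2
    peptide_length: tuple[int, int] = (5, 30)
    peptide_mass_range: tuple[float, float] = (400.0, 6000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prec_tol_ppm <= 0 or self.frag_tol <= 0:
            raise ValueError("tolerances must be positive")
        for t in (self.fdr_csm, self.fdr_crosslink, self.prefilter_q):
            if not 0 < t < 1:
                raise ValueError("FDR targets must be in (0, 1)")


@dataclass
class SearchResult:
    """Everything a search run produced, with per-stage counts."""

    csms_all: list[CSM]
    csm_fdr: FDRResult
    crosslink_fdr: FDRResult
    crosslinks: list[Crosslink]
    stage_counts: dict[str, int]
    config: RunConfig


def run_search(
    spectra: list[Spectrum],
    proteins: list[ProteinEntry],
    config: RunConfig | None = None,
    spec: CrosslinkerSpec | None = None,
) -> SearchResult:
    """Run the full MS2-MS3 cross-link search on in-memory inputs.

    ``proteins`` are target entries; reversed decoys are generated here.
    """
    cfg = config or RunConfig()
    if spec is None:
        spec = load_spec(cfg.crosslinker)

    targets = [p for p in proteins if not p.is_decoy]
    database = targets + generate_decoys(targets)
    index = PeptideIndex(
        database,
        missed_cleavages_max=cfg.missed_cleavages,
        length_range=cfg.peptide_length,
        mass_range=cfg.peptide_mass_range,
    )

    ms2_scans = [s for s in spectra if s.ms_level == 2]
    ms3_scans = [s for s in spectra if s.ms_level == 3]
    counts = {
        "ms1_scans": sum(1 for s in spectra if s.ms_level == 1),
        "ms2_scans": len(ms2_scans),
        "ms3_scans": len(ms3_scans),
        "database_entries": len(database),
        "indexed_peptides": len(index),
    }
    if not ms3_scans:
        log.warning("no MS3 scans present: proceeding in MS2-only mode")

    flagged: set[str] = set()
    if cfg.use_prefilter:
        flagged = linear_prefilter(
            ms2_scans, index, cfg.prefilter_q, cfg.prec_tol_ppm,
            cfg.frag_tol, cfg.frag_tol_unit, cfg.max_charge,
        )
    counts["prefiltered_ms2"] = len(flagged)

    csms: list[CSM] = []
    n_doublet_pairs = 0
    n_assigned = 0
    n_unassigned = 0
    for ms2 in ms2_scans:
        if ms2.scan_id in flagged:
            continue
        doublets = detect_doublets(
            ms2, spec, cfg.frag_tol if cfg.frag_tol_unit == "ppm" else 20.0,
            cfg.max_charge, cfg.prec_tol_ppm,
        )
        if not doublets:
            continue
        n_doublet_pairs += len(doublets)
        assignments, n_un = map_ms3_to_doublets(
            ms2, doublets, ms3_scans, spec, cfg.prec_tol_ppm, cfg.rt_window
        )
        n_assigned += len(assignments)
        n_unassigned += n_un
        csms.extend(_search_one_scan(ms2, doublets, assignments,
                                     {s.scan_id: s for s in ms3_scans},
                                     index, spec, cfg))

    counts["doublet_pairs"] = n_doublet_pairs
    counts["ms3_assigned"] = n_assigned
    counts["ms3_unassigned"] = n_unassigned
    counts["csms"] = len(csms)

    csm_fdr, xl_fdr, crosslinks = two_step_validate(
        csms, cfg.fdr_csm, cfg.fdr_crosslink
    )
    counts["csms_accepted"] = len(csm_fdr.accepted)
    counts["crosslinks_accepted"] = len(crosslinks)
    return SearchResult(csms, csm_fdr, xl_fdr, crosslinks, counts, cfg)


def _search_one_scan(
    ms2: Spectrum,
    doublets: list[DoubletPair],
    assignments,
    ms3_by_id: dict[str, Spectrum],
    index: PeptideIndex,
    spec: CrosslinkerSpec,
    cfg: RunConfig,
) -> list[CSM]:
    """Identify both peptides of one MS2 scan chain and assemble its CSMs."""
    ms3_for_doublet: dict[int, list] = {}
    for a in assignments:
        ms3_for_doublet.setdefault(id_of(doublets, a.doublet), []).append(a)

    pooled_by_pair: dict[int, list[PooledHit]] = {}
    for d_idx, pair in enumerate(doublets):
        psms_by_candidate: dict[tuple, list[PSM]] = {}
        for ann in (pair.light, pair.heavy):
            try:
                target_mass = peptide_mass_from_doublet(
                    ann.mono_neutral_mass, ann.arm, spec, ann.product_applied
                )
            except ValueError:
                continue
            candidates = generate_candidates(
                index, target_mass, cfg.prec_tol_ppm, spec, ann.arm
            )
            if not candidates:
                continue
            scans: list[Spectrum] = []
            for a in ms3_for_doublet.get(d_idx, []):
                if a.doublet.arm == ann.arm:
                    scans.append(ms3_by_id[a.ms3_scan_id])
            if cfg.use_ms2_supplement or not scans:
                scans.append(ms2)
            for cand in candidates:
                for scan in scans:
                    psm = score_psm(
                        scan, cand, spec, cfg.frag_tol, cfg.frag_tol_unit,
                        cfg.max_frag_charge, source_doublet=ann,
                    )
                    if psm.raw_score > 0:
                        psms_by_candidate.setdefault(cand.key, []).append(psm)
        for key, psms in psms_by_candidate.items():
            pooled_by_pair.setdefault(d_idx, []).append(
                pool_and_boost(psms, cfg.boost_p)
            )

    # choose the two distinct doublet pairs whose best hits give the highest
    # CSM (min) score while satisfying the MS1 precursor-sum check; the pair
    # of lower light-peak m/z takes the alpha role
    best_csm: list[CSM] = []
    indices = sorted(pooled_by_pair)
    for ai in range(len(indices)):
        for bi in range(ai + 1, len(indices)):
            i, j = indices[ai], indices[bi]
            light_mz_i = ms2.peaks[doublets[i].light.peak_index].mz
            light_mz_j = ms2.peaks[doublets[j].light.peak_index].mz
            first, second = (i, j) if light_mz_i <= light_mz_j else (j, i)
            csms = assemble_csms(
                ms2, pooled_by_pair[first], pooled_by_pair[second],
                spec, cfg.prec_tol_ppm,
            )
            if csms and (not best_csm or csms[0].score > best_csm[0].score):
                best_csm = csms
    if not best_csm and len(indices) == 1:
        # a single doublet pair cannot form a CSM: both peptides are needed
        log.debug("scan %s: only one doublet pair with hits, no CSM", ms2.scan_id)
    return best_csm


def id_of(doublets: list[DoubletPair], annotation) -> int:
    """Index of the doublet pair an annotation belongs to."""
    for i, pair in enumerate(doublets):
        if annotation in (pair.light, pair.heavy):
            return i
    raise ValueError("annotation does not belong to any doublet pair")
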