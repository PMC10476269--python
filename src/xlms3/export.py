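"""Result tables and exporters to community visualization formats.

CSM and cross-link tables are written as tab-separated files with stable
column names; xiVIEW/xiNET get the minimal CSV columns those tools ingest.
All positions are 1-based inclusive, both within peptides and within
proteins.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .scoring_validation import CSM, Crosslink
from .pipeline import SearchResult

log = logging.getLogger(__name__)


def csm_table(csms: list[CSM]) -> pd.DataFrame:
    rows = []
    for c in sorted(csms, key=lambda c: (c.ms2_scan_id, -c.score)):
        rows.append(
            dict(
                scan=c.ms2_scan_id,
                sequence_a=c.alpha.candidate.sequence,
                site_a=c.alpha.candidate.crosslink_site,
                proteins_a=";".join(sorted(c.alpha.candidate.protein_accessions)),
                n_scans_a=c.alpha.n,
                score_a=round(c.alpha.boosted_score, 4),
                sequence_b=c.beta.candidate.sequence,
                site_b=c.beta.candidate.crosslink_site,
                proteins_b=";".join(sorted(c.beta.candidate.protein_accessions)),
                n_scans_b=c.beta.n,
                score_b=round(c.beta.boosted_score, 4),
                score=round(c.score, 4),
                decoy_class=c.decoy_class,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scan", "sequence_a", "site_a", "proteins_a", "n_scans_a", "score_a",
            "sequence_b", "site_b", "proteins_b", "n_scans_b", "score_b",
            "score", "decoy_class",
        ],
    )


def crosslink_table(crosslinks: list[Crosslink]) -> pd.DataFrame:
    rows = []
    for xl in sorted(crosslinks, key=lambda x: (-x.score, x.peptide_a, x.peptide_b)):
        best = xl.best_csm
        rows.append(
            dict(
                sequence_a=xl.peptide_a[0],
                site_a=xl.peptide_a[1],
                sequence_b=xl.peptide_b[0],
                site_b=xl.peptide_b[1],
                n_csms=len(xl.csms),
                score=round(xl.score, 4),
                decoy_class=xl.decoy_class,
                contains_entrapment=xl.contains_entrapment,
                best_scan=best.ms2_scan_id,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_a", "site_a", "sequence_b", "site_b", "n_csms",
            "score", "decoy_class", "contains_entrapment", "best_scan",
        ],
    )


def export_xiview(crosslinks: list[Crosslink], path: str | Path) -> int:
    """Write cross-links in the minimal xiVIEW/xiNET CSV column layout.

    Protein-level link positions are 1-based: a peptide starting at protein
    position 10 with link site 2 exports position 11. Cross-links whose
    peptides map to no protein are skipped with a warning. Returns the number
    of rows written.
    """
    rows = []
    for xl in sorted(crosslinks, key=lambda x: (-x.score, x.peptide_a, x.peptide_b)):
        best = xl.best_csm
        a, b = best.alpha.candidate, best.beta.candidate
        if not a.protein_accessions or not b.protein_accessions:
            log.warning("cross-link %s--%s maps to no protein; row skipped",
                        xl.peptide_a[0], xl.peptide_b[0])
            continue
        rows.append(
            dict(
                Protein1=";".join(sorted(a.protein_accessions)),
                PepPos1=a.protein_start,
                PepSeq1=a.sequence,
                LinkPos1=a.crosslink_site,
                AbsPos1=a.protein_start + a.crosslink_site - 1,
                Protein2=";".join(sorted(b.protein_accessions)),
                PepPos2=b.protein_start,
                PepSeq2=b.sequence,
                LinkPos2=b.crosslink_site,
                AbsPos2=b.protein_start + b.crosslink_site - 1,
                Score=round(xl.score, 4),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "Protein1", "PepPos1", "PepSeq1", "LinkPos1", "AbsPos1",
            "Protein2", "PepPos2", "PepSeq2", "LinkPos2", "AbsPos2", "Score",
        ],
    )
    df.to_csv(path, index=False)
    return len(df)


def write_results(result: SearchResult, outdir: str | Path) -> dict[str, Path]:
    """Write CSM/cross-link TSVs, the xiVIEW CSV, and a JSON run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "csms": outdir / "csms.tsv",
        "crosslinks": outdir / "crosslinks.tsv",
        "xiview": outdir / "crosslinks_xiview.csv",
        "summary": outdir / "summary.json",
    }
    csm_table(result.csm_fdr.accepted).to_csv(paths["csms"], sep="\t", index=False)
    crosslink_table(result.crosslinks).to_csv(paths["crosslinks"], sep="\t", index=False)
    export_xiview(result.crosslinks, paths["xiview"])
    summary = {
        "stage_counts": result.stage_counts,
        "csm_fdr": {
            "threshold": result.csm_fdr.threshold_score,
            "estimated_fdr": result.csm_fdr.estimated_fdr,
            "accepted": len(result.csm_fdr.accepted),
        },
        "crosslink_fdr": {
            "threshold": result.crosslink_fdr.threshold_score,
            "estimated_fdr": result.crosslink_fdr.estimated_fdr,
            "accepted": len(result.crosslinks),
        },
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return paths
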