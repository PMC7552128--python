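"""End-to-end selection-signature scan: simulate/QC/Fst/di/windows/annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotate as _annotate
from .di import (
    CandidateRegion,
    DiTable,
    TopSnps,
    compute_di,
    make_windows,
    select_top,
    standardize_pairs,
)
from .fst import FstMatrix, PairFstTable, all_pairs_fst, multilocus_fst
from .panel import GenotypePanel
from .qc import QCConfig, QCReport, apply_qc


@dataclass
class ScanResult:
    """Everything one scan produces, from QC accounting to candidate genes."""

    panel: GenotypePanel
    qc_report: QCReport
    fst_table: PairFstTable = field(repr=False)
    fst_matrix: FstMatrix
    di_table: DiTable
    top_snps: TopSnps
    regions: list[CandidateRegion]
    candidate_genes: pd.DataFrame | None = None


def run_scan(
    panel: GenotypePanel,
    focal_breed: str,
    qc_config: QCConfig | None = None,
    top_fraction: float = 0.01,
    flank_bp: int = 50_000,
    genes: list[_annotate.GeneModel] | None = None,
    hwe_mode: str = "pooled",
) -> ScanResult:
    """QC-filter a panel, scan it with di for ``focal_breed``, annotate genes.

    Returns a :class:`ScanResult`; ``candidate_genes`` is ``None`` when no
    gene table is supplied, otherwise the full report with the symbol-filter
    flag set.
    """
    filtered, report = apply_qc(panel, qc_config, hwe_mode=hwe_mode)
    table = all_pairs_fst(filtered)
    matrix = multilocus_fst(table)
    std = standardize_pairs(table)
    di = compute_di(table, std, focal_breed)
    top = select_top(di, top_fraction)
    regions = make_windows(top, flank_bp)
    gene_frame = None
    if genes is not None:
        hits = _annotate.overlap_genes(regions, genes)
        _annotate.filter_symbols(hits)
        gene_frame = _annotate.candidates_to_frame(hits)
    return ScanResult(
        panel=filtered,
        qc_report=report,
        fst_table=table,
        fst_matrix=matrix,
        di_table=di,
        top_snps=top,
        regions=regions,
        candidate_genes=gene_frame,
    )
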