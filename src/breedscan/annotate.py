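"""Candidate-region gene annotation: load gene models, intersect, filter symbols.

Gene coordinates come from GFF3 (``gene``-type rows via gffutils), BED
(0-based half-open, converted) or a plain TSV.  A gene is a candidate when
its body overlaps a candidate region by at least 1 bp; overlap is computed
with an interval tree per chromosome, strand is ignored.  The symbol filter
drops uncharacterized models: absent symbols, symbols equal to the raw gene
id, and provisional ``LOC<digits>`` identifiers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .di import CandidateRegion

_LOC_PATTERN = re.compile(r"^LOC\d+$")

TSV_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


@dataclass
class GeneModel:
    """One gene with 1-based inclusive coordinates."""

    gene_id: str
    symbol: str | None
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start {self.start} < 1")


@dataclass
class CandidateGene:
    """A gene overlapping a candidate region, tagged with the region's best SNP."""

    gene: GeneModel
    region_id: str
    top_snp_id: str
    top_snp_di: float
    passes_symbol_filter: bool = True


def _load_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        symbol = None
        for key in ("Name", "gene_name", "gene"):
            if key in feat.attributes:
                symbol = feat.attributes[key][0]
                break
        gene_id = feat.id
        if "ID" in feat.attributes:
            gene_id = feat.attributes["ID"][0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                chrom=str(feat.seqid),
                start=int(feat.start),  # gffutils keeps GFF3's 1-based incl.
                end=int(feat.end),
                strand=feat.strand or ".",
            )
        )
    return genes


def _load_bed(path: str) -> list[GeneModel]:
    rows = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        dtype=str,
    )
    if rows.shape[1] < 4:
        raise ValueError(f"{path}: BED needs >= 4 columns (chrom start end name)")
    genes = []
    for i, row in enumerate(rows.itertuples(index=False), 1):
        try:
            start0, end = int(row[1]), int(row[2])
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: non-integer coordinate") from exc
        strand = row[5] if rows.shape[1] >= 6 else "."
        # BED has a single name column: treat it as the symbol and derive a
        # coordinate id, so the symbol filter judges the name, not the id
        genes.append(
            GeneModel(
                gene_id=f"{row[0]}:{start0 + 1}-{end}",
                symbol=str(row[3]),
                chrom=str(row[0]),
                start=start0 + 1,  # BED is 0-based half-open
                end=end,
                strand=strand,
            )
        )
    return genes


def _load_tsv(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: TSV missing columns {missing}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), 2):  # 1 header line
        symbol = getattr(row, "symbol", None)
        if pd.isna(symbol):
            symbol = None
        try:
            genes.append(
                GeneModel(
                    gene_id=str(row.gene_id),
                    symbol=None if symbol is None else str(symbol),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(getattr(row, "strand", ".")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return genes


def load_genes(path: str, format: str | None = None) -> list[GeneModel]:
    """Load gene models from GFF3, BED or TSV with normalized coordinates.

    ``format`` is inferred from the file extension when omitted.  All
    returned coordinates are 1-based inclusive.  An empty gene set raises.
    """
    if format is None:
        suffix = Path(path).suffix.lower().lstrip(".")
        format = {"gff": "gff3", "gff3": "gff3", "bed": "bed", "tsv": "tsv"}.get(
            suffix
        )
        if format is None:
            raise ValueError(f"cannot infer gene-table format from {path!r}")
    loaders = {"gff3": _load_gff3, "bed": _load_bed, "tsv": _load_tsv}
    if format not in loaders:
        raise ValueError(f"unknown gene-table format: {format!r}")
    genes = loaders[format](path)
    if not genes:
        raise ValueError(f"no gene records found in {path}")
    return genes


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes
        ],
        columns=TSV_COLUMNS,
    )


def overlap_genes(
    regions: list[CandidateRegion],
    genes: list[GeneModel],
    chrom_aliases: dict[str, str] | None = None,
) -> list[CandidateGene]:
    """Genes whose body overlaps a candidate region by >= 1 bp.

    ``chrom_aliases`` maps gene-table chromosome names onto the panel's
    naming (e.g. ``{"chr1": "1"}``) before intersection.  Each hit carries
    the region's maximal-di member SNP.  An empty result is allowed.
    """
    alias = chrom_aliases or {}
    trees: dict[str, IntervalTree] = {}
    region_ids: dict[int, str] = {}
    for k, r in enumerate(regions):
        region_ids[k] = f"{r.focal_breed}_region{k + 1}"
        # interval tree uses half-open ends; +1 converts 1-based inclusive
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, k)
    hits = []
    for g in genes:
        chrom = alias.get(g.chrom, g.chrom)
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(g.start, g.end + 1)):
            r = regions[iv.data]
            snp_id, _, snp_di = r.top_snp
            hits.append(
                CandidateGene(
                    gene=g,
                    region_id=region_ids[iv.data],
                    top_snp_id=snp_id,
                    top_snp_di=snp_di,
                )
            )
    return hits


def filter_symbols(
    candidates: list[CandidateGene],
) -> tuple[list[CandidateGene], list[CandidateGene]]:
    """Split candidates into named genes and uncharacterized models.

    Excluded: absent/empty symbol, symbol identical to the gene id, or a
    provisional ``LOC<digits>`` symbol.  Flags are set on the returned
    objects; the two lists partition the input.
    """
    kept, excluded = [], []
    for c in candidates:
        sym = c.gene.symbol
        ok = bool(sym) and sym != c.gene.gene_id and not _LOC_PATTERN.match(sym)
        c.passes_symbol_filter = ok
        (kept if ok else excluded).append(c)
    return kept, excluded


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    """TSV-ready candidate-gene report."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene.gene_id,
                "symbol": c.gene.symbol,
                "chrom": c.gene.chrom,
                "start": c.gene.start,
                "end": c.gene.end,
                "region_id": c.region_id,
                "top_snp": c.top_snp_id,
                "di": c.top_snp_di,
                "kept": c.passes_symbol_filter,
            }
            for c in candidates
        ],
        columns=[
            "gene_id",
            "symbol",
            "chrom",
            "start",
            "end",
            "region_id",
            "top_snp",
            "di",
            "kept",
        ],
    )
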