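"""Breed-specific di statistic: standardized pairwise Fst, outlier SNPs, windows.

For a focal breed ``i`` the statistic at one SNP is

    di = sum_{j != i} (Fst_ij - E[Fst_ij]) / sd[Fst_ij]

where the mean and standard deviation of each pair's Fst are taken over all
analyzed SNPs — here, the set of SNPs with a defined estimate in *every*
pair, so that each di sums the same number of comparable z-scores.  Large di
flags loci unusually diverged in the focal breed relative to the genome-wide
drift background.  Candidate regions are +/- ``flank_bp`` windows around
top-quantile SNPs, merged when they touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import PairFstTable


@dataclass
class PairStandardization:
    """Per-pair mean and sample sd of Fst over the common analyzed SNP set."""

    stats: dict[tuple[str, str], tuple[float, float]]
    snp_mask: np.ndarray = field(repr=False)  # SNPs defined in all pairs

    @property
    def n_snps(self) -> int:
        return int(self.snp_mask.sum())


@dataclass
class DiTable:
    """Per-SNP di values for one focal breed.

    ``frame`` columns: chrom, pos, snp_id, di — restricted to the SNPs
    standardization covers; ``n_omitted`` counts SNPs dropped because some
    pair had no defined estimate there.
    """

    focal_breed: str
    frame: pd.DataFrame = field(repr=False)
    n_omitted: int = 0

    def to_tsv(self, path: str) -> str:
        out = self.frame.copy()
        out.insert(3, "focal_breed", self.focal_breed)
        out.to_csv(path, sep="\t", index=False)
        return path


@dataclass
class TopSnps:
    """Top-quantile di SNPs with the threshold that selected them."""

    focal_breed: str
    fraction: float
    threshold: float
    frame: pd.DataFrame = field(repr=False)


@dataclass
class CandidateRegion:
    """Merged candidate window around one or more top-di SNPs (1-based incl.)."""

    chrom: str
    start: int
    end: int
    focal_breed: str
    snps: list[tuple[str, int, float]]  # (snp_id, pos, di)

    @property
    def max_di(self) -> float:
        return max(d for _, _, d in self.snps)

    @property
    def top_snp(self) -> tuple[str, int, float]:
        return max(self.snps, key=lambda t: t[2])


def standardize_pairs(table: PairFstTable) -> PairStandardization:
    """Mean and sample (n-1) sd of each pair's Fst over the common SNP set.

    The common set contains the SNPs with a defined estimate in every pair,
    so the constants entering di for any focal breed are computed on one
    shared genome-wide SNP panel.  Raises if any pair's sd is zero.
    """
    mask = table.common_defined()
    if mask.sum() < 2:
        raise ValueError("fewer than 2 SNPs defined in all pairs")
    stats = {}
    for pair, df in table.pairs.items():
        v = df["fst"].to_numpy()[mask]
        sd = float(np.std(v, ddof=1))
        if sd == 0.0:
            raise ValueError(f"pair {pair} has zero Fst variance")
        stats[pair] = (float(v.mean()), sd)
    return PairStandardization(stats=stats, snp_mask=mask)


def compute_di(
    table: PairFstTable, std: PairStandardization, focal_breed: str
) -> DiTable:
    """Sum of standardized Fst over all pairs containing the focal breed."""
    focal_pairs = [p for p in table.pairs if focal_breed in p]
    if not focal_pairs:
        raise KeyError(f"focal breed {focal_breed!r} absent from the Fst table")
    for p in focal_pairs:
        if p not in std.stats:
            raise KeyError(f"standardization missing pair {p}")
    mask = std.snp_mask
    di = np.zeros(int(mask.sum()))
    for p in focal_pairs:
        mean, sd = std.stats[p]
        di += (table.pairs[p]["fst"].to_numpy()[mask] - mean) / sd
    frame = table.snp_map.loc[mask, ["chrom", "pos", "snp_id"]].reset_index(
        drop=True
    )
    frame["di"] = di
    return DiTable(
        focal_breed=focal_breed,
        frame=frame,
        n_omitted=int((~mask).sum()),
    )


def compute_di_all(
    table: PairFstTable, std: PairStandardization | None = None
) -> dict[str, DiTable]:
    """di tables for every breed taken as focal in turn."""
    if std is None:
        std = standardize_pairs(table)
    return {b: compute_di(table, std, b) for b in table.breeds}


def select_top(di: DiTable, fraction: float = 0.01) -> TopSnps:
    """SNPs at or above the empirical (1 - fraction) di quantile.

    Ties at the threshold are included, so the returned set may slightly
    exceed the nominal fraction.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if len(di.frame) == 0:
        raise ValueError("empty di table")
    values = di.frame["di"].to_numpy()
    threshold = float(np.quantile(values, 1.0 - fraction))
    top = di.frame[values >= threshold].reset_index(drop=True)
    return TopSnps(
        focal_breed=di.focal_breed,
        fraction=fraction,
        threshold=threshold,
        frame=top,
    )


def make_windows(top: TopSnps, flank_bp: int = 50_000) -> list[CandidateRegion]:
    """+/- ``flank_bp`` windows around top SNPs, merged per chromosome.

    Windows are 1-based inclusive, clipped at position 1, and merged when
    they overlap or are book-ended (previous end + 1 == next start).
    """
    regions: list[CandidateRegion] = []
    frame = top.frame.sort_values(["chrom", "pos"], kind="stable")
    for chrom, grp in frame.groupby("chrom", sort=False):
        current: CandidateRegion | None = None
        for row in grp.itertuples(index=False):
            start = max(1, int(row.pos) - flank_bp)
            end = int(row.pos) + flank_bp
            snp = (row.snp_id, int(row.pos), float(row.di))
            if current is not None and start <= current.end + 1:
                current.end = max(current.end, end)
                current.snps.append(snp)
            else:
                current = CandidateRegion(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    focal_breed=top.focal_breed,
                    snps=[snp],
                )
                regions.append(current)
    return regions


def regions_to_frame(regions: list[CandidateRegion], bed: bool = False) -> pd.DataFrame:
    """Tabulate regions; ``bed=True`` emits 0-based half-open starts."""
    rows = []
    for k, r in enumerate(regions, 1):
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start - 1 if bed else r.start,
                "end": r.end,
                "region_id": f"{r.focal_breed}_region{k}",
                "n_snps": len(r.snps),
                "max_di": r.max_di,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "region_id", "n_snps", "max_di"]
    )
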