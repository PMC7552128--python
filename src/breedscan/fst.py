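"""Locus-specific pairwise Fst by the variance-components (mean-square) estimator.

For one SNP and one pair of populations, genotypes are unrolled into allele
indicator observations (two per diploid individual) and subjected to a
one-way ANOVA.  With ``s = 2`` groups of allele-sample sizes ``m_i``
(twice the non-missing individuals), sample frequencies ``p_i`` and the
weighted overall frequency ``p_bar``:

    MSP = sum_i m_i (p_i - p_bar)^2 / (s - 1)        between-population mean square
    MSG = sum_i m_i p_i (1 - p_i)  / sum_i (m_i - 1) within-population mean square
    n_c = (M - sum_i m_i^2 / M) / (s - 1),  M = sum_i m_i

    Fst = (MSP - MSG) / (MSP + (n_c - 1) MSG)

The estimate is at most 1, equals 1 exactly at a fixed difference
(``MSG = 0, MSP > 0``), may be negative at low differentiation, and is
undefined only when both mean squares vanish (both populations monomorphic
for the same allele).  Negative estimates are retained — downstream
standardization needs the unclipped sampling distribution.

Multi-locus pair estimates combine loci as a ratio of sums,
``sum(MSP - MSG) / sum(MSP + (n_c - 1) MSG)``, the stable weighting for
variance-components estimators; the linearized transform ``Fst/(1-Fst)``
and per-breed mean pairwise values reproduce the standard between-breed
differentiation summary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

PAIR_COMPONENT_COLUMNS = ["msg", "msp", "nc", "fst", "defined", "n_i", "n_j"]


@dataclass
class FstComponents:
    """Mean-square decomposition of one SNP's pairwise Fst."""

    msg: float
    msp: float
    nc: float
    fst: float
    defined: bool
    reason: str | None = None


@dataclass
class PairFstTable:
    """Per-SNP Fst components for every unordered breed pair of a panel.

    ``pairs`` maps a canonically sorted ``(breed_i, breed_j)`` tuple to a
    DataFrame aligned row-for-row with ``snp_map``, holding the columns
    ``msg, msp, nc, fst, defined, n_i, n_j`` (sample sizes are non-missing
    individuals; ``n_i`` belongs to the first breed of the sorted pair).
    """

    snp_map: pd.DataFrame = field(repr=False)
    pairs: dict[tuple[str, str], pd.DataFrame] = field(repr=False)

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return sorted(seen)

    @property
    def pair_names(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    def fst_frame(self) -> pd.DataFrame:
        """Wide per-SNP Fst values, one column per pair (NaN where undefined)."""
        out = {}
        for pair, df in sorted(self.pairs.items()):
            vals = df["fst"].to_numpy(copy=True)
            vals[~df["defined"].to_numpy()] = np.nan
            out["__".join(pair)] = vals
        return pd.DataFrame(out, index=self.snp_map.index)

    def common_defined(self) -> np.ndarray:
        """Boolean mask of SNPs with a defined estimate in every pair."""
        mask = np.ones(len(self.snp_map), dtype=bool)
        for df in self.pairs.values():
            mask &= df["defined"].to_numpy()
        return mask

    def to_tsv(self, path: str) -> str:
        """Long-format TSV: chrom, pos, snp_id, pair, msg, msp, nc, fst, defined."""
        blocks = []
        for pair, df in sorted(self.pairs.items()):
            block = pd.concat(
                [self.snp_map[["chrom", "pos", "snp_id"]], df], axis=1
            )
            block.insert(3, "pair", "__".join(pair))
            blocks.append(block)
        pd.concat(blocks, ignore_index=True).to_csv(path, sep="\t", index=False)
        return path


@dataclass
class FstMatrix:
    """Multi-locus pairwise Fst between breeds, raw and linearized.

    ``linearized`` holds Fst/(1-Fst); a fixed-difference pair (Fst = 1)
    linearizes to +inf and is flagged in ``saturated_pairs``.
    ``mean_pairwise`` is, per breed, the arithmetic mean of its off-diagonal
    linearized entries.
    """

    breeds: list[str]
    raw: pd.DataFrame = field(repr=False)
    linearized: pd.DataFrame = field(repr=False)
    mean_pairwise: pd.Series = field(repr=False)
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_linearized(
        cls, values: dict[tuple[str, str], float]
    ) -> "FstMatrix":
        """Build a matrix directly from linearized pairwise values.

        Useful for working with published Fst/(1-Fst) tables when the
        underlying genotypes are unavailable.
        """
        breeds = sorted({b for pair in values for b in pair})
        lin = pd.DataFrame(0.0, index=breeds, columns=breeds)
        for (a, b), v in values.items():
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) not allowed")
            lin.loc[a, b] = lin.loc[b, a] = v
        for a, b in itertools.combinations(breeds, 2):
            if (a, b) not in values and (b, a) not in values:
                raise ValueError(f"missing pairwise value for ({a}, {b})")
        raw = lin / (1.0 + lin)
        mean = pd.Series(
            {
                b: lin.loc[b, [c for c in breeds if c != b]].mean()
                for b in breeds
            }
        )
        return cls(breeds, raw, lin, mean)


def _pair_components(
    g_i: np.ndarray, g_j: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Vectorized mean squares for a breed pair over all SNP columns.

    ``g_i``/``g_j``: (samples, snps) genotype blocks of the two breeds.
    Returns (msg, msp, nc, fst, defined, n_i, n_j) arrays.
    """
    out = []
    ms = []
    for g in (g_i, g_j):
        called = g != MISSING
        n = called.sum(axis=0)  # non-missing individuals
        copies = np.where(called, g, 0).sum(axis=0)
        m = 2.0 * n  # allele observations
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(m > 0, copies / m, np.nan)
        out.append((n, m, p))
        ms.append(m)
    (n_i, m_i, p_i), (n_j, m_j, p_j) = out
    defined = (n_i >= 2) & (n_j >= 2)
    M = m_i + m_j
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (m_i * p_i + m_j * p_j) / M
        msp = m_i * (p_i - p_bar) ** 2 + m_j * (p_j - p_bar) ** 2  # / (s-1)=1
        msg = (m_i * p_i * (1 - p_i) + m_j * p_j * (1 - p_j)) / (
            (m_i - 1) + (m_j - 1)
        )
        nc = M - (m_i**2 + m_j**2) / M  # / (s-1)=1
        denom = msp + (nc - 1.0) * msg
        fst = np.where(denom > 0, (msp - msg) / np.where(denom > 0, denom, 1.0), np.nan)
    defined = defined & np.isfinite(fst)
    return msg, msp, nc, fst, defined, n_i, n_j


def snp_pair_fst(
    genotypes_pop_i: np.ndarray, genotypes_pop_j: np.ndarray
) -> FstComponents:
    """Mean-square Fst components for a single SNP and one population pair.

    Inputs are 1-D genotype vectors (0/1/2 copies, ``MISSING`` allowed).
    Requires at least two non-missing genotypes per population; otherwise
    the result is undefined with a reason.
    """
    g_i = np.asarray(genotypes_pop_i).reshape(-1, 1)
    g_j = np.asarray(genotypes_pop_j).reshape(-1, 1)
    msg, msp, nc, fst, defined, n_i, n_j = _pair_components(g_i, g_j)
    reason = None
    if n_i[0] < 2 or n_j[0] < 2:
        reason = (
            f"population with < 2 non-missing genotypes (n_i={n_i[0]}, n_j={n_j[0]})"
        )
    elif not defined[0]:
        reason = "both mean squares zero (monomorphic in both populations)"
    return FstComponents(
        msg=float(msg[0]),
        msp=float(msp[0]),
        nc=float(nc[0]),
        fst=float(fst[0]) if defined[0] else math.nan,
        defined=bool(defined[0]),
        reason=reason,
    )


def all_pairs_fst(panel: GenotypePanel) -> PairFstTable:
    """Per-SNP Fst components for every unordered breed pair.

    Missing genotypes are dropped per SNP and per pair (complete-case allele
    counts, no imputation).  Every breed must have at least two samples.
    """
    breeds = panel.breed_names
    if len(breeds) < 2:
        raise ValueError("need at least 2 breeds for pairwise Fst")
    for b in breeds:
        if panel.breed_rows(b).size < 2:
            raise ValueError(f"breed {b!r} has < 2 samples")
    blocks = {b: panel.genotypes[panel.breed_rows(b)] for b in breeds}
    pairs: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in itertools.combinations(sorted(breeds), 2):
        msg, msp, nc, fst, defined, n_i, n_j = _pair_components(
            blocks[a], blocks[b]
        )
        pairs[(a, b)] = pd.DataFrame(
            {
                "msg": msg,
                "msp": msp,
                "nc": nc,
                "fst": fst,
                "defined": defined,
                "n_i": n_i,
                "n_j": n_j,
            }
        )
    return PairFstTable(snp_map=panel.snp_map, pairs=pairs)


def multilocus_fst(table: PairFstTable) -> FstMatrix:
    """Multi-locus pairwise Fst matrix by ratio of sums over defined SNPs."""
    breeds = table.breeds
    raw = pd.DataFrame(0.0, index=breeds, columns=breeds)
    lin = pd.DataFrame(0.0, index=breeds, columns=breeds)
    saturated = []
    for (a, b), df in table.pairs.items():
        ok = df["defined"].to_numpy()
        if not ok.any():
            raise ValueError(f"pair ({a}, {b}) has no defined SNPs")
        msp = df["msp"].to_numpy()[ok]
        msg = df["msg"].to_numpy()[ok]
        nc = df["nc"].to_numpy()[ok]
        num = (msp - msg).sum()
        den = (msp + (nc - 1.0) * msg).sum()
        f = num / den
        raw.loc[a, b] = raw.loc[b, a] = f
        if f >= 1.0:
            lin.loc[a, b] = lin.loc[b, a] = np.inf
            saturated.append((a, b))
        else:
            lin.loc[a, b] = lin.loc[b, a] = f / (1.0 - f)
    mean = pd.Series(
        {b: lin.loc[b, [c for c in breeds if c != b]].mean() for b in breeds}
    )
    return FstMatrix(breeds, raw, lin, mean, saturated)


def breed_mean_pairwise(matrix: FstMatrix, breed: str) -> tuple[float, float]:
    """Mean of a breed's linearized pairwise entries: (unrounded, 3-decimal)."""
    if breed not in matrix.breeds:
        raise KeyError(f"unknown breed label: {breed!r}")
    v = float(matrix.mean_pairwise[breed])
    return v, round(v, 3)


def matrix_extremes(
    matrix: FstMatrix,
) -> tuple[tuple[tuple[str, str], float], tuple[tuple[str, str], float]]:
    """Smallest and largest off-diagonal linearized entries with their pairs."""
    best_min = best_max = None
    for a, b in itertools.combinations(matrix.breeds, 2):
        v = float(matrix.linearized.loc[a, b])
        if best_min is None or v < best_min[1]:
            best_min = ((a, b), v)
        if best_max is None or v > best_max[1]:
            best_max = ((a, b), v)
    assert best_min is not None and best_max is not None
    return best_min, best_max


def write_matrix_tsv(matrix: FstMatrix, prefix: str) -> list[str]:
    """Write raw, linearized and breed-mean tables as TSV files."""
    paths = []
    for name, obj in (
        ("raw", matrix.raw),
        ("linearized", matrix.linearized),
        ("breed_means", matrix.mean_pairwise.rename("mean_pairwise_fst")),
    ):
        path = f"{prefix}.{name}.tsv"
        obj.to_csv(path, sep="\t")
        paths.append(path)
    return paths
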