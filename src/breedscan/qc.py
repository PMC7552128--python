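"""SNP quality control: autosome, call-rate, MAF and exact HWE filters.

Filters are applied in a fixed order — autosomal/mapped, call rate, minor
allele frequency, Hardy-Weinberg — each acting on the survivors of the
previous one, so the per-criterion removal counts in the report add up
exactly to the input SNP count.  Thresholds follow the strict-inequality
reading of standard chip QC: a SNP passes with call rate > ``call_rate_min``
and MAF > ``maf_min``, and is removed when the HWE p-value is strictly below
``hwe_p_min``.

The HWE test is Levene's exact conditional test: conditioning on the
observed allele counts, the heterozygote count has a known distribution and
the two-sided p-value sums the probabilities of all heterozygote
configurations no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, GenotypePanel

# relative slack when comparing configuration probabilities in log space,
# so exact ties are counted into the tail
_TIE_EPS = 1e-9


@dataclass
class QCConfig:
    """Thresholds of the four SNP filters.

    ``autosomes`` is the set of chromosome identifiers accepted as mapped
    autosomal; ``None`` accepts chromosomes named "1".."n" for any n (i.e.
    purely numeric labels).
    """

    hwe_p_min: float = 1e-4
    call_rate_min: float = 0.95
    maf_min: float = 0.05
    autosomes: set[str] | None = None

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Accounting of a QC pass.

    ``removed`` maps each criterion (in application order) to the number of
    SNPs it removed from the survivors of the previous filter; ``per_snp``
    has one row per input SNP with its metrics and failure reasons.
    """

    n_input: int
    removed: dict[str, int]
    n_retained: int
    n_samples: int
    per_snp: pd.DataFrame = field(repr=False)
    warnings: list[str] = field(default_factory=list)

    def reconciles(self) -> bool:
        return sum(self.removed.values()) + self.n_retained == self.n_input

    def to_tsv(self, path: str) -> str:
        self.per_snp.to_csv(path, sep="\t", index=False)
        return path


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value (Levene's conditional test).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration whose probability does not exceed the
    observed configuration's.  Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotype calls: all counts zero")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = (max(n_A, n_a) - hets) // 2
    # log P(het=h | allele counts) up to the shared normalizing constant:
    #   n! / (nAA! h! naa!) * 2^h   (times nA! na!/(2n)!, constant in h)
    logp = (
        hets * np.log(2.0)
        - gammaln(homs_rare + 1)
        - gammaln(hets + 1)
        - gammaln(homs_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_Aa)[0]]
    p = probs[probs <= obs * (1.0 + _TIE_EPS)].sum()
    return float(min(p, 1.0))


def snp_call_rate(genotypes: np.ndarray) -> float:
    """Fraction of non-missing calls in one SNP column."""
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("empty genotype column")
    return float((g != MISSING).sum() / g.size)


def snp_maf(genotypes: np.ndarray) -> float:
    """Minor allele frequency (folded to [0, 0.5]) of one SNP column."""
    g = np.asarray(genotypes)
    called = g[g != MISSING]
    if called.size == 0:
        raise ValueError("cannot compute MAF: all calls missing")
    p = called.sum() / (2.0 * called.size)
    return float(min(p, 1.0 - p))


def _column_stats(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP call rate and MAF."""
    g = panel.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / g.shape[0]
    copies = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, copies / (2.0 * n_called), np.nan)
    maf = np.minimum(p, 1.0 - p)
    return call_rate, maf


def _hwe_pvalues(panel: GenotypePanel, rows: np.ndarray | None = None) -> np.ndarray:
    """Exact HWE p per SNP over the given sample rows (default: all)."""
    g = panel.genotypes if rows is None else panel.genotypes[rows]
    n_AA = (g == 2).sum(axis=0)
    n_Aa = (g == 1).sum(axis=0)
    n_aa = (g == 0).sum(axis=0)
    out = np.ones(g.shape[1])
    for j in range(g.shape[1]):
        tot = n_AA[j] + n_Aa[j] + n_aa[j]
        out[j] = np.nan if tot == 0 else hwe_exact_test(n_AA[j], n_Aa[j], n_aa[j])
    return out


def _is_autosomal(chroms: pd.Series, autosomes: set[str] | None) -> np.ndarray:
    if autosomes is not None:
        return chroms.isin({str(c) for c in autosomes}).to_numpy()
    return chroms.astype(str).str.fullmatch(r"[1-9][0-9]*").to_numpy()


def apply_qc(
    panel: GenotypePanel,
    config: QCConfig | None = None,
    hwe_mode: str = "pooled",
) -> tuple[GenotypePanel, QCReport]:
    """Filter a panel and return the surviving SNPs plus an accounting report.

    ``hwe_mode="pooled"`` tests Hardy-Weinberg on all samples together
    (single-pass chip QC); ``"per-breed"`` tests within each breed and
    removes a SNP if any breed's p-value falls below the threshold — the
    pooled test can reject strongly differentiated loci purely through the
    Wahlund effect, which the per-breed mode avoids.

    A panel in which no SNP survives is returned empty with a warning in the
    report rather than raising.
    """
    if config is None:
        config = QCConfig()
    if hwe_mode not in ("pooled", "per-breed"):
        raise ValueError(f"unknown hwe_mode: {hwe_mode!r}")

    call_rate, maf = _column_stats(panel)
    autosomal = _is_autosomal(panel.snp_map["chrom"], config.autosomes)

    alive = np.ones(panel.n_snps, dtype=bool)
    removed: dict[str, int] = {}
    reasons: list[list[str]] = [[] for _ in range(panel.n_snps)]

    def _apply(name: str, fails: np.ndarray) -> None:
        kill = alive & fails
        removed[name] = int(kill.sum())
        for j in np.flatnonzero(kill):
            reasons[j].append(name)
        alive[kill] = False

    _apply("non_autosomal", ~autosomal)
    _apply("call_rate", ~(call_rate > config.call_rate_min))
    with np.errstate(invalid="ignore"):
        _apply("maf", ~(maf > config.maf_min))

    # HWE only on survivors (all have calls after the call-rate filter)
    hwe_p = np.full(panel.n_snps, np.nan)
    surv = np.flatnonzero(alive)
    if surv.size:
        sub = panel.subset_snps(surv)
        if hwe_mode == "pooled":
            hwe_p[surv] = _hwe_pvalues(sub)
        else:
            per_breed = np.stack(
                [_hwe_pvalues(sub, sub.breed_rows(b)) for b in sub.breed_names]
            )
            hwe_p[surv] = np.nanmin(per_breed, axis=0)
    _apply("hwe", np.nan_to_num(hwe_p, nan=1.0) < config.hwe_p_min)

    per_snp = pd.DataFrame(
        {
            "snp_id": panel.snp_map["snp_id"],
            "chrom": panel.snp_map["chrom"],
            "pos": panel.snp_map["pos"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "passed": alive,
            "fail_reasons": [";".join(r) for r in reasons],
        }
    )
    warnings = []
    if not alive.any():
        warnings.append("no SNPs survived quality control")
    report = QCReport(
        n_input=panel.n_snps,
        removed=removed,
        n_retained=int(alive.sum()),
        n_samples=panel.n_samples,
        per_snp=per_snp,
        warnings=warnings,
    )
    return panel.subset_snps(alive), report
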