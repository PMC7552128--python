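"""Synthetic multi-population SNP panels under the Balding-Nichols model.

The generator emulates a medium-density SNP chip typed on a handful of
livestock breeds: for each locus an ancestral allele frequency ``p`` is drawn,
and each population's frequency is drawn from
``Beta(p (1-F)/F, (1-p)(1-F)/F)`` where ``F`` is that population's
divergence parameter (the expected Fst to the ancestral pool).  A small set
of "planted" loci receives an elevated ``F`` in one focal (highland)
population, mimicking localized directional selection on an otherwise
exchangeable drift background.  Genotypes are binomial draws of two allele
copies; missing calls are injected independently per genotype.

The defaults mirror the study design this testbed stands in for: four breeds
of 16-17 females each on 29 autosomes, with one strongly diverged highland
breed; 10,000 SNPs for desk-scale runs (use :meth:`SimConfig.chip_scale` for
a full ~50K panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

_NUCS = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    """Parameters of the Balding-Nichols panel generator.

    ``baseline_F`` holds one divergence parameter per population (each in
    (0, 1)); ``selected_F`` replaces the focal population's F at the
    ``n_selected`` planted loci and must exceed every baseline value so the
    planted loci are genuinely outliers.
    """

    n_pops: int = 4
    samples_per_pop: list[int] = field(default_factory=lambda: [17, 17, 16, 16])
    n_snps: int = 10_000
    n_chromosomes: int = 29
    chrom_length_bp: int = 100_000_000
    baseline_F: list[float] = field(default_factory=lambda: [0.05] * 4)
    n_selected: int = 20
    selected_F: float = 0.5
    focal_pop: int = 0
    missing_rate: float = 0.01
    ancestral_maf_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError(
                f"samples_per_pop has {len(self.samples_per_pop)} entries "
                f"for n_pops={self.n_pops}"
            )
        if len(self.baseline_F) != self.n_pops:
            raise ValueError("baseline_F must have one entry per population")
        for f in [*self.baseline_F, self.selected_F]:
            if not 0.0 < f < 1.0:
                raise ValueError(
                    f"divergence parameter F={f} outside (0, 1): "
                    "Beta parameters would be degenerate"
                )
        if self.selected_F <= max(self.baseline_F):
            raise ValueError("selected_F must exceed every baseline_F")
        if not 0 <= self.n_selected <= self.n_snps:
            raise ValueError("n_selected must lie in [0, n_snps]")
        if not 0 <= self.focal_pop < self.n_pops:
            raise ValueError("focal_pop out of range")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo < hi < 1")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        if self.chrom_length_bp < self.n_snps:
            raise ValueError("chromosome too short for distinct positions")

    def chip_scale(self) -> "SimConfig":
        """The same design at full chip density (~53K loci)."""
        return replace(self, n_snps=53_347)


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, pd.DataFrame]:
    """Simulate a genotype panel and its truth table.

    Returns the panel plus a truth table with one row per SNP:
    ``snp_id, chrom, pos, selected`` and the realized population allele
    frequency ``freq_<breed>`` for every breed (the frequency genotypes were
    drawn from, i.e. the expected sample frequency).  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    S, P = config.n_snps, config.n_pops
    breed_names = [f"POP{k + 1}" for k in range(P)]

    # map: spread SNPs over chromosomes, positions uniform w/o replacement
    per_chrom = np.full(config.n_chromosomes, S // config.n_chromosomes)
    per_chrom[: S % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c, k in enumerate(per_chrom, start=1):
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=k, replace=False) + 1
        )
        chroms.extend([str(c)] * k)
        positions.append(pos)
    positions = np.concatenate(positions)

    allele_pairs = np.stack(
        [rng.permutation(4)[:2] for _ in range(S)]
    )  # two distinct nucleotides per SNP
    allele_pairs.sort(axis=1)  # allele_a < allele_b lexicographically
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(S)],
            "chrom": chroms,
            "pos": positions.astype(int),
            "allele_a": _NUCS[allele_pairs[:, 0]],
            "allele_b": _NUCS[allele_pairs[:, 1]],
        }
    )

    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=S)
    selected_idx = np.sort(rng.choice(S, size=config.n_selected, replace=False))
    is_selected = np.zeros(S, dtype=bool)
    is_selected[selected_idx] = True

    # population frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F)
    pop_freq = np.empty((P, S))
    for k in range(P):
        F = np.full(S, config.baseline_F[k])
        if k == config.focal_pop:
            F[is_selected] = config.selected_F
        ratio = (1.0 - F) / F
        pop_freq[k] = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)

    geno = np.empty((sum(config.samples_per_pop), S), dtype=np.int8)
    sample_ids, breeds = [], []
    row = 0
    for k, n_k in enumerate(config.samples_per_pop):
        geno[row : row + n_k] = rng.binomial(2, pop_freq[k], size=(n_k, S))
        sample_ids.extend(f"{breed_names[k]}_{i + 1}" for i in range(n_k))
        breeds.extend([breed_names[k]] * n_k)
        row += n_k
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING

    truth = pd.DataFrame(
        {
            "snp_id": snp_map["snp_id"],
            "chrom": snp_map["chrom"],
            "pos": snp_map["pos"],
            "selected": is_selected,
            "freq_ancestral": p_anc,
        }
    )
    for k, name in enumerate(breed_names):
        truth[f"freq_{name}"] = pop_freq[k]

    panel = GenotypePanel(geno, sample_ids, breeds, snp_map)
    return panel, truth


def write_truth_table(truth: pd.DataFrame, path: str) -> str:
    truth.to_csv(path, sep="\t", index=False)
    return path


def simulate_gene_table(
    config: SimConfig,
    n_genes: int = 500,
    loc_fraction: float = 0.3,
    mean_length_bp: int = 30_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic gene-coordinate table matched to a simulated panel's genome.

    Genes are placed uniformly along the configured chromosomes with
    exponential lengths; a ``loc_fraction`` of them carry provisional
    ``LOC<digits>`` symbols (uncharacterized models), the rest short
    alphabetic symbols.  Purely synthetic — a stand-in for a reference
    annotation, usable with :func:`breedscan.annotate.load_genes` via TSV.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n_genes)
    starts = rng.integers(1, config.chrom_length_bp - 1, size=n_genes)
    lengths = np.maximum(200, rng.exponential(mean_length_bp, size=n_genes)).astype(int)
    ends = np.minimum(starts + lengths, config.chrom_length_bp)
    is_loc = rng.random(n_genes) < loc_fraction
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    symbols = []
    for i in range(n_genes):
        if is_loc[i]:
            symbols.append(f"LOC{100000000 + i}")
        else:
            symbols.append("".join(rng.choice(letters, size=4)) + str(i))
    df = pd.DataFrame(
        {
            "gene_id": [f"GeneID:{i + 1}" for i in range(n_genes)],
            "symbol": symbols,
            "chrom": chroms.astype(str),
            "start": starts,
            "end": ends,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
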