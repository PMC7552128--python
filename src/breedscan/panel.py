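"""Genotype panel container and text-format I/O (PLINK PED/MAP, VCF).

The central object is :class:`GenotypePanel`: a samples x SNPs matrix of
diploid genotypes coded as copies of the counted allele (0/1/2, missing
``MISSING``), together with per-sample breed labels and a SNP map giving
chromosome, 1-based position and the two allele labels per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the matrix.
MISSING: int = -1

MAP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


@dataclass
class GenotypePanel:
    """Multi-breed diploid biallelic genotype panel.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` integer matrix; entries are 0, 1 or 2 copies
        of ``allele_a`` (the counted allele) or :data:`MISSING`.
    sample_ids
        One identifier per sample (row).
    breeds
        One breed label per sample, aligned with ``sample_ids``.
    snp_map
        DataFrame with columns ``snp_id, chrom, pos, allele_a, allele_b``;
        positions are 1-based and strictly increasing within a chromosome.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    breeds: list[str]
    snp_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.breeds = list(self.breeds)
        self.snp_map = self.snp_map.reset_index(drop=True)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        n_samples, n_snps = self.genotypes.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} genotype rows"
            )
        if len(self.breeds) != n_samples:
            raise ValueError("breeds must align with sample_ids")
        if len(self.snp_map) != n_snps:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows for {n_snps} genotype columns"
            )
        missing_cols = [c for c in MAP_COLUMNS if c not in self.snp_map.columns]
        if missing_cols:
            raise ValueError(f"snp_map missing columns: {missing_cols}")
        valid = (self.genotypes == MISSING) | (
            (self.genotypes >= 0) & (self.genotypes <= 2)
        )
        if not valid.all():
            raise ValueError("genotypes must be 0/1/2 or the missing code")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def breed_names(self) -> list[str]:
        """Breed labels in order of first appearance."""
        seen: dict[str, None] = {}
        for b in self.breeds:
            seen.setdefault(b)
        return list(seen)

    def breed_rows(self, breed: str) -> np.ndarray:
        """Row indices of the samples belonging to ``breed``."""
        idx = np.flatnonzero(np.asarray(self.breeds, dtype=object) == breed)
        if idx.size == 0:
            raise KeyError(f"unknown breed label: {breed!r}")
        return idx

    def subset_snps(self, mask_or_index) -> "GenotypePanel":
        """Panel restricted to the given SNP columns (mask or integer index)."""
        mask_or_index = np.asarray(mask_or_index)
        if mask_or_index.dtype == bool:
            idx = np.flatnonzero(mask_or_index)
        else:
            idx = mask_or_index
        return GenotypePanel(
            self.genotypes[:, idx],
            self.sample_ids,
            self.breeds,
            self.snp_map.iloc[idx],
        )

    def subset_breeds(self, breeds: list[str]) -> "GenotypePanel":
        """Panel restricted to samples of the given breeds."""
        rows = np.concatenate([self.breed_rows(b) for b in breeds])
        rows.sort()
        return GenotypePanel(
            self.genotypes[rows],
            [self.sample_ids[i] for i in rows],
            [self.breeds[i] for i in rows],
            self.snp_map,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.sample_ids == other.sample_ids
            and self.breeds == other.breeds
            and self.snp_map[MAP_COLUMNS].equals(other.snp_map[MAP_COLUMNS])
        )


# -- PLINK text format -------------------------------------------------------


def write_plink_text(panel: GenotypePanel, prefix: str) -> tuple[str, str]:
    """Write a panel as PLINK text ``<prefix>.ped`` / ``<prefix>.map``.

    PED columns: family id (breed label), within-family sample id, paternal
    and maternal ids (0), sex (0), phenotype (0), then two allele tokens per
    SNP; a missing call is written ``0 0``.  MAP columns: chromosome, SNP id,
    genetic distance (0) and bp position.

    Round-trips losslessly through :func:`read_plink_text` provided both
    alleles of every SNP are observed in the panel (a SNP monomorphic here
    cannot recover its unobserved allele label on read).
    """
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    amat = panel.snp_map["allele_a"].to_numpy(dtype=object)
    bmat = panel.snp_map["allele_b"].to_numpy(dtype=object)
    with open(map_path, "w") as fh:
        for row in panel.snp_map.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    # genotype g -> allele pair: g copies of allele_a, 2-g of allele_b
    with open(ped_path, "w") as fh:
        for i, (sid, breed) in enumerate(zip(panel.sample_ids, panel.breeds)):
            fields = [breed, sid, "0", "0", "0", "0"]
            g = panel.genotypes[i]
            for j in range(panel.n_snps):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 2:
                    fields += [amat[j], amat[j]]
                elif g[j] == 1:
                    fields += [amat[j], bmat[j]]
                else:
                    fields += [bmat[j], bmat[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_plink_text(prefix: str) -> GenotypePanel:
    """Read PLINK text ``<prefix>.ped`` / ``<prefix>.map`` into a panel.

    The counted allele (``allele_a``) of each SNP is the lexicographically
    smaller of the two alleles observed across samples; for a monomorphic
    SNP the single observed allele is counted and ``allele_b`` is ``"0"``.
    """
    map_df = pd.read_csv(
        f"{prefix}.map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )
    n_snps = len(map_df)
    sample_ids: list[str] = []
    breeds: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(f"{prefix}.ped") as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{prefix}.ped line {line_no}: expected {6 + 2 * n_snps} "
                    f"fields, found {len(parts)}"
                )
            breeds.append(parts[0])
            sample_ids.append(parts[1])
            allele_rows.append(np.asarray(parts[6:], dtype=object))
    alleles = np.stack(allele_rows)  # (n_samples, 2*n_snps)
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    geno = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    allele_a: list[str] = []
    allele_b: list[str] = []
    for j in range(n_snps):
        obs = set(a1[:, j]) | set(a2[:, j])
        obs.discard("0")
        if len(obs) > 2:
            raise ValueError(f"SNP {map_df['snp_id'][j]} has >2 alleles: {obs}")
        if not obs:
            allele_a.append("0")
            allele_b.append("0")
            continue
        ordered = sorted(obs)
        ref = ordered[0]
        allele_a.append(ref)
        allele_b.append(ordered[1] if len(ordered) == 2 else "0")
        called = (a1[:, j] != "0") & (a2[:, j] != "0")
        geno[called, j] = (a1[called, j] == ref).astype(np.int8) + (
            a2[called, j] == ref
        ).astype(np.int8)
    snp_map = pd.DataFrame(
        {
            "snp_id": map_df["snp_id"],
            "chrom": map_df["chrom"],
            "pos": map_df["pos"].astype(int),
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return GenotypePanel(geno, sample_ids, breeds, snp_map)


# -- VCF ---------------------------------------------------------------------


def write_vcf(panel: GenotypePanel, path: str) -> str:
    """Write the panel as an uncompressed VCF v4.2 with GT fields.

    ``allele_a`` (the counted allele) is written as REF, so the 0/1/2 copy
    count equals the number of REF alleles in the GT field.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.snp_map["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        gt_codes = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
        for j, row in enumerate(panel.snp_map.itertuples(index=False)):
            alt = row.allele_b if row.allele_b not in ("0", "") else "."
            gts = "\t".join(gt_codes[int(g)] for g in panel.genotypes[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.allele_a}\t{alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


def read_vcf(path: str, breeds: dict[str, str] | list[str]) -> GenotypePanel:
    """Read a VCF into a panel (thin cyvcf2 adapter).

    ``breeds`` assigns a breed label to every sample: either a mapping
    ``sample_id -> breed`` or a list aligned with the VCF sample order.
    The REF allele is counted, so 0/0 -> 2 copies.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)  # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
    samples = list(vcf.samples)
    if isinstance(breeds, dict):
        try:
            breed_list = [breeds[s] for s in samples]
        except KeyError as exc:
            raise KeyError(f"no breed label for sample {exc.args[0]!r}") from None
    else:
        if len(breeds) != len(samples):
            raise ValueError("breed list length does not match VCF sample count")
        breed_list = list(breeds)
    rows = []
    geno_cols = []
    for var in vcf:
        if len(var.ALT) > 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        gt = var.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 2
        col[gt == 1] = 1
        col[gt == 2] = 0
        geno_cols.append(col)
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "allele_a": var.REF,
                "allele_b": var.ALT[0] if var.ALT else "0",
            }
        )
    if not rows:
        raise ValueError(f"no variant records in {path}")
    return GenotypePanel(
        np.stack(geno_cols, axis=1), samples, breed_list, pd.DataFrame(rows)
    )
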