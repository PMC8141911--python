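"""VCF 4.2 and population-map I/O for genotype matrices.

Writing uses a plain-text VCF with ``GT`` and ``DP`` per-genotype fields (one
contig per locus); reading goes through :mod:`cyvcf2`.  The population map is
the usual two-column text file (individual, TAB, population).
"""

from __future__ import annotations

import numpy as np
from cyvcf2 import VCF

from .coalsim import GenotypeMatrix

__all__ = ["write_vcf", "read_vcf", "write_popmap", "read_popmap"]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write diploid genotypes as an uncompressed VCF 4.2 with GT:DP."""
    loci = np.asarray(gm.locus_ids)
    contigs = sorted(set(int(l) for l in loci))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=vicfound\n")
        for c in contigs:
            fh.write(f"##contig=<ID=locus_{c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_names)
            + "\n"
        )
        for s in range(gm.n_sites):
            cells = [
                f"{_GT_STRINGS[int(gm.genotypes[s, i])]}:{int(gm.depth[s, i])}"
                for i in range(gm.n_individuals)
            ]
            fh.write(
                f"locus_{int(loci[s])}\t{int(gm.positions[s])}\t.\tA\tT\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path, popmap: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    ``popmap`` maps sample names to population labels; samples absent from it
    get the label ``"unknown"``.  Multi-allelic records are rejected.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    geno_rows, depth_rows, loci, pos = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"site {var.CHROM}:{var.POS} is not biallelic")
        gts = np.array(var.genotypes, dtype=int)
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        row = alleles.clip(min=0).sum(axis=1)
        row[missing] = -1
        dp = var.format("DP")
        dp_row = (
            np.zeros(len(samples), dtype=np.int32)
            if dp is None
            else dp[:, 0].astype(np.int32).clip(min=0)
        )
        geno_rows.append(row.astype(np.int8))
        depth_rows.append(dp_row)
        chrom = var.CHROM
        loci.append(int(chrom.split("_")[-1]) if chrom.startswith("locus_") else hash(chrom) % (2**31))
        pos.append(var.POS)
    n = len(samples)
    geno = np.array(geno_rows, dtype=np.int8) if geno_rows else np.zeros((0, n), np.int8)
    depth = np.array(depth_rows, dtype=np.int32) if depth_rows else np.zeros((0, n), np.int32)
    popmap = popmap or {}
    labels = [popmap.get(s, "unknown") for s in samples]
    return GenotypeMatrix(
        genotypes=geno,
        pop_labels=labels,
        depth=depth,
        locus_ids=np.array(loci, dtype=int),
        positions=np.array(pos, dtype=int),
        sample_names=samples,
    )


def write_popmap(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for name, pop in zip(gm.sample_names, gm.pop_labels):
            fh.write(f"{name}\t{pop}\n")


def read_popmap(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pop = line.split()[:2]
            out[name] = pop
    return out
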