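"""Readers and writers for the pipeline's file formats.

VCF (v4.2, diploid GT; "./." is missing) is read with cyvcf2. Map, metadata
and inversion-boundary tables are plain TSV read with pandas. The VCF writer
emits a minimal well-formed VCFv4.2 so simulated datasets round-trip through
the same reader as real call sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeTable, InversionRegion, MapTable, SnpRecord, validate_meta


def read_vcf(path: str, map_table: MapTable | None = None) -> GenotypeTable:
    """Read a biallelic diploid VCF into a GenotypeTable.

    If `map_table` is given, each SNP's contig is looked up there for its
    (lg, cm) placement and SNPs on unmapped contigs are dropped; otherwise
    the contig must carry `LG`/`CM` INFO fields.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if map_table is not None:
            hit = map_table.lookup(var.CHROM)
            if hit is None:
                continue
            lg, cm = hit
        else:
            lg, cm = int(var.INFO["LG"]), float(var.INFO["CM"])
        # gts012=True: 0/1/2 = alt count, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        snps.append(
            SnpRecord(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                contig=var.CHROM,
                lg=lg,
                cm=cm,
                alleles=(var.REF, var.ALT[0]),
            )
        )
    geno = np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeTable(samples=samples, snps=snps, genotypes=geno)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path: str) -> None:
    """Write a GenotypeTable as VCFv4.2 with LG/CM INFO fields."""
    contigs = sorted({s.contig for s in table.snps})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=LG,Number=1,Type=Integer,Description="Linkage group">\n')
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        pos_within: dict[str, int] = {}
        for j, snp in enumerate(table.snps):
            pos_within[snp.contig] = pos_within.get(snp.contig, 0) + 1
            gts = "\t".join(_GT_CODE[int(g)] for g in table.genotypes[:, j])
            fh.write(
                f"{snp.contig}\t{pos_within[snp.contig]}\t{snp.snp_id}\t"
                f"{snp.alleles[0]}\t{snp.alleles[1]}\t.\tPASS\t"
                f"LG={snp.lg};CM={snp.cm:.6g}\tGT\t{gts}\n"
            )


def read_map(path: str) -> pd.DataFrame:
    """Read a raw marker table (contig, lg, cm), one marker per row."""
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "lg", "cm"}
    if not required <= set(df.columns):
        raise ValueError(f"map table needs columns {sorted(required)}")
    return df


def write_map(mt: MapTable, path: str) -> None:
    mt.frame.to_csv(path, sep="\t", index=False)


def read_map_table(path: str) -> MapTable:
    """Read an already-averaged contig map (contig, lg, cm_mean)."""
    df = pd.read_csv(path, sep="\t")
    if "cm_mean" not in df.columns and "cm" in df.columns:
        df = df.rename(columns={"cm": "cm_mean"})
    if "n_markers" not in df.columns:
        df["n_markers"] = 1
    return MapTable(frame=df[["contig", "lg", "cm_mean", "n_markers"]].copy())


def read_meta(path: str) -> pd.DataFrame:
    return validate_meta(pd.read_csv(path, sep="\t"))


def read_regions(path: str) -> list[InversionRegion]:
    """Read an inversion-boundary table (name, lg, start_cm, end_cm[, complex_flag])."""
    df = pd.read_csv(path, sep="\t")
    if "complex_flag" not in df.columns:
        df["complex_flag"] = False
    return [
        InversionRegion(
            name=str(r.name),
            lg=int(r.lg),
            start_cm=float(r.start_cm),
            end_cm=float(r.end_cm),
            complex_flag=bool(r.complex_flag),
        )
        for r in df.itertuples(index=False)
    ]


def write_regions(regions: list[InversionRegion], path: str) -> None:
    pd.DataFrame(
        {
            "name": [r.name for r in regions],
            "lg": [r.lg for r in regions],
            "start_cm": [r.start_cm for r in regions],
            "end_cm": [r.end_cm for r in regions],
            "complex_flag": [r.complex_flag for r in regions],
        }
    ).to_csv(path, sep="\t", index=False)
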