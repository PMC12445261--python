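"""Readers and writers for genotype and relationship-matrix formats.

Formats covered: VCF (write plain text; read via cyvcf2 when available with a
pure-python fallback), PLINK .bed/.bim/.fam, full-matrix TSV, and the
GCTA-compatible lower-triangle binary GRM layout (.grm.bin float32 stream +
.grm.id table).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, RelationshipMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_plink",
    "read_plink",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_grm_binary",
    "read_grm_binary",
]

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCFv4.2 with GT fields (1-based pos)."""
    path = Path(path)
    v = geno.variants
    contigs = list(dict.fromkeys(v["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=addom\n")
        for c in contigs:
            end = int(v.loc[v["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={end + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        dos = geno.dosages
        for j in range(geno.n_variants):
            row = v.iloc[j]
            calls = [
                "./." if np.isnan(d) else _GT_CODE[float(d)] for d in dos[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _read_vcf_python(path) -> GenotypeMatrix:
    samples: list[str] = []
    chroms, poss, refs, alts, ids = [], [], [], [], []
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            if "," in parts[4]:
                continue  # multi-allelic sites skipped
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            ids.append(parts[2])
            refs.append(parts[3])
            alts.append(parts[4])
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            dos = []
            for call in parts[9:]:
                gt = call.split(":")[gt_i].replace("|", "/")
                a = gt.split("/")
                if "." in a or len(a) != 2:
                    dos.append(np.nan)  # half-calls and missing -> missing
                else:
                    dos.append(float(int(a[0]) + int(a[1])))
            rows.append(dos)
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "id": ids}
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic sites from a VCF; half-calls are treated as missing."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover
        return _read_vcf_python(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts, ids = [], [], [], [], []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        gts = rec.genotype.array()
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        dos = alleles.sum(axis=1)  # NaN if any allele missing (half-call)
        rows.append(dos)
    vcf.close()
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "id": ids}
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam (SNP-major, 2-bit codes)
# ---------------------------------------------------------------------------

# PLINK bed 2-bit codes with A1 = alt: 00 hom-A1(2), 01 missing, 10 het, 11 hom-A2(0)
_BED_MAGIC = b"\x6c\x1b\x01"


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    prefix = str(prefix)
    v = geno.variants
    fam = pd.DataFrame(
        {
            "fid": geno.samples, "iid": geno.samples,
            "father": 0, "mother": 0, "sex": 0, "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"], "id": v["id"], "cm": 0.0, "pos": v["pos"],
            "a1": v["alt"], "a2": v["ref"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    n = geno.n_samples
    code = np.empty((geno.n_variants, n), dtype=np.uint8)
    d = geno.dosages.T
    code[d == 2] = 0b00
    code[d == 1] = 0b10
    code[d == 0] = 0b11
    code[np.isnan(d)] = 0b01
    n_bytes = (n + 3) // 4
    packed = np.zeros((geno.n_variants, n_bytes), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        packed[:, cols // 4] |= code[:, cols] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None)
    samples = fam[1].astype(str).tolist()
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None)
    variants = pd.DataFrame(
        {
            "chrom": bim[0].astype(str), "pos": bim[3].astype(int),
            "ref": bim[5].astype(str), "alt": bim[4].astype(str),
            "id": bim[1].astype(str),
        }
    )
    n, m = len(samples), len(variants)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    raw = raw.reshape(m, n_bytes)
    dosages = np.empty((m, n), dtype=float)
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    for k in range(4):
        cols = np.arange(k, n, 4)
        codes = (raw[:, cols // 4] >> (2 * k)) & 0b11
        dosages[:, cols] = lut[codes]
    return GenotypeMatrix(dosages=dosages.T, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------


def write_grm_tsv(rel: RelationshipMatrix, path) -> None:
    rel.to_frame().to_csv(path, sep="\t", index_label="id")


def read_grm_tsv(path, kind: str = "G_additive") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(
        values=df.to_numpy(float), ids=[str(i) for i in df.index], kind=kind
    )


def write_grm_binary(rel: RelationshipMatrix, prefix) -> None:
    """GCTA-compatible layout: float32 lower triangle + tab-separated .grm.id."""
    prefix = str(prefix)
    n = rel.n
    tri = rel.values[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    np.full(tri.shape, 1.0, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for s in rel.ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_binary(prefix, kind: str = "G_additive") -> RelationshipMatrix:
    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError("GRM binary size does not match .grm.id")
    vals = np.zeros((n, n))
    vals[np.tril_indices(n)] = tri
    vals = vals + vals.T - np.diag(np.diag(vals))
    return RelationshipMatrix(values=vals, ids=ids, kind=kind)
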