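"""Readers and writers for the standard interchange formats.

* VCF for non-PAR chrX genotypes: males are emitted haploid ("0"/"1") by
  default or homozygous-diploid ("0/0"/"1/1") on request; the reader
  accepts either dialect (auto-detected per call via cyvcf2) and prefers a
  DS dosage field when present. Heterozygous diploid male calls are
  rejected per SNP — on the non-PAR X they indicate mixed ploidy.
* Phenotype TSV: IID, SEX (1 = male, 2 = female), TRAIT, COV1..COVk.
* Summary-statistics TSV: the xwas association/meta table format.
* GRM: gzip-compressed text triples (i, j, m_snps, value) plus an id/sex
  sidecar, round-tripping bit-exactly.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .greml import GRM
from .simulate import PhenotypeTable, XGenotypes

__all__ = [
    "write_vcf", "read_vcf",
    "write_phenotype_tsv", "read_phenotype_tsv",
    "write_summary_tsv", "read_summary_tsv",
    "write_grm", "read_grm",
]


def write_vcf(geno: XGenotypes, path, diploid_males: bool = False) -> None:
    """Write chrX genotypes as an uncompressed VCF with GT and DS fields."""
    path = Path(path)
    fem_ids = [f"F{i + 1:04d}" for i in range(geno.n_females)]
    mal_ids = [f"M{i + 1:04d}" for i in range(geno.n_males)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=X,length=155270560>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Expected effect-allele dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description='
                 '"Imputation info score (females)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(fem_ids + mal_ids) + "\n")
        for j in range(geno.n_snps):
            cells = []
            for d in geno.female_dosages[:, j]:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(round(d)), "./.")
                cells.append(f"{gt}:{d:g}")
            for d in geno.male_dosages[:, j]:
                a = int(round(d))
                gt = (f"{a}/{a}" if diploid_males else f"{a}")
                cells.append(f"{gt}:{d:g}")
            fh.write("\t".join([
                "X", str(int(geno.positions[j])), str(geno.snp_ids[j]),
                str(geno.other_allele[j]), str(geno.effect_allele[j]),
                ".", "PASS", f"INFO={float(geno.info_female[j]):g}", "GT:DS",
            ] + cells) + "\n")


def read_vcf(path, sexes: dict) -> XGenotypes:
    """Read chrX genotypes from a VCF given a sample-id -> sex mapping.

    DS is used when present; otherwise dosages come from GT, accepting
    haploid or homozygous-diploid male calls. A heterozygous male call makes
    the SNP's ploidy inconsistent and raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in sexes]
    if missing:
        raise ValueError(f"no sex assignment for samples: {missing[:5]}")
    is_female = np.array([sexes[s] == "female" for s in samples])
    f_idx = np.flatnonzero(is_female)
    m_idx = np.flatnonzero(~is_female)

    ids, pos, ea, oa, fem, mal, info = [], [], [], [], [], [], []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            dose = ds[:, 0].astype(float)
        else:
            dose = np.full(len(samples), np.nan)
            for i, g in enumerate(var.genotypes):
                alleles = [a for a in g[:-1] if a >= 0]
                if not alleles:
                    continue
                if len(alleles) == 1:  # haploid call
                    dose[i] = float(alleles[0])
                elif is_female[i]:
                    dose[i] = float(sum(alleles))
                else:  # diploid male: only homozygous calls are coherent
                    if alleles[0] != alleles[1]:
                        raise ValueError(
                            f"{var.ID}: heterozygous diploid call for male "
                            f"sample {samples[i]} (mixed ploidy)")
                    dose[i] = float(alleles[0])
        f_d = dose[f_idx]
        m_d = dose[m_idx]
        with np.errstate(invalid="ignore"):
            if np.nanmax(m_d, initial=0) > 1:
                raise ValueError(f"{var.ID}: male dosage above 1")
        ids.append(var.ID or f"X:{var.POS}")
        pos.append(var.POS)
        oa.append(var.REF)
        ea.append(var.ALT[0] if var.ALT else ".")
        fem.append(f_d)
        mal.append(m_d)
        info.append(float(var.INFO.get("INFO", 1.0)))

    fem_m = np.array(fem).T if ids else np.empty((len(f_idx), 0))
    mal_m = np.array(mal).T if ids else np.empty((len(m_idx), 0))
    with np.errstate(invalid="ignore"):
        eaf_f = np.nanmean(fem_m, axis=0) / 2.0 if len(f_idx) else np.full(len(ids), np.nan)
        eaf_m = np.nanmean(mal_m, axis=0) if len(m_idx) else np.full(len(ids), np.nan)
    return XGenotypes(
        snp_ids=np.array(ids), positions=np.array(pos, dtype=int),
        effect_allele=np.array(ea), other_allele=np.array(oa),
        female_dosages=fem_m, male_dosages=mal_m,
        eaf_female=eaf_f, eaf_male=eaf_m, info_female=np.array(info),
    )


def write_phenotype_tsv(pheno: PhenotypeTable, path) -> None:
    df = pd.DataFrame({
        "IID": pheno.sample_ids,
        "SEX": np.where(pheno.sex == "male", 1, 2),
        "TRAIT": pheno.raw_trait,
    })
    for j in range(pheno.covariates.shape[1]):
        name = (pheno.covariate_names[j] if j < len(pheno.covariate_names)
                else f"COV{j + 1}")
        df[name.upper()] = pheno.covariates[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    cov_cols = [c for c in df.columns if c not in ("IID", "SEX", "TRAIT")]
    return PhenotypeTable(
        sample_ids=df["IID"].astype(str).to_numpy(),
        sex=np.where(df["SEX"].to_numpy() == 1, "male", "female"),
        raw_trait=df["TRAIT"].to_numpy(dtype=float),
        covariates=df[cov_cols].to_numpy(dtype=float) if cov_cols
        else np.empty((len(df), 0)),
        covariate_names=cov_cols,
    )


def write_summary_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "MALE_CODING" in df.columns:
        df["MALE_CODING"] = df["MALE_CODING"].fillna("")
    return df


def write_grm(grm: GRM, prefix) -> None:
    """Serialize a GRM as gzip text triples plus an id/sex sidecar."""
    prefix = str(prefix)
    with gzip.open(prefix + ".grm.gz", "wt") as fh:
        fh.write(f"#dc_model={grm.dc_model}\n")
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m_snps}\t"
                         f"{float(grm.matrix[i, j])!r}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for sid, sx in zip(grm.sample_ids, grm.sex):
            fh.write(f"{sid}\t{sx}\n")


def read_grm(prefix) -> GRM:
    prefix = str(prefix)
    ids, sex = [], []
    with open(prefix + ".grm.id") as fh:
        for line in fh:
            sid, sx = line.rstrip("\n").split("\t")
            ids.append(sid)
            sex.append(sx)
    n = len(ids)
    mat = np.zeros((n, n))
    dc_model = "EV"
    m_snps = 0
    with gzip.open(prefix + ".grm.gz", "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                if line.startswith("#dc_model="):
                    dc_model = line.strip().split("=", 1)[1]
                continue
            i, j, m, v = line.split("\t")
            mat[int(i) - 1, int(j) - 1] = mat[int(j) - 1, int(i) - 1] = float(v)
            m_snps = int(m)
    return GRM(matrix=mat, sample_ids=np.array(ids), sex=np.array(sex),
               dc_model=dc_model, m_snps=m_snps)
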