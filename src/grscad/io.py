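"""File formats: VCF dosages, weights TSV, phenotype CSV, truth YAML.

The VCF writer emits a minimal VCFv4.2 file with a per-sample DS (dosage)
field and a GT field when dosages are integral; REF is the other allele and
ALT the effect allele, so alt-dosage equals effect-allele dosage as written.
Reading goes through cyvcf2 when it is installed and falls back to a plain
line parser (the files involved are small, uncompressed and single-allele);
either path re-orients dosages to the weights file's effect alleles via
:func:`grscad.grs.align_alleles`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeMatrix, VariantPanel
from .grs import Orientation, align_alleles

__all__ = ["write_vcf", "read_vcf", "write_weights", "read_weights",
           "write_phenotypes", "read_phenotypes", "write_truth", "read_truth"]

WEIGHT_COLUMNS = ["rsid", "chrom", "pos", "effect_allele", "other_allele",
                  "beta", "eaf", "pleiotropic"]


def write_weights(panel: VariantPanel, path) -> None:
    panel.table[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_weights(path) -> VariantPanel:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    t["pleiotropic"] = t["pleiotropic"].astype(bool)
    return VariantPanel(t).normalize()


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def write_truth(truth: dict, path) -> None:
    def _clean(v):
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v
    Path(path).write_text(yaml.safe_dump(_clean(truth), sort_keys=True))


def read_truth(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_vcf(genotypes: GenotypeMatrix, panel: VariantPanel, path) -> None:
    """Write dosages as a minimal text VCF (DS always, GT when integral)."""
    if panel.rsids != genotypes.rsids:
        raise ValueError("panel and genotypes are not aligned")
    d = genotypes.dosages
    integral = np.all(np.isnan(d) | (np.abs(d - np.round(d)) < 1e-9))
    fmt = "GT:DS" if integral else "DS"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Effect(ALT)-allele dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description='
                 '"Imputation info score">\n')
        for chrom in dict.fromkeys(str(c) for c in panel.table["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.subject_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in panel.table.iterrows():
            fields = [str(row["chrom"]), str(int(row["pos"])), row["rsid"],
                      row["other_allele"], row["effect_allele"], ".", "PASS",
                      f"INFO={genotypes.info[j]:.4g}", fmt]
            for i in range(genotypes.n_subjects):
                v = d[i, j]
                if np.isnan(v):
                    fields.append("./.:." if integral else ".")
                elif integral:
                    fields.append(f"{gt_map[int(round(v))]}:{v:g}")
                else:
                    fields.append(f"{v:g}")
            fh.write("\t".join(fields) + "\n")


def _iter_vcf_records(path):
    """Yield (rsid, ref, alt, alt_dosages, info) from a VCF."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        yield from _iter_vcf_records_text(path)
        return
    for var in VCF(str(path)):
        ds = var.format("DS")
        if ds is not None:
            dos = np.asarray(ds, float).ravel()
            dos = np.where((dos < -0.5) | (dos > 2.5), np.nan, dos)
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            dos = np.where((gts < 0).any(axis=1), np.nan,
                           gts.clip(min=0).sum(axis=1)).astype(float)
        info = var.INFO.get("INFO", 1.0)
        yield var.ID, var.REF, var.ALT[0], dos, float(info)


def _iter_vcf_records_text(path):
    with open(path) as fh:
        samples = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            fmt = f[8].split(":")
            info = 1.0
            for kv in f[7].split(";"):
                if kv.startswith("INFO="):
                    info = float(kv[5:])
            dos = np.full(len(samples), np.nan)
            if "DS" in fmt:
                k = fmt.index("DS")
                for i, cell in enumerate(f[9:]):
                    v = cell.split(":")[k]
                    if v not in (".", ""):
                        dos[i] = float(v)
            elif "GT" in fmt:
                k = fmt.index("GT")
                for i, cell in enumerate(f[9:]):
                    gt = cell.split(":")[k].replace("|", "/")
                    if "." not in gt:
                        dos[i] = sum(int(a) for a in gt.split("/"))
            yield f[2], f[3], f[4], dos, info


def read_vcf(path, panel: VariantPanel) -> GenotypeMatrix:
    """Load effect-allele dosages for the panel SNPs from a VCF.

    Records are matched by rsid; ref/alt are oriented to the panel's
    effect/other alleles (strand flips handled); panel SNPs absent from the
    VCF raise.
    """
    want = {r: j for j, r in enumerate(panel.rsids)}
    dosages = None
    info = np.ones(len(panel))
    samples: list[str] | None = None
    seen = set()
    try:
        from cyvcf2 import VCF
        samples = list(VCF(str(path)).samples)
    except ImportError:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#CHROM"):
                    samples = line.rstrip("\n").split("\t")[9:]
                    break
    if samples is None:
        raise ValueError("no #CHROM header in VCF")
    dosages = np.full((len(samples), len(panel)), np.nan)
    tab = panel.table.set_index("rsid")
    for rsid, ref, alt, dos, inf in _iter_vcf_records(path):
        if rsid not in want:
            continue
        j = want[rsid]
        orient = align_alleles(ref, alt, tab.loc[rsid, "effect_allele"],
                               tab.loc[rsid, "other_allele"], rsid=rsid)
        if orient in (Orientation.COMPLEMENTED_DOSAGE,
                      Orientation.STRAND_FLIP_COMPLEMENTED):
            dos = 2.0 - dos
        dosages[:, j] = dos
        info[j] = inf
        seen.add(rsid)
    missing = set(want) - seen
    if missing:
        raise ValueError(f"panel SNPs absent from VCF: {sorted(missing)[:5]}...")
    return GenotypeMatrix(dosages, samples, panel.rsids, info)
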