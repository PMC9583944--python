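"""File formats: VCF / TSV dosages, phenotype CSV, GRM TSV, YAML configs.

VCF is written as plain text (GT field, 1-based positions, unphased
genotypes) and read back through cyvcf2.  The TSV dosage matrix has loci as
columns (``chrom:pos`` headers) and one row per individual.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GRM, GenotypePanel


def write_vcf(panel: GenotypePanel, path) -> None:
    path = Path(path)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gxeblup\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.ids) + "\n")
        for j, row in panel.loci.iterrows():
            calls = [gt_of.get(panel.dosage[i, j], "./.")
                     for i in range(panel.n_individuals)]
            fh.write(f"{row['chrom']}\t{row['pos']}\tsnp{j}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path, population_of: dict | None = None) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    chroms, pos, ref, alt, rows = [], [], [], [], []
    for var in vcf:
        chroms.append(int(var.CHROM) if str(var.CHROM).isdigit() else var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
        g = np.asarray(var.genotype.array())[:, :2].astype(float)
        g[g < 0] = np.nan
        rows.append(g.sum(axis=1))
    vcf.close()
    dosage = np.stack(rows, axis=1) if rows else np.empty((len(ids), 0))
    loci = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    pops = [population_of.get(i, "NA") if population_of else "NA" for i in ids]
    indiv = pd.DataFrame({"id": ids, "population": pops})
    return GenotypePanel(dosage, loci, indiv)


def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    cols = [f"{c}:{p}" for c, p in zip(panel.loci["chrom"], panel.loci["pos"])]
    df = pd.DataFrame(panel.dosage, columns=cols)
    df.insert(0, "id", panel.ids)
    df.insert(1, "population", panel.populations)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta = df[["id", "population"]]
    loci_cols = [c for c in df.columns if c not in ("id", "population")]
    chroms, pos = zip(*(c.split(":") for c in loci_cols))
    chroms = [int(c) if c.isdigit() else c for c in chroms]
    loci = pd.DataFrame({"chrom": chroms, "pos": [int(p) for p in pos],
                         "ref": "A", "alt": "B"})
    return GenotypePanel(df[loci_cols].to_numpy(float), loci,
                         meta.rename(columns={"id": "id"}))


def write_grm_tsv(grm: GRM, path) -> None:
    df = pd.DataFrame(grm.matrix, index=grm.ids, columns=grm.ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_grm_tsv(path, effect_kind="additive", locus_scope="genome-wide") -> GRM:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return GRM(df.to_numpy(float), list(df.index), effect_kind, locus_scope)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, entries: dict, path_name="manifest.json") -> Path:
    out_dir = Path(out_dir)
    manifest = {
        name: {"path": str(p), "sha256": file_checksum(p)}
        for name, p in entries.items()
    }
    path = out_dir / path_name
    path.write_text(json.dumps(manifest, indent=2))
    return path
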