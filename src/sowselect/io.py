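"""Reading and writing the pipeline's on-disk formats.

Panels and sample calls travel either as biallelic VCF (GT field,
1-based positions; inbred panel genotypes are 0/0 or 1/1, field samples
may additionally be 0/1 or ./.) or as plain TSV matrices (rows = SNPs,
columns = accessions/samples; codes 0, 1, H, .). Accession and site
metadata are CSV; truth tables are TSV. VCF reading goes through cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HET, MISSING, GenotypePanel, SampleCalls, TruthRecord

_TSV_CODE = {0: "0", 1: "1", HET: "H", MISSING: "."}
_TSV_DECODE = {v: k for k, v in _TSV_CODE.items()}


# ---------------------------------------------------------------- VCF ----


def _write_vcf(
    path, chrom, pos, sample_names, genotype_matrix, ref="A", alt="T"
) -> None:
    """genotype_matrix: (n_samples, n_snps) in {0,1,HET,MISSING}."""
    gt_str = {0: "0/0", 1: "1/1", HET: "0/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for j in range(len(chrom)):
            calls = "\t".join(gt_str[int(g)] for g in genotype_matrix[:, j])
            fh.write(
                f"{chrom[j]}\t{pos[j]}\t{chrom[j]}_{pos[j]}\t{ref}\t{alt}\t.\t.\t.\tGT\t{calls}\n"
            )


def _read_vcf(path) -> tuple[list[str], list[str], np.ndarray, np.ndarray, pd.DataFrame]:
    """Returns (sample_names, chrom, pos, matrix, alleles)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom: list[str] = []
    pos: list[int] = []
    cols: list[np.ndarray] = []
    alleles: list[tuple[str, str, str]] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: only biallelic records supported ({var.CHROM}:{var.POS})"
            )
        chrom.append(var.CHROM)
        pos.append(var.POS)
        alleles.append((var.CHROM, var.REF, var.ALT[0]))
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = var.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 3] = 1
        col[gt == 1] = HET
        cols.append(col)
    vcf.close()
    matrix = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    allele_df = pd.DataFrame(alleles, columns=["chrom", "ref", "alt"])
    allele_df["pos"] = pos
    return samples, chrom, np.asarray(pos, dtype=np.int64), matrix, allele_df


def write_panel_vcf(panel: GenotypePanel, path) -> None:
    _write_vcf(path, panel.chrom, panel.pos, panel.accession_ids, panel.genotypes)


def read_panel_vcf(path, metadata: pd.DataFrame) -> tuple[GenotypePanel, pd.DataFrame]:
    """Read a panel VCF; accession metadata supplies group/coordinates.

    Heterozygous panel entries are rejected (accessions are inbred).
    Returns the panel and the (chrom, pos, ref, alt) allele table for
    encoding checks against sample files.
    """
    ids, chrom, pos, matrix, alleles = _read_vcf(path)
    if (matrix == HET).any():
        raise ValueError(f"{path}: heterozygous genotypes in an inbred panel")
    meta = metadata.set_index("accession_id")
    missing = [i for i in ids if i not in meta.index]
    if missing:
        raise ValueError(f"accessions absent from metadata: {missing[:5]}")
    panel = GenotypePanel(
        accession_ids=ids,
        group_labels=[str(meta.loc[i, "group"]) for i in ids],
        lat=np.array([meta.loc[i, "lat"] for i in ids], dtype=float),
        lon=np.array([meta.loc[i, "lon"] for i in ids], dtype=float),
        chrom=chrom,
        pos=pos,
        genotypes=matrix,
    )
    return panel, alleles


def write_calls_vcf(calls: SampleCalls, path) -> None:
    _write_vcf(path, calls.chrom, calls.pos, calls.sample_ids, calls.calls)


def read_calls_vcf(
    path, site_of_sample: dict[str, str] | pd.Series
) -> tuple[SampleCalls, pd.DataFrame]:
    ids, chrom, pos, matrix, alleles = _read_vcf(path)
    if isinstance(site_of_sample, pd.Series):
        site_of_sample = site_of_sample.to_dict()
    missing = [i for i in ids if i not in site_of_sample]
    if missing:
        raise ValueError(f"samples without a site: {missing[:5]}")
    calls = SampleCalls(
        sample_ids=ids,
        site_ids=[site_of_sample[i] for i in ids],
        chrom=chrom,
        pos=pos,
        calls=matrix,
    )
    return calls, alleles


# ---------------------------------------------------------------- TSV ----


def _matrix_to_frame(chrom, pos, names, matrix) -> pd.DataFrame:
    coded = np.empty(matrix.shape, dtype=object)
    for code, char in _TSV_CODE.items():
        coded[matrix == code] = char
    cols = {"chrom": list(chrom), "pos": np.asarray(pos)}
    cols.update({name: coded[i] for i, name in enumerate(names)})
    return pd.DataFrame(cols)


def _frame_to_matrix(df: pd.DataFrame) -> tuple[list[str], np.ndarray, list[str], np.ndarray]:
    chrom = df["chrom"].astype(str).tolist()
    pos = df["pos"].to_numpy(dtype=np.int64)
    names = [c for c in df.columns if c not in ("chrom", "pos")]
    matrix = np.empty((len(names), len(df)), dtype=np.int8)
    for i, name in enumerate(names):
        col = df[name].astype(str)
        bad = ~col.isin(_TSV_DECODE)
        if bad.any():
            raise ValueError(
                f"invalid genotype codes in column {name}: "
                f"{sorted(col[bad].unique())[:5]}"
            )
        matrix[i] = col.map(_TSV_DECODE).to_numpy(dtype=np.int8)
    return chrom, pos, names, matrix


def write_panel_tsv(panel: GenotypePanel, path) -> None:
    _matrix_to_frame(panel.chrom, panel.pos, panel.accession_ids, panel.genotypes).to_csv(
        path, sep="\t", index=False
    )


def read_panel_tsv(path, metadata: pd.DataFrame) -> GenotypePanel:
    chrom, pos, ids, matrix = _frame_to_matrix(pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""]))
    if (matrix == HET).any():
        raise ValueError(f"{path}: heterozygous genotypes in an inbred panel")
    meta = metadata.set_index("accession_id")
    missing = [i for i in ids if i not in meta.index]
    if missing:
        raise ValueError(f"accessions absent from metadata: {missing[:5]}")
    return GenotypePanel(
        accession_ids=ids,
        group_labels=[str(meta.loc[i, "group"]) for i in ids],
        lat=np.array([meta.loc[i, "lat"] for i in ids], dtype=float),
        lon=np.array([meta.loc[i, "lon"] for i in ids], dtype=float),
        chrom=chrom,
        pos=pos,
        genotypes=matrix,
    )


def write_calls_tsv(calls: SampleCalls, path, sites_path=None) -> None:
    _matrix_to_frame(calls.chrom, calls.pos, calls.sample_ids, calls.calls).to_csv(
        path, sep="\t", index=False
    )
    if sites_path is not None:
        pd.DataFrame(
            {"sample_id": calls.sample_ids, "site_id": calls.site_ids}
        ).to_csv(sites_path, sep="\t", index=False)


def read_calls_tsv(path, site_of_sample: dict[str, str] | pd.Series) -> SampleCalls:
    chrom, pos, ids, matrix = _frame_to_matrix(pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""]))
    if isinstance(site_of_sample, pd.Series):
        site_of_sample = site_of_sample.to_dict()
    missing = [i for i in ids if i not in site_of_sample]
    if missing:
        raise ValueError(f"samples without a site: {missing[:5]}")
    return SampleCalls(
        sample_ids=ids,
        site_ids=[site_of_sample[i] for i in ids],
        chrom=chrom,
        pos=pos,
        calls=matrix,
    )


# ----------------------------------------------------------- metadata ----


def write_accession_metadata(panel: GenotypePanel, path) -> None:
    panel.metadata().to_csv(path, index=False)


def read_accession_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    required = {"accession_id", "group", "lat", "lon"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    return df


def write_site_metadata(site_coords: dict[str, tuple[float, float]], path) -> None:
    pd.DataFrame(
        [
            {"site_id": s, "lat": lat, "lon": lon}
            for s, (lat, lon) in sorted(site_coords.items())
        ]
    ).to_csv(path, index=False)


def read_site_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    required = {"site_id", "lat", "lon"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: site metadata needs columns {sorted(required)}")
    return df


def write_truth(truth: TruthRecord, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthRecord:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return TruthRecord(
        sample_ids=df["sample_id"].astype(str).tolist(),
        site_ids=df["site_id"].astype(str).tolist(),
        source=df["source"].astype(str).tolist(),
    )


def concat_calls(parts: list[SampleCalls]) -> SampleCalls:
    """Stack per-site sample calls sharing the same SNP axis."""
    first = parts[0]
    for p in parts[1:]:
        if p.chrom != first.chrom or not np.array_equal(p.pos, first.pos):
            raise ValueError("cannot concatenate calls with differing SNP sets")
    return SampleCalls(
        sample_ids=[s for p in parts for s in p.sample_ids],
        site_ids=[s for p in parts for s in p.site_ids],
        chrom=list(first.chrom),
        pos=first.pos.copy(),
        calls=np.vstack([p.calls for p in parts]),
    )


def concat_truth(parts: list[TruthRecord]) -> TruthRecord:
    true_ne: dict[str, int] = {}
    true_fitness: dict[str, np.ndarray] = {}
    for p in parts:
        true_ne.update(p.true_ne)
        true_fitness.update(p.true_fitness)
    return TruthRecord(
        sample_ids=[s for p in parts for s in p.sample_ids],
        site_ids=[s for p in parts for s in p.site_ids],
        source=[s for p in parts for s in p.source],
        true_ne=true_ne,
        true_fitness=true_fitness,
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
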