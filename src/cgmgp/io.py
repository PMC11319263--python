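"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as a tab-delimited matrix (rows = genotypes, header =
marker IDs) or as a minimal biallelic GT-only VCF; weather and phenotypes
as CSV; parameters and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_model import GenotypeParameters, PARAMETER_NAMES, WeatherSeries
from .markers import MarkerMatrix

__all__ = [
    "write_genotypes_tsv", "read_genotypes_tsv",
    "write_genotypes_vcf", "read_genotypes_vcf",
    "write_weather_csv", "read_weather_csv",
    "write_phenotypes_csv", "read_phenotypes_csv",
    "write_params_json", "read_params_json",
]


def write_genotypes_tsv(markers: MarkerMatrix, path) -> None:
    markers.to_frame().to_csv(path, sep="\t", index_label="genotype_id")


def read_genotypes_tsv(path) -> MarkerMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="genotype_id")
    return MarkerMatrix.from_frame(frame)


_GT_BY_CODE = {-1: "0/0", 0: "0/1", 1: "1/1"}


def write_genotypes_vcf(markers: MarkerMatrix, path) -> None:
    """Minimal biallelic GT-only VCF; one synthetic chromosome."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(markers.genotype_ids) + "\n")
        for j, mid in enumerate(markers.marker_ids):
            gts = "\t".join(_GT_BY_CODE[int(c)] for c in markers.values[:, j])
            fh.write(f"1\t{j + 1}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path) -> MarkerMatrix:
    """Ingest biallelic SNPs from a VCF into {-1, 0, 1} codes."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    codes, ids = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue  # biallelic only
        row = np.array(
            [a + b - 1 if a >= 0 and b >= 0 else 99
             for a, b, *_ in variant.genotypes], dtype=np.int8
        )
        if (row == 99).any():
            raise ValueError(f"missing genotype at {variant.ID}: matrix must be complete")
        codes.append(row)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    return MarkerMatrix(np.array(codes).T, samples, tuple(ids))


def write_weather_csv(weather: WeatherSeries, path) -> None:
    weather.to_frame().to_csv(path, index=False)


def read_weather_csv(path) -> WeatherSeries:
    return WeatherSeries.from_frame(pd.read_csv(path))


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_params_json(params, path) -> None:
    """``params`` is a GenotypeParameters, a dict, or a genotype-indexed frame."""
    if isinstance(params, GenotypeParameters):
        payload = {n: getattr(params, n) for n in PARAMETER_NAMES}
    elif isinstance(params, pd.DataFrame):
        payload = {str(g): row.to_dict() for g, row in params.iterrows()}
    else:
        payload = params
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params_json(path):
    payload = json.loads(Path(path).read_text())
    if set(payload) == set(PARAMETER_NAMES):
        return GenotypeParameters(**payload)
    return pd.DataFrame.from_dict(payload, orient="index")[list(PARAMETER_NAMES)]
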