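"""Delimited-text readers and writers for the pipeline's tables.

All interchange formats are tab-delimited text with a header row:
cohort tables (sex as the strings "male"/"female"), summary statistics
with the column set CHR BP SNP EA OA EAF BETA SE P N TRAIT STRATUM
(subsets allowed where a stage needs less), LD tables in long
(snp_a, snp_b, r2) or square form, score weight tables
(SNP, EA, OA, WEIGHT) and BED exclusion regions.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataError
from .gwas_core import LdTable


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "sex", "age", "bmi", "height", "vat", "asat", "gfat"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"cohort table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "SNP" not in df.columns:
        raise DataError("summary statistics need at least a SNP column")
    return df


def read_ld(path) -> LdTable:
    df = pd.read_csv(path, sep="\t")
    if {"snp_a", "snp_b", "r2"}.issubset(df.columns):
        return LdTable.from_long(df)
    return LdTable.from_square(pd.read_csv(path, sep="\t", index_col=0))


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"SNP", "EA", "OA", "WEIGHT"} - set(df.columns)
    if missing:
        raise DataError(f"weight table missing columns: {sorted(missing)}")
    return df


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise DataError("BED file needs chrom, start, end columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    return out
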