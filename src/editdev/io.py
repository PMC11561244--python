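"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via pyfaidx, SAM via pysam; BED / GFF3 / site tables / matrices are
tab-separated tables handled with pandas. Coordinates follow the standards:
BED half-open 0-based, GFF3 and site/SNP tables 1-based.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyfaidx
import pysam

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
GFF_COLUMNS = ["chrom", "source", "feature", "start", "end", "score", "strand",
               "frame", "attributes"]


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in intervals.columns]
    extra = [c for c in intervals.columns if c not in cols]
    intervals[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = BED_COLUMNS[: min(len(df.columns), 6)] + (extra_columns or [])
    df.columns = names + list(df.columns[len(names):])
    return df


def write_gff(features: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        features[GFF_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_gff(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, comment="#", names=GFF_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


def write_sam(header: pysam.AlignmentHeader,
              reads: list[pysam.AlignedSegment], path: str | Path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            out.write(read)


def read_sam(path: str | Path) -> tuple[pysam.AlignmentHeader,
                                        list[pysam.AlignedSegment]]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        header = fh.header
        reads = list(fh)
    return header, reads


def write_matrix(levels: pd.DataFrame, path: str | Path) -> None:
    """Sites x samples matrix, NA for missing, site_id as first column."""
    levels.to_csv(path, sep="\t", na_rep="NA", index_label="site_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site_id", na_values=["NA"])
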