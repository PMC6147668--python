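"""Readers and writers for the flat-file interchange formats.

BED and BEDPE are 0-based half-open; scores are floats.  Count matrices
are genes x samples TSV with sample names encoding the design as
``<cell_line>.<tet>.t<time>.r<replicate>`` (e.g. ``clone1.plus.t1.r2``).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "pet_count"]


def write_bed(peaks: pd.DataFrame, path) -> None:
    df = peaks.copy()
    if "name" not in df.columns:
        df["name"] = [f"peak{i}" for i in range(len(df))]
    if "strand" not in df.columns:
        df["strand"] = "."
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                     dtype={"chrom": str})
    return df


def write_bedpe(interactions: pd.DataFrame, path) -> None:
    cols = list(BEDPE_COLUMNS)
    df = interactions.copy()
    if "name" not in df.columns:
        df["name"] = [f"pet{i}" for i in range(len(df))]
    for extra in ("p", "fdr"):
        if extra in df.columns:
            cols.append(extra)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> pd.DataFrame:
    """Read BEDPE with a PET-count column and optional p/FDR columns.

    Malformed rows raise ``ValueError`` naming the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (8, 9, 10):
                raise ValueError(
                    f"{path}: malformed BEDPE row at line {lineno}: "
                    f"expected 8-10 tab-separated fields, got {len(fields)}")
            try:
                rec = {
                    "chrom1": fields[0], "start1": int(fields[1]), "end1": int(fields[2]),
                    "chrom2": fields[3], "start2": int(fields[4]), "end2": int(fields[5]),
                    "name": fields[6], "pet_count": int(fields[7]),
                }
                if len(fields) >= 9:
                    rec["p"] = float(fields[8])
                if len(fields) == 10:
                    rec["fdr"] = float(fields[9])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed BEDPE row at line {lineno}: {exc}") from None
            rows.append(rec)
    return pd.DataFrame(rows)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"],
                       dtype={"chrom": str})
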