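"""Gene models and promoter-window geometry.

Genomic coordinates are 0-based half-open internally (BED convention).
GTF input/output converts to and from that format's 1-based closed
convention on the fly.

A gene model is a transcription unit with a strand, an exon chain, and
5'/3' UTR lengths inside the terminal exons.  Three stranded promoter
windows are derived from the TSS:

* annotation window:   -1000 .. +100 relative to the TSS (peak annotation,
  Pol II promoter status, loop anchor-to-gene mapping)
* scan window:          -400 .. +100 (promoter motif prevalence)
* conservation window: -1000 .. -1, i.e. the 1 kb strictly upstream of
  the TSS (cross-species kB-site conservation)

"Upstream" and "downstream" follow the direction of transcription; on the
minus strand upstream means larger coordinates.
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
import pandas as pd

#: (upstream, last included downstream offset) relative to the TSS
PROMOTER_ANNOTATION = (1000, 100)
PROMOTER_SCAN = (400, 100)
PROMOTER_CONSERVATION = (1000, -1)

_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "utr5_len", "utr3_len"]


class GeneModels:
    """Container for a set of gene models.

    Parameters
    ----------
    genes:
        DataFrame with columns ``gene_id, chrom, start, end, strand``
        (``utr5_len``/``utr3_len`` optional, default 0).  ``start < end``;
        strand is ``+`` or ``-``.
    exons:
        Optional DataFrame ``gene_id, start, end`` (0-based half-open).
        If omitted, each gene is treated as a single exon.
    chrom_sizes:
        Optional mapping of chromosome name to length in bp.
    """

    def __init__(self, genes: pd.DataFrame, exons: pd.DataFrame | None = None,
                 chrom_sizes: Mapping[str, int] | None = None):
        genes = genes.copy()
        for col in ("utr5_len", "utr3_len"):
            if col not in genes.columns:
                genes[col] = 0
        missing = [c for c in _GENE_COLUMNS if c not in genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        if (genes["start"] >= genes["end"]).any():
            bad = genes.loc[genes["start"] >= genes["end"], "gene_id"].tolist()
            raise ValueError(f"genes with start >= end: {bad}")
        if not genes["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in gene table")
        self.genes = genes.reset_index(drop=True)
        if exons is None:
            exons = genes[["gene_id", "start", "end"]].copy()
        self.exons = exons.reset_index(drop=True)
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else {}

    def __len__(self) -> int:
        return len(self.genes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneModels({len(self)} genes, {self.genes['chrom'].nunique()} chroms)"

    # -- derived coordinates -------------------------------------------------

    @property
    def tss(self) -> pd.Series:
        """0-based position of the first transcribed base, indexed by gene_id."""
        g = self.genes
        pos = np.where(g["strand"].values == "+", g["start"].values, g["end"].values - 1)
        return pd.Series(pos, index=g["gene_id"].values, name="tss")

    @property
    def tts(self) -> pd.Series:
        """0-based position of the last transcribed base."""
        g = self.genes
        pos = np.where(g["strand"].values == "+", g["end"].values - 1, g["start"].values)
        return pd.Series(pos, index=g["gene_id"].values, name="tts")

    def promoter_windows(self, upstream: int = PROMOTER_ANNOTATION[0],
                         downstream: int = PROMOTER_ANNOTATION[1]) -> pd.DataFrame:
        """Stranded promoter windows as 0-based half-open intervals.

        ``downstream`` is the last *included* offset relative to the TSS, so
        ``(1000, 100)`` spans -1000..+100 inclusive and ``(1000, -1)`` spans
        the kilobase strictly upstream of the TSS.
        """
        g = self.genes
        tss = self.tss.values
        plus = g["strand"].values == "+"
        start = np.where(plus, tss - upstream, tss - downstream)
        end = np.where(plus, tss + downstream + 1, tss + upstream + 1)
        return pd.DataFrame({
            "gene_id": g["gene_id"].values,
            "chrom": g["chrom"].values,
            "start": start,
            "end": end,
            "strand": g["strand"].values,
        })

    # -- GTF round trip ------------------------------------------------------

    def to_gtf(self, path) -> None:
        """Write gene and exon features as GTF (1-based, closed intervals)."""
        lines = []
        exons_by_gene = {gid: df for gid, df in self.exons.groupby("gene_id")}
        for row in self.genes.itertuples(index=False):
            attrs = (f'gene_id "{row.gene_id}"; utr5_len "{int(row.utr5_len)}"; '
                     f'utr3_len "{int(row.utr3_len)}";')
            lines.append("\t".join([
                row.chrom, "kbcascade", "gene", str(row.start + 1), str(row.end),
                ".", row.strand, ".", attrs]))
            ex = exons_by_gene.get(row.gene_id)
            if ex is not None:
                for e in ex.sort_values("start").itertuples(index=False):
                    lines.append("\t".join([
                        row.chrom, "kbcascade", "exon", str(e.start + 1), str(e.end),
                        ".", row.strand, ".", f'gene_id "{row.gene_id}";']))
        header = ""
        if self.chrom_sizes:
            header = "".join(f"#!chrom-size {c} {n}\n" for c, n in sorted(self.chrom_sizes.items()))
        with open(path, "w") as fh:
            fh.write(header + "\n".join(lines) + "\n")

    @classmethod
    def from_gtf(cls, path) -> "GeneModels":
        chrom_sizes: dict[str, int] = {}
        genes, exons = [], []
        attr_re = re.compile(r'(\w+) "([^"]*)"')
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    m = re.match(r"#!chrom-size (\S+) (\d+)", line)
                    if m:
                        chrom_sizes[m.group(1)] = int(m.group(2))
                    continue
                fields = line.split("\t")
                chrom, _, feature, start, end, _, strand, _, attr = fields
                attrs = dict(attr_re.findall(attr))
                rec = {"gene_id": attrs["gene_id"], "chrom": chrom,
                       "start": int(start) - 1, "end": int(end), "strand": strand}
                if feature == "gene":
                    rec["utr5_len"] = int(attrs.get("utr5_len", 0))
                    rec["utr3_len"] = int(attrs.get("utr3_len", 0))
                    genes.append(rec)
                elif feature == "exon":
                    exons.append({"gene_id": attrs["gene_id"],
                                  "start": int(start) - 1, "end": int(end)})
        return cls(pd.DataFrame(genes), pd.DataFrame(exons) if exons else None,
                   chrom_sizes or None)
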