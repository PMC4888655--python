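"""Readers and writers for the plain-text formats the pipeline exchanges.

GTF is 1-based closed on disk and converted to the package's 0-based
half-open convention on ingest; BED and bedGraph are already half-open.
Site tables are 4-column TSVs with a header (chrom, pos, strand, count);
gzip-compressed inputs are handled transparently by pandas.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .core import GeneModel, SiteTable

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
        rows.append((g.chrom, "hmcscan", "gene", g.start + 1, g.end, ".", g.strand, ".", attrs))
        rows.append((g.chrom, "hmcscan", "transcript", g.start + 1, g.end, ".", g.strand, ".", attrs))
        for s, e in g.exons:
            rows.append((g.chrom, "hmcscan", "exon", s + 1, e, ".", g.strand, ".", attrs))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False, quoting=3)


def read_gtf(path) -> list[GeneModel]:
    """Load genes from GTF, keeping one canonical (longest) transcript each."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"],
        dtype={"chrom": str},
    )
    df["gene_id"] = df["attrs"].str.extract(r'gene_id "([^"]*)"')
    df["transcript_id"] = df["attrs"].str.extract(r'transcript_id "([^"]*)"')
    genes: list[GeneModel] = []
    for gid, sub in df.groupby("gene_id", sort=True):
        ex = sub[sub["feature"] == "exon"]
        if len(ex) and ex["transcript_id"].notna().any():
            spans = ex.groupby("transcript_id").agg(s=("start", "min"), e=("end", "max"))
            best = (spans["e"] - spans["s"]).idxmax()
            ex = ex[ex["transcript_id"] == best]
        exons = [(int(s) - 1, int(e)) for s, e in zip(ex["start"], ex["end"])]
        if exons:
            start, end = min(s for s, _ in exons), max(e for _, e in exons)
        else:
            row = sub.iloc[0]
            start, end = int(row["start"]) - 1, int(row["end"])
        genes.append(GeneModel(
            gene_id=str(gid), chrom=str(sub["chrom"].iloc[0]),
            strand=str(sub["strand"].iloc[0]), start=start, end=end, exons=exons,
        ))
    return genes


def read_bed12(path) -> list[GeneModel]:
    names = ["chrom", "start", "end", "name", "score", "strand",
             "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    genes = []
    for _, r in df.iterrows():
        sizes = [int(x) for x in str(r["blockSizes"]).rstrip(",").split(",")]
        offs = [int(x) for x in str(r["blockStarts"]).rstrip(",").split(",")]
        exons = [(int(r["start"]) + o, int(r["start"]) + o + s) for o, s in zip(offs, sizes)]
        genes.append(GeneModel(
            gene_id=str(r["name"]), chrom=str(r["chrom"]), strand=str(r["strand"]),
            start=int(r["start"]), end=int(r["end"]), exons=exons,
        ))
    return genes


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end")) -> None:
    df.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = list(names) + [f"col{i}" for i in range(len(names), df.shape[1])]
    return df


def write_site_table(table: SiteTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_site_table(path, library_id: str | None = None, cell_type: str = "unknown") -> SiteTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return SiteTable(df, library_id=library_id or Path(path).stem, cell_type=cell_type)


def write_expression(df: pd.DataFrame, path) -> None:
    df[["gene_id", "fpkm"]].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "fpkm"} <= set(df.columns):
        raise ValueError(f"{path}: expression table needs gene_id and fpkm columns")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"], dtype={"chrom": str})


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            chrom, size = line.split()
            out[chrom] = int(size)
    return out


def write_truth(truth_dict: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
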