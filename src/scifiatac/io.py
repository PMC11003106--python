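"""Readers for the plain-text interchange formats used by the pipeline."""

from __future__ import annotations

import os

import pandas as pd


def read_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Gene intervals from a GFF3 file or a TSV with a header line.

    GFF3 ``gene`` features are converted from 1-based closed to 0-based
    half-open coordinates; a TSV must carry chrom, start, end, strand.
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or (
        len(first.rstrip("\n").split("\t")) == 9 and not first.startswith("chrom")
    ):
        gff = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=[
                "seqid", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes",
            ],
        )
        genes = gff[gff["type"] == "gene"]
        return pd.DataFrame(
            {
                "chrom": genes["seqid"].astype(str).to_numpy(),
                "start": genes["start"].to_numpy() - 1,
                "end": genes["end"].to_numpy(),
                "strand": genes["strand"].to_numpy(),
            }
        )
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_acrs(path: str | os.PathLike) -> pd.DataFrame:
    """ACR intervals from headerless BED3+ (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def read_snps(path: str | os.PathLike) -> pd.DataFrame:
    """SNP panel TSV: chrom, pos, ref, alt, one allele column per genotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"SNP table needs columns {sorted(required)}")
    return df


def read_chroms(path: str | os.PathLike) -> tuple[dict[str, int], dict[str, int]]:
    """Chromosome-size TSV (chrom, length, is_organelle) -> (nuclear, organelle)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    nuc = {
        r.chrom: int(r.length)
        for r in df.itertuples()
        if not getattr(r, "is_organelle", 0)
    }
    org = {
        r.chrom: int(r.length)
        for r in df.itertuples()
        if getattr(r, "is_organelle", 0)
    }
    return nuc, org
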