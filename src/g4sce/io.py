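"""Readers and writers for the plain-text formats used throughout.

Coordinates are 0-based half-open (BED convention) in every table.
Writers emit deterministic ordering so that identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .genome import GenomeIndex

READ_COLUMNS = ["chrom", "start", "end", "label", "hap", "cell"]
SCE_COLUMNS = ["chrom", "start", "end", "cell", "homolog", "resolution"]


def read_fasta(path) -> dict[str, str]:
    """Load a (possibly line-wrapped, multi-record) FASTA into memory."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path, names: list[str] | None = None) -> pd.DataFrame:
    base = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = names or base[: df.shape[1]]
    df.columns = cols[: df.shape[1]]
    return df


def write_bed(path, df: pd.DataFrame, columns: list[str] | None = None) -> None:
    cols = columns or list(df.columns)
    out = df[cols].sort_values(cols[:3], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads(path) -> pd.DataFrame:
    """Directional single-cell reads: chrom, start, end, W|C, haplotype, cell id."""
    df = pd.read_csv(path, sep="\t", names=READ_COLUMNS, header=0, dtype={"hap": str})
    df["hap"] = df["hap"].fillna(".")
    return df


def write_reads(path, reads: pd.DataFrame) -> None:
    out = reads[READ_COLUMNS].sort_values(["cell", "chrom", "start", "end", "label"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    """Gene table: gene_id, chrom, tss, tes, strand (tab separated, with header)."""
    return pd.read_csv(path, sep="\t")


def write_genes(path, genes: pd.DataFrame) -> None:
    genes.sort_values(["chrom", "tss", "gene_id"], kind="mergesort").to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(path, expression: pd.DataFrame) -> None:
    expression.sort_values("gene_id", kind="mergesort").to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def genome_index_to_dict(gi: GenomeIndex) -> dict:
    return {
        "lengths": dict(gi.lengths),
        "gaps": {c: gi.gaps[c].tolist() for c in gi.lengths},
    }


def genome_index_from_dict(d: dict) -> GenomeIndex:
    gaps = {c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in d["gaps"].items()}
    return GenomeIndex(lengths={c: int(v) for c, v in d["lengths"].items()}, gaps=gaps)


def write_gaps_bed(path, gi: GenomeIndex) -> None:
    rows = []
    for chrom in gi.lengths:
        for s, e in gi.gaps[chrom]:
            rows.append((chrom, int(s), int(e)))
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(path, sep="\t", header=False, index=False)


def read_gaps_bed(path, lengths: dict[str, int]) -> GenomeIndex:
    df = read_bed(path, names=["chrom", "start", "end"])
    gaps = {
        c: g[["start", "end"]].to_numpy(dtype=np.int64)
        for c, g in df.groupby("chrom", sort=False)
    }
    return GenomeIndex(lengths=lengths, gaps=gaps)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
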