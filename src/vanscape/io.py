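"""Readers and writers for the plain-text formats shared between modules.

All genomic intervals are 0-based, half-open in memory.  The only format
with 1-based coordinates on disk is the bismark-style CX report, which is
converted on read and write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONTEXTS = ("CG", "CHG", "CHH")

CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide"]

ANNOTATION_COLUMNS = ["chrom", "start", "end", "strand", "te_id", "family", "segment_type"]


class CxReportError(ValueError):
    """Raised for malformed CX report lines (message names the line)."""


@dataclass
class TECopy:
    """An annotated TE interval with its coding / non-coding sub-segments."""

    te_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    #: (start, end, segment_type) tuples covering [start, end)
    segments: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{seq_id: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# CX report (bismark dialect): chrom, 1-based pos, strand, meth, unmeth,
# context, trinucleotide
# ---------------------------------------------------------------------------

def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Parse a CX report into a DataFrame sorted by (chrom, pos).

    Positions are converted to 0-based.  Malformed lines raise
    :class:`CxReportError` naming the offending line number.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=CX_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
            header=None,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CX_COLUMNS).astype({"pos": int, "meth": int, "unmeth": int})

    for col in ("pos", "meth", "unmeth"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            raise CxReportError(f"line {bad.idxmax() + 1}: non-numeric value in column '{col}'")
        df[col] = coerced.astype(int)

    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 1
        raise CxReportError(f"line {line}: unknown context {df['context'].iloc[line - 1]!r}")
    neg = (df["meth"] < 0) | (df["unmeth"] < 0)
    if neg.any():
        raise CxReportError(f"line {int(neg.idxmax()) + 1}: negative count")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise CxReportError(f"line {int(bad_strand.idxmax()) + 1}: bad strand")

    df["pos"] = df["pos"] - 1  # to 0-based
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_cx_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a 0-based in-memory cytosine table as a 1-based CX report."""
    out = df[CX_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TE annotation: TSV of chrom, start, end, strand, te_id, family, segment_type
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=ANNOTATION_COLUMNS, header=None,
                     dtype={"chrom": str, "te_id": str, "family": str})
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def annotation_to_copies(df: pd.DataFrame) -> list[TECopy]:
    """Collapse per-segment rows into one :class:`TECopy` per te_id."""
    copies = []
    for te_id, grp in df.groupby("te_id", sort=False):
        grp = grp.sort_values("start")
        copies.append(
            TECopy(
                te_id=str(te_id),
                chrom=str(grp["chrom"].iloc[0]),
                start=int(grp["start"].min()),
                end=int(grp["end"].max()),
                strand=str(grp["strand"].iloc[0]),
                family=str(grp["family"].iloc[0]),
                segments=[(int(r.start), int(r.end), str(r.segment_type)) for r in grp.itertuples()],
            )
        )
    copies.sort(key=lambda c: (c.chrom, c.start))
    return copies


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "depth"],
                     header=None, dtype={"chrom": str})
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "depth"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file with up to 6 columns (missing ones filled)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JSON helpers (ground truth, manifests)
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
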