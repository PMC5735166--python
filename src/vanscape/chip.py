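"""ChIP coverage normalisation, fixed-bin enrichment and summit annotation.

Peak calling is upstream: this module consumes bedGraph coverage for the
immunoprecipitated (IP) and input libraries plus peak summits, normalises
to counts per million (CPM), summarises IP/input enrichment in fixed
genomic tiles (10 kb by default) and relates summits to the TE annotation
(which TE, which family, coding or non-coding segment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class CoverageTrack:
    """A sorted, non-overlapping interval coverage track (bedGraph semantics)."""

    intervals: pd.DataFrame  # chrom, start, end, depth
    library_size: float | None = None

    def __post_init__(self):
        df = self.intervals
        if (df["depth"] < 0).any():
            raise ValueError("negative depth")
        if self.library_size is None:
            # fall back to total track mass so CPM is still well defined
            self.library_size = float(
                (df["depth"] * (df["end"] - df["start"])).sum())

    def mass(self) -> float:
        df = self.intervals
        return float((df["depth"] * (df["end"] - df["start"])).sum())


@dataclass
class BinEnrichment:
    chrom: str
    start: int
    end: int
    ip_signal: float
    input_signal: float
    ratio: float
    partial: bool = False  # terminal bin shorter than the bin size


def normalize_cpm(track: CoverageTrack) -> CoverageTrack:
    """Scale depths by 1e6 / library_size (counts per million mapped reads)."""
    if not track.library_size or track.library_size <= 0:
        raise ValueError("library_size must be positive for CPM normalisation")
    df = track.intervals.copy()
    df["depth"] = df["depth"] * (1e6 / track.library_size)
    return replace(track, intervals=df, library_size=track.library_size)


def _bin_means(df: pd.DataFrame, chrom: str, n_bins: int, bin_size: int,
               chrom_size: int) -> np.ndarray:
    """Mean depth per fixed bin, weighting intervals by overlap length."""
    mass = np.zeros(n_bins)
    sub = df[df["chrom"] == chrom]
    for iv in sub.itertuples():
        b0, b1 = iv.start // bin_size, (iv.end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(iv.start, b * bin_size)
            hi = min(iv.end, (b + 1) * bin_size)
            if b < n_bins and hi > lo:
                mass[b] += iv.depth * (hi - lo)
    widths = np.minimum((np.arange(n_bins) + 1) * bin_size, chrom_size) \
        - np.arange(n_bins) * bin_size
    return mass / widths


def bin_enrichment(ip: CoverageTrack, input_: CoverageTrack, bin_size: int = 10_000,
                   pseudocount: float = 0.5,
                   mask: pd.DataFrame | None = None) -> list[BinEnrichment]:
    """Per-tile mean CPM for IP and input with a pseudocounted ratio.

    Tiles overlapping any ``mask`` interval (BED-like frame) are excluded
    — used for regions such as centromeric satellite repeats whose signal
    is unstable in both libraries.  Terminal partial tiles are retained and
    flagged.
    """
    ip_n, in_n = normalize_cpm(ip), normalize_cpm(input_)
    chrom_sizes: dict[str, int] = {}
    for tr in (ip_n, in_n):
        for chrom, grp in tr.intervals.groupby("chrom"):
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), int(grp["end"].max()))
    out: list[BinEnrichment] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_bins = -(-size // bin_size)
        ip_mean = _bin_means(ip_n.intervals, chrom, n_bins, bin_size, size)
        in_mean = _bin_means(in_n.intervals, chrom, n_bins, bin_size, size)
        for b in range(n_bins):
            start, end = b * bin_size, min((b + 1) * bin_size, size)
            if mask is not None:
                mk = mask[(mask["chrom"] == chrom) & (mask["start"] < end)
                          & (mask["end"] > start)]
                if len(mk):
                    continue
            ratio = (ip_mean[b] + pseudocount) / (in_mean[b] + pseudocount)
            out.append(BinEnrichment(chrom, start, end, float(ip_mean[b]),
                                     float(in_mean[b]), float(ratio),
                                     partial=(end - start) < bin_size))
    return out


def enrichment_to_frame(bins: list[BinEnrichment]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in bins],
                        columns=["chrom", "start", "end", "ip_signal",
                                 "input_signal", "ratio", "partial"])


def summit_annotation(summits: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Label each summit with its containing TE, family and segment type.

    Containment is half-open on the summit's start coordinate; summits
    outside every TE get te_id/family/segment_type = 'none'.
    """
    rows = []
    for s in summits.itertuples():
        seg = annotation[(annotation["chrom"] == s.chrom)
                         & (annotation["start"] <= s.start)
                         & (s.start < annotation["end"])]
        if len(seg):
            seg = seg.iloc[0]
            rows.append({"chrom": s.chrom, "pos": s.start, "name": getattr(s, "name", "."),
                         "te_id": seg["te_id"], "family": seg["family"],
                         "segment_type": seg["segment_type"]})
        else:
            rows.append({"chrom": s.chrom, "pos": s.start, "name": getattr(s, "name", "."),
                         "te_id": "none", "family": "none", "segment_type": "none"})
    return pd.DataFrame(rows, columns=["chrom", "pos", "name", "te_id",
                                       "family", "segment_type"])
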