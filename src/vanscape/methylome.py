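"""Differential DNA-methylation summaries for TE anti-silencing analysis.

Works from per-cytosine count tables (bismark-style CX reports, parsed by
:func:`vanscape.io.read_cx_report` into 0-based DataFrames).  Methylation
levels are always pooled counts, ``sum(meth) / sum(meth + unmeth)``, never
means of per-site ratios, and are pooled across strands within a context.
Ratios over zero coverage propagate as NaN, never as 0.

The hypomethylation significance statistic for a TE is

    (Mn/Cn - Mt/Ct) / (1/sqrt(Cn) + 1/sqrt(Ct))

where Mn, Cn (Mt, Ct) are methylated and total cytosine read counts in the
non-transgenic (transgenic) condition.  It weighs the methylation-ratio
change by the square root of the read counts, so it is positive when the
transgenic sample is hypomethylated and grows with evidence: scaling all
four counts by k^2 at fixed ratios scales the value by k.

CG-DMRs are 100-bp windows in which CG methylation drops by at least 0.5,
merged when adjacent or separated by a single non-qualifying window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONTEXTS, TECopy, read_cx_report  # noqa: F401  (re-exported parser)


@dataclass
class MethylationChange:
    """Pooled per-TE, per-context counts for the two conditions."""

    te_id: str
    context: str
    Mn: int
    Cn: int
    Mt: int
    Ct: int

    @property
    def value(self) -> float:
        return significance_value(self.Mn, self.Cn, self.Mt, self.Ct)


@dataclass
class FractionalProfile:
    """Sliding-window methylation profile over 100 length fractions of a TE.

    ``values`` has one entry per window of ``window`` consecutive fractions
    (94 entries for the defaults); entries are NaN where no cytosine of the
    context is covered.  Flank profiles use the same fraction size and are
    stored 5'->3' of the TE strand (left = upstream of the TE 5' end).
    """

    te_id: str
    context: str
    values: np.ndarray
    covered: np.ndarray
    flank_left: np.ndarray = field(default_factory=lambda: np.array([]))
    flank_right: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class DMR:
    """A called CG differentially-methylated region (hypomethylation)."""

    chrom: str
    start: int
    end: int
    context: str
    n_windows: int
    wt_level: float
    treated_level: float

    @property
    def diff(self) -> float:
        return self.wt_level - self.treated_level


# ---------------------------------------------------------------------------
# Significance statistic
# ---------------------------------------------------------------------------

def significance_value(Mn: float, Cn: float, Mt: float, Ct: float) -> float:
    """Hypomethylation significance (Mn/Cn - Mt/Ct)/(1/sqrt(Cn) + 1/sqrt(Ct)).

    Undefined (NaN) when either total count is zero.
    """
    if Cn <= 0 or Ct <= 0:
        return math.nan
    return (Mn / Cn - Mt / Ct) / (1.0 / math.sqrt(Cn) + 1.0 / math.sqrt(Ct))


# ---------------------------------------------------------------------------
# Pooling helpers
# ---------------------------------------------------------------------------

def _pool(records: pd.DataFrame, chrom: str, start: int, end: int,
          context: str | None = None) -> tuple[int, int]:
    """(meth, total) read counts pooled over [start, end) on both strands."""
    m = (records["chrom"] == chrom) & (records["pos"] >= start) & (records["pos"] < end)
    if context is not None:
        m &= records["context"] == context
    sub = records.loc[m]
    meth = int(sub["meth"].sum())
    return meth, meth + int(sub["unmeth"].sum())


def _ratio(meth: np.ndarray, total: np.ndarray) -> np.ndarray:
    out = np.full(np.shape(total), np.nan, dtype=float)
    nz = np.asarray(total) > 0
    out[nz] = np.asarray(meth, dtype=float)[nz] / np.asarray(total, dtype=float)[nz]
    return out


def _fraction_sums(records: pd.DataFrame, chrom: str, start: int, end: int,
                   context: str, n_fractions: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-fraction (meth, total) sums over equal length fractions of [start, end)."""
    m = ((records["chrom"] == chrom) & (records["pos"] >= start)
         & (records["pos"] < end) & (records["context"] == context))
    sub = records.loc[m]
    length = end - start
    idx = ((sub["pos"].to_numpy() - start) * n_fractions // length).astype(int)
    meth = np.bincount(idx, weights=sub["meth"].to_numpy(), minlength=n_fractions)
    total = meth + np.bincount(idx, weights=sub["unmeth"].to_numpy(), minlength=n_fractions)
    return meth, total


def _window_ratio(meth: np.ndarray, total: np.ndarray, window: int):
    """Sliding pooled ratios over ``window`` consecutive entries."""
    kernel = np.ones(window)
    wm = np.convolve(meth, kernel, mode="valid")
    wt = np.convolve(total, kernel, mode="valid")
    return _ratio(wm, wt), wt


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def fractional_profile(records: pd.DataFrame, te: TECopy, context: str = "CG",
                       n_fractions: int = 100, window: int = 7,
                       flank_bp: int | None = None) -> FractionalProfile | None:
    """Per-TE methylation profile over sliding windows of length fractions.

    The TE is split into ``n_fractions`` equal fractions; each value pools
    counts over ``window`` consecutive fractions.  Profiles are oriented
    5'->3' of the TE strand.  Flanks (default: the TE's own length each
    side) are profiled with the same fraction size.  Returns None as an
    explicit skip marker for TEs shorter than ``n_fractions``.
    """
    if te.length < n_fractions:
        return None
    flank = te.length if flank_bp is None else flank_bp

    def prof(start, end):
        meth, total = _fraction_sums(records, te.chrom, start, end, context, n_fractions)
        if te.strand == "-":
            meth, total = meth[::-1], total[::-1]
        return _window_ratio(meth, total, window)

    values, covered = prof(te.start, te.end)
    up, _ = prof(te.start - flank, te.start)
    down, _ = prof(te.end, te.end + flank)
    left, right = (down, up) if te.strand == "-" else (up, down)
    return FractionalProfile(te.te_id, context, values, covered, left, right)


def running_profile(records: pd.DataFrame, span: tuple[str, int, int] | None = None,
                    k: int = 5, context: str | None = None) -> pd.DataFrame:
    """Per-cytosine pooled ratio over each cytosine and its k-1 successors.

    Successors are the next cytosines of the same context in position
    order; the last k-1 positions get NaN (a full window is required).
    Returns columns chrom, pos, context, value.
    """
    df = records
    if span is not None:
        chrom, start, end = span
        df = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
    if context is not None:
        df = df[df["context"] == context]
    out = []
    for (chrom, ctx), grp in df.groupby(["chrom", "context"], sort=True):
        grp = grp.sort_values("pos")
        meth = grp["meth"].to_numpy(dtype=float)
        total = meth + grp["unmeth"].to_numpy(dtype=float)
        n = len(grp)
        values = np.full(n, np.nan)
        if n >= k:
            wm = np.convolve(meth, np.ones(k), mode="valid")
            wt = np.convolve(total, np.ones(k), mode="valid")
            values[: n - k + 1] = _ratio(wm, wt)
        out.append(pd.DataFrame({"chrom": chrom, "pos": grp["pos"].to_numpy(),
                                 "context": ctx, "value": values}))
    if not out:
        return pd.DataFrame(columns=["chrom", "pos", "context", "value"])
    return pd.concat(out, ignore_index=True)


def per_te_changes(wt: pd.DataFrame, treated: pd.DataFrame, annotation: pd.DataFrame,
                   contexts=CONTEXTS, min_length: int = 1000) -> pd.DataFrame:
    """Pooled methylation change and significance per (TE, context).

    Only TEs of at least ``min_length`` bp are reported.  TEs with no
    covered cytosines in a context get a NaN value (row still emitted).
    """
    tes = (annotation.groupby("te_id", sort=False)
           .agg(chrom=("chrom", "first"), start=("start", "min"),
                end=("end", "max"), family=("family", "first"))
           .reset_index())
    rows = []
    for te in tes.itertuples():
        if te.end - te.start < min_length:
            continue
        for ctx in contexts:
            Mn, Cn = _pool(wt, te.chrom, te.start, te.end, ctx)
            Mt, Ct = _pool(treated, te.chrom, te.start, te.end, ctx)
            rows.append({"te_id": te.te_id, "family": te.family, "context": ctx,
                         "Mn": Mn, "Cn": Cn, "Mt": Mt, "Ct": Ct,
                         "value": significance_value(Mn, Cn, Mt, Ct)})
    return pd.DataFrame(rows, columns=["te_id", "family", "context",
                                       "Mn", "Cn", "Mt", "Ct", "value"])


# ---------------------------------------------------------------------------
# CG-DMR calling
# ---------------------------------------------------------------------------

def _window_table(records: pd.DataFrame, chrom: str, n_windows: int,
                  window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (meth, total, covered CG site count) for one chromosome."""
    sub = records[(records["chrom"] == chrom) & (records["context"] == "CG")]
    idx = (sub["pos"].to_numpy() // window).astype(int)
    keep = idx < n_windows
    idx = idx[keep]
    meth = np.bincount(idx, weights=sub["meth"].to_numpy()[keep], minlength=n_windows)
    unmeth = np.bincount(idx, weights=sub["unmeth"].to_numpy()[keep], minlength=n_windows)
    site_total = sub["meth"].to_numpy()[keep] + sub["unmeth"].to_numpy()[keep]
    covered = np.bincount(idx[site_total > 0], minlength=n_windows)
    return meth, meth + unmeth, covered


def call_cg_dmrs(wt: pd.DataFrame, treated: pd.DataFrame, window: int = 100,
                 min_diff: float = 0.5, min_covered_sites: int = 4,
                 chrom_sizes: dict[str, int] | None = None) -> list[DMR]:
    """Call hypomethylated CG-DMRs in fixed, 0-anchored windows.

    A window is a seed when both conditions have at least
    ``min_covered_sites`` covered CG positions in it and the pooled CG
    level drops by at least ``min_diff`` (wt - treated).  Runs of seed
    windows separated by at most one non-seed window are merged into one
    DMR spanning from the first to the last seed window (bridged gaps
    included).  Reported levels pool counts over the seed windows.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    chroms = sorted(set(wt["chrom"]) | set(treated["chrom"]))
    dmrs: list[DMR] = []
    for chrom in chroms:
        if chrom_sizes and chrom in chrom_sizes:
            size = chrom_sizes[chrom]
        else:
            pos = pd.concat([wt.loc[wt["chrom"] == chrom, "pos"],
                             treated.loc[treated["chrom"] == chrom, "pos"]])
            if pos.empty:
                continue
            size = int(pos.max()) + 1
        n_windows = -(-size // window)
        wm, wtot, wcov = _window_table(wt, chrom, n_windows, window)
        tm, ttot, tcov = _window_table(treated, chrom, n_windows, window)
        wt_level = _ratio(wm, wtot)
        tr_level = _ratio(tm, ttot)
        with np.errstate(invalid="ignore"):
            seed = ((wcov >= min_covered_sites) & (tcov >= min_covered_sites)
                    & ((wt_level - tr_level) >= min_diff))
        seed_idx = np.nonzero(seed)[0]
        if len(seed_idx) == 0:
            continue
        groups: list[list[int]] = [[int(seed_idx[0])]]
        for i in seed_idx[1:]:
            if int(i) - groups[-1][-1] <= 2:  # adjacent or one-window gap
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        for grp in groups:
            sm, st = wm[grp].sum(), wtot[grp].sum()
            tm_, tt = tm[grp].sum(), ttot[grp].sum()
            dmrs.append(DMR(chrom, grp[0] * window, min((grp[-1] + 1) * window, size),
                            "CG", len(grp),
                            float(sm / st), float(tm_ / tt)))
    return dmrs


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": d.chrom, "start": d.start, "end": d.end, "name": "DMR",
          "score": d.n_windows, "strand": ".", "n_windows": d.n_windows,
          "wt_level": d.wt_level, "treated_level": d.treated_level,
          "diff": d.diff} for d in dmrs],
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "n_windows", "wt_level", "treated_level", "diff"])


# ---------------------------------------------------------------------------
# Summit-centred metaplots
# ---------------------------------------------------------------------------

def metaplot(records: pd.DataFrame, summits: pd.DataFrame, bin: int = 500,
             step: int = 50, span: int = 5000, contexts=CONTEXTS) -> pd.DataFrame:
    """Mean methylation around summits in sliding fixed-width bins.

    For offsets covering [-span, span] at ``step`` spacing (bin centres, so
    every bin lies fully inside the span), the value at an offset pools
    counts over the [offset - bin/2, offset + bin/2) window of every
    summit.  Returns a DataFrame indexed by offset with one column per
    context; empty if there are no summits.
    """
    offsets = np.arange(-span + bin // 2, span - bin // 2 + 1, step)
    if summits.empty:
        return pd.DataFrame(columns=list(contexts)).rename_axis("offset")
    out = {}
    for ctx in contexts:
        sub = records[records["context"] == ctx]
        meth_tot = np.zeros(len(offsets))
        all_tot = np.zeros(len(offsets))
        for chrom, grp in sub.groupby("chrom", sort=True):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(grp["meth"].to_numpy())])
            ct = np.concatenate([[0], np.cumsum((grp["meth"] + grp["unmeth"]).to_numpy())])
            s_here = summits[summits["chrom"] == chrom]
            for summit in s_here["start"].to_numpy():
                lo = np.searchsorted(pos, summit + offsets - bin // 2, side="left")
                hi = np.searchsorted(pos, summit + offsets + bin // 2, side="left")
                meth_tot += cm[hi] - cm[lo]
                all_tot += ct[hi] - ct[lo]
        out[ctx] = _ratio(meth_tot, all_tot)
    return pd.DataFrame(out, index=pd.Index(offsets, name="offset"))
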