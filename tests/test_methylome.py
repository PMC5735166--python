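"""Methylome summaries against brute-force pooling and merge oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vanscape.io import TECopy
from vanscape.methylome import (DMR, call_cg_dmrs, dmrs_to_frame,
                                fractional_profile, metaplot, per_te_changes,
                                running_profile, significance_value)


def records(rows):
    """rows: (pos, meth, unmeth[, context[, chrom]])."""
    out = []
    for r in rows:
        pos, meth, unmeth = r[:3]
        ctx = r[3] if len(r) > 3 else "CG"
        chrom = r[4] if len(r) > 4 else "chr1"
        out.append({"chrom": chrom, "pos": pos, "strand": "+", "meth": meth,
                    "unmeth": unmeth, "context": ctx, "trinucleotide": "CGA"})
    return pd.DataFrame(out)


def random_records(rng, n, span, context="CG", chrom="chr1"):
    pos = np.sort(rng.choice(span, size=n, replace=False))
    total = rng.poisson(20, n)
    meth = rng.binomial(total, rng.uniform(0, 1, n))
    return pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+",
                         "meth": meth, "unmeth": total - meth,
                         "context": context, "trinucleotide": "CGA"})


# ---------------------------------------------------------------------------
# Significance statistic
# ---------------------------------------------------------------------------

class TestSignificance:
    @pytest.mark.parametrize("counts,expected", [
        ((50, 100, 50, 100), 0.0),
        ((90, 100, 10, 100), 4.0),
        ((360, 400, 40, 400), 8.0),
    ])
    def test_hand_checked_values(self, counts, expected):
        assert significance_value(*counts) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_is_nan_not_zero(self):
        assert math.isnan(significance_value(0, 0, 5, 10))
        assert math.isnan(significance_value(5, 10, 0, 0))

    @given(Mn=st.integers(0, 100), Cn=st.integers(1, 100), Mt=st.integers(0, 100))
    def test_antisymmetric_at_equal_totals(self, Mn, Cn, Mt):
        Mn, Mt = min(Mn, Cn), min(Mt, Cn)
        a = significance_value(Mn, Cn, Mt, Cn)
        b = significance_value(Mt, Cn, Mn, Cn)
        assert a == pytest.approx(-b, abs=1e-12)

    @given(Mn=st.integers(0, 50), Cn=st.integers(1, 50), Mt=st.integers(0, 50),
           Ct=st.integers(1, 50), k=st.integers(1, 5))
    def test_scaling_law(self, Mn, Cn, Mt, Ct, k):
        """Multiplying all counts by k^2 multiplies the value by k."""
        Mn, Mt = min(Mn, Cn), min(Mt, Ct)
        base = significance_value(Mn, Cn, Mt, Ct)
        scaled = significance_value(Mn * k * k, Cn * k * k, Mt * k * k, Ct * k * k)
        assert scaled == pytest.approx(k * base, abs=1e-9)


# ---------------------------------------------------------------------------
# Fractional profiles
# ---------------------------------------------------------------------------

def brute_force_windows(recs, te, context, n_fractions, window):
    """Naive per-base accumulation into fractions, then explicit windows."""
    L = te.length
    meth = np.zeros(n_fractions)
    total = np.zeros(n_fractions)
    for r in recs.itertuples():
        if r.chrom != te.chrom or not (te.start <= r.pos < te.end) \
                or r.context != context:
            continue
        i = (r.pos - te.start) * n_fractions // L
        meth[i] += r.meth
        total[i] += r.meth + r.unmeth
    if te.strand == "-":
        meth, total = meth[::-1], total[::-1]
    vals = []
    for i in range(n_fractions - window + 1):
        m, t = meth[i:i + window].sum(), total[i:i + window].sum()
        vals.append(m / t if t else math.nan)
    return np.array(vals)


class TestFractionalProfile:
    def test_uniform_methylation_gives_constant_profile(self):
        te = TECopy("te1", "chr1", 0, 1000, "+", "FAM0")
        recs = records([(p, 8, 2) for p in range(0, 1000, 10)])
        prof = fractional_profile(recs, te)
        assert prof.values.shape == (94,)
        assert np.allclose(prof.values, 0.8)

    def test_matches_brute_force_enumeration(self, rng):
        te = TECopy("te1", "chr1", 200, 1200, "-", "FAM0")
        recs = random_records(rng, 300, range(0, 2400))
        prof = fractional_profile(recs, te, flank_bp=500)
        expect = brute_force_windows(recs, te, "CG", 100, 7)
        np.testing.assert_allclose(prof.values, expect)

    def test_window_defined_from_partial_coverage(self):
        te = TECopy("te1", "chr1", 0, 1000, "+", "FAM0")
        # fraction 0 covered, fractions 1-6 empty: window 0 still defined
        recs = records([(5, 3, 1)])
        prof = fractional_profile(recs, te)
        assert prof.values[0] == pytest.approx(0.75)
        assert math.isnan(prof.values[10])

    def test_short_te_skipped(self):
        te = TECopy("tiny", "chr1", 0, 50, "+", "FAM0")
        assert fractional_profile(records([(5, 1, 1)]), te) is None

    def test_minus_strand_orientation(self):
        te = TECopy("te1", "chr1", 0, 1000, "-", "FAM0")
        # methylated only in the first 100 bp of genome = TE 3' end
        recs = records([(p, 5, 0) for p in range(0, 100, 5)])
        prof = fractional_profile(recs, te)
        assert prof.values[-1] == pytest.approx(1.0)
        assert math.isnan(prof.values[0])


class TestRunningProfile:
    def test_fully_methylated_first_window(self):
        recs = records([(p, 1, 0) for p in (0, 5, 9, 14, 20)])
        out = running_profile(recs, k=5)
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_alternating_pooling_oracle(self):
        # alternating fully-meth / fully-unmeth, equal coverage 2 per site
        rows = [(i * 3, 2 if i % 2 == 0 else 0, 0 if i % 2 == 0 else 2)
                for i in range(12)]
        out = running_profile(records(rows), k=5)
        # windows starting at even index pool 3 meth sites of 5 -> 0.6
        assert out["value"].iloc[0] == pytest.approx(0.6)
        assert out["value"].iloc[1] == pytest.approx(0.4)

    def test_too_few_cytosines_all_undefined(self):
        recs = records([(p, 1, 1) for p in (0, 3, 6, 9)])
        out = running_profile(recs, k=5)
        assert out["value"].isna().all()


# ---------------------------------------------------------------------------
# Per-TE changes
# ---------------------------------------------------------------------------

class TestPerTeChanges:
    def test_min_length_filters(self, study):
        ann = study["annotation"]
        table = per_te_changes(study["wt"], study["treated"], ann, min_length=10**6)
        assert table.empty
        table = per_te_changes(study["wt"], study["treated"], ann, min_length=1000)
        assert set(table["te_id"]) == set(ann["te_id"])

    def test_targeted_family_has_largest_chh_values(self, study):
        table = per_te_changes(study["wt"], study["treated"], study["annotation"])
        truth = study["truth"]
        chh = table[table["context"] == "CHH"]
        targeted = chh[chh["family"] == truth.targeted_family]["value"]
        others = chh[chh["family"] != truth.targeted_family]["value"]
        assert targeted.min() > others.max()

    def test_non_targeted_family_centred_on_zero(self, study):
        table = per_te_changes(study["wt"], study["treated"], study["annotation"])
        truth = study["truth"]
        others = table[(table["context"] == "CHH")
                       & (table["family"] != truth.targeted_family)]["value"]
        assert abs(others.mean()) < 2.0  # null values are O(1) by construction


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def brute_force_dmrs(wt, tr, size, window=100, min_diff=0.5, min_sites=4):
    """Independent window-by-window evaluation plus explicit merge walk."""
    n = -(-size // window)
    seeds = []
    for i in range(n):
        lo, hi = i * window, (i + 1) * window

        def stats(df):
            sub = df[(df["pos"] >= lo) & (df["pos"] < hi) & (df["context"] == "CG")]
            covered = ((sub["meth"] + sub["unmeth"]) > 0).sum()
            t = (sub["meth"] + sub["unmeth"]).sum()
            return covered, (sub["meth"].sum() / t if t else math.nan)

        cw, lw = stats(wt)
        ct, lt = stats(tr)
        if cw >= min_sites and ct >= min_sites and (lw - lt) >= min_diff:
            seeds.append(i)
    merged = []
    for i in seeds:
        if merged and i - merged[-1][-1] <= 2:
            merged[-1].append(i)
        else:
            merged.append([i])
    return [(g[0] * window, min((g[-1] + 1) * window, size)) for g in merged]


class TestDmrCalling:
    def make(self, windows, window=100, sites=5, cov=10):
        """Build WT/treated records realising given per-window levels."""
        wt_rows, tr_rows = [], []
        for i, (lw, lt) in enumerate(windows):
            for j in range(sites):
                pos = i * window + 10 + j * 15
                wt_rows.append((pos, round(cov * lw), cov - round(cov * lw)))
                tr_rows.append((pos, round(cov * lt), cov - round(cov * lt)))
        return records(wt_rows), records(tr_rows)

    def test_single_qualifying_window(self):
        wt, tr = self.make([(0.9, 0.3)])
        dmrs = call_cg_dmrs(wt, tr, chrom_sizes={"chr1": 100})
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.n_windows) == (0, 100, 1)
        assert d.diff == pytest.approx(0.6)

    def test_one_gap_merges(self):
        wt, tr = self.make([(0.9, 0.9), (0.9, 0.2), (0.9, 0.9), (0.9, 0.2)])
        dmrs = call_cg_dmrs(wt, tr, chrom_sizes={"chr1": 400})
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end) == (100, 400)
        assert dmrs[0].n_windows == 2

    def test_two_gap_splits(self):
        wt, tr = self.make([(0.9, 0.2), (0.9, 0.9), (0.9, 0.9), (0.9, 0.2)])
        dmrs = call_cg_dmrs(wt, tr, chrom_sizes={"chr1": 400})
        assert [(d.start, d.end) for d in dmrs] == [(0, 100), (300, 400)]

    def test_diff_threshold_inclusive(self):
        wt, tr = self.make([(1.0, 0.5)])
        assert len(call_cg_dmrs(wt, tr, chrom_sizes={"chr1": 100})) == 1

    def test_min_covered_sites(self):
        wt, tr = self.make([(0.9, 0.1)], sites=3)
        assert call_cg_dmrs(wt, tr, chrom_sizes={"chr1": 100}) == []
        assert len(call_cg_dmrs(wt, tr, min_covered_sites=3,
                                chrom_sizes={"chr1": 100})) == 1

    def test_bad_window_rejected(self):
        wt, tr = self.make([(0.9, 0.1)])
        with pytest.raises(ValueError):
            call_cg_dmrs(wt, tr, window=0)

    def test_equals_brute_force_on_random_input(self, rng):
        for _ in range(20):
            size = 5000
            wt = random_records(rng, 300, range(size))
            tr = random_records(rng, 300, range(size))
            got = [(d.start, d.end) for d in
                   call_cg_dmrs(wt, tr, chrom_sizes={"chr1": size})]
            assert got == brute_force_dmrs(wt, tr, size)


# ---------------------------------------------------------------------------
# Metaplots
# ---------------------------------------------------------------------------

def brute_force_metaplot(recs, summits, bin_, step, span, context):
    offsets = np.arange(-span + bin_ // 2, span - bin_ // 2 + 1, step)
    vals = []
    for off in offsets:
        m = t = 0
        for s in summits.itertuples():
            for r in recs.itertuples():
                if (r.chrom == s.chrom and r.context == context
                        and s.start + off - bin_ // 2 <= r.pos < s.start + off + bin_ // 2):
                    m += r.meth
                    t += r.meth + r.unmeth
        vals.append(m / t if t else math.nan)
    return offsets, np.array(vals)


class TestMetaplot:
    summits = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [3000, 7000],
                            "end": [3001, 7001], "name": ".", "score": 0,
                            "strand": "+"})

    def test_constant_methylation_flat(self):
        recs = records([(p, 1, 1) for p in range(0, 10000, 50)])
        out = metaplot(recs, self.summits, span=2000, contexts=("CG",))
        assert np.allclose(out["CG"].dropna(), 0.5)

    def test_offset_count(self):
        recs = records([(p, 1, 1) for p in range(0, 12000, 50)])
        out = metaplot(recs, self.summits, bin=500, step=50, span=5000)
        assert len(out) == 191

    def test_matches_naive_accumulation(self, rng):
        recs = random_records(rng, 200, range(10000))
        out = metaplot(recs, self.summits, bin=400, step=100, span=1000,
                       contexts=("CG",))
        offsets, expect = brute_force_metaplot(recs, self.summits, 400, 100, 1000, "CG")
        np.testing.assert_array_equal(out.index.to_numpy(), offsets)
        np.testing.assert_allclose(out["CG"].to_numpy(), expect)

    def test_no_summits_empty(self):
        recs = records([(5, 1, 1)])
        out = metaplot(recs, self.summits.iloc[:0])
        assert out.empty

    def test_cg_dip_recovered_at_summits(self, study):
        """The planted local CG loss shows as the metaplot minimum near 0."""
        out = metaplot(study["treated"], study["summits"], span=3000)
        cg = out["CG"].dropna()
        centre = cg.loc[abs(cg.index) <= 250].mean()
        edge = cg.loc[abs(cg.index) >= 2500].mean()
        assert centre < edge


def test_dmrs_to_frame_columns():
    d = DMR("chr1", 0, 200, "CG", 2, 0.9, 0.3)
    df = dmrs_to_frame([d])
    assert df.loc[0, "diff"] == pytest.approx(0.6)
    assert list(df.columns[:6]) == ["chrom", "start", "end", "name", "score", "strand"]
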