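"""End-to-end orchestration of the simulated anti-silencing analysis.

``run_full`` executes the whole chain on synthetic data under one config:

    simulate genome/annotation -> two-condition methylomes -> per-TE
    methylation changes -> CG-DMR calling -> discriminative motif
    discovery on DMR sequences -> genome-wide motif scanning, per-TE
    counts and array detection -> ChIP binning, summit annotation and
    summit-centred metaplots -> protein-family evolution, distances,
    NJ tree with bootstrap, dot plot and tandem repeats

writing every intermediate in its declared text format plus a manifest
with parameters and per-output checksums.  Re-running with the same
config reproduces identical checksums.  ``validate_against_truth`` scores
the outputs against the planted ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip, evolution, methylome, motif
from . import io as vio
from .simulate import (GroundTruth, SimulationConfig, simulate_chip,
                       simulate_family_evolution, simulate_genome,
                       simulate_methylomes)


@dataclass
class RunConfig:
    """One run = one simulation config plus per-stage parameter blocks.

    Every constant of the analysis contract is a named default here:
    100 fractions / window 7 for fractional profiles, 100-bp DMR windows
    with a 0.5 level difference, discovery core width <= 9, 500-bp
    metaplot bins with 50-bp steps, 10-kb enrichment tiles, and dot-plot
    word 10 / window 10, threshold 23.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_te_length: int = 1000
    dmr_window: int = 100
    dmr_min_diff: float = 0.5
    dmr_min_covered_sites: int = 4
    n_fractions: int = 100
    profile_window: int = 7
    discovery_min_w: int = 6
    discovery_max_w: int = 9
    discovery_e_threshold: float = 0.05
    array_min_run: int = 3
    array_max_gap_bp: int = 200
    metaplot_bin: int = 500
    metaplot_step: int = 50
    metaplot_span: int = 5000
    chip_bin_size: int = 10_000
    chip_pseudocount: float = 0.5
    dotplot_word: int = 10
    protein_window: int = 10
    protein_threshold: int = 23
    bootstrap_replicates: int = 100

    @property
    def seed(self) -> int:
        return self.simulation.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("simulation", {}).items()})
        return cls(simulation=sim, **raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage on fresh simulated data; returns the manifest dict.

    Outputs land in ``outdir``; the manifest (also written as
    manifest.json) records the parameter set, the seed and a sha256 per
    output file, keyed by relative file name for cross-run comparison.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "simulate_genome"
        genome, annotation, truth = simulate_genome(sim)
        vio.write_fasta(genome, outdir / "genome.fa")
        vio.write_annotation(annotation, outdir / "annotation.tsv")
        truth.to_json(outdir / "truth.json")
        outputs.update(genome=outdir / "genome.fa", annotation=outdir / "annotation.tsv",
                       truth=outdir / "truth.json")

        stage = "simulate_methylomes"
        wt, tr = simulate_methylomes(genome, annotation, truth, sim)
        vio.write_cx_report(wt, outdir / "wt.CX_report.txt")
        vio.write_cx_report(tr, outdir / "treated.CX_report.txt")
        outputs.update(wt_cx=outdir / "wt.CX_report.txt",
                       treated_cx=outdir / "treated.CX_report.txt")

        stage = "simulate_chip"
        ip_df, in_df, summits = simulate_chip(genome, annotation, truth, sim)
        vio.write_bedgraph(ip_df, outdir / "ip.bedgraph")
        vio.write_bedgraph(in_df, outdir / "input.bedgraph")
        vio.write_bed(summits, outdir / "summits.bed")
        outputs.update(ip=outdir / "ip.bedgraph", input=outdir / "input.bedgraph",
                       summits=outdir / "summits.bed")

        stage = "methylation_changes"
        changes = methylome.per_te_changes(wt, tr, annotation,
                                           min_length=config.min_te_length)
        changes.to_csv(outdir / "changes.tsv", sep="\t", index=False)
        outputs["changes"] = outdir / "changes.tsv"

        stage = "dmr_calling"
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        dmrs = methylome.call_cg_dmrs(wt, tr, window=config.dmr_window,
                                      min_diff=config.dmr_min_diff,
                                      min_covered_sites=config.dmr_min_covered_sites,
                                      chrom_sizes=chrom_sizes)
        dmr_df = methylome.dmrs_to_frame(dmrs)
        dmr_df.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
        outputs["dmrs"] = outdir / "dmrs.tsv"

        stage = "motif_discovery"
        cands = discover_on_dmrs(genome, annotation, dmrs, config)
        pd.DataFrame([{"pattern": c.pattern.pattern, "pos_with": c.pos_with,
                       "pos_total": c.pos_total, "neg_with": c.neg_with,
                       "neg_total": c.neg_total, "p": c.p, "e": c.e}
                      for c in cands],
                     columns=["pattern", "pos_with", "pos_total", "neg_with",
                              "neg_total", "p", "e"]
                     ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
        outputs["motifs"] = outdir / "motifs.tsv"

        stage = "motif_scanning"
        family_motif = sim.motif_per_family[sim.targeted_family
                                            % len(sim.motif_per_family)]
        hits = []
        for chrom, seq in genome.items():
            hits.extend(motif.scan(seq, family_motif, seq_id=chrom))
        counts = motif.count_per_te(hits, annotation)
        counts.to_csv(outdir / "motif_counts.tsv", sep="\t")
        arrays = motif.find_arrays(hits, min_run=config.array_min_run,
                                   max_gap_bp=config.array_max_gap_bp)
        pd.DataFrame([{"chrom": a.seq_id, "start": a.start, "end": a.end,
                       "name": "array", "score": a.n_hits, "strand": a.strand,
                       "density": a.density} for a in arrays]
                     ).to_csv(outdir / "arrays.tsv", sep="\t", index=False)
        outputs.update(motif_counts=outdir / "motif_counts.tsv",
                       arrays=outdir / "arrays.tsv")

        stage = "chip_enrichment"
        ip_track = chip.CoverageTrack(ip_df)
        in_track = chip.CoverageTrack(in_df)
        bins = chip.bin_enrichment(ip_track, in_track, bin_size=config.chip_bin_size,
                                   pseudocount=config.chip_pseudocount)
        chip.enrichment_to_frame(bins).to_csv(outdir / "bins.tsv", sep="\t", index=False)
        ann = chip.summit_annotation(summits, annotation)
        ann.to_csv(outdir / "summit_annotation.tsv", sep="\t", index=False)
        meta = methylome.metaplot(tr, summits, bin=config.metaplot_bin,
                                  step=config.metaplot_step, span=config.metaplot_span)
        meta.to_csv(outdir / "metaplot.tsv", sep="\t")
        outputs.update(bins=outdir / "bins.tsv",
                       summit_annotation=outdir / "summit_annotation.tsv",
                       metaplot=outdir / "metaplot.tsv")

        stage = "evolution"
        aligned, evo_truth = simulate_family_evolution(sim.tree, config=sim)
        vio.write_fasta(aligned, outdir / "family.aln.fa")
        result = evolution.bootstrap_tree(aligned,
                                          n_replicates=config.bootstrap_replicates,
                                          seed=sim.seed)
        (outdir / "tree.nwk").write_text(result.tree + "\n")
        pd.DataFrame([{"bipartition": "|".join(sorted(b)), "support": s}
                      for b, s in sorted(result.supports.items(),
                                         key=lambda kv: "|".join(sorted(kv[0])))]
                     ).to_csv(outdir / "supports.tsv", sep="\t", index=False)
        names = sorted(aligned)
        dp = evolution.dotplot_protein(aligned[names[0]].replace("-", ""),
                                       aligned[names[-1]].replace("-", ""),
                                       window=config.protein_window,
                                       threshold=config.protein_threshold,
                                       x_id=names[0], y_id=names[-1])
        dp.to_frame().to_csv(outdir / "protein_dotplot.tsv", sep="\t", index=False)
        reps = []
        for a in truth.arrays[:3]:
            seq = genome[a.chrom][max(0, a.start - 50):a.end + 50]
            reps.extend(evolution.find_tandem_repeats(
                seq, min_unit=5, max_unit=2 * sim.repeat_unit_length,
                seq_id=f"{a.chrom}:{max(0, a.start - 50)}"))
        pd.DataFrame([vars(r) for r in reps]).to_csv(outdir / "tandem_repeats.tsv",
                                                     sep="\t", index=False)
        outputs.update(alignment=outdir / "family.aln.fa", tree=outdir / "tree.nwk",
                       supports=outdir / "supports.tsv",
                       protein_dotplot=outdir / "protein_dotplot.tsv",
                       tandem_repeats=outdir / "tandem_repeats.tsv")
    except Exception as exc:
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "seed": sim.seed,
        "parameters": {k: v for k, v in asdict(config).items() if k != "simulation"},
        "simulation": asdict(sim),
        "outputs": {name: {"file": p.name, "sha256": _sha256(p)}
                    for name, p in sorted(outputs.items())},
    }
    vio.write_json(manifest, outdir / "manifest.json")
    return manifest


def discover_on_dmrs(genome: dict[str, str], annotation: pd.DataFrame,
                     dmrs, config: RunConfig,
                     neg_per_pos: int = 5) -> list[motif.MotifCandidate]:
    """Discriminative discovery: DMR sequences vs length-matched background.

    Negative sequences are sampled (seeded) from regions outside every TE,
    ``neg_per_pos`` per DMR with the DMR's length.  A background set
    larger than the positive set keeps the Fisher test powered when few
    DMRs are called: with n positives and n negatives the smallest
    attainable p is 1/C(2n, n), which a Bonferroni-style E-value over all
    tested words can swamp.
    """
    if not dmrs:
        return []
    pos = [genome[d.chrom][d.start:d.end] for d in dmrs]
    rng = np.random.default_rng([config.seed, 97])
    te_iv = sorted((str(r.chrom), int(r.start), int(r.end))
                   for r in annotation.itertuples())
    negs = []
    chroms = sorted(genome)
    for d in dmrs * neg_per_pos:
        length = d.end - d.start
        for _ in range(1000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            s = int(rng.integers(0, max(1, len(genome[chrom]) - length)))
            if not any(c == chrom and s < e and s + length > b
                       for c, b, e in te_iv):
                negs.append(genome[chrom][s:s + length])
                break
        else:
            raise StageError("could not sample background sequence outside TEs")
    return motif.discover(pos, negs, min_w=config.discovery_min_w,
                          max_w=config.discovery_max_w,
                          e_threshold=config.discovery_e_threshold)


# ---------------------------------------------------------------------------
# Validation against planted truth
# ---------------------------------------------------------------------------

def _interval_overlap_stats(called: list[tuple[int, int]],
                            planted: list[tuple[int, int]]) -> tuple[float, float]:
    """(sensitivity, precision) at base level between two interval sets."""

    def mask(ivs, n):
        m = np.zeros(n, dtype=bool)
        for s, e in ivs:
            m[max(0, s):e] = True
        return m

    n = max([e for _, e in called + planted], default=0)
    if n == 0:
        return float("nan"), float("nan")
    cm, pm = mask(called, n), mask(planted, n)
    sens = (cm & pm).sum() / pm.sum() if pm.sum() else float("nan")
    prec = (cm & pm).sum() / cm.sum() if cm.sum() else float("nan")
    return float(sens), float(prec)


def validate_against_truth(outdir: str | Path, truth: GroundTruth | None = None) -> dict:
    """Score run_full outputs against the planted ground truth.

    Reports base-level DMR sensitivity/precision, the rank of the planted
    family motif among discovered candidates (by zero-mismatch
    compatibility on either strand), the gap between the smallest
    targeted-family and largest non-targeted CHH significance value, and
    the fraction of summits annotated to targeted-family non-coding
    segments.  Also written as validation.tsv.
    """
    outdir = Path(outdir)
    if truth is None:
        truth = GroundTruth.from_json(outdir / "truth.json")

    dmr_df = pd.read_csv(outdir / "dmrs.tsv", sep="\t")
    called = [(int(r.start), int(r.end)) for r in dmr_df.itertuples()
              if r.chrom == truth.chrom]
    sens, prec = _interval_overlap_stats(called, [tuple(iv) for iv in
                                                  truth.hypo_intervals["CG"]])

    planted_motif = next(a.motif for a in truth.arrays
                         if a.family == truth.targeted_family)
    motifs_df = pd.read_csv(outdir / "motifs.tsv", sep="\t")
    rank = float("nan")
    for i, pat in enumerate(motifs_df.get("pattern", pd.Series(dtype=str))):
        if (motif.min_mismatch(pat, planted_motif) == 0
                or motif.min_mismatch(motif.revcomp(pat), planted_motif) == 0):
            rank = i + 1
            break

    changes = pd.read_csv(outdir / "changes.tsv", sep="\t")
    chh = changes[changes["context"] == "CHH"].dropna(subset=["value"])
    targeted = chh[chh["family"] == truth.targeted_family]["value"]
    others = chh[chh["family"] != truth.targeted_family]["value"]
    separation = float(targeted.min() - others.max()) if len(targeted) and len(others) \
        else float("nan")

    ann = pd.read_csv(outdir / "summit_annotation.tsv", sep="\t")
    ok = ((ann["family"] == truth.targeted_family)
          & (ann["segment_type"] == "noncoding")).mean() if len(ann) else float("nan")

    report = {
        "dmr_sensitivity": sens,
        "dmr_precision": prec,
        "n_dmrs": int(len(dmr_df)),
        "motif_rank": rank,
        "chh_significance_separation": separation,
        "summit_annotation_accuracy": float(ok),
    }
    pd.DataFrame([report]).to_csv(outdir / "validation.tsv", sep="\t", index=False)
    return report
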