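"""Synthetic genomes, methylomes, ChIP tracks and protein families with truth.

The generator emulates the structures that make VANC-style anti-silencing
analysable: TE families whose non-coding regions carry a family-specific
degenerate motif as a same-orientation tandem array; a wild-type methylome
with context-stratified methylation inside TEs; a "transgenic" methylome in
which the targeted family loses CG methylation locally around its motif
arrays and non-CG methylation across entire elements; ChIP coverage
enriched over the arrays; and protein families evolved along a known tree
with conserved domains and an expandable internal repeat.

Every output is accompanied by a machine-readable :class:`GroundTruth` so
downstream callers (DMR calling, motif discovery, summit annotation,
phylogenetics) can be scored by parameter recovery.

Randomness: each operation draws from its own stream derived from
``config.seed`` and a fixed per-operation tag, so any subset of the
operations is reproducible independently of call order.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Phylo

from . import io as vio
from .motif import IUPACPattern, revcomp

_AA = "ACDEFGHIKLMNPQRSTVWY"

_OP_TAGS = {"genome": 1, "methylome": 2, "chip": 3, "evolution": 4}


class SizingError(ValueError):
    """Requested TEs do not fit in the requested genome length."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale version of the biological setting: two
    TE families on one ~150-kb chromosome, the first family targeted by the
    anti-silencing protein; Arabidopsis-like TE methylation levels
    (CG 0.8, CHG 0.5, CHH 0.15); 30x coverage; a CG methylation drop of 0.6
    within 500 bp of each motif array and milder element-wide non-CG drops.
    """

    seed: int = 0
    genome_length: int = 150_000
    chrom: str = "chr1"
    n_te_families: int = 2
    copies_per_family: int = 5
    te_length_range: tuple[int, int] = (1500, 3000)
    #: one IUPAC consensus per family (cycled if fewer than families)
    motif_per_family: tuple[str, ...] = ("YAGTATTAY", "AGTTGTMC")
    #: index of the family whose copies the simulated transgene targets
    targeted_family: int = 0
    repeat_unit_length: int = 20
    repeat_copies_range: tuple[int, int] = (4, 8)
    mean_coverage: float = 30.0
    wt_meth_levels: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.5, "CHH": 0.15})
    background_meth: float = 0.02
    hypo_local_radius: int = 500
    hypo_cg_drop: float = 0.6
    hypo_chg_drop: float = 0.3
    hypo_chh_drop: float = 0.10
    chip_enrichment_factor: float = 8.0
    chip_bin: int = 50
    tree: str = "((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1);"
    substitution_rate: float = 1.0

    def validate(self) -> None:
        props = [self.background_meth, self.hypo_cg_drop, self.hypo_chg_drop,
                 self.hypo_chh_drop, *self.wt_meth_levels.values()]
        if not all(0.0 <= p <= 1.0 for p in props):
            raise ValueError("all proportions must lie in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.repeat_unit_length < max(len(m) for m in self.motif_per_family):
            raise ValueError("repeat unit shorter than the motif it must carry")

    def rng(self, op: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _OP_TAGS[op]])


@dataclass
class MotifArrayTruth:
    te_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    unit: str          # repeat unit, TE-oriented
    n_copies: int
    motif: str         # family IUPAC consensus


@dataclass
class GroundTruth:
    """Everything planted by the generator, for downstream scoring."""

    chrom: str
    genome_length: int
    te_family: dict[str, str]
    targeted_family: str
    arrays: list[MotifArrayTruth]
    #: context -> list of [start, end) intervals with reduced methylation
    hypo_intervals: dict[str, list[tuple[int, int]]]
    tree: str = ""
    repeat_copy_number: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = asdict(self)
        vio.write_json(obj, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = vio.read_json(path)
        obj["arrays"] = [MotifArrayTruth(**a) for a in obj["arrays"]]
        obj["hypo_intervals"] = {
            k: [tuple(iv) for iv in v] for k, v in obj["hypo_intervals"].items()}
        return cls(**obj)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _concrete_instance(pattern: str, rng: np.random.Generator) -> str:
    from .motif import IUPAC
    return "".join(str(rng.choice(sorted(IUPAC[c]))) for c in pattern)


def _scrub(seq: str, pattern: IUPACPattern, rng: np.random.Generator) -> str:
    """Mutate single bases until ``seq`` has no match of pattern on either strand."""
    from .motif import scan
    seq = list(seq)
    for _ in range(100):
        hits = scan("".join(seq), pattern, both_strands=True)
        if not hits:
            break
        for h in hits:
            i = int(rng.integers(h.start, h.end))
            cur = seq[i]
            seq[i] = str(rng.choice([b for b in "ACGT" if b != cur]))
    return "".join(seq)


def _build_te(family_motif: str, te_len: int, unit_len: int, n_copies: int,
              rng: np.random.Generator):
    """A TE in its own 5'->3' orientation: noncoding(array) - coding - noncoding(array).

    Returns (sequence, segments, arrays) with TE-local coordinates; each
    array tuple is (start, end, unit).
    """
    pat = IUPACPattern(family_motif)
    pad = 100

    def make_array():
        motif_inst = _concrete_instance(family_motif, rng)
        offset = int(rng.integers(0, unit_len - pat.width + 1))
        filler = _random_dna(rng, unit_len - pat.width)
        unit = filler[:offset] + motif_inst + filler[offset:]
        return unit * n_copies, unit

    arr1, unit1 = make_array()
    arr2, unit2 = make_array()
    nc1_len = pad + len(arr1) + pad
    nc2_len = pad + len(arr2) + pad
    coding_len = te_len - nc1_len - nc2_len
    if coding_len < 200:
        raise SizingError(f"TE length {te_len} too short for two motif arrays")
    coding = _scrub(_random_dna(rng, coding_len), pat, rng)
    seq = (_random_dna(rng, pad) + arr1 + _random_dna(rng, pad)
           + coding
           + _random_dna(rng, pad) + arr2 + _random_dna(rng, pad))
    segments = [(0, nc1_len, "noncoding"),
                (nc1_len, nc1_len + coding_len, "coding"),
                (nc1_len + coding_len, te_len, "noncoding")]
    arrays = [(pad, pad + len(arr1), unit1),
              (te_len - pad - len(arr2), te_len - pad, unit2)]
    return seq, segments, arrays


def simulate_genome(config: SimulationConfig):
    """Generate (genome dict, annotation DataFrame, GroundTruth).

    TE copies of each family are interleaved along one chromosome with
    random background gaps; every copy carries its family motif as a
    same-orientation tandem array in each terminal non-coding region, and
    coding segments are scrubbed of the family motif.
    """
    config.validate()
    rng = config.rng("genome")
    families = [f"FAM{i}" for i in range(config.n_te_families)]
    motifs = {fam: config.motif_per_family[i % len(config.motif_per_family)]
              for i, fam in enumerate(families)}
    targeted = families[config.targeted_family]

    pieces: list[str] = []
    ann_rows = []
    arrays: list[MotifArrayTruth] = []
    te_family: dict[str, str] = {}
    cursor = 0
    copy_plan = [(fam, j) for j in range(config.copies_per_family) for fam in families]
    for fam, j in copy_plan:
        gap = int(rng.integers(500, 1500))
        te_len = int(rng.integers(config.te_length_range[0], config.te_length_range[1] + 1))
        n_copies = int(rng.integers(config.repeat_copies_range[0],
                                    config.repeat_copies_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        te_id = f"{fam}_{j}"
        seq, segments, te_arrays = _build_te(
            motifs[fam], te_len, config.repeat_unit_length, n_copies, rng)
        start = cursor + gap
        end = start + te_len
        if end > config.genome_length:
            raise SizingError(
                f"genome_length {config.genome_length} too short at TE {te_id}")
        if strand == "-":
            seq = revcomp(seq)
            segments = [(te_len - e, te_len - s, t) for s, e, t in segments][::-1]
            te_arrays = [(te_len - e, te_len - s, u) for s, e, u in te_arrays][::-1]
        pieces.append(_random_dna(rng, gap))
        pieces.append(seq)
        for s, e, t in segments:
            ann_rows.append((config.chrom, start + s, start + e, strand, te_id, fam, t))
        for s, e, u in te_arrays:
            arrays.append(MotifArrayTruth(te_id, config.chrom, start + s, start + e,
                                          strand, fam, u, n_copies, motifs[fam]))
        te_family[te_id] = fam
        cursor = end
    pieces.append(_random_dna(rng, config.genome_length - cursor))
    genome = {config.chrom: "".join(pieces)}

    annotation = pd.DataFrame(ann_rows, columns=vio.ANNOTATION_COLUMNS)

    # planted hypomethylation geometry: CG local around targeted arrays
    # (clipped to the element body, since methylation outside TEs is already
    # at background level), CHG/CHH across whole targeted elements
    te_span = {te_id: (int(grp["start"].min()), int(grp["end"].max()))
               for te_id, grp in annotation.groupby("te_id")}
    cg_iv = []
    for a in arrays:
        if a.family == targeted:
            lo, hi = te_span[a.te_id]
            cg_iv.append((max(lo, a.start - config.hypo_local_radius),
                          min(hi, a.end + config.hypo_local_radius)))
    te_iv = [te_span[te_id] for te_id, fam in te_family.items() if fam == targeted]
    truth = GroundTruth(
        chrom=config.chrom,
        genome_length=config.genome_length,
        te_family=te_family,
        targeted_family=targeted,
        arrays=arrays,
        hypo_intervals={"CG": _merge_intervals(cg_iv), "CHG": te_iv, "CHH": te_iv},
        tree=config.tree,
    )
    return genome, annotation, truth


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return [tuple(iv) for iv in out]


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

def _cytosine_table(seq: str, chrom: str) -> pd.DataFrame:
    """All cytosines on both strands with context and trinucleotide.

    Cytosines whose trinucleotide would run off the sequence end are
    omitted, as are those with N in the trinucleotide.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    rows = []
    c_pos = np.nonzero(arr == b"C")[0]
    c_pos = c_pos[(c_pos + 2) < len(arr)]
    g_pos = np.nonzero(arr == b"G")[0]
    g_pos = g_pos[g_pos >= 2]

    def ctx_plus(i):
        if seq[i + 1] == "G":
            return "CG"
        if seq[i + 2] == "G":
            return "CHG"
        return "CHH"

    for i in c_pos:
        tri = seq[i:i + 3]
        if "N" in tri:
            continue
        rows.append((chrom, int(i), "+", ctx_plus(int(i)), tri))
    for i in g_pos:
        tri = revcomp(seq[i - 2:i + 1])
        if "N" in tri:
            continue
        if tri[1] == "G":
            ctx = "CG"
        elif tri[2] == "G":
            ctx = "CHG"
        else:
            ctx = "CHH"
        rows.append((chrom, int(i), "-", ctx, tri))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _interval_mask(n: int, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[max(0, s):min(n, e)] = True
    return mask


def simulate_methylomes(genome: dict[str, str], annotation: pd.DataFrame,
                        truth: GroundTruth, config: SimulationConfig):
    """Sample WT and transgenic per-cytosine count tables (0-based).

    Per cytosine, total reads ~ Poisson(mean_coverage) and methylated reads
    ~ Binomial(total, p).  In the wild type p is the configured per-context
    level inside any TE and ``background_meth`` outside.  In the transgenic
    condition, CG levels drop by ``hypo_cg_drop`` within the planted local
    intervals around targeted-family arrays, and CHG/CHH levels drop by
    their configured amounts across whole targeted elements.
    """
    config.validate()
    rng = config.rng("methylome")
    chrom = config.chrom
    seq = genome[chrom]
    cyt = _cytosine_table(seq, chrom)
    n = len(cyt)
    pos = cyt["pos"].to_numpy()

    te_iv = [(int(r.start), int(r.end)) for r in
             annotation.groupby("te_id").agg(start=("start", "min"), end=("end", "max"))
             .itertuples()]
    in_te = _interval_mask(len(seq), _merge_intervals(te_iv))[pos]

    p_wt = np.full(n, config.background_meth)
    for ctx, level in config.wt_meth_levels.items():
        m = (cyt["context"] == ctx).to_numpy() & in_te
        p_wt[m] = level

    p_tr = p_wt.copy()
    drops = {"CG": config.hypo_cg_drop, "CHG": config.hypo_chg_drop,
             "CHH": config.hypo_chh_drop}
    for ctx, drop in drops.items():
        hypo = _interval_mask(len(seq), truth.hypo_intervals[ctx])[pos]
        m = (cyt["context"] == ctx).to_numpy() & hypo & in_te
        p_tr[m] = np.clip(p_tr[m] - drop, 0.0, 1.0)

    def sample(p):
        total = rng.poisson(config.mean_coverage, n)
        meth = rng.binomial(total, p)
        out = cyt.copy()
        out["meth"] = meth
        out["unmeth"] = total - meth
        return out[vio.CX_COLUMNS]

    return sample(p_wt), sample(p_tr)


# ---------------------------------------------------------------------------
# ChIP
# ---------------------------------------------------------------------------

def simulate_chip(genome: dict[str, str], annotation: pd.DataFrame,
                  truth: GroundTruth, config: SimulationConfig):
    """Sample (ip_track, input_track, summits) for the targeted family.

    Both tracks are Poisson-sampled per fixed-width bin around a flat mean;
    the IP mean is multiplied by ``chip_enrichment_factor`` over bins that
    overlap a planted motif array of the targeted family.  One summit is
    emitted per targeted array, at its midpoint.
    """
    config.validate()
    rng = config.rng("chip")
    chrom = config.chrom
    glen = len(genome[chrom])
    bin_ = config.chip_bin
    starts = np.arange(0, glen, bin_)
    ends = np.minimum(starts + bin_, glen)

    targeted_arrays = [a for a in truth.arrays if a.family == truth.targeted_family]
    enriched = _interval_mask(glen, [(a.start, a.end) for a in targeted_arrays])
    # a bin is enriched when any base of it lies in an array
    bin_enriched = np.array([enriched[s:e].any() for s, e in zip(starts, ends)])

    mu = np.full(len(starts), config.mean_coverage, dtype=float)
    input_depth = rng.poisson(mu)
    ip_mu = np.where(bin_enriched, mu * config.chip_enrichment_factor, mu)
    ip_depth = rng.poisson(ip_mu)

    def track(depth):
        return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                             "depth": depth.astype(float)})

    summits = pd.DataFrame({
        "chrom": chrom,
        "start": [(a.start + a.end) // 2 for a in targeted_arrays],
        "end": [(a.start + a.end) // 2 + 1 for a in targeted_arrays],
        "name": [f"summit_{a.te_id}_{a.start}" for a in targeted_arrays],
        "score": 0,
        "strand": [a.strand for a in targeted_arrays],
    })
    return track(ip_depth), track(input_depth), summits


# ---------------------------------------------------------------------------
# Protein family evolution
# ---------------------------------------------------------------------------

def default_root_protein(rng: np.random.Generator, domain_len: int = 60,
                         linker_len: int = 30, repeat_unit: str = "PQSTN",
                         max_repeat_copies: int = 6):
    """A root protein: conserved domain - linker - repeat block - linker - domain.

    Returns (sequence, conserved_columns boolean array, repeat block slice,
    repeat unit).
    """
    aa = np.array(list(_AA))
    dom1 = "".join(aa[rng.integers(0, 20, domain_len)])
    dom2 = "".join(aa[rng.integers(0, 20, domain_len)])
    link1 = "".join(aa[rng.integers(0, 20, linker_len)])
    link2 = "".join(aa[rng.integers(0, 20, linker_len)])
    block = repeat_unit * max_repeat_copies
    seq = dom1 + link1 + block + link2 + dom2
    conserved = np.zeros(len(seq), dtype=bool)
    conserved[:domain_len] = True
    conserved[-domain_len:] = True
    block_slice = (domain_len + linker_len, domain_len + linker_len + len(block))
    return seq, conserved, block_slice, repeat_unit


def simulate_family_evolution(tree: str, root_protein: str | None = None,
                              config: SimulationConfig | None = None,
                              conserved_factor: float = 0.1):
    """Evolve a protein family along ``tree`` (newick) by per-site substitution.

    Per branch of length b, each site substitutes with probability
    1 - exp(-b * rate) (times ``conserved_factor`` for conserved-domain
    columns) to a uniformly random different residue.  The internal repeat
    block is expandable: each leaf keeps a random number of repeat copies,
    the rest of the block becoming gap columns, so the output is an aligned
    family with conserved domains and a variable repeat region.

    Returns (aligned dict leaf->sequence, truth dict).
    """
    config = config or SimulationConfig()
    rng = config.rng("evolution")
    rate = config.substitution_rate

    if root_protein is None:
        root_seq, conserved, block_slice, unit = default_root_protein(rng)
    else:
        root_seq = root_protein
        conserved = np.zeros(len(root_seq), dtype=bool)
        block_slice, unit = (0, 0), ""

    try:
        phylo = Phylo.read(_io.StringIO(tree), "newick")
    except Exception as exc:  # Bio raises various parse errors
        raise ValueError(f"malformed newick: {exc}") from exc

    site_rate = np.where(conserved, rate * conserved_factor, rate)
    aa = np.array(list(_AA))
    leaves: dict[str, str] = {}

    def walk(clade, seq: np.ndarray):
        b = clade.branch_length or 0.0
        p_sub = 1.0 - np.exp(-b * site_rate)
        hit = rng.random(len(seq)) < p_sub
        if hit.any():
            seq = seq.copy()
            for i in np.nonzero(hit)[0]:
                choices = aa[aa != seq[i]]
                seq[i] = rng.choice(choices)
        if clade.is_terminal():
            leaves[clade.name] = "".join(seq)
        else:
            for child in clade:
                walk(child, seq)

    root_arr = np.array(list(root_seq))
    for child in phylo.root:
        walk(child, root_arr)
    if not leaves:  # degenerate single-node tree
        leaves[phylo.root.name or "root"] = root_seq

    # expandable repeat: truncate each leaf's block to a drawn copy number
    copy_number: dict[str, int] = {}
    if unit:
        s, e = block_slice
        max_copies = (e - s) // len(unit)
        for name in sorted(leaves):
            k = int(rng.integers(2, max_copies + 1))
            copy_number[name] = k
            seq = leaves[name]
            kept = seq[s:s + k * len(unit)]
            leaves[name] = seq[:s] + kept + "-" * (e - s - len(kept)) + seq[e:]

    truth = {
        "tree": tree,
        "conserved_columns": conserved.tolist(),
        "repeat_unit": unit,
        "repeat_block": list(block_slice),
        "repeat_copy_number": copy_number,
    }
    return leaves, truth
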