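"""Synthetic data generators with machine-readable planted truth.

Every fixture the pipeline consumes can be generated here: multi-species
alignments with planted conserved/accelerated/deleted segments on a known
tree, binned chromatin-contact maps with planted element-to-promoter
enrichment, replicate peak sets, expression matrices with planted
co-expression modules and graded hub loadings, and sequence sets with planted
motif instances.  Each generator is a pure function of its parameters and a
seed: identical inputs give identical outputs (and byte-identical files
through the deterministic writers).

The default demonstration phylogeny has 12 leaves in 4 clades; each clade
pairs one obligate-hibernator foreground leaf with its closest homeotherm
control leaf plus one background homeotherm.  This mirrors the design of
comparative screens for convergent evolution, where each foreground lineage
has an independent matched control in its own clade.  Terminal branches are
0.15-0.2 expected substitutions per site — the order of magnitude of terminal
branches in mammal-wide alignments, and long enough that a conserved segment
(branch scale ``rho`` < 1) is clearly distinguishable from neutral flanks at
desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentBlock, MultipleAlignment
from .phylo import MISSING, HKYModel, PhyloTree, simulate_columns

DEMO_NEWICK = (
    "((((hib_A:0.15,ctrl_A:0.15):0.05,bg_A:0.2):0.1,"
    "((hib_B:0.15,ctrl_B:0.15):0.05,bg_B:0.2):0.1):0.05,"
    "(((hib_C:0.15,ctrl_C:0.15):0.05,bg_C:0.2):0.1,"
    "((hib_D:0.15,ctrl_D:0.15):0.05,bg_D:0.2):0.1):0.05);"
)


@dataclass(frozen=True)
class LineageConfig:
    """Foreground (hibernator), matched control, and background species."""
    foreground: tuple[str, ...] = ("hib_A", "hib_B", "hib_C", "hib_D")
    control: tuple[str, ...] = ("ctrl_A", "ctrl_B", "ctrl_C", "ctrl_D")
    background: tuple[str, ...] = ("bg_A", "bg_B", "bg_C", "bg_D")
    reference: str = "bg_A"


def demo_tree() -> PhyloTree:
    return PhyloTree.from_newick(DEMO_NEWICK)


@dataclass
class Segment:
    """One planted segment of the synthetic reference genome."""
    length: int
    seg_class: str                      # neutral | conserved | accelerated | deleted
    rho: float = 1.0                    # conserved branch scale
    r: float = 1.0                      # foreground rate multiplier
    fg_lineages: tuple[str, ...] = ()
    del_lineages: tuple[str, ...] = ()

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.seg_class not in ("neutral", "conserved", "accelerated",
                                  "deleted"):
            raise ValueError(f"unknown segment class '{self.seg_class}'")
        if self.seg_class != "neutral" and not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.seg_class == "accelerated" and self.r < 1:
            raise ValueError("acceleration multiplier r must be >= 1")


@dataclass
class GenomeLayout:
    segments: list[Segment] = field(default_factory=list)

    def total_bp(self) -> int:
        return sum(s.length for s in self.segments)


def simulate_alignment(tree: PhyloTree, model: HKYModel, layout: GenomeLayout,
                       seed: int | np.random.Generator,
                       reference: str = "bg_A", chrom: str = "chrSim",
                       ) -> tuple[MultipleAlignment, pd.DataFrame]:
    """Simulate a reference-anchored alignment from a planted layout.

    Neutral segments evolve at scale 1, conserved at ``rho`` on every branch,
    accelerated additionally at ``rho * r`` on each named foreground terminal
    branch, and deleted segments are emitted as gap columns for the deleted
    lineages (conserved at ``rho`` for everyone else).  The reference row is
    gapless.  Returns the alignment and a truth table (BED-with-columns:
    chrom, start, end, class, rho, r, fg_lineages, del_lineages).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    leaves = set(tree.leaf_names)
    blocks, truth = [], []
    pos = 0
    for seg in layout.segments:
        for lin in seg.fg_lineages + seg.del_lineages:
            if lin not in leaves:
                raise ValueError(f"lineage '{lin}' is not a leaf of the tree")
        if seg.seg_class == "neutral":
            cols = simulate_columns(tree, model, seg.length, scale=1.0,
                                    rng=rng)
        elif seg.seg_class == "accelerated":
            scales = {lin: seg.r for lin in seg.fg_lineages}
            cols = simulate_columns(tree, model, seg.length, scale=seg.rho,
                                    branch_scales=scales, rng=rng)
        else:  # conserved or deleted backbone
            cols = simulate_columns(tree, model, seg.length, scale=seg.rho,
                                    rng=rng)
        rows = {name: cols[i].copy()
                for i, name in enumerate(tree.leaf_names)}
        if seg.seg_class == "deleted":
            if reference in seg.del_lineages:
                raise ValueError("cannot delete the reference lineage")
            for lin in seg.del_lineages:
                rows[lin][:] = MISSING
        blocks.append(AlignmentBlock(
            chrom, pos, rows,
            starts={name: pos for name in rows}))
        truth.append((chrom, pos, pos + seg.length, seg.seg_class, seg.rho,
                      seg.r, ",".join(seg.fg_lineages) or ".",
                      ",".join(seg.del_lineages) or "."))
        pos += seg.length
    truth_df = pd.DataFrame(truth, columns=[
        "chrom", "start", "end", "seg_class", "rho", "r",
        "fg_lineages", "del_lineages"])
    return MultipleAlignment(reference, blocks), truth_df


def simulate_contacts(n_bins: int, promoter_bins: list[int],
                      element_positions: list[int],
                      enrichment_factor: float,
                      seed: int | np.random.Generator,
                      bin_size: int = 10_000,
                      base_contact_prob: float = 0.05,
                      nb_n: float = 5.0, nb_mean_extra: float = 20.0,
                      noise_pair_frac: float = 0.1,
                      chrom: str = "chrSim",
                      ) -> tuple[pd.DataFrame, dict]:
    """Simulate a binned significant-contact map with planted enrichment.

    Each (bin, promoter-bin) pair forms a significant contact with
    probability ``base_contact_prob``, raised to
    ``base_contact_prob * enrichment_factor`` when the bin contains a planted
    element.  Significant contacts get overdispersed (negative-binomial)
    counts shifted above the count threshold, observed/expected above 2, and
    small q-values; a fraction of sub-threshold noise contacts is added to
    exercise filtering.  Non-promoter bin pairs contact at the base rate.

    Returns a BEDPE DataFrame and a truth dict including the analytic
    ``odds_ratio_true`` of an element bin (vs a background bin) contacting at
    least one promoter bin.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    promoter_bins = sorted(set(promoter_bins))
    if any(not 0 <= b < n_bins for b in promoter_bins):
        raise ValueError("promoter bin outside binned range")
    element_bins = sorted({p // bin_size for p in element_positions})
    if any(not 0 <= p < n_bins * bin_size for p in element_positions):
        raise ValueError("element position outside binned range")
    p_el = min(1.0, base_contact_prob * enrichment_factor)

    rows = []
    for b in range(n_bins):
        prob = p_el if b in element_bins else base_contact_prob
        for pb in promoter_bins:
            if pb == b:
                continue
            pair = (min(b, pb), max(b, pb))
            if rng.random() < prob:
                count = 12 + int(rng.negative_binomial(
                    nb_n, nb_n / (nb_n + nb_mean_extra)))
                oe = 2.0 + float(rng.gamma(2.0, 1.0)) + 0.1
                q = float(rng.uniform(0, 0.009))
                rows.append((*pair, count, oe, q))
    # sub-threshold noise: random pairs failing at least one filter
    n_noise = int(noise_pair_frac * max(1, len(rows)))
    for _ in range(n_noise):
        b1, b2 = sorted(rng.choice(n_bins, size=2, replace=False))
        mode = rng.integers(3)
        count = int(rng.integers(1, 12)) if mode == 0 else 12 + int(
            rng.negative_binomial(nb_n, nb_n / (nb_n + nb_mean_extra)))
        oe = float(rng.uniform(0.2, 2.0)) if mode == 1 else 2.2
        q = float(rng.uniform(0.02, 0.5)) if mode == 2 else 0.005
        if mode == 0:
            oe, q = 2.5, 0.005
        rows.append((int(b1), int(b2), count, oe, q))

    bedpe = pd.DataFrame(
        [(chrom, b1 * bin_size, (b1 + 1) * bin_size,
          chrom, b2 * bin_size, (b2 + 1) * bin_size, c, oe, q)
         for b1, b2, c, oe, q in rows],
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "count", "obs_exp", "q_value"])
    n_p = len(promoter_bins)
    p_hit_bg = 1 - (1 - base_contact_prob) ** n_p
    p_hit_el = 1 - (1 - p_el) ** n_p
    or_true = ((p_hit_el / (1 - p_hit_el)) / (p_hit_bg / (1 - p_hit_bg))
               if 0 < p_hit_bg < 1 and 0 < p_hit_el < 1 else np.inf)
    truth = {"promoter_bins": promoter_bins, "element_bins": element_bins,
             "base_contact_prob": base_contact_prob,
             "enrichment_factor": enrichment_factor,
             "p_hit_background": p_hit_bg, "p_hit_element": p_hit_el,
             "odds_ratio_true": or_true, "bin_size": bin_size,
             "n_bins": n_bins}
    return bedpe, truth


@dataclass
class ModuleSpec:
    """One planted co-expression module: graded loadings on a latent factor.

    With ``hub_loading`` set, the first ``ceil(0.1 * size)`` genes form an
    explicit hub tier at that loading and the remaining genes are graded
    linearly from ``loading_max`` down to ``loading_min``.  The tier makes
    the planted hub set statistically identifiable: under a pure linear
    grade the loading gap between adjacent ranks (< 1/size) is far below
    the sampling error of an estimated connectivity or kME at realistic
    sample sizes, so no method can recover the exact top-loading set.
    """
    size: int
    loading_max: float = 1.0
    loading_min: float = 0.5
    hub_loading: float | None = None

    def loadings(self) -> np.ndarray:
        if self.hub_loading is None:
            return np.linspace(self.loading_max, self.loading_min, self.size)
        n_hubs = int(np.ceil(0.1 * self.size))
        rest = np.linspace(self.loading_max, self.loading_min,
                           self.size - n_hubs)
        return np.concatenate([np.full(n_hubs, self.hub_loading), rest])


def simulate_expression(n_genes: int, n_samples: int,
                        modules: list[ModuleSpec], noise_sd: float,
                        seed: int | np.random.Generator,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix with planted single-factor modules.

    Module genes are ``loading * factor + N(0, noise_sd)`` with loadings
    graded linearly from ``loading_max`` down to ``loading_min`` within the
    module, so the planted hubs (highest loadings) are known.  Remaining
    genes are independent unit-variance noise.  Returns (genes x samples
    DataFrame, truth with gene/module/loading columns).
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sum(m.size for m in modules) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    X = np.empty((n_genes, n_samples))
    labels = np.zeros(n_genes, dtype=int)
    loadings = np.zeros(n_genes)
    g = 0
    for m_i, spec in enumerate(modules, start=1):
        factor = rng.normal(size=n_samples)
        for ld in spec.loadings():
            X[g] = ld * factor + rng.normal(scale=noise_sd, size=n_samples)
            labels[g], loadings[g] = m_i, ld
            g += 1
    X[g:] = rng.normal(size=(n_genes - g, n_samples))
    expr = pd.DataFrame(X, index=genes,
                        columns=[f"s{j:03d}" for j in range(n_samples)])
    truth = pd.DataFrame({"gene": genes, "module": labels,
                          "loading": loadings})
    return expr, truth


def simulate_peak_replicates(true_peaks: pd.DataFrame, n_reps: int,
                             dropout: float, jitter: int,
                             seed: int | np.random.Generator,
                             ) -> list[pd.DataFrame]:
    """Replicate peak sets: each true peak kept with prob 1 - dropout,
    boundaries jittered by up to ``jitter`` bp each way."""
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    reps = []
    for _ in range(n_reps):
        rows = []
        for _, pk in true_peaks.iterrows():
            if rng.random() < dropout:
                continue
            ds = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            de = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            s, e = int(pk["start"]) + ds, int(pk["end"]) + de
            if e - s >= 1:
                rows.append((pk["chrom"], max(0, s), e))
        reps.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return reps


def simulate_motif_sequences(pwm, n_with: int, n_without: int, seq_len: int,
                             seed: int | np.random.Generator,
                             background: np.ndarray | None = None,
                             ) -> tuple[dict[str, str], pd.DataFrame]:
    """Sequence groups with and without one planted motif instance each.

    'with' sequences carry a single instance sampled from the PWM's
    (pseudocounted) frequencies at a recorded position on a random strand;
    'without' sequences are background-composition random.  Returns
    ({seq_id: sequence}, truth with seq_id/position/strand rows for planted
    instances).
    """
    from .phylo import reverse_complement
    if seq_len < pwm.width:
        raise ValueError("seq_len must be at least the motif width")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    bg = (np.full(4, 0.25) if background is None
          else np.asarray(background, dtype=float))
    bg = bg / bg.sum()
    freq = (pwm.counts + pwm.pseudocount) / (
        pwm.counts.sum(axis=0) + 4 * pwm.pseudocount)

    def random_seq(n: int) -> str:
        return "".join(np.array(list("ACGT"))[
            rng.choice(4, size=n, p=bg)])

    seqs, truth = {}, []
    for i in range(n_with):
        sid = f"with_{i:04d}"
        s = random_seq(seq_len)
        inst = "".join("ACGT"[rng.choice(4, p=freq[:, j])]
                       for j in range(pwm.width))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            inst = reverse_complement(inst)
        pos = int(rng.integers(0, seq_len - pwm.width + 1))
        seqs[sid] = s[:pos] + inst + s[pos + pwm.width:]
        truth.append((sid, pos, strand))
    for i in range(n_without):
        seqs[f"without_{i:04d}"] = random_seq(seq_len)
    truth_df = pd.DataFrame(truth, columns=["seq_id", "position", "strand"])
    return seqs, truth_df


# -- standard demonstration layouts ---------------------------------------

def demo_layout(n_conserved: int = 10, conserved_len: int = 200,
                neutral_len: int = 500, rho: float = 0.3,
                accelerated: dict[int, tuple[float, tuple[str, ...]]] | None = None,
                deleted: dict[int, tuple[str, ...]] | None = None,
                ) -> GenomeLayout:
    """Alternating neutral/conserved layout with optional planted events.

    ``accelerated`` maps a conserved-segment index to (r, fg_lineages);
    ``deleted`` maps one to its deleted lineage set.  Neutral spacers keep
    at least ``neutral_len`` bp of aligned flank around every event.
    """
    accelerated = accelerated or {}
    deleted = deleted or {}
    segs = [Segment(neutral_len, "neutral")]
    for i in range(n_conserved):
        if i in accelerated:
            r, lins = accelerated[i]
            segs.append(Segment(conserved_len, "accelerated", rho=rho, r=r,
                                fg_lineages=tuple(lins)))
        elif i in deleted:
            segs.append(Segment(conserved_len, "deleted", rho=rho,
                                del_lineages=tuple(deleted[i])))
        else:
            segs.append(Segment(conserved_len, "conserved", rho=rho))
        segs.append(Segment(neutral_len, "neutral"))
    return GenomeLayout(segs)
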