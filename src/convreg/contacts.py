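"""Chromatin-contact integration: element-to-gene assignment and peak logic.

Significant contacts come from proximity-ligation data binned at a fixed
width (default 10 kb).  A contact is significant when its read count is at
least ``min_count`` (default 12), its observed/expected ratio exceeds
``min_oe`` (default 2), and its q-value is at most ``max_q`` (default 0.01).
Promoters are TSS +/- 2 kb by default.  An element's 10-kb bin(s) place it in
one of three contact classes:

* ``P-P``  — the element sits in a promoter bin that significantly contacts
  another promoter bin;
* ``E-P``  — the element's bin lacks a promoter but significantly contacts at
  least one promoter bin;
* ``no-P`` — no significant promoter contacts (a sub-flag distinguishes bins
  with no significant contacts at all from bins contacting only non-promoter
  bins).

The classes partition any element set.  Elements spanning a bin boundary
belong to both bins (union of contacts) — conservative for gene assignment.

Also here: consensus peak sets (base pairs covered by >= ``min_reps``
replicates), the cross-species peak partition (species-specific vs shared by
any-overlap), and the loss-of-function enrichment of accelerated regions
against that partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import BED_COLS, any_overlap, coverage_intervals, merge_intervals
from .stats import EnrichmentResult, enrichment_2x2

BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
              "count", "obs_exp", "q_value"]


@dataclass
class ContactThresholds:
    min_count: int = 12
    min_oe: float = 2.0
    max_q: float = 0.01


@dataclass
class ContactMap:
    """Fixed-width bins with significant contacts and promoter annotations."""
    bin_size: int
    bins: pd.DataFrame                  # chrom, start, end, genes (tuple)
    contacts: pd.DataFrame              # bin1, bin2 (indices), count, obs_exp, q_value
    _neighbors: dict[int, set[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        nb: dict[int, set[int]] = {}
        for b1, b2 in zip(self.contacts["bin1"], self.contacts["bin2"]):
            nb.setdefault(int(b1), set()).add(int(b2))
            nb.setdefault(int(b2), set()).add(int(b1))
        self._neighbors = nb

    def bin_of(self, chrom: str, pos: int) -> int | None:
        m = self.bins[(self.bins["chrom"] == chrom)
                      & (self.bins["start"] <= pos)
                      & (self.bins["end"] > pos)]
        return None if m.empty else int(m.index[0])

    def bins_overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        m = self.bins[(self.bins["chrom"] == chrom)
                      & (self.bins["start"] < end)
                      & (self.bins["end"] > start)]
        return [int(i) for i in m.index]

    def neighbors(self, bin_idx: int) -> set[int]:
        return self._neighbors.get(bin_idx, set())

    def promoter_bins(self) -> set[int]:
        return {int(i) for i, g in self.bins["genes"].items() if g}


@dataclass
class ContactClass:
    element_id: str
    contact_class: str                  # 'P-P', 'E-P', or 'no-P'
    genes: frozenset[str]
    no_contact_at_all: bool = False     # sub-flag within no-P


def _tile_bins(chrom_extents: dict[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom in sorted(chrom_extents):
        n = int(np.ceil(chrom_extents[chrom] / bin_size))
        for i in range(n):
            rows.append((chrom, i * bin_size,
                         (i + 1) * bin_size, ()))
    return pd.DataFrame(rows, columns=BED_COLS + ["genes"])


def load_and_filter_contacts(bedpe: str | pd.DataFrame,
                             thresholds: ContactThresholds | None = None,
                             bin_size: int = 10_000) -> ContactMap:
    """Build a ContactMap from BEDPE rows, keeping only significant contacts.

    Symmetric duplicates (binA,binB)/(binB,binA) are collapsed.  Malformed
    rows raise ``ValueError`` with the offending line number.
    """
    thresholds = thresholds or ContactThresholds()
    if isinstance(bedpe, str):
        df = pd.read_csv(bedpe, sep="\t", header=None, names=BEDPE_COLS,
                         comment="#")
    else:
        df = bedpe.copy()
        df.columns = BEDPE_COLS[: df.shape[1]]
    for i, row in df.iterrows():
        try:
            int(row["start1"]); int(row["end1"])
            int(row["start2"]); int(row["end2"])
            float(row["count"]); float(row["obs_exp"]); float(row["q_value"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed BEDPE row at line {i + 1}: {exc}")
    extents: dict[str, int] = {}
    for c, e in zip(pd.concat([df["chrom1"], df["chrom2"]]),
                    pd.concat([df["end1"], df["end2"]])):
        extents[c] = max(extents.get(c, 0), int(e))
    bins = _tile_bins(extents, bin_size)
    key = {(r.chrom, int(r.start)): i for i, r in bins.iterrows()}

    keep = ((df["count"] >= thresholds.min_count)
            & (df["obs_exp"] > thresholds.min_oe)
            & (df["q_value"] <= thresholds.max_q))
    df = df[keep]
    seen = set()
    rows = []
    for _, r in df.iterrows():
        b1 = key[(r["chrom1"], (int(r["start1"]) // bin_size) * bin_size)]
        b2 = key[(r["chrom2"], (int(r["start2"]) // bin_size) * bin_size)]
        pair = (min(b1, b2), max(b1, b2))
        if pair in seen:
            continue
        seen.add(pair)
        rows.append((*pair, int(r["count"]), float(r["obs_exp"]),
                     float(r["q_value"])))
    contacts = pd.DataFrame(rows, columns=["bin1", "bin2", "count",
                                           "obs_exp", "q_value"])
    return ContactMap(bin_size, bins, contacts)


def annotate_promoter_bins(cmap: ContactMap, tss_table: pd.DataFrame,
                           promoter_halfwidth: int = 2000) -> ContactMap:
    """Attach gene lists to bins intersected by promoter windows.

    ``tss_table`` needs columns ``gene``, ``chrom``, ``tss`` (and optionally
    ``strand``, which only determines which transcript end the caller used as
    the TSS).  A bin lists gene g iff [TSS-hw, TSS+hw) intersects the bin; a
    window straddling a bin boundary lists the gene in both bins.
    """
    genes_per_bin: dict[int, list[str]] = {}
    for _, row in tss_table.iterrows():
        lo = int(row["tss"]) - promoter_halfwidth
        hi = int(row["tss"]) + promoter_halfwidth
        for b in cmap.bins_overlapping(row["chrom"], lo, hi):
            genes_per_bin.setdefault(b, []).append(str(row["gene"]))
    genes = [tuple(sorted(set(genes_per_bin.get(i, ()))))
             for i in cmap.bins.index]
    bins = cmap.bins.copy()
    bins["genes"] = genes
    return ContactMap(cmap.bin_size, bins, cmap.contacts)


def classify_element_contacts(elements: pd.DataFrame, cmap: ContactMap,
                              ) -> tuple[list[ContactClass], list[str]]:
    """Classify each element's promoter-contact status.

    Returns (classified, excluded_ids); elements on unbinned contigs are
    excluded.  Element ids come from a ``name`` column when present, else
    ``chrom:start-end``.
    """
    promoter_bins = cmap.promoter_bins()
    out, excluded = [], []
    for _, row in elements.iterrows():
        eid = str(row["name"]) if "name" in row and pd.notna(row.get("name")) \
            else f"{row['chrom']}:{row['start']}-{row['end']}"
        ebins = cmap.bins_overlapping(row["chrom"], int(row["start"]),
                                      int(row["end"]))
        if not ebins:
            excluded.append(eid)
            continue
        contacted = set().union(*(cmap.neighbors(b) for b in ebins))
        contacted_promoters = contacted & promoter_bins
        in_promoter_bin = any(b in promoter_bins for b in ebins)
        genes = frozenset(
            g for b in contacted_promoters for g in cmap.bins.loc[b, "genes"])
        if in_promoter_bin and contacted_promoters:
            cls = "P-P"
        elif (not in_promoter_bin) and contacted_promoters:
            cls = "E-P"
        else:
            cls = "no-P"
        out.append(ContactClass(eid, cls, genes,
                                no_contact_at_all=(len(contacted) == 0)))
    return out, excluded


def consensus_peaks(replicates: list[pd.DataFrame], min_reps: int = 4,
                    min_width: int = 50) -> pd.DataFrame:
    """Consensus peak set: bp covered by >= ``min_reps`` replicates.

    Runs of sufficient coverage are merged into maximal intervals; intervals
    narrower than ``min_width`` bp are dropped (suppresses 1-bp artifacts at
    jittered replicate edges).
    """
    return coverage_intervals(replicates, min_reps, min_width)


def classify_species_peaks(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                           ) -> dict[str, pd.DataFrame]:
    """Partition two species' peak sets (one shared coordinate system).

    Overlapping peaks within one species are merged first.  Peaks overlapping
    the other species' set (by any overlap, 1 bp suffices) are *shared*; the
    remainder are species-specific.  Keys: ``a_specific``, ``shared``,
    ``b_specific`` (shared reported from both sides, merged).
    """
    a = merge_intervals(peaks_a) if len(peaks_a) else peaks_a
    b = merge_intervals(peaks_b) if len(peaks_b) else peaks_b
    a_hit = any_overlap(a, b) if len(a) and len(b) else np.zeros(len(a), bool)
    b_hit = any_overlap(b, a) if len(a) and len(b) else np.zeros(len(b), bool)
    shared_parts = pd.concat([a[a_hit], b[b_hit]], ignore_index=True)
    shared = (merge_intervals(shared_parts) if len(shared_parts)
              else pd.DataFrame(columns=BED_COLS))
    return {"a_specific": a[~a_hit].reset_index(drop=True),
            "shared": shared,
            "b_specific": b[~b_hit].reset_index(drop=True)}


def lof_enrichment(ars: pd.DataFrame, cr_background: pd.DataFrame,
                   peak_partition: dict[str, pd.DataFrame],
                   ) -> dict[str, EnrichmentResult | None]:
    """Loss-of-function signature: AR enrichment in each peak-partition class.

    For accelerated regions of species A, depletion in A-specific and shared
    active-chromatin peaks combined with enrichment in B-specific peaks
    indicates the accelerated elements lost regulatory activity in A.  Empty
    partition classes are skipped (value ``None``).
    """
    out: dict[str, EnrichmentResult | None] = {}
    for name, peaks in peak_partition.items():
        out[name] = (enrichment_2x2(ars, cr_background, peaks, label=name)
                     if len(peaks) else None)
    return out
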