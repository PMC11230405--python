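"""Reference-anchored multiple alignments and MAF input/output.

A :class:`MultipleAlignment` is a list of blocks, each holding per-species
aligned rows over a contiguous stretch of a designated *reference* species.
Coordinates are 0-based half-open on the reference's forward strand.  MAF
``src`` fields follow the usual ``species.chrom`` convention; rows on the
``-`` strand keep their aligned text (columns stay homologous) and have their
start converted to forward-strand coordinates.

Species absent from a block, gap characters, and ambiguous bases are all
treated as missing data (code 4) when columns are extracted for likelihood
computations; deletion calling downstream distinguishes gaps from absence via
the per-lineage gap fraction within and around a region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo import MISSING, decode_bases, encode_bases


@dataclass
class AlignmentBlock:
    """One aligned block: encoded rows over a contiguous reference interval."""
    chrom: str
    ref_start: int                      # 0-based on the reference forward strand
    rows: dict[str, np.ndarray]         # species -> int8 codes, incl. gaps (4)
    src_sizes: dict[str, int] = field(default_factory=dict)
    starts: dict[str, int] = field(default_factory=dict)

    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


class MultipleAlignment:
    """Blocks of per-species aligned rows anchored on a reference species."""

    def __init__(self, reference: str, blocks: list[AlignmentBlock]):
        if not all(reference in b.rows for b in blocks):
            raise ValueError(f"reference species '{reference}' missing from a block")
        self.reference = reference
        self.blocks = sorted(blocks, key=lambda b: (b.chrom, b.ref_start))
        # per-chromosome index for fast interval queries
        self._by_chrom: dict[str, list[int]] = {}
        self._block_ends: dict[str, list[int]] = {}
        for i, b in enumerate(self.blocks):
            self._by_chrom.setdefault(b.chrom, []).append(i)
        for chrom, idxs in self._by_chrom.items():
            ends = []
            for i in idxs:
                b = self.blocks[i]
                n_ref = int((b.rows[reference] != MISSING).sum())
                ends.append(b.ref_start + n_ref)
            self._block_ends[chrom] = ends

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.blocks:
            for s in b.rows:
                seen.setdefault(s)
        return list(seen)

    def reference_extent(self, chrom: str) -> tuple[int, int]:
        """(min_start, max_end) covered by blocks on a reference chromosome."""
        spans = [(b.ref_start, b.ref_start + int((b.rows[self.reference] != MISSING).sum()))
                 for b in self.blocks if b.chrom == chrom]
        if not spans:
            raise KeyError(f"no blocks on reference chromosome '{chrom}'")
        return min(s for s, _ in spans), max(e for _, e in spans)

    def columns(self, chrom: str, start: int, end: int,
                leaf_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Extract alignment columns whose reference coordinate lies in
        ``[start, end)``.

        Returns ``(matrix, positions)`` where ``matrix`` is int8 of shape
        ``(len(leaf_names), n_cols)`` (missing species filled with 4) and
        ``positions`` gives each column's reference coordinate.  Columns where
        the reference row is a gap carry no reference coordinate and are
        skipped.
        """
        mats, poss = [], []
        idxs = self._by_chrom.get(chrom, [])
        ends = self._block_ends.get(chrom, [])
        # blocks are start-sorted; restrict to those that can intersect
        import bisect
        starts = [self.blocks[i].ref_start for i in idxs]
        lo_i = 0
        hi_i = bisect.bisect_left(starts, end)
        for k in range(lo_i, hi_i):
            if ends[k] <= start:
                continue
            b = self.blocks[idxs[k]]
            ref_row = b.rows[self.reference]
            has_ref = ref_row != MISSING
            pos = b.ref_start + np.cumsum(has_ref) - 1
            keep = has_ref & (pos >= start) & (pos < end)
            if not keep.any():
                continue
            mat = np.full((len(leaf_names), int(keep.sum())), MISSING,
                          dtype=np.int8)
            for r, name in enumerate(leaf_names):
                if name in b.rows:
                    mat[r] = b.rows[name][keep]
            mats.append(mat)
            poss.append(pos[keep])
        if not mats:
            return (np.empty((len(leaf_names), 0), dtype=np.int8),
                    np.empty(0, dtype=np.int64))
        order = np.argsort([p[0] for p in poss], kind="stable")
        return (np.concatenate([mats[i] for i in order], axis=1),
                np.concatenate([poss[i] for i in order]))


def _split_src(src: str) -> tuple[str, str]:
    species, _, chrom = src.partition(".")
    return species, chrom or "chr"


def read_maf(path: str, reference: str) -> MultipleAlignment:
    """Read a MAF file into a :class:`MultipleAlignment`.

    ``reference`` is the species (the part of ``src`` before the first dot)
    whose coordinates anchor every block.  Reverse-strand rows keep their
    aligned text; their start coordinate is converted to the forward strand
    (``srcSize - start - size``).
    """
    blocks = []
    with open(path) as fh:
        for aln in AlignIO.parse(fh, "maf"):
            rows, starts, sizes = {}, {}, {}
            chrom = None
            ref_start = None
            for rec in aln:
                species, rchrom = _split_src(rec.id)
                ann = rec.annotations
                text = str(rec.seq).upper()
                codes = encode_bases(text)
                n_bases = int((codes != MISSING).sum())
                declared = int(ann.get("size", n_bases))
                if "-" not in text and declared != n_bases:
                    raise ValueError(
                        f"MAF row for {rec.id}: declared size {declared} != "
                        f"{n_bases} aligned bases")
                start = int(ann.get("start", 0))
                src_size = int(ann.get("srcSize", 0))
                if ann.get("strand", 1) in (-1, "-"):
                    start = src_size - start - declared
                rows[species] = codes
                starts[species] = start
                sizes[species] = src_size
                if species == reference:
                    chrom = rchrom
                    ref_start = start
            if reference not in rows:
                raise ValueError(
                    f"MAF block lacks reference species '{reference}'")
            lengths = {len(v) for v in rows.values()}
            if len(lengths) != 1:
                raise ValueError("MAF block rows have unequal aligned lengths")
            blocks.append(AlignmentBlock(chrom, ref_start, rows, sizes, starts))
    return MultipleAlignment(reference, blocks)


def write_maf(path: str, alignment: MultipleAlignment,
              chrom_sizes: dict[str, int] | None = None) -> None:
    """Write the alignment to MAF (all rows forward strand)."""
    alns = []
    for b in alignment.blocks:
        recs = []
        for species, codes in b.rows.items():
            text = decode_bases(codes)
            size = int((codes != MISSING).sum())
            chrom = b.chrom if species == alignment.reference else b.chrom
            start = b.starts.get(species, b.ref_start)
            src_size = b.src_sizes.get(species, 0)
            if chrom_sizes and species in chrom_sizes:
                src_size = chrom_sizes[species]
            recs.append(SeqRecord(
                Seq(text), id=f"{species}.{chrom}",
                annotations={"start": start, "size": size, "strand": 1,
                             "srcSize": src_size or start + size}))
        alns.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(alns, fh, "maf")
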