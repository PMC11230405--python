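"""Parallel (convergent) elements across lineages and the bootstrap null.

A conserved region carrying the same class of call (acceleration or deletion)
in two or more lineages of a group — the hibernator foregrounds, or their
matched homeotherm controls — is a *parallel element*.  Overlap is defined at
the level of CR identity: the CR is the unit shared across lineages, since
per-lineage events are sub-regions of the same background element.

The significance of the observed number of parallel elements is assessed with
a resampling null: in each bootstrap replicate, every lineage independently
draws its own number of calls uniformly *without replacement* from the shared
background CR universe, and the replicate's parallel count is the number of
CRs drawn by at least ``min_lineages`` lineages.  The empirical p-value uses
the add-one estimator ``(1 + #{null >= observed}) / (B + 1)`` and therefore
never reports zero.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ParallelElement:
    """A CR called in >= min_lineages lineages of one group."""
    cr_id: str
    event_class: str          # 'AR' or 'DEL'
    group: str                # 'foreground' or 'control'
    lineages: frozenset[str]


@dataclass
class BootstrapResult:
    """Bootstrap assessment of parallel-element excess."""
    observed: int
    B: int
    null_counts: np.ndarray
    p_value: float
    null_mean: float
    null_sd: float
    seed: int | None = None
    min_lineages: int = 2
    n_background: int = 0
    calls_per_lineage: dict[str, int] = field(default_factory=dict)


def find_parallel_elements(per_lineage_calls: dict[str, set[str]],
                           group: str, event_class: str = "AR",
                           min_lineages: int = 2,
                           background_cr_ids: set[str] | None = None,
                           ) -> list[ParallelElement]:
    """Collect CRs called in at least ``min_lineages`` lineages of a group.

    If ``background_cr_ids`` is given, any call outside it raises
    ``ValueError`` (calls must come from one shared CR universe).
    """
    if background_cr_ids is not None:
        for lineage, calls in per_lineage_calls.items():
            unknown = calls - background_cr_ids
            if unknown:
                raise ValueError(
                    f"lineage '{lineage}' has calls outside the background CR "
                    f"universe: {sorted(unknown)[:5]}")
    counts: Counter[str] = Counter()
    carriers: dict[str, set[str]] = {}
    for lineage, calls in per_lineage_calls.items():
        for cr in calls:
            counts[cr] += 1
            carriers.setdefault(cr, set()).add(lineage)
    return [ParallelElement(cr, event_class, group, frozenset(carriers[cr]))
            for cr, c in sorted(counts.items()) if c >= min_lineages]


def bootstrap_parallel_excess(per_lineage_calls: dict[str, set[str]],
                              background_cr_ids: set[str] | list[str],
                              min_lineages: int = 2, B: int = 1000,
                              seed: int | np.random.Generator = 0,
                              ) -> BootstrapResult:
    """Bootstrap test for an excess of parallel elements.

    Each replicate draws, independently per lineage, that lineage's observed
    number of calls without replacement from the background universe and
    counts CRs drawn in >= ``min_lineages`` lineages.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    universe = sorted(background_cr_ids)
    n = len(universe)
    sizes = {lin: len(calls) for lin, calls in per_lineage_calls.items()}
    for lin, k in sizes.items():
        if k > n:
            raise ValueError(
                f"lineage '{lin}' has {k} calls but the background has only "
                f"{n} CRs")
    observed = len(find_parallel_elements(
        per_lineage_calls, group="any", min_lineages=min_lineages,
        background_cr_ids=set(universe)))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    null_counts = np.empty(B, dtype=np.int64)
    ks = list(sizes.values())
    hits = np.zeros(n, dtype=np.int16)
    for b in range(B):
        hits[:] = 0
        for k in ks:
            hits[rng.choice(n, size=k, replace=False)] += 1
        null_counts[b] = int((hits >= min_lineages).sum())
    p = (1 + int((null_counts >= observed).sum())) / (B + 1)
    return BootstrapResult(
        observed=observed, B=B, null_counts=null_counts, p_value=p,
        null_mean=float(null_counts.mean()), null_sd=float(null_counts.std()),
        seed=seed if isinstance(seed, int) else None,
        min_lineages=min_lineages, n_background=n, calls_per_lineage=sizes)


def size_distribution(parallel_elements: list[ParallelElement],
                      cr_lengths: dict[str, int],
                      bin_width: int = 10) -> dict[int, int]:
    """Histogram of parallel-element counts by CR length bin.

    Keys are bin lower bounds (bp); every element falls in exactly one bin, so
    bin counts sum to the element count.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    hist: Counter[int] = Counter()
    for pe in parallel_elements:
        length = cr_lengths[pe.cr_id]
        hist[(length // bin_width) * bin_width] += 1
    return dict(sorted(hist.items()))
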