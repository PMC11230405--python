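"""Enrichment statistics: 2x2 odds ratios, Woolf heterogeneity,
hypergeometric overlap, and locus-set enrichment with BH correction.

All 2x2 machinery applies the Haldane–Anscombe correction (add 0.5 to every
cell) whenever any cell is zero, and flags the result.  Fisher exact p-values
are two-sided (point-probability method, via scipy).  The Woolf test weights
per-stratum log odds ratios by the inverse of their approximate variance
``w_i = 1 / (1/a + 1/b + 1/c + 1/d)`` and refers
``X^2 = sum_i w_i (lnOR_i - pooled)^2`` to chi-square with ``strata - 1``
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .intervals import any_overlap


@dataclass
class EnrichmentResult:
    """Odds-ratio enrichment for one 2x2 table (a,b,c,d row-major)."""
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity: bool        # True when Haldane +0.5 was applied
    q_value: float = float("nan")
    label: str = ""


@dataclass
class WoolfResult:
    """Woolf chi-square test of odds-ratio homogeneity across strata."""
    statistic: float
    df: int
    p_value: float
    pooled_log_or: float
    log_ors: list[float] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)


def enrichment_from_counts(a: int, b: int, c: int, d: int,
                           label: str = "") -> EnrichmentResult:
    """Odds ratio, Wald 95% CI on the log scale, and two-sided Fisher p."""
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cells must be non-negative")
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    continuity = min(a, b, c, d) == 0
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if continuity
                      else (a, b, c, d))
    orr = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(orr) + np.array([-1.96, 1.96]) * se)
    return EnrichmentResult(a, b, c, d, float(orr), float(lo), float(hi),
                            float(p), continuity, label=label)


def _element_key(df: pd.DataFrame) -> pd.Series:
    return (df["chrom"].astype(str) + ":" + df["start"].astype(str)
            + "-" + df["end"].astype(str))


def enrichment_2x2(query: pd.DataFrame, background: pd.DataFrame,
                   targets: pd.DataFrame, label: str = "") -> EnrichmentResult:
    """Element-in-target enrichment of a query set against background.

    ``query`` must be drawn from the ``background`` universe; query elements
    are removed from the background rows so no element is counted twice.
    Membership is any-overlap with the target regions.
    """
    if len(query) == 0:
        raise ValueError("empty query set")
    bg = background[~_element_key(background).isin(set(_element_key(query)))]
    q_in = any_overlap(query, targets)
    b_in = any_overlap(bg, targets)
    return enrichment_from_counts(int(q_in.sum()), int((~q_in).sum()),
                                  int(b_in.sum()), int((~b_in).sum()),
                                  label=label)


def woolf_test(tables: list[tuple[int, int, int, int]]) -> WoolfResult:
    """Test homogeneity of odds ratios across >= 2 strata.

    Any stratum containing a zero cell gets the Haldane +0.5 correction.
    Identical strata give X^2 = 0, p = 1.
    """
    if len(tables) < 2:
        raise ValueError("Woolf test needs at least 2 strata")
    log_ors, weights = [], []
    for (a, b, c, d) in tables:
        if min(a, b, c, d) < 0:
            raise ValueError("2x2 cells must be non-negative")
        if min(a, b, c, d) == 0:
            a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        log_ors.append(np.log((a * d) / (b * c)))
        weights.append(1.0 / (1 / a + 1 / b + 1 / c + 1 / d))
    log_ors, weights = np.array(log_ors), np.array(weights)
    pooled = float((weights * log_ors).sum() / weights.sum())
    x2 = float((weights * (log_ors - pooled) ** 2).sum())
    df = len(tables) - 1
    return WoolfResult(x2, df, float(chi2.sf(x2, df)), pooled,
                       list(log_ors), list(weights))


def hypergeometric_overlap(set_a: set, set_b: set, universe: set) -> float:
    """Upper-tail hypergeometric p-value, P(X >= |A & B|).

    Both sets must be subsets of the universe; violations raise ``ValueError``
    listing the offenders.  Computed in log-space by scipy's survival
    function, so large universes do not underflow.
    """
    bad_a, bad_b = set_a - universe, set_b - universe
    if bad_a or bad_b:
        raise ValueError(
            f"sets not within universe: A-extra={sorted(bad_a)[:5]} "
            f"B-extra={sorted(bad_b)[:5]}")
    n_overlap = len(set_a & set_b)
    return float(hypergeom.sf(n_overlap - 1, len(universe), len(set_a),
                              len(set_b)))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values."""
    return multipletests(np.asarray(pvals, dtype=float),
                         method="fdr_bh")[1]


def locus_set_enrichment(elements: pd.DataFrame, region_sets:
                         dict[str, pd.DataFrame],
                         universe_elements: pd.DataFrame,
                         ) -> list[EnrichmentResult]:
    """LOLA-style overlap enrichment of an element set per region set.

    ``enrichment_2x2`` against the element universe for every region set,
    with BH correction across the collection.
    """
    results = [enrichment_2x2(elements, universe_elements, regions, label=name)
               for name, regions in region_sets.items()]
    qvals = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return results


def differential_chisq(observed: list[int],
                       expected: list[float] | None = None,
                       ) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of observed category counts.

    Default null: equal split across categories.  Returns (X^2, df, p).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.sum() < 1:
        raise ValueError("total observed count must be >= 1")
    exp = (np.full(len(obs), obs.sum() / len(obs)) if expected is None
           else np.asarray(expected, dtype=float))
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    x2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return x2, df, float(chi2.sf(x2, df))
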