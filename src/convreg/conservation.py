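"""Conserved-region calling with a two-state phylogenetic HMM.

The model has two hidden states, *neutral* and *conserved*.  Emissions are
phylogenetic column likelihoods under a fixed tree and substitution model: the
neutral state uses the branch lengths as given, the conserved state scales all
branches by a factor ``rho`` in (0, 1].  State transitions are governed by
``mu`` (conserved -> neutral) and ``nu`` (neutral -> conserved); the chain is
started at its stationary distribution.

Defaults are chosen so the expected conserved-element length is 45 bp
(``mu = 1/45``) and the stationary conserved fraction is 5 %
(``nu = mu * 0.05/0.95``), matching a genome where short conserved elements
(modal size a few tens of bp) cover a few percent of aligned sequence.

Decoding is posterior thresholding by default (threshold 0.5, ties conserved);
Viterbi decoding is available.  Regions shorter than ``min_length`` reference
bp (default 20) are discarded.  A simulation-based score threshold targeting a
given false-discovery rate is provided by :func:`estimate_cr_fdr`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MultipleAlignment
from .phylo import HKYModel, PhyloTree, TreeLikelihood, simulate_columns


@dataclass
class PhyloHMMParams:
    """Tuning parameters of the two-state conservation HMM."""
    rho: float = 0.3                 # conserved branch scale, in (0, 1]
    mu: float = 1.0 / 45.0           # P(conserved -> neutral)
    nu: float = (1.0 / 45.0) * (0.05 / 0.95)   # P(neutral -> conserved)
    decoding: str = "posterior"      # 'posterior' or 'viterbi'
    posterior_threshold: float = 0.5
    min_length: int = 20             # minimum CR length in reference bp
    min_informative_frac: float = 0.5  # min mean fraction of non-missing leaves

    def __post_init__(self):
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if not (0 < self.mu < 1 and 0 < self.nu < 1):
            raise ValueError("mu and nu must be in (0, 1)")
        if self.decoding not in ("posterior", "viterbi"):
            raise ValueError("decoding must be 'posterior' or 'viterbi'")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")

    @property
    def stationary_conserved(self) -> float:
        return self.nu / (self.mu + self.nu)


@dataclass(frozen=True)
class ConservedRegion:
    """A called conserved region on the reference (0-based half-open)."""
    chrom: str
    start: int
    end: int
    score: float     # mean conserved-state posterior over the region

    @property
    def length(self) -> int:
        return self.end - self.start


def _log_emissions(columns: np.ndarray, tree: PhyloTree, model: HKYModel,
                   rho: float) -> np.ndarray:
    """(n_cols, 2) log emission matrix: column 0 neutral, column 1 conserved."""
    tl = TreeLikelihood(tree, model)
    le = np.stack([tl.column_log_likelihoods(columns, scale=1.0),
                   tl.column_log_likelihoods(columns, scale=rho)], axis=1)
    if not np.all(np.isfinite(le)):
        bad = int(np.argwhere(~np.isfinite(le).all(axis=1))[0][0])
        raise ValueError(f"non-finite emission at column {bad}")
    return le


def forward_backward(columns: np.ndarray, tree: PhyloTree, model: HKYModel,
                     params: PhyloHMMParams) -> np.ndarray:
    """Posterior probability of the conserved state per alignment column.

    Computed with per-column rescaling (log-space safe for millions of
    columns).  All-missing columns emit equally in both states, so their
    posterior relaxes toward the chain's stationary conserved probability.
    """
    post, _ = _forward_backward_full(columns, tree, model, params)
    return post


def total_log_likelihood(columns: np.ndarray, tree: PhyloTree,
                         model: HKYModel, params: PhyloHMMParams) -> float:
    """Marginal log-likelihood of the column sequence under the HMM."""
    _, ll = _forward_backward_full(columns, tree, model, params)
    return ll


def _forward_backward_full(columns, tree, model, params):
    le = _log_emissions(columns, tree, model, params.rho)
    n = le.shape[0]
    if n == 0:
        raise ValueError("need at least one column")
    # per-column normalization keeps emissions in (0, 1]; posteriors unchanged
    shift = le.max(axis=1)
    e = np.exp(le - shift[:, None])
    T = np.array([[1 - params.nu, params.nu],
                  [params.mu, 1 - params.mu]])
    start = np.array([1 - params.stationary_conserved,
                      params.stationary_conserved])

    alpha = np.empty((n, 2))
    cnorm = np.empty(n)
    a = start * e[0]
    cnorm[0] = a.sum()
    alpha[0] = a / cnorm[0]
    for i in range(1, n):
        a = (alpha[i - 1] @ T) * e[i]
        cnorm[i] = a.sum()
        alpha[i] = a / cnorm[i]

    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        b = T @ (e[i + 1] * beta[i + 1])
        beta[i] = b / cnorm[i + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(cnorm).sum() + shift.sum())
    return gamma[:, 1], loglik


def viterbi_path(columns: np.ndarray, tree: PhyloTree, model: HKYModel,
                 params: PhyloHMMParams) -> np.ndarray:
    """Most probable state path (bool array, True = conserved)."""
    le = _log_emissions(columns, tree, model, params.rho)
    n = le.shape[0]
    logT = np.log(np.array([[1 - params.nu, params.nu],
                            [params.mu, 1 - params.mu]]))
    delta = np.log([1 - params.stationary_conserved,
                    params.stationary_conserved]) + le[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        cand = delta[:, None] + logT
        back[i] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + le[i]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(delta.argmax())
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path.astype(bool)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open index pairs."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def call_conserved_regions(alignment: MultipleAlignment, tree: PhyloTree,
                           model: HKYModel, params: PhyloHMMParams,
                           chrom: str | None = None) -> list[ConservedRegion]:
    """Call conserved regions from the alignment on the reference coordinates.

    Maximal runs of conserved-decoded columns are mapped to reference
    intervals (columns where the reference is gapped carry no coordinate; a
    run spanning them is emitted as the containing reference interval),
    filtered to ``length >= min_length``, and returned sorted and
    non-overlapping.  An empty alignment yields an empty list.
    """
    chroms = ([chrom] if chrom else
              sorted({b.chrom for b in alignment.blocks}))
    leaf_names = tree.leaf_names
    out: list[ConservedRegion] = []
    for c in chroms:
        lo, hi = alignment.reference_extent(c)
        cols, pos = alignment.columns(c, lo, hi, leaf_names)
        if cols.shape[1] == 0:
            continue
        post = forward_backward(cols, tree, model, params)
        if params.decoding == "posterior":
            conserved = post >= params.posterior_threshold
        else:
            conserved = viterbi_path(cols, tree, model, params)
        for i0, i1 in _runs(conserved):
            start, end = int(pos[i0]), int(pos[i1 - 1]) + 1
            if end - start < params.min_length:
                continue
            if params.min_informative_frac > 0:
                informative = (cols[:, i0:i1] != 4).mean()
                if informative < params.min_informative_frac:
                    continue
            out.append(ConservedRegion(c, start, end,
                                       float(post[i0:i1].mean())))
    return out


def fit_hmm_rho(alignment: MultipleAlignment, tree: PhyloTree,
                model: HKYModel, params: PhyloHMMParams,
                chrom: str | None = None) -> float:
    """Estimate the conserved branch scale by maximum marginal likelihood.

    Coarse grid over {0.1 .. 0.9} followed by bounded golden-section
    refinement around the best grid point.
    """
    chroms = ([chrom] if chrom else sorted({b.chrom for b in alignment.blocks}))
    pieces = []
    for c in chroms:
        lo, hi = alignment.reference_extent(c)
        cols, _ = alignment.columns(c, lo, hi, tree.leaf_names)
        if cols.shape[1]:
            pieces.append(cols)
    cols = np.concatenate(pieces, axis=1)

    def nll(rho: float) -> float:
        return -total_log_likelihood(cols, tree, model,
                                     replace(params, rho=float(rho)))

    grid = np.arange(0.1, 0.95, 0.1)
    best = grid[int(np.argmin([nll(r) for r in grid]))]
    res = minimize_scalar(nll, bounds=(max(best - 0.1, 1e-3),
                                       min(best + 0.1, 1.0)),
                          method="bounded", options={"xatol": 1e-4})
    return float(res.x)


def estimate_cr_fdr(observed_scores: np.ndarray, tree: PhyloTree,
                    model: HKYModel, params: PhyloHMMParams,
                    n_null_bp: int, observed_bp: int,
                    seed: int | np.random.Generator,
                    target: float = 0.05) -> float:
    """Score threshold at which the estimated FDR of CR calls meets ``target``.

    A neutral alignment of ``n_null_bp`` columns is simulated under the model
    (all leaves present), candidate regions are called with the same HMM
    parameters, and the returned threshold is the smallest observed score t
    such that ``(#null >= t) * (observed_bp / n_null_bp) / (#observed >= t)``
    is at most ``target``.  Monotone (non-increasing threshold) in ``target``.
    """
    observed_scores = np.sort(np.asarray(observed_scores, dtype=float))
    if observed_scores.size == 0:
        raise ValueError("no observed conserved regions to threshold")
    if n_null_bp < 10 * params.min_length:
        raise ValueError("n_null_bp must be at least 10 * min_length")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cols = simulate_columns(tree, model, n_null_bp, scale=1.0, rng=rng)
    post = forward_backward(cols, tree, model, params)
    if params.decoding == "posterior":
        conserved = post >= params.posterior_threshold
    else:
        conserved = viterbi_path(cols, tree, model, params)
    null_scores = np.sort([float(post[i0:i1].mean())
                           for i0, i1 in _runs(conserved)
                           if i1 - i0 >= params.min_length])
    factor = observed_bp / n_null_bp
    # candidate thresholds: the observed scores, ascending
    n_obs = observed_scores.size
    for i, t in enumerate(observed_scores):
        n_above_obs = n_obs - i
        n_above_null = null_scores.size - np.searchsorted(null_scores, t)
        fdr_hat = min(1.0, (n_above_null * factor) / n_above_obs)
        if fdr_hat <= target:
            return float(t)
    return float(observed_scores[-1])
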