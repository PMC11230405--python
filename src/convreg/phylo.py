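"""Phylogenetic trees, nucleotide substitution models, and pruning likelihoods.

This module is the computational substrate for conserved-element detection and
lineage-specific acceleration testing.  It provides:

* :class:`PhyloTree` — a rooted tree with branch lengths in expected
  substitutions per site, round-trippable through Newick.
* :class:`HKYModel` — an HKY-style reversible nucleotide model (equilibrium
  frequencies ``pi`` and transition/transversion ratio ``kappa``); ``kappa=1``
  with uniform ``pi`` reduces to the Jukes–Cantor equal-rate model, which has
  closed-form transition probabilities used by the test suite.
* :class:`TreeLikelihood` — vectorized Felsenstein pruning over many alignment
  columns at once, with optional per-branch rate multipliers (the quantity the
  acceleration likelihood-ratio test optimizes).
* :func:`simulate_columns` — forward simulation of alignment columns along the
  tree, used by the neutral-null calibration machinery.

Bases are encoded as integers 0..3 for A,C,G,T; the value 4 (``MISSING``)
represents both alignment gaps and unaligned/missing leaves, which contribute a
partial-likelihood vector of ones (fully missing data).  Evidence for
lineage-specific *deletion* is handled separately, downstream, so gap runs do
not inflate rate estimates here.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy
import numpy as np

BASES = "ACGT"
MISSING = 4
_ENCODE = np.full(256, MISSING, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A,C,G,T -> 0..3, else 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_bases`; MISSING decodes to ``-``."""
    lookup = np.array(list(BASES + "-"), dtype="U1")
    return "".join(lookup[np.asarray(codes)])


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c.upper(), "N") for c in reversed(seq))


class PhyloTree:
    """A rooted phylogeny with non-negative branch lengths.

    Nodes are stored in postorder; every non-root node carries the length of
    the branch to its parent (expected substitutions per site).  Leaf names
    are unique and non-empty.  Internal nodes may carry labels, usable as
    branch identifiers for per-branch rate scaling.
    """

    def __init__(self, parent: np.ndarray, lengths: np.ndarray,
                 labels: list[str | None], is_leaf: np.ndarray):
        self.parent = parent          # parent index per node; -1 at root
        self.lengths = lengths        # branch length to parent; 0 at root
        self.labels = labels
        self.is_leaf = is_leaf
        n = len(parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(parent):
            if p < 0:
                root = i
            else:
                self.children[p].append(i)
        self.root = root
        self.postorder = self._postorder()
        self.leaf_names = [labels[i] for i in range(n) if is_leaf[i]]
        self.leaf_index = {labels[i]: i for i in range(n) if is_leaf[i]}
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a single rooted Newick statement.

        Missing branch lengths default to 0.  Unbalanced parentheses,
        duplicate leaf names, and negative branch lengths raise
        :class:`NewickError` naming the offending token.
        """
        text = text.strip()
        if not text.endswith(";"):
            raise NewickError("Newick statement must end with ';'")
        if text.count("(") != text.count(")"):
            raise NewickError(
                f"unbalanced parentheses: {text.count('(')} '(' vs "
                f"{text.count(')')} ')'")
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                terminating_semicolon_required=True)
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"Newick parse failed: {exc}") from exc

        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n, dtype=float)
        labels: list[str | None] = [None] * n
        is_leaf = np.zeros(n, dtype=bool)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                bl = nd.edge.length
                if bl is not None:
                    if not np.isfinite(bl):
                        raise NewickError(f"non-finite branch length: {bl}")
                    if bl < 0:
                        raise NewickError(f"negative branch length: {bl}")
                    lengths[i] = float(bl)
            if nd.is_leaf():
                is_leaf[i] = True
                name = nd.taxon.label if nd.taxon else None
                if not name:
                    raise NewickError("leaf with empty name")
                labels[i] = name.replace(" ", "_")
            elif nd.label:
                labels[i] = nd.label
        names = [labels[i] for i in range(n) if is_leaf[i]]
        dupes = {x for x in names if names.count(x) > 1}
        if dupes:
            raise NewickError(f"duplicate leaf names: {sorted(dupes)}")
        return cls(parent, lengths, labels, is_leaf)

    def _postorder(self) -> np.ndarray:
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.array(order, dtype=np.int64)

    def _validate(self) -> None:
        if self.root < 0:
            raise NewickError("tree has no root")
        if len(self.postorder) != len(self.parent):
            raise NewickError("tree contains a cycle or unreachable nodes")
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise NewickError("branch lengths must be finite and non-negative")
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise NewickError("duplicate leaf names")

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_leaf[i]:
                s = self.labels[i]
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
                if self.labels[i]:
                    s += self.labels[i]
            if i != self.root:
                s += f":{self.lengths[i]:.10g}"
            return s
        return fmt(self.root) + ";"

    # -- queries -----------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def branch_index(self, label: str) -> int:
        """Node index identifying the branch above the named node."""
        for i, lab in enumerate(self.labels):
            if lab == label:
                if i == self.root:
                    raise KeyError(f"'{label}' is the root; it has no branch")
                return i
        raise KeyError(f"no node labelled '{label}'")

    def total_length(self) -> float:
        return float(self.lengths.sum())


class HKYModel:
    """HKY-style reversible substitution model.

    Parameters
    ----------
    pi : equilibrium base frequencies (A,C,G,T); must be positive and sum to 1.
    kappa : transition/transversion rate ratio (> 0); ``kappa=1`` gives the
        equal-rate (F81/JC-type) special case.

    The rate matrix Q is normalized so that one unit of branch length equals
    one expected substitution per site at equilibrium
    (``-sum_i pi_i Q_ii = 1``).  Transition matrices are computed exactly by
    eigendecomposition of the symmetrized form
    ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``.
    """

    #: index pairs that are transitions (A<->G, C<->T)
    _TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}

    def __init__(self, pi: Sequence[float] | None = None, kappa: float = 1.0):
        pi = np.full(4, 0.25) if pi is None else np.asarray(pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be 4 positive frequencies summing to 1")
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        self.pi = pi / pi.sum()
        self.kappa = float(kappa)
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i != j:
                    rate = self.kappa if (i, j) in self._TRANSITIONS else 1.0
                    Q[i, j] = rate * self.pi[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(self.pi @ np.diag(Q))
        self.Q = Q / mu
        # eigendecomposition of the symmetrized rate matrix (exact P(t))
        sp = np.sqrt(self.pi)
        S = (sp[:, None] * self.Q) / sp[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2)
        self._w = w
        self._left = U.T * sp[None, :]          # U' diag(sqrt pi)
        self._right = (1 / sp)[:, None] * U     # diag(1/sqrt pi) U

    @classmethod
    def jukes_cantor(cls) -> "HKYModel":
        return cls(pi=None, kappa=1.0)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt): row-stochastic matrix of substitution probabilities."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        P = (self._right * np.exp(self._w * t)) @ self._left
        return np.clip(P, 0.0, 1.0)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of branch lengths, shape (n, 4, 4)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be non-negative")
        E = np.exp(np.multiply.outer(ts, self._w))            # (n, 4)
        P = np.einsum("ij,nj,jk->nik", self._right, E, self._left)
        return np.clip(P, 0.0, 1.0)


def _resolve_scales(tree: PhyloTree,
                    branch_scales: Mapping[str, float] | None) -> np.ndarray:
    scales = np.ones(len(tree.parent))
    if branch_scales:
        for label, s in branch_scales.items():
            if s <= 0:
                raise ValueError(f"branch scale for '{label}' must be > 0")
            scales[tree.branch_index(label)] = s
    return scales


class TreeLikelihood:
    """Felsenstein pruning over batches of alignment columns.

    Columns are an int8 array of shape ``(n_leaves, n_columns)`` in the order
    of ``tree.leaf_names``; value 4 marks gap/missing leaves (partial
    likelihood of ones).  Likelihoods are computed with per-node rescaling so
    arbitrarily many taxa do not underflow.
    """

    def __init__(self, tree: PhyloTree, model: HKYModel):
        self.tree = tree
        self.model = model
        # postorder with leaves materialized; cache structure arrays
        self._nonroot = np.array(
            [i for i in tree.postorder if i != tree.root], dtype=np.int64)

    def column_log_likelihoods(self, columns: np.ndarray, scale: float = 1.0,
                               branch_scales: Mapping[str, float] | None = None,
                               ) -> np.ndarray:
        """Per-column log-likelihoods.

        ``scale`` multiplies every branch; ``branch_scales`` maps a node label
        (leaf name or internal-node label) to an extra multiplier on the
        branch above that node.
        """
        tree, model = self.tree, self.model
        columns = np.asarray(columns)
        if columns.ndim == 1:
            columns = columns[:, None]
        if columns.shape[0] != tree.n_leaves:
            raise ValueError(
                f"columns have {columns.shape[0]} rows but tree has "
                f"{tree.n_leaves} leaves")
        if scale < 0:
            raise ValueError("scale must be non-negative")
        per_branch = _resolve_scales(tree, branch_scales)
        ts = tree.lengths * per_branch * scale
        P = model.transition_matrices(ts)

        ncols = columns.shape[1]
        leaf_row = {tree.leaf_index[name]: r
                    for r, name in enumerate(tree.leaf_names)}
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(ncols)
        eye5 = np.vstack([np.eye(4), np.ones(4)])  # rows: A,C,G,T,missing
        for node in tree.postorder:
            if tree.is_leaf[node]:
                partial[node] = eye5[columns[leaf_row[node]]]
                continue
            prod = None
            for child in tree.children[node]:
                msg = partial.pop(child) @ P[child].T
                prod = msg if prod is None else prod * msg
            m = prod.max(axis=1)
            # fully-missing subtrees keep probability 1; avoid 0/0
            safe = np.where(m > 0, m, 1.0)
            logscale += np.log(safe)
            partial[node] = prod / safe[:, None]
        lik = partial[tree.root] @ model.pi
        with np.errstate(divide="ignore"):
            return np.log(lik) + logscale

    def log_likelihood(self, columns: np.ndarray, scale: float = 1.0,
                       branch_scales: Mapping[str, float] | None = None,
                       ) -> float:
        """Summed log-likelihood over all columns."""
        return float(self.column_log_likelihoods(
            columns, scale, branch_scales).sum())


def column_log_likelihood(tree: PhyloTree, model: HKYModel,
                          column: Mapping[str, str] | np.ndarray,
                          branch_scales: Mapping[str, float] | None = None,
                          ) -> float:
    """Log-likelihood of one alignment column.

    ``column`` is either a mapping from leaf name to a single-character state
    (A/C/G/T, '-' or 'N' for missing) or an already-encoded int8 vector in
    ``tree.leaf_names`` order.  Raises ``ValueError`` listing unmatched names
    if the column's leaves do not match the tree's.
    """
    if isinstance(column, Mapping):
        missing = set(tree.leaf_names) - set(column)
        extra = set(column) - set(tree.leaf_names)
        if missing or extra:
            raise ValueError(
                f"column/tree leaf mismatch: missing={sorted(missing)} "
                f"extra={sorted(extra)}")
        codes = encode_bases("".join(column[n] for n in tree.leaf_names))
    else:
        codes = np.asarray(column, dtype=np.int8)
        if codes.shape != (tree.n_leaves,):
            raise ValueError("encoded column length does not match leaf count")
    tl = TreeLikelihood(tree, model)
    return float(tl.column_log_likelihoods(codes[:, None], 1.0,
                                           branch_scales)[0])


def simulate_columns(tree: PhyloTree, model: HKYModel, n: int,
                     scale: float = 1.0,
                     branch_scales: Mapping[str, float] | None = None,
                     rng: np.random.Generator | int | None = None,
                     ) -> np.ndarray:
    """Simulate ``n`` independent alignment columns along the tree.

    Root states are drawn from the model's equilibrium frequencies and
    propagated to descendants with the (scaled) transition matrices.  Returns
    an int8 array of shape ``(n_leaves, n)`` in ``tree.leaf_names`` order.
    Deterministic for a fixed ``rng`` seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    per_branch = _resolve_scales(tree, branch_scales)
    ts = tree.lengths * per_branch * scale
    P = model.transition_matrices(ts)
    Pcum = np.cumsum(P, axis=2)

    states = np.empty((len(tree.parent), n), dtype=np.int8)
    pi_cum = np.cumsum(model.pi)
    states[tree.root] = np.searchsorted(pi_cum, rng.random(n), side="right")
    for node in tree.postorder[::-1]:  # preorder
        for child in tree.children[node]:
            u = rng.random(n)
            cum = Pcum[child][states[node]]            # (n, 4)
            states[child] = (u[:, None] > cum).sum(axis=1)
    leaf_idx = np.array([tree.leaf_index[name] for name in tree.leaf_names])
    return states[leaf_idx]
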