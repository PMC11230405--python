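import numpy as np
import pytest

import convreg as cv


@pytest.fixture(scope="session")
def tree():
    return cv.demo_tree()


@pytest.fixture(scope="session")
def jc():
    return cv.HKYModel.jukes_cantor()


@pytest.fixture(scope="session")
def hky():
    return cv.HKYModel(pi=[0.3, 0.2, 0.2, 0.3], kappa=2.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def brute_force_column_loglik(tree, model, column_codes, scale=1.0,
                              branch_scales=None):
    """Independent pruning oracle: sum over all internal-node state
    assignments, using transition matrices directly."""
    from itertools import product

    per_branch = np.ones(len(tree.parent))
    if branch_scales:
        for label, s in branch_scales.items():
            per_branch[tree.branch_index(label)] = s
    P = {i: model.transition_matrix(tree.lengths[i] * per_branch[i] * scale)
         for i in range(len(tree.parent)) if i != tree.root}
    internal = [i for i in range(len(tree.parent)) if not tree.is_leaf[i]]
    leaf_state = {}
    for r, name in enumerate(tree.leaf_names):
        leaf_state[tree.leaf_index[name]] = int(column_codes[r])
    total = 0.0
    for assign in product(range(4), repeat=len(internal)):
        states = dict(zip(internal, assign))
        states.update(leaf_state)
        p = model.pi[states[tree.root]]
        for i in range(len(tree.parent)):
            if i == tree.root:
                continue
            s = states[i]
            if s == 4:      # missing leaf: marginalize (prob 1)
                continue
            p *= P[i][states[tree.parent[i]], s]
        total += p
    return np.log(total)
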