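"""Independent brute-force oracles used to validate the fast implementations.

These enumerate state assignments exhaustively and are intentionally written
without reusing the package's pruning/parsimony code paths.
"""

import itertools

import numpy as np

from ancres.substitution import N_STATES


def brute_force_site_likelihood(tree, aln, model, site):
    """Likelihood of one alignment column by exhaustive enumeration over all
    internal-node state assignments and rate categories."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    total = 0.0
    for k, rate in enumerate(model.rates):
        P = {node: model.transition_matrix(node.edge.length or 0.0, rate)
             for node in tree.preorder_node_iter()
             if node is not tree.seed_node}
        for assign in itertools.product(range(N_STATES), repeat=len(internal)):
            state = dict(zip(internal, assign))
            val = model.weights[k] * model.pi[state[tree.seed_node]]
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    continue
                parent_state = state[node.parent_node]
                if node.is_leaf():
                    code = aln.row(node.taxon.label)[site]
                    p = 1.0 if code >= N_STATES else P[node][parent_state, code]
                else:
                    p = P[node][parent_state, state[node]]
                val *= p
                if val == 0.0:
                    break
            total += val
    return total


def brute_force_log_likelihood(tree, aln, model):
    return float(sum(np.log(brute_force_site_likelihood(tree, aln, model, s))
                     for s in range(aln.n_sites)))


def brute_force_marginal_posterior(tree, aln, model, target_label, site):
    """Posterior over the target internal node's state at one site, by Bayes
    over the exhaustive enumeration."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    labels = [n.label for n in internal]
    t_idx = labels.index(target_label)
    numer = np.zeros(N_STATES)
    for k, rate in enumerate(model.rates):
        P = {node: model.transition_matrix(node.edge.length or 0.0, rate)
             for node in tree.preorder_node_iter()
             if node is not tree.seed_node}
        for assign in itertools.product(range(N_STATES), repeat=len(internal)):
            state = dict(zip(internal, assign))
            val = model.weights[k] * model.pi[state[tree.seed_node]]
            for node in tree.preorder_node_iter():
                if node is tree.seed_node:
                    continue
                parent_state = state[node.parent_node]
                if node.is_leaf():
                    code = aln.row(node.taxon.label)[site]
                    p = 1.0 if code >= N_STATES else P[node][parent_state, code]
                else:
                    p = P[node][parent_state, state[node]]
                val *= p
                if val == 0.0:
                    break
            numer[assign[t_idx]] += val
    return numer / numer.sum()


def brute_force_fitch(tree, leaf_states):
    """Minimum number of binary-character changes over all full labelings,
    and the set of root states attaining it."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    best_root_states = set()
    for assign in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, assign))

        def node_state(node):
            if node.is_leaf():
                return leaf_states[node.taxon.label]
            return state[node]

        changes = sum(
            1 for node in tree.preorder_node_iter()
            if node is not tree.seed_node
            and node_state(node) != node_state(node.parent_node))
        root_state = state[tree.seed_node]
        if best is None or changes < best:
            best = changes
            best_root_states = {root_state}
        elif changes == best:
            best_root_states.add(root_state)
    return best, best_root_states
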