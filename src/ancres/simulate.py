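"""Synthetic data with recorded ground truth.

Every generator is a pure function of its parameters and a seed, emitting the
same standard formats the analysis modules consume:

* protein alignments evolved site-by-site under the substitution model along
  a tree, with the true sequence at every internal node recorded;
* binary presence/absence characters evolved under a two-state gain/loss
  CTMC (the stand-in for alignment gap blocks);
* Michaelis-Menten rate datasets and single-exponential stopped-flow traces,
  with multiplicative noise on rates (typical of enzymatic assays, where
  error scales with signal) and additive noise on photometric traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .kinetics import RateDataset, michaelis_menten
from .substitution import AMINO_ACIDS, N_STATES, SubstitutionModel
from .trees import node_label


@dataclass
class SimulationTruth:
    """Ground truth recorded during an alignment simulation."""

    seed: int
    alpha: float
    node_sequences: dict[str, str]     # every internal node, by label
    site_categories: np.ndarray        # per-site gamma category index
    tree_newick: str = ""


def _sample_markov_step(parent_states: np.ndarray, P: np.ndarray,
                        u: np.ndarray) -> np.ndarray:
    """Draw child states given parent states and a transition matrix, using
    pre-drawn uniforms (one per site)."""
    cum = np.cumsum(P, axis=1)
    return (cum[parent_states] < u[:, None]).sum(axis=1).astype(np.int64)


def simulate_alignment(tree, model: SubstitutionModel, n_sites: int,
                       seed: int) -> tuple[Alignment, SimulationTruth]:
    """Evolve an alignment along the tree under the model.

    Root states are drawn from the equilibrium frequencies; each site draws
    one of the K discrete-gamma rates uniformly (exactly the mixture the
    likelihood assumes, so calibration tests are exact-model tests); states
    then evolve down each branch with P(Q, r·t).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    categories = rng.integers(0, model.n_categories, size=n_sites)
    states: dict = {}
    root = tree.seed_node
    states[root] = _sample_markov_step(
        np.zeros(n_sites, dtype=np.int64),
        np.tile(model.pi, (N_STATES, 1)),
        rng.random(n_sites),
    )
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length
        if t is None:
            raise ValueError(
                f"branch above {node_label(node)!r} has no length")
        parent = states[node.parent_node]
        child = np.empty(n_sites, dtype=np.int64)
        u = rng.random(n_sites)
        for k, rate in enumerate(model.rates):
            sel = categories == k
            if not sel.any():
                continue
            P = model.transition_matrix(t, rate)
            child[sel] = _sample_markov_step(parent[sel], P, u[sel])
        states[node] = child

    def decode(arr):
        return "".join(AMINO_ACIDS[i] for i in arr)

    ids, rows = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        rows.append(states[leaf])
    aln = Alignment(ids=ids, codes=np.array(rows, dtype=np.int8))
    truth = SimulationTruth(
        seed=seed, alpha=model.alpha,
        node_sequences={node_label(n): decode(states[n])
                        for n in tree.preorder_node_iter() if not n.is_leaf()},
        site_categories=categories,
        tree_newick=tree.as_string(schema="newick"),
    )
    return aln, truth


@dataclass
class IndelSimulation:
    taxa: list[str]
    matrix: np.ndarray                 # (n_taxa, n_chars) of 0/1
    node_states: dict[str, np.ndarray]  # internal nodes, by label
    seed: int


def _two_state_transition(gain: float, loss: float, t: float) -> np.ndarray:
    """Closed-form P(t) of the absent<->present chain (0 gains at ``gain``,
    1 is lost at ``loss``)."""
    total = gain + loss
    pi1 = gain / total
    decay = np.exp(-total * t)
    return np.array([
        [1 - pi1 + pi1 * decay, pi1 * (1 - decay)],
        [(1 - pi1) * (1 - decay), pi1 + (1 - pi1) * decay],
    ])


def simulate_indels(tree, gain_rate: float, loss_rate: float, n_chars: int,
                    seed: int) -> IndelSimulation:
    """Binary presence/absence characters under a gain/loss CTMC, root state
    from the stationary distribution, truth at every node."""
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    if gain_rate == 0 and loss_rate == 0:
        raise ValueError("gain and loss rates cannot both be zero")
    rng = np.random.default_rng(seed)
    pi1 = gain_rate / (gain_rate + loss_rate)
    states: dict = {}
    states[tree.seed_node] = (rng.random(n_chars) < pi1).astype(np.int64)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        P = _two_state_transition(gain_rate, loss_rate, t)
        states[node] = _sample_markov_step(states[node.parent_node], P,
                                           rng.random(n_chars))
    taxa, rows = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append(states[leaf])
    return IndelSimulation(
        taxa=taxa, matrix=np.array(rows),
        node_states={node_label(n): states[n]
                     for n in tree.preorder_node_iter() if not n.is_leaf()},
        seed=seed,
    )


def simulate_mm_dataset(k_cat: float, K_M: float, concentrations, cv: float,
                        seed: int, n_replicates: int = 1) -> RateDataset:
    """Michaelis-Menten rates with multiplicative Gaussian noise (CV)."""
    if k_cat <= 0 or K_M <= 0 or cv < 0:
        raise ValueError("k_cat, K_M must be positive and cv non-negative")
    rng = np.random.default_rng(seed)
    conc = np.tile(np.asarray(concentrations, dtype=float), n_replicates)
    rep = np.repeat(np.arange(n_replicates), len(concentrations))
    true = michaelis_menten(conc, k_cat, K_M)
    noisy = true * (1.0 + cv * rng.standard_normal(conc.size))
    return RateDataset(conc_uM=conc, rate_per_s=noisy, replicate=rep)


def simulate_kobs_curve(k_red: float, K_d: float, concentrations, cv: float,
                        seed: int, n_replicates: int = 1):
    """Stopped-flow k_obs saturation points, same noise model as rates.

    Returns ``(conc_uM, k_obs)`` arrays.
    """
    data = simulate_mm_dataset(k_red, K_d, concentrations, cv, seed,
                               n_replicates)
    return data.conc_uM, data.rate_per_s


def simulate_trace(k_obs: float, A0: float, A_inf: float, noise_sd: float,
                   dt: float, n_points: int, seed: int):
    """Single-exponential absorbance trace with additive Gaussian noise.

    Returns ``(time_s, absorbance)``; A(t) = (A0 - A_inf)·exp(-k_obs·t) + A_inf.
    """
    if k_obs <= 0 or dt <= 0 or n_points < 2 or noise_sd < 0:
        raise ValueError("invalid trace parameters")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    y = (A0 - A_inf) * np.exp(-k_obs * t) + A_inf
    return t, y + noise_sd * rng.standard_normal(n_points)


def random_tree(n_taxa: int, seed: int, height: float = 0.5):
    """A random bifurcating tree with exponential branch lengths, rescaled so
    the mean root-to-tip path length is ``height`` substitutions/site.

    Topology by random sequential pairwise joining — deterministic in the
    seed, with no dependence on any library's sampler internals.
    """
    import dendropy

    from .trees import label_internal_nodes, read_newick

    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    subtrees = [f"t{i + 1}" for i in range(n_taxa)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        subtrees.append(f"({left},{right})")
    skeleton = subtrees[0] + ";"
    tree = read_newick(skeleton, is_path=False)
    edges = [e for e in tree.preorder_edge_iter()
             if e.head_node is not tree.seed_node]
    for e, ln in zip(edges, rng.exponential(1.0, size=len(edges))):
        e.length = float(ln)
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node is not tree.seed_node:
            d += node.edge.length
            node = node.parent_node
        depths.append(d)
    scale = height / float(np.mean(depths))
    for e in edges:
        e.length = round(e.length * scale, 10)
    label_internal_nodes(tree)
    return tree
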