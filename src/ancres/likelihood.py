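"""Tree likelihood by the pruning algorithm under a reversible amino-acid
model with discrete-gamma rate categories.

Conditional (partial) likelihoods are propagated post-order, vectorised over
alignment sites, with per-site log scaling factors to avoid underflow.  Gaps
and unknown residues are missing data: their tip vectors are all ones, so an
all-gap column contributes exactly zero log-likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment
from .substitution import N_STATES, SubstitutionModel
from .trees import check_leaves_match


def _tip_partial(codes: np.ndarray) -> np.ndarray:
    """(n_sites, 20) tip conditional likelihoods; missing data -> all ones."""
    n_sites = codes.shape[0]
    L = np.zeros((n_sites, N_STATES))
    observed = codes < N_STATES
    L[observed, codes[observed].astype(int)] = 1.0
    L[~observed, :] = 1.0
    return L


def category_partials(aln: Alignment, tree, model: SubstitutionModel,
                      rate: float):
    """Post-order conditional likelihoods for one rate category.

    Returns ``(partials, logscale)`` where ``partials`` maps each dendropy
    node to its (n_sites, 20) conditional-likelihood matrix and ``logscale``
    maps it to the per-site log scaling factor already factored out.
    """
    row_of = {name: i for i, name in enumerate(aln.ids)}
    partials: dict = {}
    logscale: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[node] = _tip_partial(aln.codes[row_of[node.taxon.label]])
            logscale[node] = np.zeros(aln.n_sites)
            continue
        L = np.ones((aln.n_sites, N_STATES))
        scale = np.zeros(aln.n_sites)
        for child in node.child_nodes():
            t = child.edge.length if child.edge.length is not None else 0.0
            P = model.transition_matrix(t, rate)
            L *= partials[child] @ P.T
            scale += logscale[child]
        with np.errstate(divide="ignore"):
            m = L.max(axis=1)
            nonzero = m > 0
            L[nonzero] /= m[nonzero, None]
            scale += np.where(nonzero, np.log(np.where(nonzero, m, 1.0)),
                              -np.inf)
        partials[node] = L
        logscale[node] = scale
    return partials, logscale


def site_log_likelihoods(aln: Alignment, tree,
                         model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihood, mixing over gamma categories."""
    check_leaves_match(tree, aln.ids)
    if aln.n_sites == 0:
        raise ValueError("alignment has zero sites")
    root = tree.seed_node
    per_cat = np.empty((model.n_categories, aln.n_sites))
    for k, rate in enumerate(model.rates):
        partials, logscale = category_partials(aln, tree, model, rate)
        with np.errstate(divide="ignore"):
            per_cat[k] = np.log(partials[root] @ model.pi) + logscale[root]
    return logsumexp(per_cat + np.log(model.weights)[:, None], axis=0)


def tree_log_likelihood(aln: Alignment, tree,
                        model: SubstitutionModel) -> float:
    """Total log-likelihood of the alignment on the tree under the model."""
    return float(site_log_likelihoods(aln, tree, model).sum())


def optimize_alpha(aln: Alignment, tree, model: SubstitutionModel,
                   bounds: tuple[float, float] = (0.02, 20.0)):
    """Maximum-likelihood gamma shape by bounded 1-D search.

    Returns ``(alpha_hat, log_likelihood)``.  Deterministic: Brent's bounded
    method on a fixed bracket, no randomness.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")

    def objective(alpha: float) -> float:
        ll = tree_log_likelihood(aln, tree, model.with_alpha(alpha))
        if not np.isfinite(ll):
            raise ValueError(f"non-finite log-likelihood at alpha={alpha}")
        return -ll

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x), float(-res.fun)
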