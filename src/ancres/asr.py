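"""Empirical-Bayes marginal ancestral sequence reconstruction.

For a target internal node the tree is virtually rerooted there (valid under
a reversible model), and the per-site posterior over the 20 amino acids is

    p(a | site) \\propto  sum_k w_k  pi_a  prod_c [P(r_k t_c) L_c](a)

where the product runs over the subtrees hanging off the node and ``L_c`` are
their conditional likelihoods.  This integrates over all other nodes' states
(marginal, not joint reconstruction) and mixes the gamma categories by their
per-site likelihood weight.

A site is *ambiguously reconstructed* when any non-best state has posterior
probability above a threshold (default 0.2); the alternative ancestor
substitutes the second-best state at exactly those sites.  The overall
posterior probability of a reconstruction is the arithmetic mean of the
per-site best-state posteriors over sites inferred present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment
from .likelihood import category_partials
from .substitution import AMINO_ACIDS, N_STATES, SubstitutionModel
from .trees import find_node, mrca_node, node_label


@dataclass
class SitePosterior:
    """Posterior distribution over amino acids at one node and site."""

    node: str
    site: int                 # 1-based alignment column
    p: np.ndarray             # length-20, sums to 1
    best_state: str
    best_pp: float

    @property
    def second_best(self) -> tuple[str, float]:
        order = np.argsort(-self.p, kind="stable")
        return AMINO_ACIDS[order[1]], float(self.p[order[1]])


@dataclass
class AmbiguousSite:
    site: int
    best_state: str
    best_pp: float
    alt_state: str
    alt_pp: float
    #: all non-best states over the threshold (the alt substitution uses
    #: only the second-best; others are reported for inspection)
    over_threshold: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class AncestralReconstruction:
    """Maximum-likelihood ancestral sequence with per-site posteriors."""

    node: str
    ml_sequence: str
    alt_sequence: str
    per_site: list[SitePosterior]
    ambiguous_sites: list[AmbiguousSite]
    overall_pp: float
    present_sites: list[int]   # 1-based columns included in the sequence

    def summary(self) -> dict:
        return {
            "node": self.node,
            "length": len(self.ml_sequence),
            "overall_pp": round(self.overall_pp, 2),
            "n_ambiguous": len(self.ambiguous_sites),
        }


def _resolve_target(tree, node=None, taxa=None):
    if node is None and taxa is None:
        raise ValueError("specify a target node or a taxon set for its MRCA")
    if node is not None:
        target = find_node(tree, node) if isinstance(node, str) else node
    else:
        target = mrca_node(tree, taxa)
    if target.is_leaf():
        raise ValueError(
            f"target {node_label(target)!r} is a leaf, not an ancestor")
    return target


def marginal_posteriors(aln: Alignment, tree, model: SubstitutionModel,
                        node=None, taxa=None) -> list[SitePosterior]:
    """Per-site marginal posterior state distributions at an internal node.

    The node may be given by label (``node``) or as the MRCA of a leaf-label
    set (``taxa``).
    """
    target = _resolve_target(tree, node, taxa)
    label = node_label(target)

    if target is not tree.seed_node:
        work = tree.clone(depth=1)
        target = find_node(work, label)
        work.reroot_at_node(target, update_bipartitions=False)
        work.suppress_unifurcations()
        tree = work
        target = tree.seed_node

    n_sites = aln.n_sites
    # log numerator per category/site/state, scaling factors included
    lognum = np.empty((model.n_categories, n_sites, N_STATES))
    for k, rate in enumerate(model.rates):
        partials, logscale = category_partials(aln, tree, model, rate)
        with np.errstate(divide="ignore"):
            lognum[k] = (np.log(partials[target] * model.pi[None, :])
                         + logscale[target][:, None]
                         + np.log(model.weights[k]))
    m = lognum.max(axis=(0, 2), keepdims=True)
    post = np.exp(lognum - m).sum(axis=0)
    post /= post.sum(axis=1, keepdims=True)

    result = []
    for s in range(n_sites):
        best = int(np.argmax(post[s]))  # argmax takes lowest index on ties
        result.append(SitePosterior(
            node=label, site=s + 1, p=post[s],
            best_state=AMINO_ACIDS[best], best_pp=float(post[s, best]),
        ))
    return result


def ambiguous_sites(posteriors: list[SitePosterior],
                    threshold: float = 0.2) -> list[AmbiguousSite]:
    """Sites where a non-best state has posterior probability > threshold."""
    if not (0 < threshold < 1):
        raise ValueError("ambiguity threshold must lie in (0, 1)")
    out = []
    for sp in posteriors:
        order = np.argsort(-sp.p, kind="stable")
        runners = [(AMINO_ACIDS[i], float(sp.p[i])) for i in order[1:]
                   if sp.p[i] > threshold]
        if runners:
            alt_state, alt_pp = runners[0]
            out.append(AmbiguousSite(
                site=sp.site, best_state=sp.best_state, best_pp=sp.best_pp,
                alt_state=alt_state, alt_pp=alt_pp, over_threshold=runners,
            ))
    return out


def alt_ancestor(ml_sequence: str, ambiguous: list[AmbiguousSite],
                 site_to_position: dict[int, int] | None = None) -> str:
    """Alternative ancestor: second-best state at every ambiguous site.

    ``site_to_position`` maps 1-based alignment columns to 0-based positions
    in ``ml_sequence``; identity mapping when omitted.
    """
    chars = list(ml_sequence)
    for amb in ambiguous:
        pos = (site_to_position[amb.site] if site_to_position is not None
               else amb.site - 1)
        if not (0 <= pos < len(chars)):
            raise IndexError(f"ambiguous site {amb.site} outside sequence")
        if amb.alt_state == chars[pos]:
            raise RuntimeError(
                f"site {amb.site}: alternative state equals the best state")
        chars[pos] = amb.alt_state
    return "".join(chars)


def reconstruct_ancestor(posteriors: list[SitePosterior],
                         present_mask=None,
                         threshold: float = 0.2) -> AncestralReconstruction:
    """Assemble the ML ancestor, ambiguity calls, and the alternative
    ancestor from per-site posteriors.

    ``present_mask`` (boolean per alignment column) restricts the sequence to
    columns inferred present at the node; masked columns are excluded from
    the sequence, the ambiguity set, and the overall posterior probability.
    """
    if not posteriors:
        raise ValueError("no posteriors supplied")
    if present_mask is None:
        present_mask = np.ones(len(posteriors), dtype=bool)
    present_mask = np.asarray(present_mask, dtype=bool)
    if present_mask.shape != (len(posteriors),):
        raise ValueError("present_mask must have one entry per site")
    if not present_mask.any():
        raise ValueError("no sites inferred present at the node")

    kept = [sp for sp, keep in zip(posteriors, present_mask) if keep]
    ml_sequence = "".join(sp.best_state for sp in kept)
    overall_pp = float(np.mean([sp.best_pp for sp in kept]))
    ambiguous = ambiguous_sites(kept, threshold)
    site_to_position = {sp.site: i for i, sp in enumerate(kept)}
    alt_sequence = alt_ancestor(ml_sequence, ambiguous, site_to_position)
    return AncestralReconstruction(
        node=kept[0].node,
        ml_sequence=ml_sequence,
        alt_sequence=alt_sequence,
        per_site=kept,
        ambiguous_sites=ambiguous,
        overall_pp=overall_pp,
        present_sites=[sp.site for sp in kept],
    )


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, int, int]:
    """Percent identity and change count between two aligned sequences.

    Columns where both sequences are gapped are skipped; a gap aligned to a
    residue counts as a change.  Returns ``(percent_identity, n_changes,
    compared_columns)`` with the percentage rounded to one decimal.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)}); "
            "align them first")
    gap = {"-", "."}
    n_changes = 0
    compared = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in gap and b in gap:
            continue
        compared += 1
        if a != b:
            n_changes += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    percent = round(100.0 * (compared - n_changes) / compared, 1)
    return percent, n_changes, compared


def posterior_table(posteriors: list[SitePosterior],
                    threshold: float = 0.2) -> pd.DataFrame:
    """Tidy per-site posterior table (one row per site, 20 PP columns)."""
    amb = {a.site: a for a in ambiguous_sites(posteriors, threshold)}
    rows = []
    for sp in posteriors:
        row = {"node": sp.node, "site": sp.site}
        row.update({aa: sp.p[i] for i, aa in enumerate(AMINO_ACIDS)})
        row["best"] = sp.best_state
        row["best_pp"] = sp.best_pp
        row["ambiguous"] = sp.site in amb
        row["alt"] = amb[sp.site].alt_state if sp.site in amb else ""
        row["alt_pp"] = amb[sp.site].alt_pp if sp.site in amb else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
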