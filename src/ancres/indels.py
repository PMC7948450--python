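"""Ancestral sequence length by gap parsimony.

Alignment gaps are recoded as binary presence/absence characters (one per
maximal run of columns sharing an identical per-taxon gap pattern) and their
ancestral states reconstructed with the two-pass Fitch algorithm.  Columns
whose character resolves to *absent* at the target node are removed from the
reconstructed ancestor, fixing its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .trees import find_node, node_label

PRESENT, ABSENT = 1, 0


@dataclass
class IndelCharacter:
    """One binary presence/absence character spanning alignment columns
    ``start..end`` (1-based, inclusive)."""

    start: int
    end: int
    states: dict[str, int]    # taxon -> 0 (gap) / 1 (residues)

    @property
    def columns(self) -> range:
        return range(self.start, self.end + 1)

    def is_variable(self) -> bool:
        return len(set(self.states.values())) > 1


@dataclass
class IndelCharacterMatrix:
    taxa: list[str]
    characters: list[IndelCharacter]


@dataclass
class FitchResult:
    """Fitch state sets, minimum change count, and the resolved target state."""

    character: IndelCharacter
    state_sets: dict[str, frozenset]   # node label -> subset of {0, 1}
    min_changes: int
    target: str
    resolved_state: int
    tie_at_target: bool = field(default=False)


def encode_indel_characters(aln: Alignment, *,
                            merge_blocks: bool = True) -> IndelCharacterMatrix:
    """Binary gap characters from an alignment.

    With ``merge_blocks`` (default) maximal runs of columns with identical
    per-taxon gap patterns become one character; otherwise one character per
    gap-containing column.  Gap-free column runs produce no character.
    """
    gaps = aln.gap_mask()
    n_sites = aln.n_sites
    characters: list[IndelCharacter] = []
    start = 0
    while start < n_sites:
        end = start
        if merge_blocks:
            while (end + 1 < n_sites
                   and np.array_equal(gaps[:, end + 1], gaps[:, start])):
                end += 1
        if gaps[:, start].any():
            states = {taxon: ABSENT if gaps[i, start] else PRESENT
                      for i, taxon in enumerate(aln.ids)}
            characters.append(IndelCharacter(start + 1, end + 1, states))
        start = end + 1
    return IndelCharacterMatrix(taxa=list(aln.ids), characters=characters)


def fitch_ancestral(tree, character: IndelCharacter,
                    target=None) -> FitchResult:
    """Two-pass Fitch parsimony for one binary character.

    Bottom-up intersections/unions give per-node state sets and the minimum
    number of changes.  An ambiguous set ``{0, 1}`` at the target node is
    resolved toward presence (state 1), a stated convention; the tie is
    flagged in the result.
    """
    sets: dict = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            taxon = node.taxon.label
            if taxon not in character.states:
                raise ValueError(f"leaf {taxon!r} has no state for character "
                                 f"{character.start}..{character.end}")
            sets[node] = frozenset({character.states[taxon]})
            continue
        child_sets = [sets[c] for c in node.child_nodes()]
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[node] = inter
        else:
            sets[node] = frozenset.union(*child_sets)
            changes += 1

    if target is None:
        target_node = tree.seed_node
    elif isinstance(target, str):
        target_node = find_node(tree, target)
    else:
        target_node = target
    target_set = sets[target_node]
    tie = len(target_set) > 1
    resolved = PRESENT if PRESENT in target_set else ABSENT
    return FitchResult(
        character=character,
        state_sets={node_label(n): s for n, s in sets.items()},
        min_changes=changes,
        target=node_label(target_node),
        resolved_state=resolved,
        tie_at_target=tie,
    )


def present_site_mask(n_sites: int,
                      fitch_results: list[FitchResult]) -> np.ndarray:
    """Boolean mask over alignment columns: False where the target node's
    character resolved to absent."""
    mask = np.ones(n_sites, dtype=bool)
    for res in fitch_results:
        if res.resolved_state == ABSENT:
            mask[res.character.start - 1:res.character.end] = False
    return mask


def ancestral_length(reconstruction, fitch_results: list[FitchResult]):
    """Trim an ancestral reconstruction to the columns its indel characters
    keep; returns ``(ml_sequence, alt_sequence, length)``.

    The reconstruction's ``present_sites`` give the alignment column of each
    sequence position; any column resolved absent is removed.
    """
    removed = set()
    for res in fitch_results:
        if res.resolved_state == ABSENT:
            removed.update(res.character.columns)
    keep = [i for i, site in enumerate(reconstruction.present_sites)
            if site not in removed]
    ml = "".join(reconstruction.ml_sequence[i] for i in keep)
    alt = "".join(reconstruction.alt_sequence[i] for i in keep)
    return ml, alt, len(ml)
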