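"""Canonical labeling of internal nodes at three relaxation levels.

Each internal node at or below the distance threshold receives a canonical
text label built bottom-up (post-order), so that two clusters are considered
equivalent exactly when their labels are equal.  Two boolean knobs,
``keep_structure`` and ``keep_duplicates``, select the relaxation level:

=================  ==============  ===============
mode               keep_structure  keep_duplicates
=================  ==============  ===============
bio-isomorphic     True            True
re-arranged        False           True
contained          False           False
=================  ==============  ===============

* bio-isomorphic — same topology and same per-type replicate counts;
  replicate positions are free.  Label: ``"(" + sorted child labels + ")"``,
  recursively, with leaves labeled by sample type.  Sorting the children
  makes the label invariant to child order, and dropping replicate ids makes
  it invariant to replicate placement.
* re-arranged — same per-type counts, topology free.  Label: the sorted
  list of descendant-leaf sample types, duplicates kept.
* contained — same set of types, counts and topology free.  Label: the
  sorted list of distinct descendant-leaf sample types.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import ParameterError
from .newick_io import Dendrogram, DendroNode
from .replicate_model import DEFAULT_DELIMITER, leaf_type


class MatchMode(enum.Enum):
    """Relaxation level for cluster equivalence."""

    BIO_ISOMORPHIC = "bio-isomorphic"
    REARRANGED = "rearranged"
    CONTAINED = "contained"

    @property
    def keep_structure(self) -> bool:
        return self is MatchMode.BIO_ISOMORPHIC

    @property
    def keep_duplicates(self) -> bool:
        return self is not MatchMode.CONTAINED

    @classmethod
    def from_flags(cls, keep_structure: bool, keep_duplicates: bool) -> "MatchMode":
        """Map the (keep_structure, keep_duplicates) pair to a named mode.

        (True, False) — structural labels with de-duplicated types — is
        representable in the grammar but is not one of the three defined
        relaxation levels, so it is rejected.
        """
        table = {
            (True, True): cls.BIO_ISOMORPHIC,
            (False, True): cls.REARRANGED,
            (False, False): cls.CONTAINED,
        }
        try:
            return table[(keep_structure, keep_duplicates)]
        except KeyError:
            raise ParameterError(
                "keep_structure=True with keep_duplicates=False does not "
                "correspond to a defined match mode") from None


@dataclass(frozen=True)
class ClusterLabel:
    text: str
    mode: MatchMode
    node: DendroNode = field(compare=False)


@dataclass
class LabelingStats:
    """Instrumentation for the complexity contract: one visit per node."""

    nodes_visited: int = 0


def label_nodes(
    d: Dendrogram,
    mode: MatchMode,
    threshold: float,
    delimiter: str = DEFAULT_DELIMITER,
    stats: LabelingStats | None = None,
) -> dict[DendroNode, ClusterLabel]:
    """Label every internal node whose height is ≤ ``threshold``.

    Single post-order pass.  Nodes above the threshold get no label and are
    thereby excluded from matching; because height is monotone from leaves
    to root, their descendants at or below the threshold are still labeled
    (the threshold excludes nodes, not whole subtrees).  Leaves contribute
    their sample type to parent labels but never appear in the returned map.
    """
    if threshold < 0:
        raise ParameterError(f"distance threshold must be >= 0, got {threshold}")

    labels: dict[DendroNode, ClusterLabel] = {}
    # per-node canonical text, kept for composition even above the threshold
    text: dict[DendroNode, str] = {}
    types: dict[DendroNode, list[str]] = {}

    for node in d.root.walk_postorder():
        if stats is not None:
            stats.nodes_visited += 1
        if node.is_leaf:
            t = leaf_type(node, delimiter)
            text[node] = t
            types[node] = [t]
            continue
        if mode.keep_structure:
            text[node] = "(" + ",".join(sorted(text[c] for c in node.children)) + ")"
        else:
            pooled: list[str] = []
            for c in node.children:
                pooled.extend(types[c])
            types[node] = pooled
            shown = sorted(set(pooled)) if not mode.keep_duplicates else sorted(pooled)
            text[node] = ",".join(shown)
        if node.height <= threshold:
            labels[node] = ClusterLabel(text=text[node], mode=mode, node=node)
    return labels
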