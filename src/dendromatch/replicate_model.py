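"""Sample-type / replicate decomposition of leaf names.

In replicated experiments (e.g. toxicogenomics panels) each biological
entity is measured several times; clustering output then carries leaf names
like ``versicolor.1``, ``versicolor.2`` — a sample type plus a replicate
indicator.  All cluster matching in this package works on sample types;
replicate indicators are retained for display only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import IdentityError
from .newick_io import DendroNode

DEFAULT_DELIMITER = "."


@dataclass(frozen=True)
class LeafIdentity:
    """Decomposition of a leaf name; the original name is recoverable."""

    sample_type: str
    replicate_id: str | None = None

    def full_name(self, delimiter: str = DEFAULT_DELIMITER) -> str:
        if self.replicate_id is None:
            return self.sample_type
        return f"{self.sample_type}{delimiter}{self.replicate_id}"


def parse_leaf_identity(name: str, delimiter: str = DEFAULT_DELIMITER) -> LeafIdentity:
    """Split ``name`` at the LAST occurrence of ``delimiter``.

    ``"iris.setosa.5"`` → type ``"iris.setosa"``, replicate ``"5"``.  A name
    without the delimiter is a bare sample type with no replicate indicator;
    two such leaves of the same name count as two replicates of that type.
    """
    if not name:
        raise IdentityError("empty leaf name")
    head, sep, tail = name.rpartition(delimiter)
    if not sep:
        return LeafIdentity(sample_type=name)
    if not head or not tail:
        raise IdentityError(
            f"leaf name {name!r} has an empty sample type or replicate part")
    return LeafIdentity(sample_type=head, replicate_id=tail)


def leaf_type(node: DendroNode, delimiter: str = DEFAULT_DELIMITER) -> str:
    if node.name is None:
        raise IdentityError(f"unnamed leaf (node id {node.id})")
    return parse_leaf_identity(node.name, delimiter).sample_type


def type_multiset(node: DendroNode, delimiter: str = DEFAULT_DELIMITER) -> Counter:
    """Multiset of sample types over all descendant leaves of ``node``.

    Additive over children: the parent's multiset is the union of its
    children's, which is what makes containment/re-arrangement checks local.
    """
    return Counter(leaf_type(leaf, delimiter) for leaf in node.leaves())
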