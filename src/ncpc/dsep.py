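"""d-separation on a DAG given as parent/children adjacency maps.

Implements the standard reachability ("Bayes-ball") algorithm: X and Y are
d-separated given Z iff no active trail connects them, where a trail is
blocked at a non-collider in Z and at a collider with no member of
Z among itself or its descendants.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping

__all__ = ["d_separated"]


def _ancestors_of(parents: Mapping, nodes: Iterable) -> set:
    out = set(nodes)
    stack = list(nodes)
    while stack:
        v = stack.pop()
        for p in parents.get(v, ()):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def d_separated(
    parents: Mapping[Hashable, tuple],
    children: Mapping[Hashable, tuple],
    x: Hashable,
    y: Hashable,
    z: Iterable[Hashable],
) -> bool:
    """True iff every trail between ``x`` and ``y`` is blocked given ``z``."""
    z = set(z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in z or y in z:
        raise ValueError("x and y must not be in the conditioning set")
    # nodes that are in z or have a descendant in z: colliders open there
    anc_z = _ancestors_of(parents, z)
    # state: (node, came_from_child); start as if arriving from a child of x
    stack = [(x, True)]
    seen: set[tuple] = set()
    while stack:
        v, up = stack.pop()
        if (v, up) in seen:
            continue
        seen.add((v, up))
        if v == y:
            return False
        if up and v not in z:
            for p in parents.get(v, ()):
                stack.append((p, True))
            for c in children.get(v, ()):
                stack.append((c, False))
        elif not up:
            if v not in z:
                for c in children.get(v, ()):
                    stack.append((c, False))
            if v in anc_z:
                for p in parents.get(v, ()):
                    stack.append((p, True))
    return True
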