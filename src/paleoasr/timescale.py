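"""Timescaling fossil trees from stratigraphic ranges.

Node ages are assigned with the "basic" rule: each tip is dated by its
stratigraphic range (first appearance by default) and each internal node
is at least as old as the oldest first appearance among its descendants.
Zero-length branches — unavoidable when a node's age ties its oldest
descendant — are then removed by shifting ancestors rootward by the
minimum amount that makes every branch at least ``mbl`` Myr long.

Ages are in Ma (before present, larger = older); branch lengths in Myr.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trees import Node, Tree, TreeError


class TimescaleError(ValueError):
    pass


@dataclass(frozen=True)
class StratRange:
    """Stratigraphic range of one taxon: first and last appearance in Ma."""

    taxon: str
    fad: float
    lad: float

    def __post_init__(self):
        if self.lad < 0:
            raise TimescaleError(f"{self.taxon}: LAD {self.lad} < 0")
        if self.fad < self.lad:
            raise TimescaleError(
                f"{self.taxon}: FAD {self.fad} younger than LAD {self.lad}"
            )

    def tip_age(self, policy: str) -> float:
        if policy == "fad":
            return self.fad
        if policy == "lad":
            return self.lad
        if policy == "midpoint":
            return 0.5 * (self.fad + self.lad)
        raise TimescaleError(f"unknown tip age policy {policy!r}")


def read_strat_ranges(path) -> dict[str, StratRange]:
    """Read a delimited table with columns taxon, fad_ma, lad_ma."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"taxon", "fad_ma", "lad_ma"}
    if not required.issubset(df.columns):
        raise TimescaleError(
            f"range table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = {}
    for row in df.itertuples(index=False):
        r = StratRange(str(row.taxon), float(row.fad_ma), float(row.lad_ma))
        out[r.taxon] = r
    return out


def write_strat_ranges(ranges: dict[str, StratRange], path) -> None:
    df = pd.DataFrame(
        [(r.taxon, r.fad, r.lad) for r in ranges.values()],
        columns=["taxon", "fad_ma", "lad_ma"],
    )
    df.to_csv(path, sep="\t", index=False)


def assign_node_ages(
    tree: Tree,
    ranges: dict[str, StratRange],
    tip_age_policy: str = "fad",
) -> dict[int, float]:
    """Date every node; returns node id → age (Ma) and sets ``node.age``.

    Tips take their range's age under the chosen policy; an internal
    node's age is the maximum FAD over its descendant tips (a node
    cannot be younger than the first appearance of any descendant).
    """
    missing = [lab for lab in tree.leaf_labels() if lab not in ranges]
    if missing:
        raise TimescaleError(f"no stratigraphic range for: {sorted(missing)}")

    ages: dict[int, float] = {}
    max_fad: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            r = ranges[node.label]
            ages[node.id] = r.tip_age(tip_age_policy)
            max_fad[node.id] = r.fad
        else:
            max_fad[node.id] = max(max_fad[c.id] for c in node.children)
            ages[node.id] = max_fad[node.id]
        node.age = ages[node.id]
    return ages


def apply_branch_lengths(tree: Tree, ages: dict[int, float], mbl: float = 1.0) -> Tree:
    """Derive branch lengths from node ages, enforcing a minimum length.

    Branch length = parent age − child age.  Any branch shorter than
    ``mbl`` is fixed by shifting ancestor ages rootward (older) by the
    minimum amount that makes every branch ≥ mbl; tips never move and
    relative node order is preserved.
    """
    if mbl <= 0:
        raise TimescaleError("mbl must be > 0 Myr (zero branches break ML)")
    out = tree.copy()
    # map adjusted ages postorder: internal age = max(raw age, child + mbl)
    adj: dict[Node, float] = {}
    raw: dict[Node, float] = {}
    for orig, new in zip(tree.postorder(), out.postorder()):
        raw[new] = ages[orig.id]
    for node in out.postorder():
        if node.is_leaf:
            adj[node] = raw[node]
        else:
            if raw[node] < max(raw[c] for c in node.children) - 1e-9:
                raise TimescaleError(
                    "inconsistent ages: a child is older than its parent"
                )
            floor = max(adj[c] for c in node.children) + mbl
            adj[node] = max(raw[node], floor)
    for node in out.postorder():
        node.age = adj[node]
        node.length = None if node.parent is None else adj[node.parent] - adj[node]
        if node.parent is not None and node.length < mbl - 1e-12:
            raise TimescaleError("internal error: mbl correction failed")  # pragma: no cover
    out.mbl = mbl
    out.branch_mode = "timescaled"
    return out


def timescale_tree(
    tree: Tree,
    ranges: dict[str, StratRange],
    mbl: float = 1.0,
    tip_age_policy: str = "fad",
) -> Tree:
    """Convenience: assign ages from ranges, then derive branch lengths."""
    ages = assign_node_ages(tree, ranges, tip_age_policy)
    return apply_branch_lengths(tree, ages, mbl=mbl)


def unit_branch_lengths(tree: Tree) -> Tree:
    """Set every branch length to exactly 1 (the "no branch lengths" mode)."""
    out = tree.copy()
    for node in out.postorder():
        node.age = None
        node.length = None if node.parent is None else 1.0
    out.mbl = None
    out.branch_mode = "unit"
    return out
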