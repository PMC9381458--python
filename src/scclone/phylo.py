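"""Neighbour-joining clone phylogenies, evolution-mode classification and
fishplot-ready clone-fraction tables.

Trees are built over clone consensus copy-number profiles plus a synthetic
all-diploid "normal" taxon, using classic Saitou-Nei neighbour joining on
pairwise (bin-weighted) Euclidean distances, then re-rooted on the edge
subtending the normal leaf.  Each tumour is assigned one of three
evolution modes from explicit rules over its clone count, the nesting
structure of per-clone event sets, and event losses (detected as carrier
sets that are not compatible with any single subtree of the rooted tree):

* ``no_evolution`` — a single stable clone;
* ``punctuated`` — two or more sibling clones sharing early events with
  private later alterations, and nothing lost;
* ``gradual_branching`` — nested clone-over-clone descent and/or loss of
  inherited events, the signature of ongoing instability.

The mode rules operationalize published descriptions of the three
trajectories as testable predicates; tree inference by mutation-tree
samplers is intentionally not reproduced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clones import Clone

NORMAL_LEAF = "normal"


class InvalidDistanceError(ValueError):
    pass


class RootAnchorError(ValueError):
    pass


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


def to_newick(node: TreeNode) -> str:
    def fmt(n: TreeNode) -> str:
        if n.is_leaf:
            return f"{n.name}:{n.length:.10g}"
        inner = ",".join(fmt(c) for c in n.children)
        name = n.name or ""
        return f"({inner}){name}:{n.length:.10g}"

    if node.is_leaf:
        return f"{node.name}:{node.length:.10g};"
    inner = ",".join(fmt(c) for c in node.children)
    return f"({inner}){node.name or ''};"


def parse_newick(text: str) -> TreeNode:
    """Minimal Newick parser (names + branch lengths), for round-tripping."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        label = text[start:pos]
        if label:
            if ":" in label:
                name, length = label.split(":", 1)
                node.name = name or None
                node.length = float(length)
            else:
                node.name = label
        elif pos < len(text) and text[pos] == ":":
            pass
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            node.length = float(text[start:pos])
        return node

    return parse_node()


def leaf_distances(root: TreeNode) -> pd.DataFrame:
    """Pairwise path-length distances between all leaves."""
    dists: dict[str, dict[str, float]] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        below: list[dict[str, float]] = []
        for c in walk_children(node):
            below.append(c)
        merged: dict[str, float] = {}
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        dists.setdefault(a, {})[b] = da + db
                        dists.setdefault(b, {})[a] = da + db
            merged.update(below[i])
        return merged

    def walk_children(node: TreeNode) -> list[dict[str, float]]:
        return [
            {k: v + c.length for k, v in walk(c).items()} for c in node.children
        ]

    walk(root)
    names = sorted(root.leaf_names())
    return pd.DataFrame(
        [[0.0 if a == b else dists[a][b] for b in names] for a in names],
        index=names,
        columns=names,
    )


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


def nj_tree(distances: pd.DataFrame) -> TreeNode:
    """Classic neighbour joining (Saitou-Nei) from a distance matrix.

    The input must be symmetric with a zero diagonal and >= 3 taxa.  The
    result is the unrooted NJ tree represented with an arbitrary
    trifurcating root (the final three-way join).  Negative branch lengths
    are clamped to zero with the deficit moved to the sister branch, so
    leaf-to-leaf path distances are preserved.
    """
    D = distances.to_numpy(dtype=float)
    labels = list(distances.index)
    n = len(labels)
    if D.shape != (n, n):
        raise InvalidDistanceError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise InvalidDistanceError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise InvalidDistanceError("distance matrix must have zero diagonal")
    if n < 3:
        raise InvalidDistanceError("need >= 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    D = D.copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj = max(lj + li, 0.0)
            li = 0.0
        elif lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        fi, gi = np.unravel_index(np.argmin(Q), Q.shape)
        if fi > gi:
            fi, gi = gi, fi
        f, g = active[fi], active[gi]
        d_fg = D[f, g]
        lf = 0.5 * d_fg + (r[fi] - r[gi]) / (2.0 * (m - 2))
        lg = d_fg - lf
        lf, lg = clamp(lf, lg)
        parent = TreeNode(children=[nodes[f], nodes[g]])
        nodes[f].length = lf
        nodes[g].length = lg
        # distances from the new node
        new_d = 0.5 * (D[f, :] + D[g, :] - d_fg)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_d)] = new_d
        D[: len(new_d), -1] = new_d
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (f, g)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, l in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(l, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def root_tree(tree: TreeNode, normal_leaf: str = NORMAL_LEAF) -> TreeNode:
    """Re-root on the node to which the normal diploid leaf attaches.

    The returned tree has the normal leaf as a direct child of the root
    carrying its full branch length, so re-rooting is idempotent.
    """
    # build undirected adjacency
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}
    counter = [0]

    def index(node: TreeNode) -> int:
        i = counter[0]
        counter[0] += 1
        names[i] = node.name
        adj.setdefault(i, [])
        for c in node.children:
            j = index(c)
            adj[i].append((j, c.length))
            adj[j].append((i, c.length))
        return i

    index(tree)
    normal_ids = [i for i, nm in names.items() if nm == normal_leaf]
    if not normal_ids:
        raise RootAnchorError(f"no leaf named {normal_leaf!r} in tree")
    nid = normal_ids[0]
    if len(adj[nid]) != 1:
        raise RootAnchorError(f"{normal_leaf!r} is not a leaf")
    root_id = adj[nid][0][0]

    def build(i: int, parent: int | None, length: float) -> TreeNode:
        node = TreeNode(name=names[i], length=length)
        for j, l in adj[i]:
            if j != parent:
                node.children.append(build(j, i, l))
        return node

    rooted = build(root_id, None, 0.0)
    rooted.name = None
    # normal leaf first, for stable serialization
    rooted.children.sort(key=lambda c: (c.name != normal_leaf, c.name or "~"))
    return rooted


def clone_distance_matrix(clones: list[Clone], weights: np.ndarray) -> pd.DataFrame:
    """Bin-weighted Euclidean distances between clone consensus profiles.

    A synthetic all-diploid ``normal`` taxon is appended; any inferred
    normal-cell cluster is represented by that taxon rather than
    duplicated.
    """
    tumour = [c for c in clones if not c.is_normal]
    profiles = {c.clone_id: c.consensus.astype(float) for c in tumour}
    profiles[NORMAL_LEAF] = np.full_like(
        next(iter(profiles.values())), 2.0
    )
    names = [c.clone_id for c in tumour] + [NORMAL_LEAF]
    w = np.asarray(weights, dtype=float)
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                d = float(np.sqrt((w * (profiles[a] - profiles[b]) ** 2).sum()))
                mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# Evolution-mode classification
# ---------------------------------------------------------------------------


@dataclass
class EvolutionCall:
    mode: str  # no_evolution | punctuated | gradual_branching
    n_clones: int
    evidence: dict
    fraction_table: pd.DataFrame | None = None


def _subtree_clone_sets(root: TreeNode, clone_ids: set[str]) -> set[frozenset]:
    sets: set[frozenset] = set()

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            s = {node.name} if node.name in clone_ids else set()
        else:
            s = set()
            for c in node.children:
                s |= walk(c)
        if s:
            sets.add(frozenset(s))
        return s

    walk(root)
    return sets


def classify_evolution(
    clones: list[Clone],
    rooted_tree: TreeNode,
    annotated_events: list,
) -> EvolutionCall:
    """Assign one of the three evolution modes from explicit rules.

    1. one tumour clone -> ``no_evolution``;
    2. nesting (one clone's event set a strict superset of a sibling's) or
       loss (an event whose carrier clones do not form a subtree of the
       rooted phylogeny) -> ``gradual_branching``;
    3. otherwise (clones share early events and differ only by private
       later alterations) -> ``punctuated``.
    """
    tumour = [c for c in clones if not c.is_normal]
    clone_ids = {c.clone_id for c in tumour}
    n = len(tumour)
    evidence: dict = {"n_clones": n}
    if n == 1:
        return EvolutionCall("no_evolution", 1, evidence)

    cnv_events = [a for a in annotated_events if a.kind == "cnv"]
    clone_sets: dict[str, set] = {cid: set() for cid in clone_ids}
    for a in cnv_events:
        for cid, present in a.clone_presence.items():
            if present and cid in clone_sets:
                clone_sets[cid].add(a.event.key())
    evidence["events_per_clone"] = {k: len(v) for k, v in clone_sets.items()}
    shared = set.intersection(*clone_sets.values()) if clone_sets else set()
    evidence["n_shared_events"] = len(shared)

    nesting = any(
        clone_sets[i] > clone_sets[j] and clone_sets[j]
        for i in clone_ids
        for j in clone_ids
        if i != j
    )
    subtree_sets = _subtree_clone_sets(rooted_tree, clone_ids)
    losses = []
    for a in cnv_events:
        carriers = frozenset(
            cid for cid, p in a.clone_presence.items() if p and cid in clone_ids
        )
        if not carriers or carriers == frozenset(clone_ids):
            continue
        if carriers not in subtree_sets:
            losses.append(a.event.key())
    evidence["nesting"] = nesting
    evidence["lost_events"] = losses
    if nesting or losses:
        return EvolutionCall("gradual_branching", n, evidence)
    return EvolutionCall("punctuated", n, evidence)


def fishplot_table(clones: list[Clone], rooted_tree: TreeNode) -> pd.DataFrame:
    """Clone fractions at two pseudo-time points, per sampled region.

    ``Later`` holds the observed clone fractions (tumour clones plus the
    normal fraction).  ``Earlier`` collapses the tumour mass onto the
    founding lineage: the unique clone whose aberrant consensus segments
    are shared by every other clone when one exists, otherwise a synthetic
    ``ancestor`` row.  Fractions sum to one within each (region,
    timepoint) column.
    """
    tumour = [c for c in clones if not c.is_normal]
    normals = [c for c in clones if c.is_normal]
    regions = sorted(
        {r for c in clones for r in c.region_counts if r not in ("control",)}
    )
    if not regions:
        regions = ["all"]
        for c in clones:
            c.region_counts = {"all": c.size}

    def aberr(c: Clone) -> set[tuple[int, int]]:
        return {(j, int(v)) for j, v in enumerate(c.consensus) if v != 2}

    founder = None
    for c in tumour:
        if all(aberr(c) <= aberr(o) for o in tumour):
            founder = c.clone_id
            break
    founder_label = founder if founder is not None else "ancestor"

    rows = []
    for region in regions:
        totals = {c.clone_id: c.region_counts.get(region, 0) for c in clones}
        n_region = sum(totals.values())
        if n_region == 0:
            continue
        normal_frac = sum(totals[c.clone_id] for c in normals) / n_region
        for c in tumour:
            rows.append(
                {
                    "clone": c.clone_id,
                    "region": region,
                    "timepoint": "Later",
                    "fraction": totals[c.clone_id] / n_region,
                }
            )
        rows.append(
            {
                "clone": NORMAL_LEAF,
                "region": region,
                "timepoint": "Later",
                "fraction": normal_frac,
            }
        )
        rows.append(
            {
                "clone": founder_label,
                "region": region,
                "timepoint": "Earlier",
                "fraction": 1.0 - normal_frac,
            }
        )
        rows.append(
            {
                "clone": NORMAL_LEAF,
                "region": region,
                "timepoint": "Earlier",
                "fraction": normal_frac,
            }
        )
    return pd.DataFrame(rows, columns=["clone", "region", "timepoint", "fraction"])
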