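"""Unrooted phylogenies with dense edge numbering.

Trees are stored rooted at an arbitrary node (the virtual root); for the
reversible substitution models used here the root choice does not affect
likelihoods (pulley principle). Every non-root node owns the edge to its
parent; edge ids are dense ``0..E-1`` and stable across serialization via
jplace-style ``{N}`` tags appended after branch lengths. Those tags are
not standard Newick, so a small recursive-descent reader/writer lives
here rather than delegating to a tree library.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass
class Node:
    index: int
    name: str | None = None
    parent: "Node | None" = None
    children: list = field(default_factory=list)
    length: float | None = None  # branch to parent
    edge_id: int | None = None   # id of that branch

    @property
    def is_tip(self):
        return not self.children

    def __repr__(self):
        return f"<Node {self.index} {self.name or ''}>"


class Tree:
    def __init__(self, root: Node, nodes: list[Node]):
        self.root = root
        self.nodes = nodes

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        text = text.strip()
        if not text.endswith(";"):
            raise ValueError("Newick string must end with ';'")
        s = text[:-1]
        pos = 0
        nodes: list[Node] = []

        def new_node():
            n = Node(len(nodes))
            nodes.append(n)
            return n

        token_re = re.compile(r"[^(),:;{}\[\]]+")

        def parse(parent) -> Node:
            nonlocal pos
            node = new_node()
            node.parent = parent
            if pos < len(s) and s[pos] == "(":
                pos += 1
                while True:
                    child = parse(node)
                    node.children.append(child)
                    if pos >= len(s):
                        raise ValueError("unbalanced parentheses in Newick")
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
            m = token_re.match(s, pos)
            if m:
                node.name = m.group(0).strip() or None
                pos = m.end()
            if pos < len(s) and s[pos] == ":":
                pos += 1
                m = re.match(r"[0-9.eE+\-]+", s[pos:])
                if not m:
                    raise ValueError(f"missing branch length at position {pos}")
                node.length = float(m.group(0))
                pos += len(m.group(0))
            if pos < len(s) and s[pos] == "{":
                m = re.match(r"\{(\d+)\}", s[pos:])
                if not m:
                    raise ValueError(f"malformed edge tag at position {pos}")
                node.edge_id = int(m.group(1))
                pos += m.end()
            return node

        root = parse(None)
        if pos != len(s):
            raise ValueError(f"trailing characters in Newick at position {pos}")
        tree = cls(root, nodes)
        tree._check_tips()
        if any(n.edge_id is None for n in nodes if n is not root):
            tree.assign_edge_ids()
        else:
            ids = sorted(n.edge_id for n in nodes if n is not root)
            if ids != list(range(len(ids))):
                raise ValueError("edge ids are not dense 0..E-1")
        return tree

    def _check_tips(self):
        names = [n.name for n in self.nodes if n.is_tip]
        if any(n is None for n in names):
            raise ValueError("unlabeled tip in tree")
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip labels in tree")

    def assign_edge_ids(self):
        """Dense edge ids in postorder (stable for a fixed topology)."""
        i = 0
        for n in self.postorder():
            if n is not self.root:
                n.edge_id = i
                i += 1

    # -- traversal -----------------------------------------------------
    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out[::-1]

    def preorder(self):
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def tips(self):
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self):
        return [n.name for n in self.tips()]

    @property
    def n_tips(self):
        return len(self.tips())

    def edges(self) -> dict[int, Node]:
        """edge_id -> child-end node of that edge."""
        return {n.edge_id: n for n in self.nodes if n is not self.root}

    def edge_node(self, edge_id: int) -> Node:
        for n in self.nodes:
            if n is not self.root and n.edge_id == edge_id:
                return n
        raise KeyError(f"no edge with id {edge_id}")

    # -- serialization -------------------------------------------------
    def to_newick(self, edge_tags: bool = False, lengths: bool = True,
                  fmt: str = "%.9g") -> str:
        def render(n: Node) -> str:
            if n.children:
                body = "(" + ",".join(render(c) for c in n.children) + ")"
                label = n.name or ""
            else:
                body = ""
                label = n.name or ""
            out = body + label
            if n is not self.root and lengths and n.length is not None:
                out += ":" + (fmt % n.length)
            if n is not self.root and edge_tags:
                out += "{%d}" % n.edge_id
            return out

        return render(self.root) + ";"

    def copy(self) -> "Tree":
        return Tree.from_newick(self.to_newick(edge_tags=True))

    # -- editing -------------------------------------------------------
    def prune_tip(self, name: str):
        """Remove a tip; merge any degree-2 node this creates. Edge ids
        are reassigned densely afterwards."""
        tip = next((n for n in self.tips() if n.name == name), None)
        if tip is None:
            raise KeyError(f"no tip named {name!r}")
        parent = tip.parent
        parent.children.remove(tip)
        if parent is not self.root and len(parent.children) == 1:
            only = parent.children[0]
            only.length = (only.length or 0.0) + (parent.length or 0.0)
            gp = parent.parent
            gp.children[gp.children.index(parent)] = only
            only.parent = gp
        elif parent is self.root and len(parent.children) == 1:
            # root collapses onto its single remaining child
            child = parent.children[0]
            child.parent = None
            child.length = None
            self.root = child
        self.nodes = self.preorder()
        for i, n in enumerate(self.nodes):
            n.index = i
        self.assign_edge_ids()

    def reroot_on_edge(self, edge_id: int, fraction: float = 0.5) -> "Tree":
        """Return a new tree whose virtual root splits the given edge.

        Used to verify likelihood invariance under root placement; edge
        ids of the result are freshly assigned.
        """
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0,1]")
        # undirected adjacency
        adj: dict[int, list[tuple[int, float]]] = {n.index: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent is not None:
                adj[n.index].append((n.parent.index, n.length or 0.0))
                adj[n.parent.index].append((n.index, n.length or 0.0))
        v = self.edge_node(edge_id)
        u = v.parent
        t = v.length or 0.0
        names = {n.index: n.name for n in self.nodes}

        nodes: list[Node] = []

        def build(old_idx: int, parent: Node | None, came_from: int | None,
                  length: float | None) -> Node:
            n = Node(len(nodes), name=names[old_idx], parent=parent, length=length)
            nodes.append(n)
            for nb, ln in adj[old_idx]:
                if nb == came_from:
                    continue
                if {old_idx, nb} == {u.index, v.index}:
                    continue  # the split edge is handled at the root
                n.children.append(build(nb, n, old_idx, ln))
            return n

        root = Node(0)
        nodes.append(root)
        root.children.append(build(u.index, root, v.index, t * fraction))
        root.children.append(build(v.index, root, u.index, t * (1 - fraction)))
        tree = Tree(root, nodes)
        tree.assign_edge_ids()
        return tree

    # -- metrics -------------------------------------------------------
    def node_depths(self) -> dict[int, float]:
        """Path length from the root to every node (by node index)."""
        d = {self.root.index: 0.0}
        for n in self.preorder():
            if n is not self.root:
                d[n.index] = d[n.parent.index] + (n.length or 0.0)
        return d

    def tip_distance(self, a: str, b: str) -> float:
        """Patristic distance between two tips."""
        byname = {n.name: n for n in self.tips()}
        na, nb = byname[a], byname[b]
        depths = self.node_depths()
        anc_a = set()
        x = na
        while x is not None:
            anc_a.add(x.index)
            x = x.parent
        x = nb
        while x.index not in anc_a:
            x = x.parent
        lca = x
        return depths[na.index] + depths[nb.index] - 2 * depths[lca.index]

    def terminal_branch_lengths(self) -> dict[str, float]:
        return {n.name: (n.length or 0.0) for n in self.tips()}

    def __repr__(self):
        return f"<Tree {self.n_tips} tips, {len(self.nodes) - 1} edges>"
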