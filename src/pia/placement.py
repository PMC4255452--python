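"""Evolutionary placement: score a query on every edge of a fixed tree.

For each edge of the reference tree the query is attached by a new node
splitting the edge; the pendant branch length and the attachment
position along the edge are optimized while all reference branch
lengths and the topology stay untouched. The per-edge likelihood uses
conditional likelihood vectors of the reference alignment computed once
per tree ("down" partials toward the tips and "up" partials toward the
rest of the tree), so no edge requires a full-tree recomputation —
which is the point of placement: annotating a query costs far less than
re-estimating the gene tree.

Placements are ranked by log-likelihood and reported with
likelihood-weight ratios (LWR), the per-query softmax of edge
log-likelihoods; all edges are reported so users can inspect where a
query falls, with the best edge flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .model import BRANCH_MAX, BRANCH_MIN, SubstitutionModel, tip_partial
from .tree import Node, Tree

JPLACE_FIELDS = ["edge_num", "likelihood", "like_weight_ratio",
                 "distal_length", "pendant_length"]


@dataclass(frozen=True)
class Placement:
    query_id: str
    edge_id: int
    log_likelihood: float
    lwr: float
    pendant_length: float
    distal_length: float
    best: bool = False


class PlacementEngine:
    """Caches reference partials for one (tree, alignment, model)."""

    def __init__(self, tree: Tree, ref_aln, model: SubstitutionModel):
        if tree.n_tips < 3:
            raise ValueError("reference tree must have at least 3 tips")
        self.tree = tree
        self.model = model
        rows = ref_aln.rows if hasattr(ref_aln, "rows") else dict(ref_aln)
        missing = [t for t in tree.tip_names() if t not in rows]
        if missing:
            raise ValueError(f"tips without alignment rows: {missing}")
        self.n_sites = len(next(iter(rows.values())))
        self.rates = model.rates()
        rowmap = {t: tip_partial(rows[t]) for t in tree.tip_names()}
        # per rate category: down partials D (subtree below node, given the
        # node's state) and up partials G (everything outside the node's
        # subtree, given the state at the node's PARENT)
        self._down = []
        self._down_scale = []
        self._up = []
        self._up_scale = []
        for r in self.rates:
            D, Ds, G, Gs = self._compute_partials(rowmap, r)
            self._down.append(D)
            self._down_scale.append(Ds)
            self._up.append(G)
            self._up_scale.append(Gs)

    def _compute_partials(self, rowmap, rate):
        tree, model = self.tree, self.model
        D, Ds = {}, {}
        CH = {}  # child contribution P(t_c) @ D_c, keyed by node index
        for n in tree.postorder():
            if n.is_tip:
                D[n.index] = rowmap[n.name]
                Ds[n.index] = np.zeros(self.n_sites)
            else:
                L, sc = None, None
                for c in n.children:
                    P = model.transition_probs((c.length or 0.0) * rate)
                    CH[c.index] = D[c.index] @ P.T
                    L = CH[c.index] if L is None else L * CH[c.index]
                    sc = Ds[c.index].copy() if sc is None else sc + Ds[c.index]
                m = L.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                D[n.index] = L / m[:, None]
                Ds[n.index] = sc + np.log(m)
        # tips hanging off the traversal never had CH computed (root's tips)
        for n in tree.postorder():
            if n is not tree.root and n.index not in CH:
                P = model.transition_probs((n.length or 0.0) * rate)
                CH[n.index] = D[n.index] @ P.T
        # up partials: A[node] = outside-subtree likelihood given node state
        A, As = {tree.root.index: np.ones((self.n_sites, 20))}, \
                {tree.root.index: np.zeros(self.n_sites)}
        G, Gs = {}, {}
        for n in tree.preorder():
            for c in n.children:
                gv = A[n.index].copy()
                gs = As[n.index].copy()
                for sib in n.children:
                    if sib is c:
                        continue
                    gv = gv * CH[sib.index]
                    gs = gs + Ds[sib.index]
                m = gv.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                gv = gv / m[:, None]
                gs = gs + np.log(m)
                G[c.index] = gv
                Gs[c.index] = gs
                P = model.transition_probs((c.length or 0.0) * rate)
                A[c.index] = gv @ P.T
                As[c.index] = gs
        return D, Ds, G, Gs

    def edge_loglik(self, edge_id: int, query_partial: np.ndarray,
                    distal: float, pendant: float) -> float:
        """Log-likelihood of the tree with the query attached on the edge
        at ``distal`` from the parent end, with the given pendant length."""
        node = self.tree.edge_node(edge_id)
        t = node.length or 0.0
        if not 0.0 <= distal <= t + 1e-12:
            raise ValueError("distal length outside the edge")
        site_logs = []
        for k, r in enumerate(self.rates):
            Pd = self.model.transition_probs((t - distal) * r)  # toward child
            Pu = self.model.transition_probs(distal * r)        # toward parent
            Pp = self.model.transition_probs(pendant * r)
            below = self._down[k][node.index] @ Pd.T
            above = self._up[k][node.index] @ Pu.T
            qv = query_partial @ Pp.T
            site_l = (below * above * qv) @ self.model.freqs
            site_logs.append(np.log(np.maximum(site_l, 1e-300))
                             + self._down_scale[k][node.index]
                             + self._up_scale[k][node.index])
        site_logs = np.array(site_logs)
        return float(np.sum(logsumexp(site_logs, axis=0) - np.log(len(self.rates))))


def place_on_edge(engine: PlacementEngine, masked_query_row: str, edge_id: int,
                  max_iter: int = 32, tol: float = 1e-6,
                  pendant_init: float = 0.1):
    """Optimize pendant length and attachment position on one edge.

    Coordinate-wise bounded scalar optimization; returns
    ``(logL, pendant_length, distal_length)``. The result is never worse
    than the starting configuration (midpoint attachment, initial
    pendant).
    """
    node = engine.tree.edge_node(edge_id)
    t = node.length or 0.0
    if len(masked_query_row) != engine.n_sites:
        raise ValueError(
            f"query row has {len(masked_query_row)} columns, reference has "
            f"{engine.n_sites}")
    qp = tip_partial(masked_query_row)
    distal = t / 2.0
    pendant = pendant_init
    best = engine.edge_loglik(edge_id, qp, distal, pendant)
    for _ in range(max_iter):
        res = minimize_scalar(
            lambda p: -engine.edge_loglik(edge_id, qp, distal, p),
            bounds=(BRANCH_MIN, BRANCH_MAX), method="bounded",
            options={"xatol": tol})
        if -res.fun > best:
            best, pendant = -res.fun, float(res.x)
        if t > BRANCH_MIN:
            res = minimize_scalar(
                lambda d: -engine.edge_loglik(edge_id, qp, d, pendant),
                bounds=(0.0, t), method="bounded", options={"xatol": tol})
            if -res.fun > best + 1e-12:
                best, distal = -res.fun, float(res.x)
            else:
                break
        else:
            break
    return best, pendant, distal


def epa_place(engine: PlacementEngine, query_id: str, masked_query_row: str,
              keep: int | None = None) -> list[Placement]:
    """Score the query on every edge; rank and weight the placements.

    LWR is the softmax of edge log-likelihoods; placements are sorted by
    descending log-likelihood with near-ties (< 1e-9) broken by smaller
    edge id, and the best placement is flagged.
    """
    qp_results = []
    for edge_id in sorted(engine.tree.edges()):
        ll, pend, dist = place_on_edge(engine, masked_query_row, edge_id)
        qp_results.append((edge_id, ll, pend, dist))
    lls = np.array([r[1] for r in qp_results])
    w = np.exp(lls - lls.max())
    lwr = w / w.sum()
    items = [(r[0], r[1], r[2], r[3], lw) for r, lw in zip(qp_results, lwr)]
    items.sort(key=lambda x: -x[1])
    # near-tie stabilization: within 1e-9 of the neighbour above, order by id
    i = 0
    while i < len(items):
        j = i + 1
        while j < len(items) and items[i][1] - items[j][1] < 1e-9:
            j += 1
        items[i:j] = sorted(items[i:j], key=lambda x: x[0])
        i = j
    if keep is not None:
        items = items[:keep]
    return [Placement(query_id, e, ll, float(lw), p, d, best=(k == 0))
            for k, (e, ll, p, d, lw) in enumerate(items)]


def graft_placements(tree: Tree, placements_by_query: dict[str, list[Placement]]
                     ) -> Tree:
    """A display tree with each query grafted at its best placement.

    The reference topology and lengths are untouched except for the
    splits introduced by the graft points; edge ids of the result are
    freshly assigned, so this tree is for reading and drawing, not for
    further placement.
    """
    out = tree.copy()
    targets = {}
    for q, ps in sorted(placements_by_query.items()):
        if ps:
            best = ps[0]
            targets[q] = (out.edge_node(best.edge_id), best)
    for q, (v, best) in targets.items():
        u = v.parent
        t = v.length or 0.0
        distal = min(best.distal_length, t)
        mid = Node(-1, parent=u, length=distal)
        u.children[u.children.index(v)] = mid
        v.parent = mid
        v.length = t - distal
        tip = Node(-2, name=q, parent=mid, length=best.pendant_length)
        mid.children = [v, tip]
        out.nodes = out.preorder()
    out.nodes = out.preorder()
    for i, n in enumerate(out.nodes):
        n.index = i
    out.assign_edge_ids()
    return out


def write_jplace(placements_by_query: dict[str, list[Placement]],
                 tree: Tree, path, metadata: dict | None = None) -> None:
    """Write a jplace (version 3) placement document."""
    edge_ids = set(tree.edges())
    for q, ps in placements_by_query.items():
        bad = {p.edge_id for p in ps} - edge_ids
        if bad:
            raise ValueError(f"placements for {q!r} reference unknown edges {sorted(bad)}")
    doc = {
        "version": 3,
        "tree": tree.to_newick(edge_tags=True),
        "fields": JPLACE_FIELDS,
        "placements": [
            {"p": [[p.edge_id, p.log_likelihood, p.lwr,
                    p.distal_length, p.pendant_length] for p in ps],
             "n": [q]}
            for q, ps in sorted(placements_by_query.items())
        ],
        "metadata": metadata or {"invocation": "pia"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_jplace(path) -> tuple[Tree, dict[str, list[Placement]]]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("fields") != JPLACE_FIELDS:
        raise ValueError(f"unsupported jplace fields: {doc.get('fields')}")
    tree = Tree.from_newick(doc["tree"])
    out: dict[str, list[Placement]] = {}
    for entry in doc["placements"]:
        name = entry["n"][0]
        ps = [Placement(name, int(e), ll, lwr, pend, dist, best=(k == 0))
              for k, (e, ll, lwr, dist, pend) in enumerate(entry["p"])]
        out[name] = ps
    return tree, out
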