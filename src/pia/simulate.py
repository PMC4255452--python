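"""Simulate reference packages and queries with known true placements.

Protein alignments are evolved along random bifurcating trees under the
package substitution model: root states are drawn from the stationary
frequencies and propagated through ``P(t)`` along each branch. Queries
are fabricated by evolving a new lineage from the midpoint of a chosen
edge for a given pendant length, so the true edge is known and
placement accuracy can be measured. All randomness flows from a single
integer seed; identical configurations reproduce identical output
bit-for-bit.

Simulated data is indel-free (profile-alignment insert handling is
exercised with hand-built fragments instead) and gap-free, which makes
it cleaner than real transcriptome data: no fragmentary ORFs, no
misassembly, no compositional bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._wag import AA_ORDER
from .annotate import LandmarkEntry, LandmarkMap
from .model import SubstitutionModel
from .profilealn import Alignment
from .refpkg import ReferencePackage
from .seqs import ProteinSequence
from .tree import Tree


def random_tree(n_tips: int, seed: int, mean_branch: float = 0.1) -> Tree:
    """Random unrooted bifurcating topology with Exp(mean) branch lengths.

    Built by sequential random attachment: starting from a 3-tip star,
    each new tip is grafted onto a uniformly chosen edge.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)

    def bl():
        return float(max(rng.exponential(mean_branch), 1e-4))

    newick = "(t1:%f,t2:%f,t3:%f);" % (bl(), bl(), bl())
    tree = Tree.from_newick(newick)
    for k in range(4, n_tips + 1):
        edges = sorted(tree.edges())
        target = tree.edge_node(int(rng.choice(edges)))
        t = target.length or 0.0
        split = float(rng.uniform(0.1, 0.9)) * t
        parent = target.parent
        from .tree import Node
        mid = Node(len(tree.nodes), parent=parent, length=t - split)
        tip = Node(len(tree.nodes) + 1, name=f"t{k}", parent=mid, length=bl())
        parent.children[parent.children.index(target)] = mid
        target.parent = mid
        target.length = split
        mid.children = [target, tip]
        tree.nodes.extend([mid, tip])
        tree.assign_edge_ids()
    tree.nodes = tree.preorder()
    for i, n in enumerate(tree.nodes):
        n.index = i
    tree.assign_edge_ids()
    return tree


def _evolve_states(tree: Tree, model: SubstitutionModel, n_sites: int, rng):
    """Draw ancestral and tip states; returns {node_index: state array}."""
    states = {}
    root_states = rng.choice(20, size=n_sites, p=model.freqs)
    states[tree.root.index] = root_states
    for n in tree.preorder():
        if n is tree.root:
            continue
        P = model.transition_probs(n.length or 0.0)
        parent_states = states[n.parent.index]
        u = rng.random(n_sites)
        cum = P.cumsum(axis=1)
        states[n.index] = (u[:, None] > cum[parent_states]).sum(axis=1)
    return states


def evolve(tree: Tree, model: SubstitutionModel, n_sites: int, seed: int) -> Alignment:
    """Evolve an ungapped alignment at the tips of a tree.

    The returned Alignment carries the simulated states of every node in
    ``node_states`` (by node index), which ``make_query`` needs to grow
    a query from a point inside the tree.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    states = _evolve_states(tree, model, n_sites, rng)
    rows = {}
    for tip in tree.tips():
        rows[tip.name] = "".join(AA_ORDER[i] for i in states[tip.index])
    aln = Alignment(rows)
    aln.node_states = states
    return aln


@dataclass(frozen=True)
class QueryTruth:
    query_id: str
    edge_id: int
    pendant_length: float


def make_query(tree: Tree, aln: Alignment, model: SubstitutionModel,
               edge_id: int, pendant: float, seed: int,
               query_id: str = "query"):
    """Evolve a query lineage from the midpoint of a chosen edge.

    The state at the midpoint is drawn conditional on the simulated
    state at the edge's parent end (available only for alignments made
    by ``evolve``), then evolved for ``pendant``. Returns
    (ProteinSequence, QueryTruth).
    """
    if pendant < 0:
        raise ValueError("pendant must be >= 0")
    states = getattr(aln, "node_states", None)
    if states is None:
        raise ValueError("alignment lacks simulated node states; "
                         "make_query requires an alignment from evolve()")
    rng = np.random.default_rng(seed)
    node = tree.edge_node(edge_id)
    t = node.length or 0.0
    n_sites = len(next(iter(aln.rows.values())))

    def step(from_states, dt):
        P = model.transition_probs(dt)
        u = rng.random(n_sites)
        cum = P.cumsum(axis=1)
        return (u[:, None] > cum[from_states]).sum(axis=1)

    mid = step(states[node.parent.index], t / 2.0)
    q = step(mid, pendant)
    seq = ProteinSequence(query_id, "".join(AA_ORDER[i] for i in q))
    return seq, QueryTruth(query_id, edge_id, pendant)


def adjacent_edges(tree: Tree, edge_id: int) -> set[int]:
    """Edge ids sharing a node with the given edge (placement 'near miss'
    neighbourhood)."""
    v = tree.edge_node(edge_id)
    u = v.parent
    adj = set()
    for n in tree.nodes:
        if n is tree.root or n.edge_id == edge_id:
            continue
        if n is u or n.parent is u or n is v.parent or n.parent is v:
            adj.add(n.edge_id)
    return adj


def simulate_refpkg(family: str, n_tips: int, n_sites: int, seed: int,
                    n_landmark1: int = 2, n_landmark2: int = 1,
                    n_baits: int = 2, model: SubstitutionModel | None = None
                    ) -> ReferencePackage:
    """A complete simulated reference package.

    Landmarks are assigned to the first tips in name order: LANDMARK1
    tips carry the sought function, LANDMARK2 tips are characterized
    outgroup-like relatives. Baits are ungapped copies of LANDMARK1
    rows (falling back to the first tips when there are none).
    """
    model = model or SubstitutionModel()
    tree = random_tree(n_tips, seed)
    aln = evolve(tree, model, n_sites, seed + 1)
    names = sorted(aln.rows, key=lambda s: int(s[1:]))
    entries = []
    for name in names[:n_landmark1]:
        entries.append(LandmarkEntry(name, "LANDMARK1", display_name=name))
    for name in names[n_landmark1:n_landmark1 + n_landmark2]:
        entries.append(LandmarkEntry(name, "LANDMARK2", display_name=name))
    landmarks = LandmarkMap(entries)
    bait_names = names[:max(n_baits, 1)]
    baits = [ProteinSequence(f"{family}_bait_{n}", aln.ungapped(n))
             for n in bait_names]
    pkg = ReferencePackage(family=family, baits=baits, ref_alignment=aln,
                           tree=tree, landmarks=landmarks, model=model,
                           manifest={"simulated": True, "seed": seed,
                                     "n_tips": n_tips, "n_sites": n_sites})
    pkg.validate()
    return pkg


# Deterministic reverse translation (first codon per amino acid, TAA stop)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT", "X": "NNN",
}


def back_translate(protein: str, flank: str = "TAA") -> str:
    """Encode a protein as nucleotides, bracketed by stop codons so the
    six-frame ORF scan recovers exactly the original peptide."""
    return flank + "".join(_CODON[c] for c in protein) + flank


def random_transcript(transcript_id: str, length_nt: int, seed: int):
    """A junk transcript: uniform random nucleotides."""
    from .seqs import NucSequence
    rng = np.random.default_rng(seed)
    return NucSequence(transcript_id,
                       "".join("ACGT"[i] for i in rng.choice(4, size=length_nt)))
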