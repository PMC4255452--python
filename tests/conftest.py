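import numpy as np
import pytest

from pia.model import SubstitutionModel
from pia.simulate import simulate_refpkg


@pytest.fixture(scope="session")
def wag():
    return SubstitutionModel()


@pytest.fixture(scope="session")
def pkg8(wag):
    """Simulated 8-tip, 150-site reference package shared across tests."""
    return simulate_refpkg("fam8", 8, 150, seed=3, model=wag)


@pytest.fixture(scope="session")
def pkg16(wag):
    return simulate_refpkg("fam16", 16, 200, seed=11, model=wag)


def attach_query_naive(tree, edge_id, distal, pendant, qrow, aln, model,
                       qname="__query__"):
    """Full-tree oracle: physically attach the query and run plain pruning.

    Independent of the cached-partial placement engine; used to verify it.
    """
    from pia.model import pruning_loglik
    from pia.tree import Node
    t2 = tree.copy()
    v = t2.edge_node(edge_id)
    u = v.parent
    t = v.length or 0.0
    mid = Node(-1, parent=u, length=distal)
    u.children[u.children.index(v)] = mid
    v.parent = mid
    v.length = t - distal
    qt = Node(-2, name=qname, parent=mid, length=pendant)
    mid.children = [v, qt]
    t2.nodes = t2.preorder()
    for i, n in enumerate(t2.nodes):
        n.index = i
    t2.assign_edge_ids()
    rows = dict(aln.rows)
    rows[qname] = qrow

    class A:
        pass

    a = A()
    a.rows = rows
    return pruning_loglik(t2, a, model)
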