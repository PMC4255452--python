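"""Interpret placements against landmark taxa.

Reference tips can carry a landmark tier: LANDMARK1 tips are
well-characterized genes with the sought function; LANDMARK2 tips are
well-characterized relatives whose function differs (e.g. non-visual
GPCRs in an opsin family). A placed query is given advisory context by
comparing its patristic distance to the nearest landmark of each tier:
a query attaching nearest a LANDMARK1 on a short pendant branch is a
candidate ortholog of the sought gene; one attaching nearest a
LANDMARK2 is likely a distant relative. The flag is an explicit,
reproducible heuristic standing in for by-eye tree inspection — it is
context for a human reader, not an orthology assertion, and both
distances are always reported so the call can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import pandas as pd

from .placement import Placement
from .tree import Tree

TIERS = ("LANDMARK1", "LANDMARK2", "NONE")
SUFFIXES = ("_LANDMARK1", "_LANDMARK2", "_QUERY")


@dataclass(frozen=True)
class LandmarkEntry:
    tip_id: str
    tier: str
    display_name: str = ""
    note: str = ""

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"unknown landmark tier {self.tier!r}")


class LandmarkMap:
    def __init__(self, entries: list[LandmarkEntry]):
        self.entries = {e.tip_id: e for e in entries}

    def tier(self, tip_id: str) -> str:
        e = self.entries.get(tip_id)
        return e.tier if e else "NONE"

    def tips_of_tier(self, tier: str) -> list[str]:
        return sorted(t for t, e in self.entries.items() if e.tier == tier)

    def validate(self, tree: Tree) -> list[str]:
        """Return warnings; raise if a landmark id is not a tree tip."""
        tipset = set(tree.tip_names())
        unknown = sorted(set(self.entries) - tipset)
        if unknown:
            raise ValueError(f"landmark ids not in tree: {unknown}")
        warnings = []
        if not self.tips_of_tier("LANDMARK1"):
            warnings.append("no LANDMARK1 tips in package")
        return warnings

    @classmethod
    def from_tsv(cls, path) -> "LandmarkMap":
        entries = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#") or \
                        (lineno == 1 and line.startswith("tip_id\t")):
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ValueError(f"{path}, line {lineno}: need >= 2 columns")
                entries.append(LandmarkEntry(cols[0], cols[1],
                                             cols[2] if len(cols) > 2 else "",
                                             cols[3] if len(cols) > 3 else ""))
        return cls(entries)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("tip_id\ttier\tdisplay_name\tnote\n")
            for t in sorted(self.entries):
                e = self.entries[t]
                fh.write(f"{e.tip_id}\t{e.tier}\t{e.display_name}\t{e.note}\n")


@dataclass(frozen=True)
class AnnotationRecord:
    query_id: str
    family: str
    best_edge_id: int
    best_lwr: float
    pendant_length: float
    nearest_l1: str | None
    nearest_l1_dist: float | None
    nearest_l2: str | None
    nearest_l2_dist: float | None
    flag: str  # candidate_ortholog_context / distant_relative_context / ambiguous


def tag_tree(tree: Tree, landmark_map: LandmarkMap,
             query_tips: list[str] = ()) -> str:
    """Newick text with _LANDMARK1/_LANDMARK2/_QUERY tip suffixes."""
    out = tree.copy()
    qset = set(query_tips)
    for tip in out.tips():
        if any(tip.name.endswith(s) for s in SUFFIXES):
            raise ValueError(f"tip {tip.name!r} already carries a tag suffix")
        if tip.name in qset:
            tip.name = tip.name + "_QUERY"
        else:
            tier = landmark_map.tier(tip.name)
            if tier != "NONE":
                tip.name = tip.name + "_" + tier
    return out.to_newick()


def patristic_distance(tree: Tree, point: tuple[int, float], tip: str) -> float:
    """Branch-length distance from a point on an edge to a tip.

    The point is (edge_id, distal_length) with distal measured from the
    parent (root-side) end of the edge.
    """
    edge_id, distal = point
    v = tree.edge_node(edge_id)
    t = v.length or 0.0
    if not 0.0 <= distal <= t + 1e-9:
        raise ValueError(f"distal {distal} outside edge of length {t}")
    tipnode = next((n for n in tree.tips() if n.name == tip), None)
    if tipnode is None:
        raise KeyError(f"no tip named {tip!r}")
    depths = tree.node_depths()
    # is the tip inside the subtree below v?
    x = tipnode
    inside = False
    while x is not None:
        if x is v:
            inside = True
            break
        x = x.parent
    if inside:
        return (t - distal) + depths[tipnode.index] - depths[v.index]
    u = v.parent
    # distance from u to tip, path not entering v's subtree
    x = tipnode
    anc = set()
    while x is not None:
        anc.add(x.index)
        x = x.parent
    y = u
    while y.index not in anc:
        y = y.parent
    lca = y
    d_u_tip = (depths[u.index] - depths[lca.index]) + \
              (depths[tipnode.index] - depths[lca.index])
    return distal + d_u_tip


def classify_query(placement: Placement, landmark_map: LandmarkMap, tree: Tree,
                   family: str = "family",
                   pendant_max: float | None = None) -> AnnotationRecord:
    """Advisory orthology-context flag for one placed query.

    candidate_ortholog_context: nearest landmark (patristic, from the
    attachment point) is LANDMARK1 and the pendant branch is short
    (<= pendant_max, default twice the median terminal branch length).
    distant_relative_context: nearest landmark is LANDMARK2.
    ambiguous: no landmarks, equidistant tiers (within 1e-9), or a
    LANDMARK1 neighbour reached on a long pendant branch.
    """
    point = (placement.edge_id, placement.distal_length)
    if pendant_max is None:
        terms = list(tree.terminal_branch_lengths().values())
        pendant_max = 2.0 * median(terms)

    def nearest(tier):
        tips = landmark_map.tips_of_tier(tier)
        if not tips:
            return None, None
        dists = sorted((patristic_distance(tree, point, t), t) for t in tips)
        return dists[0][1], dists[0][0]

    l1, d1 = nearest("LANDMARK1")
    l2, d2 = nearest("LANDMARK2")
    if d1 is None and d2 is None:
        flag = "ambiguous"
    elif d1 is not None and (d2 is None or d1 < d2 - 1e-9):
        flag = ("candidate_ortholog_context"
                if placement.pendant_length <= pendant_max else "ambiguous")
    elif d2 is not None and (d1 is None or d2 < d1 - 1e-9):
        flag = "distant_relative_context"
    else:  # equidistant within tolerance
        flag = "ambiguous"
    return AnnotationRecord(placement.query_id, family, placement.edge_id,
                            placement.lwr, placement.pendant_length,
                            l1, d1, l2, d2, flag)


def presence_matrix(records_by_sample: dict[str, list[AnnotationRecord]],
                    contamination: dict[tuple[str, str], bool] | None = None
                    ) -> pd.DataFrame:
    """Family x sample table: 1 where a sample has a candidate ortholog.

    ``contamination`` optionally marks (family, sample) cells "C" — a
    user-supplied judgement passed through to the report, not computed.
    """
    if not records_by_sample:
        raise ValueError("need at least one sample")
    samples = sorted(records_by_sample)
    families = sorted({r.family for rs in records_by_sample.values() for r in rs})
    mat = pd.DataFrame(0, index=families, columns=samples, dtype=object)
    for sample, recs in records_by_sample.items():
        for r in recs:
            if r.flag == "candidate_ortholog_context":
                mat.loc[r.family, sample] = 1
    for (fam, sample), is_c in (contamination or {}).items():
        if is_c and fam in mat.index and sample in mat.columns:
            mat.loc[fam, sample] = "C"
    mat.index.name = "family"
    return mat
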