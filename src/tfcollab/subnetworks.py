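"""Triple-Link decomposition of the SCCM into non-overlapping
collaborative TF subnetworks, plus merged-CCG bookkeeping.

The heuristic is seed-and-extend: the highest-weight unassigned TF pair
seeds a subnetwork; members are then admitted greedily, each needing
strong links (shared CCGs >= min_shared) to at least ``min_links``
current members (to *all* members while the subnetwork is still smaller
than min_links). Extraction repeats on the remaining pool, so earlier
subnetworks carry the strongest collaborations and member sets are
disjoint by construction. All ties break by ascending TF id, making the
decomposition a pure function of the SCCM.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ccg import CCGRanking, SCCM

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """A disjoint set of collaborative TFs extracted from the SCCM."""

    id: int                      # 1-based, in extraction order
    member_tfs: list             # admission order, seed pair first
    edges: list = field(default_factory=list)   # (tf_a, tf_b, weight), weight >= min_shared
    merged_ccgs: list = field(default_factory=list)
    diagnostics: object = None   # PCScreen, attached by the screening stage

    @property
    def seed_weight(self) -> int:
        """Shared-CCG count of the seeding pair."""
        a, b = self.member_tfs[0], self.member_tfs[1]
        for x, y, w in self.edges:
            if {x, y} == {a, b}:
                return w
        return 0


def decompose(S: SCCM, min_shared: int | None = None, min_links: int = 3) -> list[Subnetwork]:
    """Decompose the SCCM into non-overlapping subnetworks.

    Returns subnetworks in extraction order; TFs that never join any
    subnetwork are reported in the log but not emitted.
    """
    ms = S.min_shared if min_shared is None else min_shared
    n = len(S.tf_ids)
    if n == 0:
        return []
    ids = np.asarray(S.tf_ids)
    # ascending-id rank used for every tie break
    id_rank = np.empty(n, dtype=int)
    id_rank[np.argsort(ids, kind="stable")] = np.arange(n)
    C = S.counts.astype(np.int64).copy()
    np.fill_diagonal(C, -1)

    unassigned = np.ones(n, dtype=bool)
    subnets: list[Subnetwork] = []
    while True:
        # --- seed: unassigned pair with maximal shared count -------------
        avail = np.where(unassigned)[0]
        if len(avail) < 2:
            break
        sub = C[np.ix_(avail, avail)]
        best = sub.max()
        if best < ms:
            break
        pi, pj = np.where(sub == best)
        pairs = [(avail[a], avail[b]) for a, b in zip(pi, pj) if a < b]
        # lexicographically smallest id pair among ties
        pairs.sort(key=lambda p: tuple(sorted((ids[p[0]], ids[p[1]]))))
        a, b = pairs[0]
        if id_rank[b] < id_rank[a]:
            a, b = b, a
        members = [a, b]
        member_set = {a, b}

        # --- growth ------------------------------------------------------
        while True:
            cand = [i for i in np.where(unassigned)[0] if i not in member_set]
            qualified = []
            for c in cand:
                links = sum(C[c, m] >= ms for m in members)
                need = len(members) if len(members) < min_links else min_links
                if links >= need:
                    qualified.append(c)
            if not qualified:
                break
            # admit the candidate with greatest summed counts to members
            qualified.sort(key=lambda c: (-int(C[c, members].sum()), ids[c]))
            chosen = qualified[0]
            members.append(chosen)
            member_set.add(chosen)

        unassigned[members] = False
        edges = [(str(ids[i]), str(ids[j]), int(C[i, j]))
                 for x, i in enumerate(members) for j in members[x + 1:]
                 if C[i, j] >= ms]
        subnets.append(Subnetwork(id=len(subnets) + 1,
                                  member_tfs=[str(ids[m]) for m in members],
                                  edges=edges))

    leftovers = [str(g) for g in ids[unassigned]]
    if leftovers:
        logger.info("decompose: %d TFs remain unassigned", len(leftovers))
    # sanity: disjoint member sets
    seen: set = set()
    for s in subnets:
        overlap = seen & set(s.member_tfs)
        assert not overlap, f"subnetwork overlap at {sorted(overlap)[0]}"
        seen |= set(s.member_tfs)
    return subnets


def unassigned_tfs(S: SCCM, subnets: list[Subnetwork]) -> list:
    members = {t for s in subnets for t in s.member_tfs}
    return [t for t in S.tf_ids if t not in members]


def assign_ccgs(subnets: list[Subnetwork], rankings: list[CCGRanking]) -> list[Subnetwork]:
    """Attach to each subnetwork the deduplicated union of its members'
    top-k CCG lists (order of first appearance, then by gene id is not
    material — a sorted unique list is stored for determinism)."""
    by_tf = {r.tf_id: r for r in rankings}
    out = []
    for s in subnets:
        merged: set = set()
        for tf in s.member_tfs:
            if tf not in by_tf:
                raise KeyError(f"no CCG ranking for subnetwork member {tf!r}")
            merged |= set(by_tf[tf].ranked_genes)
        out.append(Subnetwork(id=s.id, member_tfs=list(s.member_tfs),
                              edges=list(s.edges), merged_ccgs=sorted(merged),
                              diagnostics=s.diagnostics))
    return out


def classify_ccgs(subnets: list[Subnetwork], tf_universe) -> pd.DataFrame:
    """Partition each subnetwork's merged CCGs into three classes:

    (a) non-TF CCGs, (b) TF CCGs outside every analyzed subnetwork,
    (c) TF CCGs that are members of an analyzed subnetwork.
    Returns one row per subnetwork with counts and fractions.
    """
    tf_universe = set(tf_universe)
    members_all = {t for s in subnets for t in s.member_tfs}
    rows = []
    for s in subnets:
        ccgs = set(s.merged_ccgs)
        non_tf = {g for g in ccgs if g not in tf_universe}
        tf_member = {g for g in ccgs if g in members_all}
        tf_outside = ccgs - non_tf - tf_member
        total = max(len(ccgs), 1)
        rows.append({
            "subnetwork": s.id, "n_ccgs": len(ccgs),
            "non_tf": len(non_tf), "tf_outside": len(tf_outside),
            "tf_member": len(tf_member),
            "frac_non_tf": len(non_tf) / total,
            "frac_tf_outside": len(tf_outside) / total,
            "frac_tf_member": len(tf_member) / total,
        })
    return pd.DataFrame(rows)


# -- I/O -----------------------------------------------------------------

def subnetworks_to_tsv(subnets: list[Subnetwork], path) -> None:
    rows = [(s.id, tf) for s in subnets for tf in s.member_tfs]
    pd.DataFrame(rows, columns=["subnetwork", "tf"]).to_csv(path, sep="\t", index=False)


def merged_ccgs_to_tsv(subnets: list[Subnetwork], path) -> None:
    rows = [(s.id, g) for s in subnets for g in s.merged_ccgs]
    pd.DataFrame(rows, columns=["subnetwork", "ccg"]).to_csv(path, sep="\t", index=False)


def subnetworks_from_tsv(path, S: SCCM | None = None,
                         min_shared: int | None = None) -> list[Subnetwork]:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str})
    out = []
    for sid, grp in df.groupby("subnetwork", sort=True):
        members = list(grp["tf"])
        edges = []
        if S is not None:
            ms = S.min_shared if min_shared is None else min_shared
            pos = {t: i for i, t in enumerate(S.tf_ids)}
            edges = [(a, b, int(S.counts[pos[a], pos[b]]))
                     for x, a in enumerate(members) for b in members[x + 1:]
                     if S.counts[pos[a], pos[b]] >= ms]
        out.append(Subnetwork(id=int(sid), member_tfs=members, edges=edges))
    return out


def subnetwork_to_graphml(s: Subnetwork, path) -> None:
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(s.member_tfs)
    for a, b, w in s.edges:
        G.add_edge(a, b, weight=w)
    nx.write_graphml(G, path)


def summary_table(subnets: list[Subnetwork], known_genes=None) -> pd.DataFrame:
    """Per-subnetwork summary: member count, merged-CCG count and, when a
    curated list of known genes is supplied, how many members are on it."""
    known = set(known_genes or [])
    rows = []
    for s in subnets:
        rows.append({
            "subnetwork": s.id,
            "n_tfs": len(s.member_tfs),
            "n_merged_ccgs": len(s.merged_ccgs),
            "n_known_genes": len(known & set(s.member_tfs)),
        })
    return pd.DataFrame(rows)
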