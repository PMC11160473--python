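"""Synteny-aware reciprocal-best-hit transfer of tandem-cluster gene IDs.

Tier 1 pairs genes that are each other's unique top bit-score hit (RBH).
Tier 2 works between consecutive RBH anchors: the unassigned genes of each
gap interval are aligned order-preservingly (Needleman-Wunsch with pairwise
score = percent identity and a flat gap penalty), and aligned pairs clearing
a minimum identity are accepted. Identity, not bit-score, drives this tier:
a truncated gene model deflates alignment scores but not identity, which is
exactly the situation the fill is meant to rescue. Genes left unaligned are
flagged collapsed when their best hit already belongs to another query
(two old genes, one new gene), otherwise novel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("antseq")

TIER_RBH = "RBH"
TIER_SYNTENY = "synteny_identity"
TIER_COLLAPSED = "unmatched_collapsed"
TIER_NOVEL = "unmatched_novel"


@dataclass
class SyntenyAssignment:
    gene_a: str
    gene_b: str | None
    evidence: str
    note: str = ""


def _best_hits(similarity: pd.DataFrame, by: str, key: str):
    """Unique top hit per gene along axis ``by`` (None when tied)."""
    best = {}
    for g, sub in similarity.groupby(by, sort=False):
        top = sub[key].max()
        winners = sub[sub[key] == top]
        other = "subject" if by == "query" else "query"
        best[g] = None if len(winners) > 1 else winners.iloc[0][other]
    return best


def reciprocal_best_hits(similarity: pd.DataFrame) -> dict:
    """Mutual unique top-bit-score pairs. Returns {gene_A: gene_B}."""
    if similarity.empty:
        return {}
    best_a = _best_hits(similarity, "query", "bit_score")
    best_b = _best_hits(similarity, "subject", "bit_score")
    return {
        a: b
        for a, b in best_a.items()
        if b is not None and best_b.get(b) == a
    }


def _needleman_wunsch(a_genes, b_genes, score, gap_penalty):
    """Order-preserving global alignment; returns list of (a, b) pairs."""
    n, m = len(a_genes), len(b_genes)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = -gap_penalty * np.arange(n + 1)
    dp[0, :] = -gap_penalty * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(
                dp[i - 1, j - 1] + score(a_genes[i - 1], b_genes[j - 1]),
                dp[i - 1, j] - gap_penalty,
                dp[i, j - 1] - gap_penalty,
            )
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if np.isclose(dp[i, j],
                      dp[i - 1, j - 1] + score(a_genes[i - 1], b_genes[j - 1])):
            pairs.append((a_genes[i - 1], b_genes[j - 1]))
            i, j = i - 1, j - 1
        elif np.isclose(dp[i, j], dp[i - 1, j] - gap_penalty):
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def _longest_increasing(anchor_pairs):
    """Indices of a maximal set of non-crossing anchors (LIS on B position)."""
    if not anchor_pairs:
        return []
    b_pos = [b for _, b in anchor_pairs]
    n = len(b_pos)
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if b_pos[j] < b_pos[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    k = int(np.argmax(best))
    out = []
    while k != -1:
        out.append(k)
        k = prev[k]
    return out[::-1]


def synteny_fill(rbh: dict, list_a, list_b, similarity: pd.DataFrame,
                 min_identity: float = 60.0, gap_penalty: float = 40.0) -> list:
    """Complete an RBH matching over two ordered gene lists.

    Returns a list of :class:`SyntenyAssignment`, one per gene of ``list_a``.
    """
    apos = {g: i for i, g in enumerate(list_a)}
    bpos = {g: i for i, g in enumerate(list_b)}
    ident = {}
    for row in similarity.itertuples(index=False):
        ident[(row.query, row.subject)] = float(row.pct_identity)

    anchors = sorted(
        ((apos[a], bpos[b]) for a, b in rbh.items() if a in apos and b in bpos),
    )
    keep_idx = _longest_increasing(anchors)
    if len(keep_idx) < len(anchors):
        logger.warning("%d crossing RBH anchor(s) demoted to candidates",
                       len(anchors) - len(keep_idx))
    anchors = [anchors[i] for i in keep_idx]
    anchor_a = {list_a[ia] for ia, _ in anchors}
    anchor_b = {list_b[ib] for _, ib in anchors}

    assigned = {list_a[ia]: list_b[ib] for ia, ib in anchors}
    evidence = {a: TIER_RBH for a in assigned}

    def score(a, b):
        return ident.get((a, b), 0.0)

    bounds = [(-1, -1)] + anchors + [(len(list_a), len(list_b))]
    for (ia0, ib0), (ia1, ib1) in zip(bounds[:-1], bounds[1:]):
        gap_a = [g for g in list_a[ia0 + 1:ia1] if g not in anchor_a]
        gap_b = [g for g in list_b[ib0 + 1:ib1] if g not in anchor_b]
        if not gap_a or not gap_b:
            continue
        for a, b in _needleman_wunsch(gap_a, gap_b, score, gap_penalty):
            if score(a, b) >= min_identity:
                assigned[a] = b
                evidence[a] = TIER_SYNTENY

    # flag the leftovers
    taken = set(assigned.values())
    best_hit = _best_hits(similarity, "query", "bit_score") if len(similarity) else {}
    out = []
    for a in list_a:
        if a in assigned:
            out.append(SyntenyAssignment(a, assigned[a], evidence[a]))
            continue
        bh = best_hit.get(a)
        if bh is not None and bh in taken:
            out.append(SyntenyAssignment(
                a, None, TIER_COLLAPSED,
                note=f"best hit {bh} already assigned"))
        else:
            out.append(SyntenyAssignment(a, None, TIER_NOVEL))
    # injectivity check (both tiers)
    used = [x.gene_b for x in out if x.gene_b is not None]
    assert len(used) == len(set(used)), "matching is not injective"
    return out


def transfer_report(assignments) -> dict:
    """Evidence-tier counts plus the collapsed/novel gene lists and a
    machine-readable table."""
    tiers = {TIER_RBH: 0, TIER_SYNTENY: 0, TIER_COLLAPSED: 0, TIER_NOVEL: 0}
    rows = []
    for a in assignments:
        tiers[a.evidence] += 1
        rows.append((a.gene_a, a.gene_b if a.gene_b else "", a.evidence, a.note))
    table = pd.DataFrame(
        rows, columns=["gene_A", "gene_B", "evidence", "note"]
    ).set_index("gene_A")
    return {
        "tier_counts": tiers,
        "collapsed": [a.gene_a for a in assignments if a.evidence == TIER_COLLAPSED],
        "novel": [a.gene_a for a in assignments if a.evidence == TIER_NOVEL],
        "table": table,
    }
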