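"""Chaining of homologous gene-pair anchors into collinear blocks.

An anchor is a homologous gene pair; its coordinates for chaining are the
gene-order ranks of the two genes on their chromosomes. A collinear block is
a chain of anchors whose ranks increase strictly on the query and increase
(forward) or decrease (inverted) strictly on the subject, with rank gaps on
both sides bounded by ``max_gap_genes``.

Chain score = sum of anchor scores minus a gap penalty of 1 per skipped gene
rank on either side. Blocks are extracted greedily: the maximum-score chain
is found by dynamic programming, removed, and the search repeats; extraction
stops when the best remaining chain has fewer than ``match_size`` anchors.
Ties between chains are broken by leftmost query start, then forward
orientation. This makes the block set deterministic and independent of
anchor input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from polyrearrange.errors import ValidationError
from polyrearrange.formats_io import AnchorPair, GeneRecord

DEFAULT_MATCH_SIZE = 8
#: Gap tolerance in gene ranks; the common default of collinearity chaining
#: tools run with default parameters.
DEFAULT_MAX_GAP_GENES = 25


@dataclass(frozen=True)
class CollinearBlock:
    """An orientation-signed chained run of anchors between two chromosomes."""

    block_id: int
    chrom_q: str
    chrom_s: str
    orientation: str  # {"forward", "inverted"}
    anchors: tuple[AnchorPair, ...]
    span_q: tuple[int, int]
    span_s: tuple[int, int]
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def dedupe_anchors(
    pairs: list[AnchorPair],
    genes_q: dict[str, GeneRecord],
    genes_s: dict[str, GeneRecord],
    top_n: int = 5,
) -> list[AnchorPair]:
    """Limit hits per query and collapse tandem arrays.

    Keeps at most ``top_n`` subject genes per query gene (best score first),
    then collapses tandem arrays — runs of consecutive-rank genes on one
    chromosome all hitting the same partner gene — to the best-scoring
    representative. Collapse is applied on both the query and subject side.
    """
    by_query: dict[str, list[AnchorPair]] = {}
    for p in pairs:
        by_query.setdefault(p.gene_q, []).append(p)
    kept: list[AnchorPair] = []
    for q, hits in by_query.items():
        hits.sort(key=lambda a: (-a.score, a.evalue, a.gene_s))
        kept.extend(hits[:top_n])
    kept = _collapse_tandem(kept, genes_q, genes_s, side="q")
    kept = _collapse_tandem(kept, genes_q, genes_s, side="s")
    kept.sort(key=lambda a: (a.gene_q, a.gene_s))
    return kept


def _collapse_tandem(
    pairs: list[AnchorPair],
    genes_q: dict[str, GeneRecord],
    genes_s: dict[str, GeneRecord],
    side: str,
) -> list[AnchorPair]:
    # group anchors sharing the same partner gene; within a group, genes on
    # the collapsing side that form consecutive-rank runs on one chromosome
    # are a tandem array -> keep best score
    groups: dict[str, list[AnchorPair]] = {}
    for p in pairs:
        partner = p.gene_s if side == "q" else p.gene_q
        groups.setdefault(partner, []).append(p)
    out: list[AnchorPair] = []
    for members in groups.values():
        own = genes_q if side == "q" else genes_s

        def key(p: AnchorPair):
            g = own[p.gene_q if side == "q" else p.gene_s]
            return (g.chrom, g.rank)

        members.sort(key=key)
        run: list[AnchorPair] = []
        prev: tuple[str, int] | None = None
        for p in members:
            k = key(p)
            if prev is not None and (k[0] != prev[0] or k[1] != prev[1] + 1):
                out.append(max(run, key=lambda a: a.score))
                run = []
            run.append(p)
            prev = k
        if run:
            out.append(max(run, key=lambda a: a.score))
    return out


def _anchor_tuples(
    anchors: list[AnchorPair],
    genes_q: dict[str, GeneRecord],
    genes_s: dict[str, GeneRecord],
):
    """Resolve anchors to (q_rank, s_rank, score, anchor, q_gene, s_gene)."""
    rows = []
    for a in anchors:
        if a.gene_q not in genes_q or a.gene_s not in genes_s:
            raise ValidationError(f"anchor {a.gene_q}/{a.gene_s} has unknown gene id")
        gq, gs = genes_q[a.gene_q], genes_s[a.gene_s]
        rows.append((gq.rank, gs.rank, a.score, a, gq, gs))
    return rows


def best_chain(
    rows: list[tuple],
    max_gap_genes: int,
) -> tuple[float, list[int], str] | None:
    """Maximum-score monotone chain over anchor tuples, by DP.

    ``rows`` are (q_rank, s_rank, score, ...) tuples. Returns (score,
    indices-into-rows, orientation) for the best chain across both
    orientations, or None if rows is empty. Tie-break: leftmost query rank of
    the chain start, then forward before inverted, then lexicographic rank
    sequence.
    """
    if not rows:
        return None
    order = sorted(range(len(rows)), key=lambda i: (rows[i][0], rows[i][1]))
    best: tuple[float, list[int], str] | None = None
    for orientation in ("forward", "inverted"):
        sign = 1 if orientation == "forward" else -1
        n = len(order)
        dp = [rows[i][2] for i in (order)]
        back: list[int | None] = [None] * n

        def chain_ranks(j: int) -> list[tuple[int, int]]:
            out = []
            k: int | None = j
            while k is not None:
                out.append((rows[order[k]][0], rows[order[k]][1]))
                k = back[k]
            out.reverse()
            return out

        for j in range(n):
            qj, sj = rows[order[j]][0], rows[order[j]][1]
            for i in range(j):
                qi, si = rows[order[i]][0], rows[order[i]][1]
                if qj <= qi:
                    continue
                gap_q = qj - qi - 1
                if gap_q > max_gap_genes:
                    continue
                ds = sign * (sj - si)
                if ds <= 0:
                    continue
                gap_s = ds - 1
                if gap_s > max_gap_genes:
                    continue
                cand = dp[i] + rows[order[j]][2] - (gap_q + gap_s)
                if cand > dp[j]:
                    dp[j] = cand
                    back[j] = i
                elif cand == dp[j] and back[j] != i:
                    # exact score tie: keep the lexicographically smallest
                    # rank sequence (the documented deterministic tie-break)
                    if chain_ranks(i) + [(qj, sj)] < chain_ranks(j):
                        back[j] = i
        for j in range(n):
            chain: list[int] = []
            k: int | None = j
            while k is not None:
                chain.append(order[k])
                k = back[k]
            chain.reverse()
            cand = (dp[j], chain, orientation)
            if best is None or _chain_better(cand, best, rows):
                best = cand
    return best


def _chain_better(a: tuple, b: tuple, rows: list[tuple]) -> bool:
    """True if chain ``a`` beats chain ``b`` under the deterministic tie-break."""
    if a[0] != b[0]:
        return a[0] > b[0]
    qa = rows[a[1][0]][0]
    qb = rows[b[1][0]][0]
    if qa != qb:
        return qa < qb
    if a[2] != b[2]:
        return a[2] == "forward"
    ka = [(rows[i][0], rows[i][1]) for i in a[1]]
    kb = [(rows[i][0], rows[i][1]) for i in b[1]]
    return ka < kb


def chain_collinear_blocks(
    anchors: list[AnchorPair],
    genes_q: dict[str, GeneRecord],
    genes_s: dict[str, GeneRecord],
    match_size: int = DEFAULT_MATCH_SIZE,
    max_gap_genes: int = DEFAULT_MAX_GAP_GENES,
    exclude_self_chrom: bool = False,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks, per chromosome pair.

    ``match_size`` is the minimum number of anchors for a block. Anchors
    belong to at most one block. ``exclude_self_chrom`` drops same-chromosome
    anchor pairs (useful for within-genome self comparisons where the trivial
    diagonal is meaningless after self-pair removal but tandem neighbours
    remain).
    """
    if match_size < 2:
        raise ValidationError(f"match_size must be >= 2, got {match_size}")
    rows_all = _anchor_tuples(anchors, genes_q, genes_s)
    by_pair: dict[tuple[str, str], list[tuple]] = {}
    for row in rows_all:
        cq, cs = row[4].chrom, row[5].chrom
        if exclude_self_chrom and cq == cs:
            continue
        by_pair.setdefault((cq, cs), []).append(row)

    blocks: list[CollinearBlock] = []
    bid = 0
    for (cq, cs) in sorted(by_pair):
        rows = by_pair[(cq, cs)]
        remaining = list(range(len(rows)))
        while remaining:
            sub = [rows[i] for i in remaining]
            found = best_chain(sub, max_gap_genes)
            if found is None:
                break
            score, chain_idx, orientation = found
            chain_rows = [sub[i] for i in chain_idx]
            removed = {id(r) for r in chain_rows}
            remaining = [i for i in remaining if id(rows[i]) not in removed]
            if len(chain_idx) < match_size:
                # anchors go to their best chain; chains below match_size are
                # discarded, not reassigned — keeps extraction independent of
                # match_size (block sets shrink monotonically as it rises)
                continue
            span_q = (
                min(r[4].start for r in chain_rows),
                max(r[4].end for r in chain_rows),
            )
            span_s = (
                min(r[5].start for r in chain_rows),
                max(r[5].end for r in chain_rows),
            )
            blocks.append(
                CollinearBlock(
                    block_id=bid,
                    chrom_q=cq,
                    chrom_s=cs,
                    orientation=orientation,
                    anchors=tuple(r[3] for r in chain_rows),
                    span_q=span_q,
                    span_s=span_s,
                    score=score,
                )
            )
            bid += 1
    return blocks


def collinearity_summary(
    blocks: list[CollinearBlock] | None,
    totals: dict[str, int],
    collinear_counts: dict[str, int] | None = None,
    comparison_of_block=None,
) -> pd.DataFrame:
    """Counts and percentages of genes in collinear blocks per comparison.

    ``totals`` maps comparison name -> total genes considered. Collinear gene
    counts are either taken from ``collinear_counts`` directly, or computed
    as distinct gene ids in the blocks assigned to each comparison by
    ``comparison_of_block(block) -> name``. Percentage = 100 * collinear /
    total; a zero total yields NA.
    """
    if collinear_counts is None:
        if blocks is None or comparison_of_block is None:
            raise ValidationError("need blocks + comparison_of_block or collinear_counts")
        genes_by_comp: dict[str, set[str]] = {name: set() for name in totals}
        for b in blocks:
            name = comparison_of_block(b)
            if name is None:
                continue
            bucket = genes_by_comp.setdefault(name, set())
            for a in b.anchors:
                bucket.add(("q", a.gene_q))
                bucket.add(("s", a.gene_s))
        collinear_counts = {name: len(g) for name, g in genes_by_comp.items()}
    rows = []
    for name, total in totals.items():
        coll = collinear_counts.get(name, 0)
        pct = float("nan") if total == 0 else 100.0 * coll / total
        rows.append({"comparison": name, "collinear_genes": coll, "total_genes": total,
                     "pct_collinear": pct})
    return pd.DataFrame(rows)


def blocks_to_frame(blocks: list[CollinearBlock]) -> pd.DataFrame:
    """Tabular export of a block set (one row per block)."""
    return pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "chrom_q": b.chrom_q,
                "chrom_s": b.chrom_s,
                "orientation": b.orientation,
                "n_anchors": b.n_anchors,
                "span_q_start": b.span_q[0],
                "span_q_end": b.span_q[1],
                "span_s_start": b.span_s[0],
                "span_s_end": b.span_s[1],
                "score": b.score,
                "anchors": ",".join(f"{a.gene_q}|{a.gene_s}" for a in b.anchors),
            }
            for b in blocks
        ]
    )
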