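"""Calling of chromosomal rearrangements from collinear blocks.

The evidence model follows how large rearrangements are read off a synteny
map of an allotetraploid:

* a **translocation** shows up as a region collinear with a non-homoeologous
  chromosome, while that region lacks synteny with the carrier chromosome's
  own diploid relative; two such regions exchanged between one chromosome
  pair merge into a **reciprocal translocation**;
* an **inversion** is a maximal run of inverted-orientation blocks between a
  homoeologous chromosome pair;
* a **segmental duplication** is a region of one chromosome that aligns to
  two or more disjoint partner regions through the *same* query region
  (requiring the query regions to coincide is what separates duplications
  from translocations, whose extra partners attach to disjoint query
  regions).

Events are accounted per subgenome with overlapping intervals merged before
summation, so one base is never counted twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from polyrearrange._intervals import merge_intervals, overlap_len
from polyrearrange.collinearity import CollinearBlock
from polyrearrange.errors import ValidationError

#: An event is "major" above this span and gene count.
MAJOR_SPAN_BP = 1_000_000
MAJOR_N_GENES = 100


@dataclass(frozen=True)
class Region:
    """One interval of a rearrangement, with its gene count."""

    chrom: str
    start: int
    end: int
    n_genes: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"region {self.chrom}:{self.start}-{self.end} empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Rearrangement:
    """A typed rearrangement event spanning one or two intervals."""

    kind: str  # {translocation, reciprocal_translocation, inversion, segmental_duplication}
    regions: tuple[Region, ...]
    scope: str = "intra_subgenome"  # {intra_subgenome, inter_subgenome}
    evidence: tuple[str, ...] = field(default_factory=tuple)

    @property
    def span_bp(self) -> int:
        return sum(r.length for r in self.regions)

    @property
    def n_genes(self) -> int:
        return sum(r.n_genes for r in self.regions)

    @property
    def major(self) -> bool:
        return self.span_bp > MAJOR_SPAN_BP and self.n_genes > MAJOR_N_GENES


def chrom_index_subgenome(chrom: str) -> tuple[str, str]:
    """Split a chromosome name into (index, subgenome letter).

    Follows the Cq{n}{A|B} convention: trailing A/B is the subgenome, the
    digits before it the homoeolog index.
    """
    m = re.match(r"^(\D*)(\d+)([AB])$", chrom)
    if not m:
        return (chrom, "none")
    return (m.group(2), m.group(3))


def default_homoeolog_map(chroms_q, chroms_s) -> dict[str, str]:
    """Pair chromosomes with the same index across subgenomes by name."""
    by_index_s = {chrom_index_subgenome(c)[0]: c for c in chroms_s}
    out = {}
    for c in chroms_q:
        idx, _ = chrom_index_subgenome(c)
        if idx in by_index_s:
            out[c] = by_index_s[idx]
    return out


def _region_genes(block: CollinearBlock, side: str) -> int:
    return len({a.gene_q for a in block.anchors} if side == "q" else {a.gene_s for a in block.anchors})


def _scope(regions: tuple[Region, ...], subgenome_of: dict[str, str] | None) -> str:
    subs = set()
    for r in regions:
        if subgenome_of and r.chrom in subgenome_of:
            subs.add(subgenome_of[r.chrom])
        else:
            subs.add(chrom_index_subgenome(r.chrom)[1])
    return "intra_subgenome" if len(subs) <= 1 else "inter_subgenome"


# ---------------------------------------------------------------------------
# Inversions
# ---------------------------------------------------------------------------


def detect_inversions(
    blocks_self: list[CollinearBlock],
    homoeolog_map: dict[str, str] | None = None,
    subgenome_of: dict[str, str] | None = None,
) -> list[Rearrangement]:
    """Inversions between homoeologous chromosomes.

    Maximal runs of inverted-orientation blocks along the query chromosome
    are emitted as one inversion each, with intervals covering the run on
    both chromosomes (which homoeolog physically carries the inversion is not
    decidable from self-synteny alone).
    """
    if homoeolog_map is None:
        homoeolog_map = default_homoeolog_map(
            {b.chrom_q for b in blocks_self}, {b.chrom_s for b in blocks_self}
        )
    events: list[Rearrangement] = []
    pairs = sorted({(b.chrom_q, b.chrom_s) for b in blocks_self})
    for cq, cs in pairs:
        if homoeolog_map.get(cq) != cs:
            continue
        chain = sorted(
            (b for b in blocks_self if b.chrom_q == cq and b.chrom_s == cs),
            key=lambda b: b.span_q,
        )
        run: list[CollinearBlock] = []
        for b in chain + [None]:  # sentinel flushes the last run
            if b is not None and b.orientation == "inverted":
                run.append(b)
                continue
            if run:
                rq = Region(
                    cq,
                    min(x.span_q[0] for x in run),
                    max(x.span_q[1] for x in run),
                    n_genes=sum(_region_genes(x, "q") for x in run),
                )
                rs = Region(
                    cs,
                    min(x.span_s[0] for x in run),
                    max(x.span_s[1] for x in run),
                    n_genes=sum(_region_genes(x, "s") for x in run),
                )
                events.append(
                    Rearrangement(
                        kind="inversion",
                        regions=(rq, rs),
                        scope="intra_subgenome",
                        evidence=tuple(f"block:{x.block_id}" for x in run),
                    )
                )
                run = []
    return events


# ---------------------------------------------------------------------------
# Segmental duplications
# ---------------------------------------------------------------------------


def detect_segmental_duplications(
    blocks_self: list[CollinearBlock],
    genes_q: dict,
    genes_s: dict,
    min_query_cover: float = 0.8,
    subgenome_of: dict[str, str] | None = None,
) -> list[Rearrangement]:
    """Duplicated blocks of genes with conserved order.

    A block ``b2`` marks a duplication when another block ``b1`` aligns the
    same query region (>= ``min_query_cover`` of ``b2``'s query span, backed
    by ``b1`` anchors inside it) to a disjoint partner region. The event's
    intervals are the two partner copies. ``genes_q``/``genes_s`` map gene id
    -> GeneRecord for the two sides of the block set.
    """
    events: list[Rearrangement] = []
    claimed: set[tuple[int, int]] = set()
    for b2 in blocks_self:
        for b1 in blocks_self:
            if b1.block_id == b2.block_id or b1.chrom_q != b2.chrom_q:
                continue
            q2 = b2.span_q
            cover = overlap_len(b1.span_q, q2) / max(1, q2[1] - q2[0])
            if cover < min_query_cover:
                continue
            # the original copy: the sub-span of b1's subject aligned from
            # within b2's query region (outer gene bounds of those anchors)
            inner = [
                (genes_q[a.gene_q], genes_s[a.gene_s])
                for a in b1.anchors
                if q2[0] <= genes_q[a.gene_q].start and genes_q[a.gene_q].end <= q2[1]
            ]
            if len(inner) < max(2, int(min_query_cover * b2.n_anchors)):
                continue  # b1 has a gap here: translocation geometry, not a copy
            orig = Region(
                b1.chrom_s,
                min(s.start for (_, s) in inner),
                max(s.end for (_, s) in inner),
                n_genes=len({s.gene_id for (_, s) in inner}),
            )
            copy = Region(
                b2.chrom_s, b2.span_s[0], b2.span_s[1], n_genes=_region_genes(b2, "s")
            )
            if orig.chrom == copy.chrom and overlap_len(
                (orig.start, orig.end), (copy.start, copy.end)
            ):
                continue  # partner regions must be disjoint
            key = min(b1.block_id, b2.block_id), max(b1.block_id, b2.block_id)
            if key in claimed:
                continue
            claimed.add(key)
            first, second = sorted((orig, copy), key=lambda r: (r.chrom, r.start))
            events.append(
                Rearrangement(
                    kind="segmental_duplication",
                    regions=(first, second),
                    scope=_scope((first, second), subgenome_of),
                    evidence=(f"block:{b1.block_id}", f"block:{b2.block_id}"),
                )
            )
    return events


# ---------------------------------------------------------------------------
# Translocations
# ---------------------------------------------------------------------------


def detect_translocations(
    blocks_self: list[CollinearBlock],
    blocks_vs_diploids: dict[str, list[CollinearBlock]] | None,
    diploid_chrom_map: dict[str, str] | None,
    homoeolog_map: dict[str, str] | None = None,
    min_diploid_cover: float = 0.5,
    exclude_blocks: set[int] = frozenset(),
    subgenome_of: dict[str, str] | None = None,
    genes_q: dict | None = None,
) -> list[Rearrangement]:
    """Translocations from breaks in homoeologous collinearity.

    A block between non-homoeologous chromosomes marks a candidate region on
    each side; the carrier is the side whose region is *not* collinear with
    its own diploid relative (checked against ``blocks_vs_diploids``, keyed
    by subgenome, tetraploid chromosomes on the query side). Two reciprocal
    regions between one chromosome pair merge into a reciprocal
    translocation. With no diploid evidence the subject-side region is
    emitted flagged ``diploid-unconfirmed``.
    """
    if homoeolog_map is None:
        homoeolog_map = default_homoeolog_map(
            {b.chrom_q for b in blocks_self}, {b.chrom_s for b in blocks_self}
        )
    candidates = [
        b
        for b in blocks_self
        if b.block_id not in exclude_blocks and homoeolog_map.get(b.chrom_q) != b.chrom_s
    ]
    raw: list[tuple[str, str, Region, tuple[str, ...]]] = []  # carrier, partner, region, evidence
    for b in candidates:
        sides = [
            (b.chrom_q, b.span_q, _region_genes(b, "q"), b.chrom_s),
            (b.chrom_s, b.span_s, _region_genes(b, "s"), b.chrom_q),
        ]
        carrier = None
        flags: list[str] = [f"block:{b.block_id}"]
        if blocks_vs_diploids is not None and diploid_chrom_map is not None:
            failing = []
            for chrom, span, n_genes, partner in sides:
                if _diploid_synteny_cover(
                    chrom, span, blocks_vs_diploids, diploid_chrom_map, genes_q
                ) < min_diploid_cover:
                    failing.append((chrom, span, n_genes, partner))
            if len(failing) == 1:
                carrier = failing[0]
            elif len(failing) == 2:
                # both sides lack diploid support: keep the subject side,
                # flagged, rather than dropping the event
                carrier = sides[1]
                flags.append("diploid-ambiguous")
            else:
                continue  # both sides diploid-confirmed: not a translocation
        else:
            carrier = sides[1]
            flags.append("diploid-unconfirmed")
        chrom, span, n_genes, partner = carrier
        raw.append((chrom, partner, Region(chrom, span[0], span[1], n_genes), tuple(flags)))

    merged = _merge_same_pair(raw)
    return _pair_reciprocals(merged, subgenome_of)


def _diploid_synteny_cover(
    chrom: str,
    span: tuple[int, int],
    blocks_vs_diploids: dict[str, list[CollinearBlock]],
    diploid_chrom_map: dict[str, str],
    genes_q: dict | None,
) -> float:
    """Fraction of ``span`` on ``chrom`` backed by synteny with the expected
    diploid chromosome. Coverage is anchor-backed — the outer bounds of each
    block's anchors *inside* the region — so a block that merely bridges the
    region with a rank gap contributes nothing."""
    expected = diploid_chrom_map.get(chrom)
    if expected is None:
        return 0.0
    _, sub = chrom_index_subgenome(chrom)
    blocks = blocks_vs_diploids.get(sub, [])
    covered = []
    for b in blocks:
        if b.chrom_q != chrom or b.chrom_s != expected:
            continue
        if overlap_len(b.span_q, span) == 0:
            continue
        if genes_q is None:
            covered.append((max(b.span_q[0], span[0]), min(b.span_q[1], span[1])))
            continue
        inside = [
            genes_q[a.gene_q]
            for a in b.anchors
            if span[0] <= genes_q[a.gene_q].start and genes_q[a.gene_q].end <= span[1]
        ]
        if inside:
            covered.append(
                (min(g.start for g in inside), max(g.end for g in inside))
            )
    if not covered:
        return 0.0
    return sum(e - s for s, e in merge_intervals(covered)) / max(1, span[1] - span[0])


def _merge_same_pair(raw):
    """Merge candidate regions on one carrier from one partner chromosome."""
    grouped: dict[tuple[str, str], list] = {}
    for chrom, partner, region, flags in raw:
        grouped.setdefault((chrom, partner), []).append((region, flags))
    out = []
    for (chrom, partner), items in sorted(grouped.items()):
        ivs = merge_intervals([(r.start, r.end) for r, _ in items])
        # keep merged pieces as separate regions only if truly disjoint
        n_genes = sum(r.n_genes for r, _ in items)
        flags = tuple(dict.fromkeys(f for _, fl in items for f in fl))
        start = min(s for s, _ in ivs)
        end = max(e for _, e in ivs)
        out.append((chrom, partner, Region(chrom, start, end, n_genes), flags))
    return out


def _pair_reciprocals(merged, subgenome_of):
    events: list[Rearrangement] = []
    used = [False] * len(merged)
    for i, (c1, p1, r1, f1) in enumerate(merged):
        if used[i]:
            continue
        idx1, sub1 = chrom_index_subgenome(c1)
        origin1, _ = chrom_index_subgenome(p1)
        mate = None
        for j in range(i + 1, len(merged)):
            if used[j]:
                continue
            c2, p2, r2, f2 = merged[j]
            idx2, sub2 = chrom_index_subgenome(c2)
            origin2, _ = chrom_index_subgenome(p2)
            if sub1 == sub2 and idx1 == origin2 and idx2 == origin1:
                mate = j
                break
        if mate is not None:
            c2, p2, r2, f2 = merged[mate]
            used[i] = used[mate] = True
            regions = tuple(sorted((r1, r2), key=lambda r: (r.chrom, r.start)))
            events.append(
                Rearrangement(
                    kind="reciprocal_translocation",
                    regions=regions,
                    scope=_scope(regions, subgenome_of),
                    evidence=tuple(dict.fromkeys(f1 + f2)),
                )
            )
        else:
            used[i] = True
            events.append(
                Rearrangement(
                    kind="translocation",
                    regions=(r1,),
                    scope=_scope((r1,), subgenome_of),
                    evidence=f1,
                )
            )
    return events


# ---------------------------------------------------------------------------
# Read-mapping exchange scan (reciprocal translocations between homoeologs)
# ---------------------------------------------------------------------------


def detect_readmap_exchanges(
    track: pd.DataFrame,
    min_run: int = 2,
) -> list[tuple[int, int]]:
    """Windows where diploid read-mapping rates invert.

    ``track`` has columns ``expected_rate`` and ``alternative_rate`` over
    consecutive windows of one chromosome. A window is exchanged when the
    expected diploid's rate is at most half its chromosome-wide mean while
    the alternative diploid's rate is at least half of its own mean. Runs of
    at least ``min_run`` such windows are returned as (first_window,
    last_window + 1) half-open index intervals.
    """
    exp = track["expected_rate"].to_numpy(dtype=float)
    alt = track["alternative_rate"].to_numpy(dtype=float)
    if len(exp) == 0:
        return []
    flag = (exp <= exp.mean() / 2.0) & (alt >= alt.mean() / 2.0)
    out: list[tuple[int, int]] = []
    start = None
    for i, f in enumerate(list(flag) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                out.append((start, i))
            start = None
    return out


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------


def rearrangement_totals(
    events: list[Rearrangement],
    subgenome_sizes: dict[str, int],
    subgenome_gene_totals: dict[str, int] | None = None,
    subgenome_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-subgenome rearranged bp/gene accounting.

    Overlapping event intervals are merged (union) per chromosome before bp
    sums, so shared bases count once. The returned frame has one row per
    subgenome plus a ``total`` row; percentages are of subgenome size.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    genes_by_sub: dict[str, int] = {}
    intra_bp = 0
    for ev in events:
        for r in ev.regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
            sub = (
                subgenome_of.get(r.chrom)
                if subgenome_of and r.chrom in subgenome_of
                else chrom_index_subgenome(r.chrom)[1]
            )
            genes_by_sub[sub] = genes_by_sub.get(sub, 0) + r.n_genes
        if ev.scope == "intra_subgenome":
            intra_bp += ev.span_bp
    bp_by_sub: dict[str, int] = {}
    for chrom, ivs in by_chrom.items():
        sub = (
            subgenome_of.get(chrom)
            if subgenome_of and chrom in subgenome_of
            else chrom_index_subgenome(chrom)[1]
        )
        bp_by_sub[sub] = bp_by_sub.get(sub, 0) + sum(
            e - s for s, e in merge_intervals(ivs)
        )
    rows = []
    for sub in sorted(set(subgenome_sizes) | set(bp_by_sub)):
        bp = bp_by_sub.get(sub, 0)
        size = subgenome_sizes.get(sub, 0)
        genes = genes_by_sub.get(sub, 0)
        gene_total = (subgenome_gene_totals or {}).get(sub, 0)
        rows.append(
            {
                "subgenome": sub,
                "rearranged_bp": bp,
                "pct_of_subgenome": 100.0 * bp / size if size else float("nan"),
                "rearranged_genes": genes,
                "pct_of_genes": 100.0 * genes / gene_total if gene_total else float("nan"),
            }
        )
    total_bp = sum(r["rearranged_bp"] for r in rows)
    rows.append(
        {
            "subgenome": "total",
            "rearranged_bp": total_bp,
            "pct_of_subgenome": float("nan"),
            "rearranged_genes": sum(r["rearranged_genes"] for r in rows),
            "pct_of_genes": float("nan"),
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["fraction_intra_subgenome"] = (
        intra_bp / sum(ev.span_bp for ev in events) if events else float("nan")
    )
    return df


def events_to_frame(events: list[Rearrangement]) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        for r in ev.regions:
            rows.append(
                {
                    "event_id": i,
                    "kind": ev.kind,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "n_genes": r.n_genes,
                    "span_bp": ev.span_bp,
                    "scope": ev.scope,
                    "major": ev.major,
                    "evidence": ";".join(ev.evidence),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "kind", "chrom", "start", "end", "n_genes",
            "span_bp", "scope", "major", "evidence",
        ],
    )


def events_to_bed(events: list[Rearrangement]) -> pd.DataFrame:
    df = events_to_frame(events)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    bed = df[["chrom", "start", "end"]].copy()
    bed["name"] = df["kind"] + "." + df["event_id"].astype(str)
    return bed
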