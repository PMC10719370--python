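"""Inversion breakpoint location and panel genotyping from read alignments.

The reference assembly carries the inversion, so an accession that *lacks*
it produces discordant read pairs: one mate maps near the left breakpoint,
the other near the right breakpoint, and the recomputed outer span falls in
a narrow gate around (pos_right - pos_left). An accession that carries the
inversion matches the reference, so its pairs are concordant and individual
reads span the breakpoints. The genotyping rule follows that logic:

* ``absent``  — one or more gated discordant pairs join the two breakpoint
  windows (both sites are hit by definition, one mate in each);
* ``present`` — zero discordant pairs and at least one read spanning each
  breakpoint position;
* ``inconclusive`` — zero discordant pairs but a breakpoint without
  spanning reads (coverage too thin to conclude).

Accessions below the genome-wide coverage floor are excluded up front.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from polyrearrange.errors import LowCoverageError, NoSignalError, ValidationError
from polyrearrange.formats_io import AlignedPair, read_sam

#: Genome-wide fold-coverage an accession must reach to be genotyped.
MIN_GENOME_COVERAGE = 5.0


@dataclass(frozen=True)
class BreakpointPair:
    """Two breakpoint positions of one inversion, with counting windows and
    an insert-size gate for breakpoint-joining pairs."""

    chrom: str
    pos_left: int
    pos_right: int
    window_left: tuple[int, int]
    window_right: tuple[int, int]
    insert_min: int
    insert_max: int

    def __post_init__(self) -> None:
        if not self.pos_left < self.pos_right:
            raise ValidationError("pos_left must be < pos_right")
        for pos, win, name in (
            (self.pos_left, self.window_left, "left"),
            (self.pos_right, self.window_right, "right"),
        ):
            if not (win[0] <= pos < win[1]):
                raise ValidationError(f"{name} window does not contain its position")
        span = self.pos_right - self.pos_left
        if not (self.insert_min < span < self.insert_max):
            raise ValidationError(
                f"insert gate [{self.insert_min}, {self.insert_max}] does not "
                f"bracket the breakpoint span {span}"
            )

    @classmethod
    def from_positions(
        cls,
        chrom: str,
        pos_left: int,
        pos_right: int,
        window_halfwidth: int = 500,
        gate_halfwidth: int | None = None,
    ) -> "BreakpointPair":
        """Windows of ±window_halfwidth around each position; insert gate of
        ±gate_halfwidth around the breakpoint span (default: 2000 bp, the
        scale of a short-insert library)."""
        gate = gate_halfwidth if gate_halfwidth is not None else 2000
        span = pos_right - pos_left
        return cls(
            chrom=chrom,
            pos_left=pos_left,
            pos_right=pos_right,
            window_left=(pos_left - window_halfwidth, pos_left + window_halfwidth),
            window_right=(pos_right - window_halfwidth, pos_right + window_halfwidth),
            insert_min=span - gate,
            insert_max=span + gate,
        )


@dataclass(frozen=True)
class InversionCall:
    accession: str
    n_discordant: int
    n_span_left: int
    n_span_right: int
    mean_depth: float
    call: str  # {present, absent, inconclusive}


# ---------------------------------------------------------------------------
# Breakpoint location
# ---------------------------------------------------------------------------


def locate_breakpoints(
    pairs: list[AlignedPair],
    candidate_regions: tuple[tuple[str, int, int], tuple[str, int, int]],
    window_halfwidth: int = 500,
    cluster_bp: int = 1000,
) -> BreakpointPair:
    """Locate the two breakpoints of an inversion inside candidate regions.

    Candidate regions (chrom, start, end) come from synteny breaks or
    genetic-map breaks. Pairs joining the two regions (one mate in each) are
    the signal; because no read can cross a breakpoint end-to-end, their
    alignments abut it — ends pile up just below the breakpoint and starts
    just above it. Within each region the densest 1-kb abutment cluster is
    found and the breakpoint estimated as the midpoint between the largest
    alignment end below and the smallest alignment start above it (one-sided
    if only one kind of evidence exists). The returned insert gate brackets
    the observed joining-pair spans.
    """
    (c1, s1, e1), (c2, s2, e2) = candidate_regions
    if c1 != c2:
        raise ValidationError("inversion breakpoints must share a chromosome")
    if (s1, e1) > (s2, e2):
        (s1, e1), (s2, e2) = (s2, e2), (s1, e1)

    def in_region(pos: int, lo: int, hi: int) -> bool:
        return lo <= pos < hi

    joining: list[AlignedPair] = []
    for p in pairs:
        if p.chrom1 != c1 or p.chrom2 != c1 or p.insert is None:
            continue
        a, b = sorted([(p.pos1, p.end1), (p.pos2, p.end2)])
        if in_region(a[0], s1, e1) and in_region(b[0], s2, e2):
            joining.append(p)
    if not joining:
        raise NoSignalError(
            f"no breakpoint signal: no discordant pairs join "
            f"{c1}:{s1}-{e1} and {c2}:{s2}-{e2}"
        )

    def estimate(mates: list[tuple[int, int]], side: str) -> int:
        # no read can cross the breakpoint end-to-end, so the breakpoint is
        # crossed by zero alignments (the 1-bp coverage interruption) while
        # alignment ends pile up just below it and starts just above it
        ends = sorted(e for _, e in mates)
        starts = sorted(s for s, _ in mates)

        def crossed(x: int) -> bool:
            return any(s < x < e for s, e in mates)

        def abutment(x: int) -> tuple[int, int]:
            en = sum(1 for e in ends if x - cluster_bp < e <= x)
            sn = sum(1 for s in starts if x <= s < x + cluster_bp)
            # balanced evidence first: the breakpoint has ends piling up on
            # one side AND starts on the other, a pile edge has only one
            return (min(en, sn), en + sn)

        candidates = sorted(set(ends) | set(starts))
        open_candidates = [x for x in candidates if not crossed(x)]
        pool = open_candidates or candidates  # degenerate data: best effort
        # remaining ties resolve toward the inversion interior: the left
        # breakpoint is the rightmost open boundary of its cluster, the
        # right breakpoint the leftmost
        sign = 1 if side == "left" else -1
        best_pos = max(pool, key=lambda x: (*abutment(x), sign * x))
        max_end = max((e for e in ends if e <= best_pos), default=None)
        min_start = min((s for s in starts if s >= best_pos), default=None)
        if max_end is not None and min_start is not None and min_start >= max_end:
            return (max_end + min_start) // 2
        return best_pos

    left_mates, right_mates = [], []
    for p in joining:
        a, b = sorted([(p.pos1, p.end1), (p.pos2, p.end2)])
        left_mates.append(a)
        right_mates.append(b)
    pos_left = estimate(left_mates, "left")
    pos_right = estimate(right_mates, "right")

    spans = [p.insert for p in joining]
    span = pos_right - pos_left
    insert_min = min(min(spans), span - 1) - 100
    insert_max = max(max(spans), span + 1) + 100
    return BreakpointPair(
        chrom=c1,
        pos_left=pos_left,
        pos_right=pos_right,
        window_left=(pos_left - window_halfwidth, pos_left + window_halfwidth),
        window_right=(pos_right - window_halfwidth, pos_right + window_halfwidth),
        insert_min=insert_min,
        insert_max=insert_max,
    )


# ---------------------------------------------------------------------------
# Counting and genotyping
# ---------------------------------------------------------------------------


def count_discordant_pairs(pairs: list[AlignedPair], bp: BreakpointPair) -> int:
    """Pairs with one mate starting in each breakpoint window and an insert
    inside the gate. Each pair counts once."""
    n = 0
    for p in pairs:
        if p.chrom1 != bp.chrom or p.chrom2 != bp.chrom or p.insert is None:
            continue
        if not (bp.insert_min <= p.insert <= bp.insert_max):
            continue
        wl, wr = bp.window_left, bp.window_right
        hit = (wl[0] <= p.pos1 < wl[1] and wr[0] <= p.pos2 < wr[1]) or (
            wl[0] <= p.pos2 < wl[1] and wr[0] <= p.pos1 < wr[1]
        )
        if hit:
            n += 1
    return n


def _spanning(pairs: list[AlignedPair], chrom: str, pos: int) -> int:
    """Reads whose alignment covers ``pos`` with at least 1 bp on each side."""
    n = 0
    for p in pairs:
        for c, s, e in ((p.chrom1, p.pos1, p.end1), (p.chrom2, p.pos2, p.end2)):
            if c == chrom and s < pos and e > pos + 1:
                n += 1
    return n


def mean_depth(pairs: list[AlignedPair], genome_size: int) -> float:
    """Fold coverage from summed aligned lengths."""
    total = sum((p.end1 - p.pos1) + (p.end2 - p.pos2) for p in pairs)
    return total / genome_size if genome_size else 0.0


def genotype_inversion(
    pairs: list[AlignedPair],
    bp: BreakpointPair,
    accession: str = "",
    genome_size: int | None = None,
    min_genome_coverage: float = MIN_GENOME_COVERAGE,
) -> InversionCall:
    """Genotype one accession for the inversion (rules in module docstring).

    When ``genome_size`` is given, accessions below ``min_genome_coverage``
    raise LowCoverageError and are to be reported as excluded.
    """
    depth = mean_depth(pairs, genome_size) if genome_size else float("nan")
    if genome_size and depth < min_genome_coverage:
        raise LowCoverageError(
            f"{accession or 'accession'}: coverage {depth:.2f}x below "
            f"{min_genome_coverage}x floor"
        )
    n_disc = count_discordant_pairs(pairs, bp)
    n_left = _spanning(pairs, bp.chrom, bp.pos_left)
    n_right = _spanning(pairs, bp.chrom, bp.pos_right)
    if n_disc >= 1:
        call = "absent"
    elif n_left >= 1 and n_right >= 1:
        call = "present"
    else:
        call = "inconclusive"
    return InversionCall(
        accession=accession,
        n_discordant=n_disc,
        n_span_left=n_left,
        n_span_right=n_right,
        mean_depth=depth,
        call=call,
    )


def genotype_panel(
    sam_paths: dict[str, str | Path],
    bp: BreakpointPair,
    genome_size: int,
    min_mapq: int = 20,
    min_genome_coverage: float = MIN_GENOME_COVERAGE,
) -> tuple[list[InversionCall], dict[str, str]]:
    """Genotype every accession of a panel from its SAM file.

    Returns (calls, excluded) where excluded maps accession -> reason.
    """
    calls: list[InversionCall] = []
    excluded: dict[str, str] = {}
    for acc in sorted(sam_paths):
        pairs = read_sam(sam_paths[acc], min_mapq=min_mapq)
        try:
            calls.append(
                genotype_inversion(
                    pairs, bp, accession=acc, genome_size=genome_size,
                    min_genome_coverage=min_genome_coverage,
                )
            )
        except LowCoverageError as exc:
            excluded[acc] = str(exc)
    return calls, excluded


def genotype_summary(
    calls: list[InversionCall],
    ecotype_labels: dict[str, str],
) -> pd.DataFrame:
    """Ecotype-by-call contingency table with column percentages.

    One row per (ecotype, call) cell; percentages are of the ecotype's total
    accession count. Unlabeled accessions are an error; an empty panel gives
    an empty table.
    """
    if not calls:
        return pd.DataFrame(columns=["ecotype", "call", "n", "pct"])
    rows = []
    for c in calls:
        if c.accession not in ecotype_labels:
            raise ValidationError(f"accession {c.accession!r} has no ecotype label")
        rows.append({"ecotype": ecotype_labels[c.accession], "call": c.call})
    df = pd.DataFrame(rows)
    totals = df.groupby("ecotype").size()
    out = (
        df.groupby(["ecotype", "call"]).size().rename("n").reset_index()
    )
    out["pct"] = out.apply(
        lambda r: 100.0 * r["n"] / totals[r["ecotype"]], axis=1
    )
    return out.sort_values(["ecotype", "call"]).reset_index(drop=True)


def calls_to_frame(calls: list[InversionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": c.accession,
                "call": c.call,
                "n_discordant": c.n_discordant,
                "n_span_left": c.n_span_left,
                "n_span_right": c.n_span_right,
                "mean_depth": round(c.mean_depth, 3)
                if np.isfinite(c.mean_depth)
                else c.mean_depth,
            }
            for c in calls
        ]
    )
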