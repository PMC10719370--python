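"""Genetic-map versus physical-map concordance.

Markers are placed on the assembly by exact search of their flanking
sequence (forward and reverse complement); only markers with a single best
hit are placed, ambiguous or absent flanks stay unplaced with a reason. A
break between the genetic and physical maps — the signature of a
rearrangement between the mapping population and the assembled accession —
is an interval where genetic order runs against physical order.

Break rule: after normalizing the chromosome's global orientation (the sign
of the Spearman correlation between cM and bp), adjacent-marker cM steps
with negative sign mark a reversed segment; runs of at least ``min_run``
negative steps are called, and each internal run boundary is reported as a
break interval — the physical gap between the two markers flanking the
orientation change, which by construction contains the true breakpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from polyrearrange.errors import ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MarkerPlacement:
    marker_id: str
    linkage_group: str
    cm: float
    chrom: str | None  # None = unplaced
    pos: int | None
    hit_quality: float
    reason: str = ""  # why unplaced: {absent, ambiguous, short_flank}

    @property
    def placed(self) -> bool:
        return self.chrom is not None


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def place_markers(
    markers: pd.DataFrame,
    flanks: dict[str, str],
    assembly: dict[str, str],
    min_flank: int = 100,
) -> list[MarkerPlacement]:
    """Place each marker at the single best hit of its flank sequence.

    ``markers`` has columns (marker, linkage_group, cm); ``flanks`` maps
    marker id -> flank sequence (the marker sits at the flank midpoint);
    ``assembly`` maps chromosome -> sequence. Exact matching on both strands;
    zero hits -> unplaced ("absent"); more than one -> unplaced
    ("ambiguous"); flanks below ``min_flank`` bp are skipped ("short_flank").
    """
    if not assembly or all(len(s) == 0 for s in assembly.values()):
        raise ValidationError("empty assembly")
    out: list[MarkerPlacement] = []
    for row in markers.itertuples(index=False):
        mid, lg, cm = row.marker, row.linkage_group, float(row.cm)
        flank = flanks.get(mid, "").upper()
        if len(flank) < min_flank:
            out.append(MarkerPlacement(mid, lg, cm, None, None, 0.0, "short_flank"))
            continue
        hits: list[tuple[str, int]] = []
        rc = _revcomp(flank)
        for chrom, seq in assembly.items():
            hits.extend((chrom, i) for i in _find_all(seq, flank))
            if rc != flank:
                hits.extend((chrom, i) for i in _find_all(seq, rc))
        if not hits:
            out.append(MarkerPlacement(mid, lg, cm, None, None, 0.0, "absent"))
        elif len(hits) > 1:
            out.append(MarkerPlacement(mid, lg, cm, None, None, 0.0, "ambiguous"))
        else:
            chrom, i = hits[0]
            # marker position = flank midpoint (250 for a 500-bp flank)
            out.append(
                MarkerPlacement(mid, lg, cm, chrom, i + len(flank) // 2, 1.0)
            )
    return out


def placements_frame(placements: list[MarkerPlacement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker": p.marker_id,
                "linkage_group": p.linkage_group,
                "cm": p.cm,
                "chrom": p.chrom if p.placed else "unplaced",
                "pos": p.pos if p.placed else -1,
                "hit_quality": p.hit_quality,
                "reason": p.reason,
            }
            for p in placements
        ]
    )


def detect_map_breaks(
    placements: list[MarkerPlacement],
    min_markers: int = 10,
    min_run: int = 2,
) -> pd.DataFrame:
    """Break intervals between genetic and physical marker order.

    Returns a frame (chrom, break_start, break_end, n_markers_reversed); see
    module docstring for the rule. Chromosomes with fewer than
    ``min_markers`` placed markers are skipped with a warning. A perfectly
    monotone map (in either global orientation) yields no breaks.
    """
    rows = []
    placed = [p for p in placements if p.placed]
    by_chrom: dict[str, list[MarkerPlacement]] = {}
    for p in placed:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda p: p.pos)
        if len(ms) < min_markers:
            logger.warning(
                "chromosome %s skipped: %d placed markers < %d",
                chrom, len(ms), min_markers,
            )
            continue
        pos = np.array([p.pos for p in ms], dtype=float)
        cm = np.array([p.cm for p in ms], dtype=float)
        rho = spearmanr(cm, pos).statistic
        if np.isnan(rho):
            continue
        if rho < 0:  # normalize global orientation
            cm = -cm
        d = np.sign(np.diff(cm))
        # runs of negative steps = reversed segments
        i = 0
        while i < len(d):
            if d[i] >= 0:
                i += 1
                continue
            j = i
            while j < len(d) and d[j] < 0:
                j += 1
            if j - i >= min_run:
                # gaps flanking the run: between markers (i-1, i) and (j, j+1)
                if i - 1 >= 0:
                    rows.append(
                        {
                            "chrom": chrom,
                            "break_start": int(pos[i - 1]),
                            "break_end": int(pos[i]),
                            "n_markers_reversed": j - i + 1,
                        }
                    )
                if j + 1 < len(pos):
                    rows.append(
                        {
                            "chrom": chrom,
                            "break_start": int(pos[j]),
                            "break_end": int(pos[j + 1]),
                            "n_markers_reversed": j - i + 1,
                        }
                    )
            i = j
    return pd.DataFrame(
        rows, columns=["chrom", "break_start", "break_end", "n_markers_reversed"]
    )


def concordance_table(placements: list[MarkerPlacement]) -> pd.DataFrame:
    """Plot-ready (marker, chrom, pos, cm) table of placed markers."""
    df = placements_frame(placements)
    return df[df.chrom != "unplaced"][["marker", "chrom", "pos", "cm"]].sort_values(
        ["chrom", "pos"]
    ).reset_index(drop=True)
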