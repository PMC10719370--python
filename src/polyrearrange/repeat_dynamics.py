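"""Subgenome-resolved transposable-element accounting and dynamics.

Copy numbers are counts of annotated elements; base-pair totals merge
overlapping copies of the same family (union) before summing, so nested or
overlapping annotations never double-count sequence (a ``sum-raw`` policy is
available). Partitions (subgenome A, subgenome B, each diploid relative) are
disjoint chromosome sets, so per-family partition totals add up exactly to
whole-genome totals under the same merge policy.

Subgenome enrichment of an LTR family uses the log2 ratio of B to A copy
number: |log2FC| >= 1 (a two-fold change) calls the family enriched on the
higher side; a family absent from one subgenome is subgenome-specific; and a
family is "highly repeated" when its whole-genome copy number exceeds the
mean per-family LTR copy number of the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from polyrearrange._intervals import total_length
from polyrearrange.errors import ValidationError
from polyrearrange.formats_io import LTR_SUPERFAMILIES, RepeatCopy


@dataclass(frozen=True)
class FamilyStats:
    family: str
    superfamily: str
    partition: str  # {subgenome_A, subgenome_B, diploidA, diploidB, whole}
    n_copies: int
    total_bp: int
    n_complete: int


@dataclass(frozen=True)
class EnrichmentCall:
    family: str
    superfamily: str
    log2fc: float  # log2(copies_B / copies_A); NaN for *_specific
    enrichment: str  # {A_enriched, B_enriched, A_specific, B_specific, not_enriched}
    highly_repeated: bool
    copies_A: int
    copies_B: int


def partition_of(copy: RepeatCopy) -> str:
    """Partition label for one repeat copy (by genome and subgenome)."""
    if copy.genome_label in ("diploidA", "diploidB"):
        return copy.genome_label
    if copy.subgenome in ("A", "B"):
        return f"subgenome_{copy.subgenome}"
    raise ValidationError(
        f"repeat copy on {copy.chrom} has no partition "
        f"(genome={copy.genome_label!r}, subgenome={copy.subgenome!r})"
    )


def summarize_repeats(
    copies: list[RepeatCopy],
    merge_policy: str = "merge",
    known_chroms: set[str] | None = None,
) -> list[FamilyStats]:
    """Per-family, per-partition copy and bp totals.

    Emits one FamilyStats per (family, partition) plus a ``whole`` rollup per
    family for the tetraploid (subgenome_A + subgenome_B).
    """
    if merge_policy not in ("merge", "sum-raw"):
        raise ValidationError(f"unknown merge policy {merge_policy!r}")
    grouped: dict[tuple[str, str], list[RepeatCopy]] = {}
    superfamily: dict[str, str] = {}
    for c in copies:
        if known_chroms is not None and c.chrom not in known_chroms:
            raise ValidationError(f"repeat copy on unknown chromosome {c.chrom!r}")
        part = partition_of(c)
        grouped.setdefault((c.family, part), []).append(c)
        superfamily[c.family] = c.superfamily

    def bp_total(items: list[RepeatCopy]) -> int:
        if merge_policy == "sum-raw":
            return sum(c.end - c.start for c in items)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c in items:
            by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
        return sum(total_length(ivs) for ivs in by_chrom.values())

    out: list[FamilyStats] = []
    for (family, part), items in sorted(grouped.items()):
        out.append(
            FamilyStats(
                family=family,
                superfamily=superfamily[family],
                partition=part,
                n_copies=len(items),
                total_bp=bp_total(items),
                n_complete=sum(1 for c in items if c.complete),
            )
        )
    # tetraploid whole-genome rollup (A and B chromosome sets are disjoint,
    # so bp under "merge" adds exactly)
    families = sorted({f for (f, p) in grouped if p.startswith("subgenome_")})
    for family in families:
        subs = [
            s for s in out
            if s.family == family and s.partition.startswith("subgenome_")
        ]
        out.append(
            FamilyStats(
                family=family,
                superfamily=superfamily[family],
                partition="whole",
                n_copies=sum(s.n_copies for s in subs),
                total_bp=sum(s.total_bp for s in subs),
                n_complete=sum(s.n_complete for s in subs),
            )
        )
    return out


def stats_frame(stats: list[FamilyStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


def superfamily_rollup(stats: list[FamilyStats]) -> pd.DataFrame:
    """Per-superfamily copy and bp totals by partition (bp summed over
    families; cross-family overlaps are not re-merged)."""
    df = stats_frame(stats)
    if df.empty:
        return pd.DataFrame(
            columns=["superfamily", "partition", "n_copies", "total_bp", "n_complete"]
        )
    return (
        df.groupby(["superfamily", "partition"], as_index=False)[
            ["n_copies", "total_bp", "n_complete"]
        ].sum()
    )


# ---------------------------------------------------------------------------
# TE space attribution
# ---------------------------------------------------------------------------


def te_space_attribution(
    bp_A: int,
    bp_B: int,
    size_diff_bp: int,
    superfamily_deltas: dict[str, int] | None = None,
) -> tuple[int, float, pd.DataFrame]:
    """How much of the subgenome size difference TE space explains.

    ``te_diff = |bp_B - bp_A|``; ``pct = 100 * te_diff / size_diff_bp``.
    ``superfamily_deltas`` (bp of differential representation per
    superfamily) yields a contribution table as bp and percent of te_diff.
    A zero size difference gives pct = NaN; equal TE totals give zero.
    """
    te_diff = abs(int(bp_B) - int(bp_A))
    if size_diff_bp == 0:
        pct = float("nan")
    elif te_diff == 0:
        pct = 0.0
    else:
        pct = 100.0 * te_diff / size_diff_bp
    rows = []
    for sf, delta in sorted((superfamily_deltas or {}).items()):
        rows.append(
            {
                "superfamily": sf,
                "delta_bp": int(abs(delta)),
                "pct_of_te_diff": 100.0 * abs(delta) / te_diff if te_diff else float("nan"),
            }
        )
    return te_diff, pct, pd.DataFrame(
        rows, columns=["superfamily", "delta_bp", "pct_of_te_diff"]
    )


def subgenome_te_deltas(stats: list[FamilyStats]) -> tuple[int, int, dict[str, int]]:
    """(bp_A, bp_B, per-superfamily signed B-A bp deltas) from family stats."""
    roll = superfamily_rollup(stats)
    a = roll[roll.partition == "subgenome_A"].set_index("superfamily")["total_bp"]
    b = roll[roll.partition == "subgenome_B"].set_index("superfamily")["total_bp"]
    sfs = sorted(set(a.index) | set(b.index))
    deltas = {sf: int(b.get(sf, 0) - a.get(sf, 0)) for sf in sfs}
    return int(a.sum()), int(b.sum()), deltas


# ---------------------------------------------------------------------------
# LTR family enrichment
# ---------------------------------------------------------------------------


def ltr_family_enrichment(
    stats: list[FamilyStats],
    avg_copy_threshold: float | None = None,
    complete_only: bool = True,
) -> list[EnrichmentCall]:
    """Classify LTR families by subgenome copy-number bias.

    Families (optionally restricted to those with a complete full-length
    structure) are called A/B-enriched at |log2FC| >= 1, subgenome-specific
    when one side has zero copies, and highly repeated when whole-genome
    copies exceed ``avg_copy_threshold`` (default: the mean per-family LTR
    copy number of the input). Output is sorted by log2FC within superfamily.
    """
    df = stats_frame(stats)
    if df.empty:
        return []
    ltr = df[df.superfamily.isin(LTR_SUPERFAMILIES)]
    whole = ltr[ltr.partition == "whole"].set_index("family")
    if avg_copy_threshold is None:
        avg_copy_threshold = float(whole["n_copies"].mean()) if len(whole) else 0.0
    a = ltr[ltr.partition == "subgenome_A"].set_index("family")["n_copies"]
    b = ltr[ltr.partition == "subgenome_B"].set_index("family")["n_copies"]
    calls: list[EnrichmentCall] = []
    for family in whole.index:
        if complete_only and whole.loc[family, "n_complete"] == 0:
            continue
        ca, cb = int(a.get(family, 0)), int(b.get(family, 0))
        if ca == 0 and cb == 0:
            continue
        if ca == 0:
            lfc, klass = float("nan"), "B_specific"
        elif cb == 0:
            lfc, klass = float("nan"), "A_specific"
        else:
            lfc = float(np.log2(cb / ca))
            if lfc >= 1:
                klass = "B_enriched"
            elif lfc <= -1:
                klass = "A_enriched"
            else:
                klass = "not_enriched"
        calls.append(
            EnrichmentCall(
                family=family,
                superfamily=str(whole.loc[family, "superfamily"]),
                log2fc=lfc,
                enrichment=klass,
                highly_repeated=bool(
                    whole.loc[family, "n_copies"] > avg_copy_threshold
                ),
                copies_A=ca,
                copies_B=cb,
            )
        )
    calls.sort(
        key=lambda c: (c.superfamily, float("inf") if np.isnan(c.log2fc) else c.log2fc)
    )
    return calls


# ---------------------------------------------------------------------------
# Windowed density tracks
# ---------------------------------------------------------------------------


def window_density(
    features: list,
    chrom_lengths: dict[str, int],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window feature counts (BED-like: chrom, start, end, count).

    A feature belongs to the window containing its start; the last partial
    window is kept; chromosomes without features get all-zero tracks.
    """
    counts: dict[tuple[str, int], int] = {}
    for f in features:
        if f.chrom not in chrom_lengths:
            raise ValidationError(f"feature on unknown chromosome {f.chrom!r}")
        counts[(f.chrom, f.start // window_bp)] = (
            counts.get((f.chrom, f.start // window_bp), 0) + 1
        )
    rows = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n_win = max(1, -(-L // window_bp))
        for w in range(n_win):
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * window_bp,
                    "end": min((w + 1) * window_bp, L),
                    "count": counts.get((chrom, w), 0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dynamics versus the diploid relatives
# ---------------------------------------------------------------------------


def dynamics_vs_diploid(
    stats_subgenome: list[FamilyStats],
    stats_diploid: list[FamilyStats],
    subgenome_partition: str,
    diploid_partition: str,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-superfamily copy/bp change of a subgenome against its diploid.

    delta_copies = subgenome - diploid. The summary reports the fraction of
    the total absolute copy-number change due to reductions, and the net bp
    change. Superfamilies present on only one side are kept and flagged
    ``shared=False``.
    """
    roll_s = superfamily_rollup(stats_subgenome)
    roll_d = superfamily_rollup(stats_diploid)
    s = roll_s[roll_s.partition == subgenome_partition].set_index("superfamily")
    d = roll_d[roll_d.partition == diploid_partition].set_index("superfamily")
    sfs = sorted(set(s.index) | set(d.index))
    rows = []
    for sf in sfs:
        cs = int(s["n_copies"].get(sf, 0))
        cd = int(d["n_copies"].get(sf, 0))
        bs = int(s["total_bp"].get(sf, 0))
        bd = int(d["total_bp"].get(sf, 0))
        delta_c = cs - cd
        rows.append(
            {
                "superfamily": sf,
                "copies_subgenome": cs,
                "copies_diploid": cd,
                "delta_copies": delta_c,
                "delta_bp": bs - bd,
                "label": "expansion" if delta_c > 0 else
                         ("contraction" if delta_c < 0 else "stable"),
                "shared": sf in s.index and sf in d.index,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {"fraction_reduction": float("nan"), "net_bp": 0.0}
    abs_total = df["delta_copies"].abs().sum()
    reductions = -df.loc[df.delta_copies < 0, "delta_copies"].sum()
    summary = {
        "fraction_reduction": float(reductions / abs_total) if abs_total else float("nan"),
        "net_bp": float(df["delta_bp"].sum()),
    }
    return df, summary


def enrichment_frame(calls: list[EnrichmentCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
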