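"""End-to-end wiring of the analysis stages.

Stages exchange only documented in-memory containers (gene records, anchor
lists, blocks, events), so any input can be swapped for real data loaded
through formats_io.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from polyrearrange import collinearity as coll
from polyrearrange import rearrangements as rearr
from polyrearrange.formats_io import AnchorPair, GeneRecord
from polyrearrange.synthetic_data import SyntheticGenome


@dataclass
class SyntenyResult:
    blocks_self: list
    blocks_vs_diploids: dict[str, list]
    events: list
    totals: pd.DataFrame
    summary: pd.DataFrame


def diploid_chrom_map(chroms: list[str]) -> dict[str, str]:
    """Cq{i}A -> Cp{i}, Cq{i}B -> Cs{i} naming convention."""
    out = {}
    for c in chroms:
        idx, sub = rearr.chrom_index_subgenome(c)
        if sub == "A":
            out[c] = f"Cp{idx}"
        elif sub == "B":
            out[c] = f"Cs{idx}"
    return out


def analyze_synteny(
    genes: dict[str, dict[str, GeneRecord]],
    anchors: dict[str, list[AnchorPair]],
    subgenome_sizes: dict[str, int],
    subgenome_gene_totals: dict[str, int] | None = None,
    match_size: int = coll.DEFAULT_MATCH_SIZE,
    max_gap_genes: int = coll.DEFAULT_MAX_GAP_GENES,
    top_n: int = 5,
) -> SyntenyResult:
    """Collinearity -> rearrangement calling -> accounting.

    ``genes`` maps {"tetraploid", "diploidA", "diploidB"} to gene-id ->
    GeneRecord dicts; ``anchors`` holds the three comparisons ("A_vs_B",
    "A_vs_diploidA", "B_vs_diploidB"), tetraploid genes on the query side.
    """
    g_t = genes["tetraploid"]

    def chain(name: str, genes_s: dict[str, GeneRecord]):
        deduped = coll.dedupe_anchors(anchors[name], g_t, genes_s, top_n=top_n)
        return coll.chain_collinear_blocks(
            deduped, g_t, genes_s, match_size=match_size, max_gap_genes=max_gap_genes
        )

    blocks_self = chain("A_vs_B", g_t)
    blocks_dip = {
        "A": chain("A_vs_diploidA", genes["diploidA"]),
        "B": chain("B_vs_diploidB", genes["diploidB"]),
    }

    chroms = sorted({g.chrom for g in g_t.values()})
    dip_map = diploid_chrom_map(chroms)

    dups = rearr.detect_segmental_duplications(blocks_self, g_t, g_t)
    dup_blocks = {
        int(e.split(":")[1]) for ev in dups for e in ev.evidence if e.startswith("block:")
    }
    inversions = rearr.detect_inversions(blocks_self)
    translocs = rearr.detect_translocations(
        blocks_self, blocks_dip, dip_map, exclude_blocks=dup_blocks, genes_q=g_t
    )
    events = translocs + inversions + dups

    totals = rearr.rearrangement_totals(
        events, subgenome_sizes, subgenome_gene_totals
    )

    anchored = {
        "A_vs_B": len({g for g in g_t.values()}),
        "A_vs_diploidA": len([g for g in g_t.values() if g.subgenome == "A"])
        + len(genes["diploidA"]),
        "B_vs_diploidB": len([g for g in g_t.values() if g.subgenome == "B"])
        + len(genes["diploidB"]),
    }

    def comparison_of(block):
        if block.chrom_s.startswith("Cp"):
            return "A_vs_diploidA"
        if block.chrom_s.startswith("Cs"):
            return "B_vs_diploidB"
        return "A_vs_B"

    summary = coll.collinearity_summary(
        blocks_self + blocks_dip["A"] + blocks_dip["B"],
        anchored,
        comparison_of_block=comparison_of,
    )
    return SyntenyResult(blocks_self, blocks_dip, events, totals, summary)


def analyze_synthetic(genome: SyntheticGenome, **kwargs) -> SyntenyResult:
    """Run the synteny pipeline on a simulated genome bundle."""
    cfg = genome.config
    n = cfg.n_chrom_per_subgenome
    sizes = {"A": n * cfg.chrom_length, "B": n * cfg.chrom_length}
    gene_totals = {
        "A": sum(1 for g in genome.genes["tetraploid"] if g.subgenome == "A"),
        "B": sum(1 for g in genome.genes["tetraploid"] if g.subgenome == "B"),
    }
    return analyze_synteny(
        genome.genes_by_id, genome.anchors, sizes, gene_totals, **kwargs
    )
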