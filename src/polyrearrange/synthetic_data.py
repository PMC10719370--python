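"""Synthetic allotetraploid with planted truth.

Generates a toy allotetraploid (two subgenomes of ordered gene arrays, each
descended from a diploid progenitor gene order) plus the two diploid
relatives, with planted rearrangements, subgenome-biased TE families,
genetic-map markers, and simulated paired-end alignments for an accession
panel — together with machine-readable truth for every planted feature.

Realism choices the generator makes (and their limits) are documented in
docs/methods.md: gene density rises toward the telomeres, TE density toward
the centromere, homologous gene pairs are emitted as a BLAST-style anchor
table rather than by aligning sequences, and reads are emitted as placed SAM
records (the mapping step itself is outside this pipeline's scope, which
consumes alignments).

Determinism: one global seed; every component draws from its own derived
substream, so each output file is byte-stable regardless of which other
outputs are produced.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from polyrearrange.errors import ConfigError
from polyrearrange.formats_io import (
    AnchorPair,
    GeneRecord,
    RepeatCopy,
    assign_ranks,
    write_blast_tab,
    write_fasta,
    write_gff3,
    write_sam,
)
from polyrearrange.rearrangements import Rearrangement, Region

# substream identifiers (mixed with the global seed)
_STREAM_COORDS = 1
_STREAM_ANCHORS = 2
_STREAM_TE = 3
_STREAM_READS = 4
_STREAM_SEQ = 5
_STREAM_MARKERS = 6
_STREAM_TRACKS = 7


@dataclass(frozen=True)
class PlantedEvent:
    """Specification of one planted rearrangement (gene-order units)."""

    kind: str  # {inversion, translocation, reciprocal_translocation, segmental_duplication}
    chrom: str
    start_gene: int | None = None
    n_genes: int | None = None
    chrom2: str | None = None
    n_genes2: int | None = None
    insert_chrom: str | None = None
    insert_pos: int | None = None


@dataclass(frozen=True)
class TEFamilySpec:
    """Copy numbers of one TE family in each genome partition."""

    family: str
    superfamily: str
    copies_A: int
    copies_B: int
    copies_diploidA: int
    copies_diploidB: int
    mean_length: int
    complete: bool = True


@dataclass(frozen=True)
class AccessionSpec:
    accession_id: str
    carries_inversion: bool
    depth: float


def _default_events() -> list[PlantedEvent]:
    return [
        PlantedEvent(
            kind="reciprocal_translocation", chrom="Cq1B", chrom2="Cq2B",
            n_genes=30, n_genes2=25,
        ),
        PlantedEvent(kind="inversion", chrom="Cq3B", start_gene=80, n_genes=52),
        PlantedEvent(
            kind="segmental_duplication", chrom="Cq2B", start_gene=50, n_genes=12,
            insert_chrom="Cq2B", insert_pos=100,
        ),
    ]


def _default_te_families() -> list[TEFamilySpec]:
    return [
        TEFamilySpec("RLG_alpha", "Gypsy", 100, 400, 120, 500, 2000),
        TEFamilySpec("RLG_beta", "Gypsy", 240, 80, 250, 90, 1500),
        TEFamilySpec("RLC_gamma", "Copia", 150, 160, 140, 150, 1200),
        TEFamilySpec("RLT_delta", "TRIM_LARD", 0, 60, 0, 70, 600),
        TEFamilySpec("RLG_eps", "Gypsy", 50, 0, 60, 0, 1800),
        TEFamilySpec("SINE_zeta", "SINE", 80, 90, 70, 80, 300, complete=False),
    ]


def _default_panel() -> list[AccessionSpec]:
    return [
        AccessionSpec(f"acc{i:02d}", carries_inversion=(i <= 10), depth=10.0)
        for i in range(1, 21)
    ]


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom_per_subgenome: int = 3
    genes_per_chrom: int = 200
    chrom_length: int = 1_000_000
    planted_events: list[PlantedEvent] = field(default_factory=_default_events)
    te_families: list[TEFamilySpec] = field(default_factory=_default_te_families)
    panel: list[AccessionSpec] = field(default_factory=_default_panel)
    read_length: int = 100
    insert_mean: int = 500
    insert_sd: int = 50
    anchor_noise: int = 0  # spurious random anchors per comparison

    def __post_init__(self) -> None:
        if self.insert_mean <= 2 * self.read_length:
            raise ConfigError("insert_mean must exceed 2 x read_length")
        if any(a.depth <= 0 for a in self.panel):
            raise ConfigError("panel depths must be > 0")
        if self.genes_per_chrom < 2 or self.n_chrom_per_subgenome < 1:
            raise ConfigError("need >=1 chromosome with >=2 genes")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), stream])


@dataclass
class TruthSet:
    """Exact coordinates / labels of everything planted."""

    events: list[Rearrangement]
    genotypes: dict[str, str]  # accession -> {present, absent}
    family_truth: dict[str, str]  # family -> enrichment class
    inversion_breakpoints: tuple[str, int, int] | None  # (chrom, left, right)


@dataclass
class _GeneSpec:
    anc_chrom: int  # ancestral chromosome index (1-based)
    anc_slot: int
    uid: str
    strand: str


def _classify_counts(a: int, b: int) -> str:
    if a == 0 and b == 0:
        return "not_enriched"
    if a == 0:
        return "B_specific"
    if b == 0:
        return "A_specific"
    lfc = np.log2(b / a)
    if lfc >= 1:
        return "B_enriched"
    if lfc <= -1:
        return "A_enriched"
    return "not_enriched"


class SyntheticGenome:
    """In-memory bundle of a simulated allotetraploid study system."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.genes: dict[str, list[GeneRecord]] = {}
        self.genes_by_id: dict[str, dict[str, GeneRecord]] = {}
        self.anchors: dict[str, list[AnchorPair]] = {}
        self.repeats: list[RepeatCopy] = []
        self.chrom_lengths: dict[str, int] = {}
        self.subgenome_of: dict[str, str] = {}
        self.truth: TruthSet | None = None
        self._sequences: dict[str, str] = {}
        self._build()

    # -- gene orders ------------------------------------------------------

    def _build(self) -> None:
        cfg = self.config
        n, G = cfg.n_chrom_per_subgenome, cfg.genes_per_chrom
        orders: dict[str, list[_GeneSpec]] = {}
        for i in range(1, n + 1):
            for sub, prefix in (("A", "qa"), ("B", "qb")):
                chrom = f"Cq{i}{sub}"
                orders[chrom] = [
                    _GeneSpec(i, j, f"{prefix}{i}_{j}", "+") for j in range(G)
                ]
                self.subgenome_of[chrom] = sub
            self.chrom_lengths[f"Cq{i}A"] = cfg.chrom_length
            self.chrom_lengths[f"Cq{i}B"] = cfg.chrom_length
            self.chrom_lengths[f"Cp{i}"] = cfg.chrom_length
            self.chrom_lengths[f"Cs{i}"] = cfg.chrom_length

        affected = self._apply_events(orders)

        # diploid relatives keep the ancestral orders
        dip_orders: dict[str, list[_GeneSpec]] = {}
        for i in range(1, n + 1):
            dip_orders[f"Cp{i}"] = [
                _GeneSpec(i, j, f"cpa{i}_{j}", "+") for j in range(G)
            ]
            dip_orders[f"Cs{i}"] = [
                _GeneSpec(i, j, f"csu{i}_{j}", "+") for j in range(G)
            ]

        rng = self.config.rng(_STREAM_COORDS)
        self.genes["tetraploid"] = self._place_genes(orders, "tetraploid", rng)
        self.genes["diploidA"] = self._place_genes(
            {c: o for c, o in dip_orders.items() if c.startswith("Cp")}, "diploidA", rng
        )
        self.genes["diploidB"] = self._place_genes(
            {c: o for c, o in dip_orders.items() if c.startswith("Cs")}, "diploidB", rng
        )
        for label, recs in self.genes.items():
            self.genes_by_id[label] = {g.gene_id: g for g in recs}

        self._uid_spec = {
            s.uid: s for order in list(orders.values()) + list(dip_orders.values()) for s in order
        }
        self._orders = orders
        self._make_anchors(orders, dip_orders)
        self._make_repeats()
        self._make_truth(affected)

    def _apply_events(self, orders) -> list[tuple[PlantedEvent, dict[str, list[str]]]]:
        """Mutate gene orders in place; return per-event affected uids."""
        out = []
        for ev in self.config.planted_events:
            if ev.chrom not in orders:
                raise ConfigError(f"planted event on unknown chromosome {ev.chrom}")
            affected: dict[str, list[str]] = {}
            if ev.kind == "inversion":
                a, k = ev.start_gene, ev.n_genes
                order = orders[ev.chrom]
                if a is None or k is None or a < 0 or a + k > len(order):
                    raise ConfigError("inversion outside chromosome bounds")
                seg = order[a : a + k][::-1]
                seg = [_GeneSpec(s.anc_chrom, s.anc_slot, s.uid,
                                 "-" if s.strand == "+" else "+") for s in seg]
                order[a : a + k] = seg
                affected[ev.chrom] = [s.uid for s in seg]
            elif ev.kind == "reciprocal_translocation":
                o1, o2 = orders[ev.chrom], orders.get(ev.chrom2, None)
                if o2 is None:
                    raise ConfigError(f"unknown chromosome {ev.chrom2}")
                k1, k2 = ev.n_genes, ev.n_genes2
                if k1 is None or k2 is None or k1 >= len(o1) or k2 >= len(o2):
                    raise ConfigError("translocated tails exceed chromosome bounds")
                tail1, tail2 = o1[-k1:], o2[-k2:]
                o1[-k1:], o2[-k2:] = tail2, tail1
                affected[ev.chrom] = [s.uid for s in tail2]
                affected[ev.chrom2] = [s.uid for s in tail1]
            elif ev.kind == "translocation":
                src = orders[ev.chrom]
                dst = orders.get(ev.insert_chrom, None)
                a, k = ev.start_gene, ev.n_genes
                if dst is None or a is None or k is None or a + k > len(src):
                    raise ConfigError("translocation segment outside bounds")
                seg = src[a : a + k]
                del src[a : a + k]
                pos = min(ev.insert_pos or len(dst), len(dst))
                dst[pos:pos] = seg
                affected[ev.insert_chrom] = [s.uid for s in seg]
            elif ev.kind == "segmental_duplication":
                src = orders[ev.chrom]
                dst = orders.get(ev.insert_chrom, None)
                a, k = ev.start_gene, ev.n_genes
                if dst is None or a is None or k is None or a + k > len(src):
                    raise ConfigError("duplication segment outside bounds")
                seg = src[a : a + k]
                copy = [
                    _GeneSpec(s.anc_chrom, s.anc_slot, s.uid + "d", s.strand)
                    for s in seg
                ]
                pos = min(ev.insert_pos or len(dst), len(dst))
                dst[pos:pos] = copy
                affected["__original__" + ev.chrom] = [s.uid for s in seg]
                affected[ev.insert_chrom] = [s.uid for s in copy]
            else:
                raise ConfigError(f"unknown planted event kind {ev.kind!r}")
            out.append((ev, affected))
        return out

    def _place_genes(self, orders, label: str, rng) -> list[GeneRecord]:
        cfg = self.config
        recs: list[GeneRecord] = []
        for chrom in sorted(orders):
            order = orders[chrom]
            L = self.chrom_lengths[chrom]
            # telomere-biased density: genes are laid down in order, with the
            # intergenic slack distributed by a U-shaped (telomere-heavy) law
            lens = rng.integers(600, 1400, size=len(order))
            occupied = int(lens.sum()) + 50 * len(order)
            slack = L - occupied - 4000
            if slack <= 0:
                raise ConfigError(f"genes overflow chromosome {chrom}")
            u = np.sort(rng.beta(0.5, 0.5, size=len(order))) * slack
            offsets = np.concatenate([[0], np.cumsum(lens[:-1] + 50)])
            starts = (2000 + u + offsets).astype(int)
            for spec, s, ln in zip(order, starts, lens):
                s, e = int(s), int(s) + int(ln)
                sub = self.subgenome_of.get(chrom, "none")
                recs.append(
                    GeneRecord(spec.uid, chrom, s, e, spec.strand, label, sub)
                )
        return assign_ranks(recs)

    # -- anchors ----------------------------------------------------------

    def _make_anchors(self, orders, dip_orders) -> None:
        rng = self.config.rng(_STREAM_ANCHORS)

        def index(orderset, pred):
            idx: dict[tuple[int, int], list[str]] = {}
            for chrom, order in orderset.items():
                if not pred(chrom):
                    continue
                for s in order:
                    idx.setdefault((s.anc_chrom, s.anc_slot), []).append(s.uid)
            return idx

        idx_A = index(orders, lambda c: c.endswith("A"))
        idx_B = index(orders, lambda c: c.endswith("B"))
        idx_cp = index(dip_orders, lambda c: c.startswith("Cp"))
        idx_cs = index(dip_orders, lambda c: c.startswith("Cs"))

        def pair_up(idx_q, idx_s, name, genes_q_label, genes_s_label):
            anchors = []
            for key in sorted(set(idx_q) & set(idx_s)):
                for uq in idx_q[key]:
                    for us in idx_s[key]:
                        anchors.append(
                            AnchorPair(uq, us, float(rng.uniform(900, 1100)), 1e-50)
                        )
            if self.config.anchor_noise:
                all_q = [u for v in idx_q.values() for u in v]
                all_s = [u for v in idx_s.values() for u in v]
                for _ in range(self.config.anchor_noise):
                    anchors.append(
                        AnchorPair(
                            all_q[rng.integers(len(all_q))],
                            all_s[rng.integers(len(all_s))],
                            float(rng.uniform(900, 1100)),
                            1e-20,
                        )
                    )
            self.anchors[name] = anchors

        pair_up(idx_A, idx_B, "A_vs_B", "tetraploid", "tetraploid")
        pair_up(idx_A, idx_cp, "A_vs_diploidA", "tetraploid", "diploidA")
        pair_up(idx_B, idx_cs, "B_vs_diploidB", "tetraploid", "diploidB")

    # -- repeats ----------------------------------------------------------

    def _make_repeats(self) -> None:
        rng = self.config.rng(_STREAM_TE)
        cfg = self.config
        partitions = {
            "A": ("tetraploid", [c for c in self.chrom_lengths if c.startswith("Cq") and c.endswith("A")]),
            "B": ("tetraploid", [c for c in self.chrom_lengths if c.startswith("Cq") and c.endswith("B")]),
            "diploidA": ("diploidA", [c for c in self.chrom_lengths if c.startswith("Cp")]),
            "diploidB": ("diploidB", [c for c in self.chrom_lengths if c.startswith("Cs")]),
        }
        for fam in cfg.te_families:
            counts = {
                "A": fam.copies_A,
                "B": fam.copies_B,
                "diploidA": fam.copies_diploidA,
                "diploidB": fam.copies_diploidB,
            }
            for part, n_copies in counts.items():
                label, chroms = partitions[part]
                for _ in range(n_copies):
                    chrom = chroms[rng.integers(len(chroms))]
                    L = self.chrom_lengths[chrom]
                    ln = max(100, int(rng.normal(fam.mean_length, fam.mean_length / 5)))
                    # centromere-proximal bias
                    pos = int(rng.beta(3, 3) * (L - ln))
                    self.repeats.append(
                        RepeatCopy(
                            family=fam.family,
                            superfamily=fam.superfamily,
                            chrom=chrom,
                            start=pos,
                            end=pos + ln,
                            complete=fam.complete,
                            genome_label=label,
                            subgenome=part if part in ("A", "B") else "none",
                        )
                    )

    # -- truth ------------------------------------------------------------

    def _make_truth(self, affected) -> None:
        by_id = self.genes_by_id["tetraploid"]
        events: list[Rearrangement] = []
        inversion_bp = None
        for ev, aff in affected:
            regions = []
            for chrom_key, uids in sorted(aff.items()):
                chrom = chrom_key.removeprefix("__original__")
                recs = [by_id[u] for u in uids]
                regions.append(
                    Region(chrom, min(r.start for r in recs),
                           max(r.end for r in recs), n_genes=len(recs))
                )
            if ev.kind == "inversion":
                # witness region on the homoeologous chromosome (same slots)
                seg_specs = [self._uid_spec[u] for u in aff[ev.chrom]]
                slots = {(s.anc_chrom, s.anc_slot) for s in seg_specs}
                homoeo = ev.chrom[:-1] + ("A" if ev.chrom.endswith("B") else "B")
                witness = [
                    g for g in self.genes["tetraploid"]
                    if g.chrom == homoeo
                    and (self._uid_spec[g.gene_id].anc_chrom,
                         self._uid_spec[g.gene_id].anc_slot) in slots
                ]
                regions.append(
                    Region(homoeo, min(g.start for g in witness),
                           max(g.end for g in witness), n_genes=len(witness))
                )
                carrier = regions[0]
                inversion_bp = (carrier.chrom, carrier.start, carrier.end)
            regions.sort(key=lambda r: (r.chrom, r.start))
            events.append(Rearrangement(kind=ev.kind, regions=tuple(regions)))
        genotypes = {
            a.accession_id: "present" if a.carries_inversion else "absent"
            for a in self.config.panel
        }
        family_truth = {
            f.family: _classify_counts(f.copies_A, f.copies_B)
            for f in self.config.te_families
        }
        self.truth = TruthSet(events, genotypes, family_truth, inversion_bp)

    # -- sequences --------------------------------------------------------

    def sequence(self, chrom: str) -> str:
        if chrom not in self._sequences:
            L = self.chrom_lengths[chrom]
            # per-chromosome substream: byte-stable regardless of access order
            # (crc32, not hash(): the latter is randomized per process)
            rng = np.random.default_rng(
                [self.config.seed % (2**31), _STREAM_SEQ,
                 zlib.crc32(chrom.encode()) % (2**31)]
            )
            idx = rng.integers(0, 4, size=L)
            self._sequences[chrom] = "".join(
                np.array(["A", "C", "G", "T"])[idx].tolist()
            )
        return self._sequences[chrom]

    # -- output -----------------------------------------------------------

    def write(self, outdir: str | Path, with_fasta: bool = False) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for label, recs in self.genes.items():
            p = outdir / f"{label}.genes.gff3"
            write_gff3(recs, p)
            paths[f"genes_{label}"] = p
        p = outdir / "repeats.gff3"
        write_gff3(self.repeats, p)
        paths["repeats"] = p
        for name, anchors in self.anchors.items():
            p = outdir / f"{name}.blast.tsv"
            write_blast_tab(anchors, p)
            paths[f"anchors_{name}"] = p
        if with_fasta:
            for label, prefix in (
                ("tetraploid", "Cq"), ("diploidA", "Cp"), ("diploidB", "Cs")
            ):
                seqs = {
                    c: self.sequence(c)
                    for c in sorted(self.chrom_lengths)
                    if c.startswith(prefix)
                }
                p = outdir / f"{label}.fasta"
                write_fasta(seqs, p)
                paths[f"fasta_{label}"] = p
        paths["truth"] = self.write_truth(outdir / "truth.json")
        return paths

    def write_truth(self, path: str | Path) -> Path:
        path = Path(path)
        truth = self.truth
        payload = {
            "events": [
                {
                    "kind": ev.kind,
                    "regions": [asdict(r) for r in ev.regions],
                }
                for ev in truth.events
            ],
            "genotypes": truth.genotypes,
            "family_truth": truth.family_truth,
            "inversion_breakpoints": truth.inversion_breakpoints,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def simulate_genomes(config: SimConfig) -> SyntheticGenome:
    """Generate the synthetic allotetraploid bundle (see SyntheticGenome)."""
    return SyntheticGenome(config)


# ---------------------------------------------------------------------------
# Panel read simulation
# ---------------------------------------------------------------------------


def simulate_panel_alignments(
    config: SimConfig,
    breakpoints: tuple[str, int, int],
    outdir: str | Path,
) -> tuple[dict[str, Path], dict[str, str]]:
    """Simulate per-accession paired-end SAM files around a known inversion.

    The reference arrangement carries the inversion between ``breakpoints``
    (chrom, pos_left, pos_right). Carrier accessions match the reference, so
    their pairs are concordant and their reads span both breakpoints.
    Non-carriers are modeled by re-inverting the segment and projecting mate
    coordinates back to the reference: fragments straddling a boundary yield
    discordant pairs with one mate near each breakpoint and an outer span
    close to pos_right - pos_left; reads individually crossing a boundary are
    unmappable end-to-end and are dropped, producing the sharp coverage
    interruption at the breakpoints.

    Returns ({accession: sam_path}, {accession: truth genotype}).
    """
    chrom, L, R = breakpoints
    if chrom not in _panel_chrom_lengths(config):
        raise ConfigError(f"breakpoints on unknown chromosome {chrom}")
    Lc = _panel_chrom_lengths(config)[chrom]
    if not (0 <= L < R <= Lc):
        raise ConfigError("breakpoints outside the reference chromosome")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rl = config.read_length
    paths: dict[str, Path] = {}
    genotypes: dict[str, str] = {}
    for k, acc in enumerate(config.panel):
        rng = np.random.default_rng(
            [config.seed % (2**31), _STREAM_READS, k]
        )
        n_frag = int(round(acc.depth * Lc / (2 * rl)))
        inserts = np.clip(
            rng.normal(config.insert_mean, config.insert_sd, size=n_frag),
            2 * rl + 2, None,
        ).astype(int)
        starts = rng.integers(0, np.maximum(1, Lc - inserts))
        records = []
        for i in range(n_frag):
            f, ins = int(starts[i]), int(inserts[i])
            m1 = (f, f + rl)
            m2 = (f + ins - rl, f + ins)
            if acc.carries_inversion:
                placed = [m1, m2]
            else:
                placed = []
                for (s, e) in (m1, m2):
                    if s < L < e or s < R < e:
                        placed = None  # read crosses a breakpoint: unmappable
                        break
                    if L <= s and e <= R:
                        placed.append((L + R - e, L + R - s))
                    else:
                        placed.append((s, e))
            if placed is None:
                continue
            (s1, e1), (s2, e2) = sorted(placed)
            span = e2 - s1
            proper = abs(span - config.insert_mean) <= 4 * config.insert_sd
            records.append(
                (f"{acc.accession_id}_{i}", chrom, s1, e1 - s1, chrom, s2,
                 e2 - s2, 60, proper)
            )
        records.sort(key=lambda r: (r[2], r[0]))
        path = outdir / f"{acc.accession_id}.sam"
        write_sam(records, path, {chrom: Lc})
        paths[acc.accession_id] = path
        genotypes[acc.accession_id] = "present" if acc.carries_inversion else "absent"
    return paths, genotypes


def _panel_chrom_lengths(config: SimConfig) -> dict[str, int]:
    out = {}
    for i in range(1, config.n_chrom_per_subgenome + 1):
        for sub in "AB":
            out[f"Cq{i}{sub}"] = config.chrom_length
    return out


# ---------------------------------------------------------------------------
# Diploid read-mapping rate tracks
# ---------------------------------------------------------------------------


def simulate_diploid_readmap(
    config: SimConfig,
    swapped_windows: tuple[int, int] | None,
    n_windows: int = 60,
    expected_baseline: float = 0.9,
    alternative_baseline: float = 0.2,
    noise_sd: float = 0.0,
    swap_drop: float | None = None,
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Windowed diploid read-mapping rate tracks for one chromosome.

    Outside an exchanged region the expected diploid relative maps at
    ``expected_baseline`` and the alternative diploid at the cross-subgenome
    background ``alternative_baseline``. Inside ``swapped_windows`` (half-open
    window index interval) the two levels exchange — the expected diploid's
    reads no longer map and the alternative's map fully; ``swap_drop``
    overrides the level the expected track falls to. Gaussian noise with sd
    ``noise_sd`` is added and rates are clipped to [0, 1].
    """
    rng = np.random.default_rng(
        [config.seed % (2**31), _STREAM_TRACKS, seed_offset]
    )
    exp = np.full(n_windows, expected_baseline)
    alt = np.full(n_windows, alternative_baseline)
    if swapped_windows is not None:
        a, b = swapped_windows
        if not (0 <= a < b <= n_windows):
            raise ConfigError("swapped window interval out of range")
        exp[a:b] = alternative_baseline if swap_drop is None else swap_drop
        alt[a:b] = expected_baseline
    if noise_sd:
        exp = exp + rng.normal(0, noise_sd, n_windows)
        alt = alt + rng.normal(0, noise_sd, n_windows)
    return pd.DataFrame(
        {
            "window": np.arange(n_windows),
            "expected_rate": np.clip(exp, 0, 1),
            "alternative_rate": np.clip(alt, 0, 1),
        }
    )


# ---------------------------------------------------------------------------
# Genetic-map markers
# ---------------------------------------------------------------------------


def simulate_marker_map(
    genome: SyntheticGenome,
    chrom: str,
    n_markers: int = 40,
    flank: int = 250,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Markers with genetic positions from a non-carrier cross.

    cM increases with the *ancestral* (non-inverted) coordinate; physical
    positions are projected through the planted inversion carried by the
    reference, so markers inside the inversion appear in reversed genetic
    order along the assembly. Returns (marker table, flank sequences keyed by
    marker id, truth table with true physical positions).
    """
    cfg = genome.config
    L = genome.chrom_lengths[chrom]
    rng = cfg.rng(_STREAM_MARKERS)
    anc = np.sort(
        rng.choice(
            np.arange(flank + 10, L - flank - 10), size=n_markers, replace=False
        )
    )
    inv = None
    if genome.truth and genome.truth.inversion_breakpoints:
        c, a, b = genome.truth.inversion_breakpoints
        if c == chrom:
            inv = (a, b)
    phys = []
    for p in anc:
        if inv and inv[0] <= p < inv[1]:
            phys.append(inv[0] + inv[1] - 1 - int(p))
        else:
            phys.append(int(p))
    cm = 100.0 * anc / L
    markers = pd.DataFrame(
        {
            "marker": [f"mk{i:03d}" for i in range(n_markers)],
            "linkage_group": chrom,
            "cm": np.round(cm, 3),
        }
    )
    seq = genome.sequence(chrom)
    flanks = {
        f"mk{i:03d}": seq[p - flank : p + flank] for i, p in enumerate(phys)
    }
    truth = pd.DataFrame(
        {"marker": markers["marker"], "chrom": chrom, "pos": phys}
    )
    return markers, flanks, truth
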