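"""Genome anchoring: gene models, the intergenic filter, nearest neighbours.

An lncRNA candidate only graduates to lincRNA (long *intergenic* non-coding
RNA) if its genomic footprint stays clear of protein-coding genes.  Because
non-strand-specific libraries cannot distinguish a genuine antisense
transcript from a misassembled fragment of the coding gene itself, overlap
is judged strand-agnostically.  Overlap with the ORF-covered exonic regions
or with introns of a coding gene removes a candidate; UTR-only exon overlap
is flagged but, by default, tolerated.

Internally every interval is 0-based half-open.  GFF3 I/O converts to and
from the format's 1-based inclusive coordinates; BED stays 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A genome-anchored gene structure (0-based half-open intervals)."""

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[Interval, ...]
    cds_span: Interval | None = None
    kind: str = "coding"  # coding | noncoding

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.kind not in ("coding", "noncoding"):
            raise ValueError(f"{self.gene_id}: bad kind {self.kind!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"{self.gene_id}: empty exon {(a, b)}")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)
        if self.cds_span is not None:
            s, e = self.cds_span
            if not (exons[0][0] <= s < e <= exons[-1][1]):
                raise ValueError(f"{self.gene_id}: CDS outside exon span")
            object.__setattr__(self, "cds_span", (int(s), int(e)))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons."""
        return tuple(
            (b1, a2) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def cds_exon_regions(self) -> tuple[Interval, ...]:
        """Exonic intervals clipped to the CDS span (the ORF on the genome)."""
        if self.cds_span is None:
            return ()
        s, e = self.cds_span
        out = []
        for a, b in self.exons:
            lo, hi = max(a, s), min(b, e)
            if lo < hi:
                out.append((lo, hi))
        return tuple(out)

    @property
    def utr_exon_regions(self) -> tuple[Interval, ...]:
        """Exonic intervals outside the CDS span (UTRs)."""
        if self.cds_span is None:
            return self.exons
        s, e = self.cds_span
        out = []
        for a, b in self.exons:
            if a < s:
                out.append((a, min(b, s)))
            if b > e:
                out.append((max(a, e), b))
        return tuple(out)


# ---------------------------------------------------------------------------
# GFF3 / BED I/O
# ---------------------------------------------------------------------------


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            gid = g.gene_id
            cols = [g.scaffold, "spongelinc", "gene", str(g.start + 1),
                    str(g.end), ".", g.strand, "."]
            fh.write("\t".join(cols) + f"\tID={gid};gene_kind={g.kind}\n")
            mid = f"{gid}.t1"
            cols[2] = "mRNA"
            fh.write("\t".join(cols) + f"\tID={mid};Parent={gid}\n")
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tspongelinc\texon\t{a + 1}\t{b}\t.\t"
                    f"{g.strand}\t.\tID={mid}.exon{i};Parent={mid}\n"
                )
            if g.cds_span is not None:
                for i, (a, b) in enumerate(g.cds_exon_regions, 1):
                    fh.write(
                        f"{g.scaffold}\tspongelinc\tCDS\t{a + 1}\t{b}\t.\t"
                        f"{g.strand}\t0\tID={mid}.cds{i};Parent={mid}\n"
                    )


def load_gene_models(
    path: str | Path, scaffold_lengths: dict[str, int] | None = None
) -> list[GeneModel]:
    """Read gene models back from GFF3 (round-trips `write_gff3` losslessly).

    ``scaffold_lengths``, when given, bounds-checks every feature and raises
    naming the offending feature id.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons, cds_lo, cds_hi = [], None, None
        for mrna in db.children(gene, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
            for cds in db.children(mrna, featuretype="CDS"):
                lo, hi = cds.start - 1, cds.end
                cds_lo = lo if cds_lo is None else min(cds_lo, lo)
                cds_hi = hi if cds_hi is None else max(cds_hi, hi)
        kind = gene.attributes.get("gene_kind", ["coding" if cds_lo is not None
                                                 else "noncoding"])[0]
        model = GeneModel(
            gene_id=gene.id, scaffold=gene.seqid, strand=gene.strand,
            exons=tuple(exons),
            cds_span=None if cds_lo is None else (cds_lo, cds_hi),
            kind=kind,
        )
        if scaffold_lengths is not None:
            limit = scaffold_lengths.get(model.scaffold)
            if limit is None or model.end > limit or model.start < 0:
                raise ValueError(
                    f"feature {model.gene_id} out of bounds on "
                    f"{model.scaffold}"
                )
        models.append(model)
    return models


def write_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    """Gene spans as 6-column BED (0-based half-open, as BED requires)."""
    with Path(path).open("w") as fh:
        for g in models:
            fh.write(
                f"{g.scaffold}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def load_bed(path: str | Path, kind: str = "noncoding") -> list[GeneModel]:
    """Read single-exon gene spans from 4+ column BED."""
    models = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        strand = f[5] if len(f) > 5 else "+"
        models.append(GeneModel(
            gene_id=f[3], scaffold=f[0], strand=strand,
            exons=((int(f[1]), int(f[2])),), kind=kind,
        ))
    return models


# ---------------------------------------------------------------------------
# Intergenic filter
# ---------------------------------------------------------------------------


@dataclass
class OverlapEvidence:
    """Why a candidate was removed (or flagged) by the intergenic filter."""

    gene_id: str
    coding_gene_id: str
    region: str  # cds_exon | intron | utr_exon
    overlap_bp: int


def _coding_trees(
    coding: Sequence[GeneModel],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in coding:
        if g.kind != "coding":
            continue
        tree = trees.setdefault(g.scaffold, IntervalTree())
        for a, b in g.cds_exon_regions:
            tree.addi(a, b, (g.gene_id, "cds_exon"))
        for a, b in g.introns:
            tree.addi(a, b, (g.gene_id, "intron"))
        for a, b in g.utr_exon_regions:
            tree.addi(a, b, (g.gene_id, "utr_exon"))
    return trees


def intergenic_filter(
    candidates: Sequence[GeneModel],
    coding: Sequence[GeneModel],
    strict_exon_overlap: bool = False,
) -> tuple[list[GeneModel], list[GeneModel], list[OverlapEvidence]]:
    """Split candidates into lincRNAs and removed models.

    A candidate is removed when any of its exons intersects (>= 1 bp,
    either strand) a coding gene's CDS-covered exonic region or an intron.
    UTR-only overlap is reported as evidence but removes the candidate only
    under ``strict_exon_overlap``.  Returns (lincRNAs, removed, evidence);
    evidence covers removed candidates and UTR-flagged survivors.
    """
    trees = _coding_trees(coding)
    removing = {"cds_exon", "intron"} | ({"utr_exon"} if strict_exon_overlap
                                         else set())
    lincs, removed, evidence = [], [], []
    for cand in candidates:
        tree = trees.get(cand.scaffold)
        hit_regions: list[OverlapEvidence] = []
        if tree is not None:
            for a, b in cand.exons:
                for iv in tree.overlap(a, b):
                    gid, region = iv.data
                    bp = min(b, iv.end) - max(a, iv.begin)
                    hit_regions.append(OverlapEvidence(cand.gene_id, gid,
                                                       region, bp))
        if any(ev.region in removing for ev in hit_regions):
            removed.append(cand)
        else:
            lincs.append(cand)
        evidence.extend(hit_regions)
    return lincs, removed, evidence


# ---------------------------------------------------------------------------
# Nearest coding neighbours
# ---------------------------------------------------------------------------


@dataclass
class NeighborPair:
    """A lincRNA and its nearest coding gene on one side of the genome axis.

    ``rho``/``p_adj`` are filled later by the expression independence
    filter.
    """

    linc_gene_id: str
    neighbor_gene_id: str
    side: str  # upstream | downstream (genome forward axis)
    distance: int
    rho: float | None = None
    p_adj: float | None = None


def nearest_coding_neighbors(
    linc: GeneModel, coding: Sequence[GeneModel]
) -> list[NeighborPair]:
    """Nearest coding gene up- and downstream on the genome forward axis.

    Distance is the gap between the closest interval ends (0 if abutting or
    overlapping).  Ties break toward the lexicographically smaller gene id;
    a side with no coding gene is omitted.
    """
    best: dict[str, tuple[int, str]] = {}
    for g in coding:
        if g.kind != "coding" or g.scaffold != linc.scaffold:
            continue
        if g.end <= linc.start:
            side, gap = "upstream", linc.start - g.end
        elif g.start >= linc.end:
            side, gap = "downstream", g.start - linc.end
        else:  # overlapping span (e.g. UTR-flagged survivor): distance 0
            g_mid = (g.start + g.end) / 2
            l_mid = (linc.start + linc.end) / 2
            side, gap = ("upstream" if g_mid <= l_mid else "downstream"), 0
        cur = best.get(side)
        if cur is None or (gap, g.gene_id) < cur:
            best[side] = (gap, g.gene_id)
    return [
        NeighborPair(linc.gene_id, gid, side, gap)
        for side, (gap, gid) in sorted(best.items(), reverse=True)
    ]


def all_neighbor_pairs(
    lincs: Sequence[GeneModel], coding: Sequence[GeneModel]
) -> list[NeighborPair]:
    """`nearest_coding_neighbors` for every lincRNA, coding set pre-sorted."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in coding:
        if g.kind == "coding":
            by_scaffold.setdefault(g.scaffold, []).append(g)
    pairs = []
    for linc in lincs:
        pairs.extend(
            nearest_coding_neighbors(linc, by_scaffold.get(linc.scaffold, ()))
        )
    return pairs
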