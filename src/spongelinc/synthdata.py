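"""Synthetic genome, transcripts, homology hits and staged count matrices.

The generator emulates the data regime of a lincRNA discovery study in a
sponge-like organism: a multi-scaffold genome carrying coding genes
(planted ORF >= 300 nt sampled from a biased codon-usage prior), intergenic
non-coding loci (>= 600 nt with no long ORF), and three decoy classes that
exercise each arm of the downstream cascade — pseudogene-like transcripts
with planted protein-homology hits, transcripts embedded inside introns of
coding genes, and short non-coding fragments.  Counts are negative-binomial
around stage-structured means over ~8 developmental conditions (first
condition = non-reproductive baseline) with planted stage-specific
upregulation, planted co-expression modules, and planted lincRNA/neighbour
correlated pairs.  Every planted fact is recorded so downstream stages can
be scored against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import TranscriptRecord, find_orfs, revcomp
from .codons import SENSE_CODONS, SENSE_CODON_P, STOP_CODONS
from .exprstats import CountMatrix
from .genomecontext import GeneModel, all_neighbor_pairs, write_gff3

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

DEFAULT_STAGES = (
    "nonreproductive",
    "vitellogenesis",
    "fertilization",
    "early_cleavage",
    "late_cleavage",
    "preinversion",
    "postinversion",
    "larva",
)

TRUE_CLASSES = ("coding", "lincRNA", "pseudogene_decoy", "overlap_decoy",
                "short_decoy")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic dataset.

    Defaults are the reference conditions every planted-truth check runs
    under; the same seed always yields byte-identical output files.
    """

    seed: int = 42
    n_scaffolds: int = 10
    scaffold_len: int = 250_000
    n_coding: int = 200
    n_linc: int = 200
    n_pseudo_decoys: int = 50
    n_overlap_decoys: int = 50
    n_short_decoys: int = 50
    stages: tuple[str, ...] = DEFAULT_STAGES
    reps_per_stage: int = 3
    nb_dispersion: float = 0.1
    planted_fold_change: float = 4.0
    de_fraction: float = 0.3
    n_modules: int = 4
    module_size: int = 40
    n_correlated_pairs: int = 30

    def __post_init__(self):
        counts = (self.n_scaffolds, self.scaffold_len, self.n_coding,
                  self.n_linc, self.n_pseudo_decoys, self.n_overlap_decoys,
                  self.n_short_decoys, self.reps_per_stage, self.n_modules,
                  self.module_size, self.n_correlated_pairs)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages (first = baseline)")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage names")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.planted_fold_change <= 0:
            raise ValueError("planted_fold_change must be positive")
        if self.n_overlap_decoys > self.n_coding:
            raise ValueError(
                "overlap decoys are embedded in coding-gene introns: "
                "n_overlap_decoys must be <= n_coding"
            )
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth, verifiable from the emitted files alone."""

    transcripts: pd.DataFrame  # transcript_id, gene_id, true_class
    de: pd.DataFrame = field(default_factory=pd.DataFrame)
    modules: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    expected_means: pd.DataFrame = field(default_factory=pd.DataFrame)

    def class_of(self, transcript_id: str) -> str:
        row = self.transcripts.loc[
            self.transcripts["transcript_id"] == transcript_id
        ]
        return str(row["true_class"].iloc[0])


@dataclass
class SyntheticDataset:
    config: SimConfig
    genome: dict[str, str]
    models: list[GeneModel]
    transcripts: list[TranscriptRecord]
    hits: pd.DataFrame
    truth: SyntheticTruth

    @property
    def coding_models(self) -> list[GeneModel]:
        ids = set(self.truth.transcripts.loc[
            self.truth.transcripts["true_class"] == "coding", "gene_id"])
        return [m for m in self.models if m.gene_id in ids]

    def models_of_class(self, true_class: str) -> list[GeneModel]:
        ids = set(self.truth.transcripts.loc[
            self.truth.transcripts["true_class"] == true_class, "gene_id"])
        return [m for m in self.models if m.gene_id in ids]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_fasta({t.id: t.sequence for t in self.transcripts},
                    outdir / "transcripts.fa")
        write_gff3(self.models, outdir / "genes.gff3")
        for source, fname in (("blastx_refseq", "hits_blastx.tsv"),
                              ("pfam_hmm", "hits_pfam.tsv"),
                              ("blastp_refseq", "hits_blastp.tsv")):
            write_hits_tsv(self.hits[self.hits["source"] == source],
                           outdir / fname)
        self.truth.transcripts.to_csv(outdir / "truth_transcripts.tsv",
                                      sep="\t", index=False)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80
                ) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


HIT_COLUMNS = ("query", "subject", "pident", "length", "evalue", "bitscore")


def write_hits_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    """BLAST-outfmt-6-like TSV with a '#' header line."""
    with Path(path).open("w") as fh:
        fh.write("#" + "\t".join(HIT_COLUMNS) + "\n")
        for _, row in hits.iterrows():
            fh.write(
                f"{row['query_id']}\t{row['subject_id']}\t"
                f"{row['pident']:.1f}\t{int(row['length'])}\t"
                f"{row['evalue']:.3g}\t{row['bitscore']:.1f}\n"
            )


def read_hits_tsv(path: str | Path, source: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    return pd.DataFrame({
        "query_id": df["query"], "subject_id": df["subject"],
        "evalue": df["evalue"].astype(float), "source": source,
        "pident": df["pident"], "length": df["length"],
        "bitscore": df["bitscore"],
    })


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def _coding_orf(rng: np.random.Generator, n_inner_codons: int) -> str:
    """ATG + inner sense codons from the usage prior + one stop codon."""
    codons = rng.choice(len(SENSE_CODONS), size=n_inner_codons,
                        p=[SENSE_CODON_P[c] for c in SENSE_CODONS])
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in codons) + stop


def _noncoding_seq(rng: np.random.Generator, length: int,
                   max_orf: int = 299, max_tries: int = 200) -> str:
    """Random sequence rejection-sampled to carry no ORF >= 300 nt."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        orfs = find_orfs(seq)
        if not orfs or orfs[0].length_nt <= max_orf:
            return seq
    raise RuntimeError(f"could not draw a {length} nt sequence without a "
                       f"long ORF in {max_tries} tries")


def _split_lengths(rng: np.random.Generator, total: int, n_parts: int,
                   min_part: int = 50) -> list[int]:
    """Split `total` into n_parts pieces, each >= min_part."""
    if n_parts * min_part > total:
        n_parts = max(1, total // min_part)
    if n_parts == 1:
        return [total]
    cuts = np.sort(rng.choice(
        np.arange(min_part, total - min_part + 1), size=n_parts - 1,
        replace=False,
    ))
    # enforce min_part between cuts by falling back to an even split
    bounds = [0, *cuts.tolist(), total]
    lens = [b - a for a, b in zip(bounds, bounds[1:])]
    if min(lens) < min_part:
        base = total // n_parts
        lens = [base] * (n_parts - 1) + [total - base * (n_parts - 1)]
    return lens


@dataclass
class _Locus:
    gene_id: str
    true_class: str
    transcript_seq: str  # on the transcript's own strand
    exon_lens: list[int]
    intron_seqs: list[str]
    strand: str
    cds_transcript: tuple[int, int] | None = None
    embedded: "_Locus | None" = None  # intron-embedded overlap decoy
    embedded_intron_offset: int = 0  # decoy offset within intron 0


def _transcript_to_genome(offset: int, exon_ivs: Sequence[tuple[int, int]],
                          strand: str, tlen: int) -> int:
    """Map a transcript offset to its genomic coordinate."""
    if strand == "-":
        offset = tlen - 1 - offset
    for a, b in exon_ivs:
        if offset < b - a:
            return a + offset
        offset -= b - a
    raise IndexError("offset beyond transcript")


def simulate_genome(config: SimConfig) -> SyntheticDataset:
    """Generate the genome, gene models, transcripts, hit tables and truth.

    Post-conditions: coding transcripts contain an ORF >= 300 nt; planted
    lincRNAs are >= 600 nt, carry no ORF >= 300 nt, receive no hits and
    occupy intergenic loci; pseudogene decoys receive BLASTX hit rows with
    e-value < 10; overlap decoys sit inside introns of coding genes; short
    decoys are < 600 nt.  Raises when the loci cannot be packed onto the
    configured scaffolds.
    """
    rng = np.random.default_rng(config.seed)
    loci: list[_Locus] = []

    # --- coding genes (the first n_overlap_decoys host an embedded decoy)
    for i in range(config.n_coding):
        n_inner = int(rng.integers(98, 399))  # ORF 300..1203 nt incl. stop
        orf = _coding_orf(rng, n_inner)
        utr5 = _random_seq(rng, int(rng.integers(50, 151)))
        utr3 = _random_seq(rng, int(rng.integers(50, 151)))
        tseq = utr5 + orf + utr3
        host = i < config.n_overlap_decoys
        n_exons = 2 if host else int(rng.integers(1, 4))
        exon_lens = _split_lengths(rng, len(tseq), n_exons)
        embedded = None
        offset = 0
        intron_seqs = []
        if host:
            decoy_len = int(rng.integers(600, 1001))
            decoy_seq = _noncoding_seq(rng, decoy_len)
            pad5 = _random_seq(rng, 20)
            pad3 = _random_seq(rng, 20)
            intron_seqs = [pad5 + decoy_seq + pad3]
            offset = len(pad5)
            embedded = _Locus(
                gene_id="", true_class="overlap_decoy",
                transcript_seq=decoy_seq, exon_lens=[decoy_len],
                intron_seqs=[], strand="+",
            )
        else:
            intron_seqs = [_random_seq(rng, int(rng.integers(80, 401)))
                           for _ in range(n_exons - 1)]
        loci.append(_Locus(
            gene_id="", true_class="coding", transcript_seq=tseq,
            exon_lens=exon_lens, intron_seqs=intron_seqs,
            strand="+-"[rng.integers(0, 2)],
            cds_transcript=(len(utr5), len(utr5) + len(orf)),
            embedded=embedded, embedded_intron_offset=offset,
        ))

    # --- intergenic lincRNA loci
    for _ in range(config.n_linc):
        length = int(rng.integers(600, 2001))
        seq = _noncoding_seq(rng, length)
        n_exons = int(rng.integers(1, 3))
        exon_lens = _split_lengths(rng, length, n_exons)
        introns = [_random_seq(rng, int(rng.integers(80, 401)))
                   for _ in range(len(exon_lens) - 1)]
        loci.append(_Locus("", "lincRNA", seq, exon_lens, introns,
                           "+-"[rng.integers(0, 2)]))

    # --- pseudogene-like decoys (intergenic, get homology hits)
    for _ in range(config.n_pseudo_decoys):
        length = int(rng.integers(600, 1501))
        seq = _noncoding_seq(rng, length)
        loci.append(_Locus("", "pseudogene_decoy", seq, [length], [], "+"))

    # --- short decoys
    for _ in range(config.n_short_decoys):
        length = int(rng.integers(200, 600))
        seq = _noncoding_seq(rng, length)
        loci.append(_Locus("", "short_decoy", seq, [length], [], "+"))

    order = rng.permutation(len(loci))
    placed: list[tuple[str, _Locus, list[tuple[int, int]]]] = []
    scaffold_names = [f"scaffold{i + 1:03d}" for i in range(config.n_scaffolds)]
    cursors = {s: 0 for s in scaffold_names}
    sc_idx = 0
    gene_counter = 0
    truth_rows = []
    transcripts: list[TranscriptRecord] = []
    models: list[GeneModel] = []
    fragments: dict[str, list[tuple[int, str]]] = {s: [] for s in
                                                   scaffold_names}

    def _emit(locus: _Locus, scaffold: str, exon_ivs: list[tuple[int, int]]):
        nonlocal gene_counter
        gene_counter += 1
        gid = f"scgene{gene_counter:05d}"
        tid = f"{gid}.t1"
        locus.gene_id = gid
        tlen = len(locus.transcript_seq)
        cds_span = None
        if locus.cds_transcript is not None:
            a, b = locus.cds_transcript
            g1 = _transcript_to_genome(a, exon_ivs, locus.strand, tlen)
            g2 = _transcript_to_genome(b - 1, exon_ivs, locus.strand, tlen)
            cds_span = (min(g1, g2), max(g1, g2) + 1)
        models.append(GeneModel(
            gene_id=gid, scaffold=scaffold, strand=locus.strand,
            exons=tuple(exon_ivs), cds_span=cds_span,
            kind="coding" if locus.true_class == "coding" else "noncoding",
        ))
        transcripts.append(TranscriptRecord(tid, gid, locus.transcript_seq))
        truth_rows.append({"transcript_id": tid, "gene_id": gid,
                           "true_class": locus.true_class})

    for idx in order:
        locus = loci[idx]
        span = sum(locus.exon_lens) + sum(len(s) for s in locus.intron_seqs)
        gap = int(rng.integers(300, 1501))
        tried = 0
        while cursors[scaffold_names[sc_idx]] + gap + span > \
                config.scaffold_len:
            sc_idx = (sc_idx + 1) % config.n_scaffolds
            tried += 1
            if tried > config.n_scaffolds:
                raise ValueError(
                    "infeasible packing: loci do not fit the configured "
                    f"scaffolds (need {span + gap} more nt; increase "
                    "scaffold_len or n_scaffolds)"
                )
        scaffold = scaffold_names[sc_idx]
        pos = cursors[scaffold] + gap
        # genomic exon sequences: transcript runs 5'->3' on its own strand
        genome_seq = locus.transcript_seq if locus.strand == "+" \
            else revcomp(locus.transcript_seq)
        exon_ivs = []
        t_off = 0
        g = pos
        for k, elen in enumerate(locus.exon_lens):
            fragments[scaffold].append((g, genome_seq[t_off: t_off + elen]))
            exon_ivs.append((g, g + elen))
            g += elen
            t_off += elen
            if k < len(locus.intron_seqs):
                fragments[scaffold].append((g, locus.intron_seqs[k]))
                g += len(locus.intron_seqs[k])
        cursors[scaffold] = g
        _emit(locus, scaffold, exon_ivs)
        if locus.embedded is not None:
            intron_start = exon_ivs[0][1]
            d0 = intron_start + locus.embedded_intron_offset
            dlen = len(locus.embedded.transcript_seq)
            _emit(locus.embedded, scaffold, [(d0, d0 + dlen)])
        sc_idx = (sc_idx + 1) % config.n_scaffolds

    # compose scaffold sequences: random background, then planted fragments
    genome: dict[str, str] = {}
    for s in scaffold_names:
        arr = BASES[rng.integers(0, 4, config.scaffold_len)]
        for start, frag in fragments[s]:
            arr[start: start + len(frag)] = list(frag)
        genome[s] = "".join(arr)

    truth = SyntheticTruth(transcripts=pd.DataFrame(
        truth_rows, columns=["transcript_id", "gene_id", "true_class"]))
    hits = _planted_hits(rng, truth)
    return SyntheticDataset(config=config, genome=genome, models=models,
                            transcripts=transcripts, hits=hits, truth=truth)


def _planted_hits(rng: np.random.Generator, truth: SyntheticTruth
                  ) -> pd.DataFrame:
    """Hit rows: strong hits for coding, sub-10 BLASTX hits for pseudogene
    decoys (half also get a Pfam hit below 0.01); lincRNAs get none."""
    rows = []

    def add(tid, source, evalue):
        rows.append({
            "query_id": tid, "subject_id": f"ref|{rng.integers(10**6):06d}|",
            "pident": float(rng.uniform(35, 95)),
            "length": int(rng.integers(30, 300)),
            "evalue": float(evalue),
            "bitscore": float(rng.uniform(40, 400)),
            "source": source,
        })

    for _, row in truth.transcripts.iterrows():
        tid, cls = row["transcript_id"], row["true_class"]
        if cls == "coding":
            add(tid, "blastx_refseq", 10.0 ** rng.uniform(-80, -10))
        elif cls == "pseudogene_decoy":
            for _ in range(int(rng.integers(1, 4))):
                add(tid, "blastx_refseq", 10.0 ** rng.uniform(-30, 0.9))
            if rng.random() < 0.5:
                add(tid, "pfam_hmm", 10.0 ** rng.uniform(-12, -2.1))
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "pident",
                                       "length", "evalue", "bitscore",
                                       "source"])


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def simulate_counts(dataset: SyntheticDataset,
                    config: SimConfig | None = None) -> CountMatrix:
    """Stage-structured negative-binomial counts with planted signals.

    Gene base means are gamma-distributed; planted-DE genes carry the
    configured fold change in a contiguous run of developmental stages;
    module members share a smooth stage profile peaking at the module's
    characteristic stage; correlated lincRNA/neighbour pairs share a
    log-normal stage profile.  Library depths vary ~30% so size-factor
    estimation is exercised.  nb_dispersion = 0 degrades to Poisson noise.
    Updates ``dataset.truth`` (de, modules, pairs, expected_means) in
    place.
    """
    config = config or dataset.config
    rng = np.random.default_rng(config.seed + 1_000_003)
    truth = dataset.truth
    genes = list(truth.transcripts["gene_id"])
    classes = dict(zip(truth.transcripts["gene_id"],
                       truth.transcripts["true_class"]))
    stages = list(config.stages)
    dev_stages = stages[1:]
    n_g, n_s = len(genes), len(stages)
    fc = config.planted_fold_change

    base = rng.gamma(2.0, 150.0, size=n_g) + 1.0
    mult = np.ones((n_g, n_s))
    gene_index = {g: i for i, g in enumerate(genes)}

    coding_genes = [g for g in genes if classes[g] == "coding"]
    linc_genes = [g for g in genes if classes[g] == "lincRNA"]

    # (1) plain stage-specific upregulation
    if fc != 1.0 and dev_stages:
        for pool in (coding_genes, linc_genes):
            n_de = int(round(config.de_fraction * len(pool)))
            for g in rng.choice(pool, size=n_de, replace=False) if n_de \
                    else []:
                width = int(rng.integers(1, min(3, len(dev_stages)) + 1))
                start = int(rng.integers(0, len(dev_stages) - width + 1))
                mult[gene_index[g], 1 + start: 1 + start + width] = fc

    # (2) correlated lincRNA/neighbour pairs share a log-normal profile
    pair_rows = []
    pair_lincs: set[str] = set()
    if config.n_correlated_pairs and linc_genes:
        linc_models = dataset.models_of_class("lincRNA")
        neighbor_of = {}
        for p in all_neighbor_pairs(linc_models, dataset.coding_models):
            neighbor_of.setdefault(p.linc_gene_id, p.neighbor_gene_id)
        eligible = [g for g in linc_genes if g in neighbor_of]
        chosen = []
        used_neighbors: set[str] = set()
        for g in rng.permutation(eligible):
            if neighbor_of[g] in used_neighbors:
                continue  # one planted profile per neighbour gene
            chosen.append(g)
            used_neighbors.add(neighbor_of[g])
            if len(chosen) == config.n_correlated_pairs:
                break
        for g in chosen:
            profile = np.exp(rng.normal(0.0, 0.8, size=n_s))
            mult[gene_index[g]] = profile
            mult[gene_index[neighbor_of[g]]] = profile
            pair_lincs.add(g)
            pair_rows.append({"linc_gene_id": g,
                              "neighbor_gene_id": neighbor_of[g]})

    # (3) co-expression modules among DE coding genes and free lincRNAs
    module_labels = pd.Series("noise", index=genes, dtype=object)
    if config.n_modules and fc != 1.0 and dev_stages:
        pair_members = pair_lincs | {r["neighbor_gene_id"]
                                     for r in pair_rows}
        de_coding = [g for g in coding_genes
                     if g not in pair_members
                     and (mult[gene_index[g]] >= fc - 1e-9).any()]
        free_lincs = [g for g in linc_genes if g not in pair_members]
        eligible = de_coding + free_lincs
        need = config.n_modules * config.module_size
        if need > len(eligible):
            raise ValueError(
                f"cannot plant {config.n_modules} modules of "
                f"{config.module_size}: only {len(eligible)} eligible genes"
            )
        members = rng.choice(eligible, size=need, replace=False)
        centers = np.linspace(1, n_s - 1, config.n_modules)
        for m in range(config.n_modules):
            profile = 1.0 + (fc - 1.0) * np.exp(
                -((np.arange(n_s) - centers[m]) / 1.2) ** 2)
            profile[0] = 1.0  # baseline stays at baseline
            for g in members[m * config.module_size:
                             (m + 1) * config.module_size]:
                mult[gene_index[g]] = profile
                module_labels[g] = f"planted{m + 1}"

    # expected means and sampled counts
    libraries, lib_stage = [], []
    for s in stages:
        for r in range(1, config.reps_per_stage + 1):
            libraries.append(f"{s}_r{r}")
            lib_stage.append(s)
    depth = rng.uniform(0.7, 1.3, size=len(libraries))
    stage_idx = np.array([stages.index(s) for s in lib_stage])
    mu = base[:, None] * mult[:, stage_idx] * depth[None, :]

    if config.nb_dispersion > 1e-12:
        r_nb = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=genes, columns=libraries)
    design = pd.DataFrame(
        {"stage": lib_stage,
         "replicate": [int(l.rsplit("_r", 1)[1]) for l in libraries]},
        index=pd.Index(libraries, name="library"),
    )
    de_rows = []
    for s_i, s in enumerate(stages):
        if s_i == 0:
            continue
        planted = mult[:, s_i] >= (fc - 1e-9) if fc != 1.0 \
            else np.zeros(n_g, bool)
        for g_i, g in enumerate(genes):
            de_rows.append({"gene_id": g, "stage": s,
                            "planted_up": bool(planted[g_i])})
    truth.de = pd.DataFrame(de_rows)
    truth.modules = module_labels
    truth.pairs = pd.DataFrame(pair_rows,
                               columns=["linc_gene_id", "neighbor_gene_id"])
    truth.expected_means = pd.DataFrame(mu, index=genes, columns=libraries)
    return CountMatrix(counts=counts_df, design=design)


def write_truth_tables(truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.de.to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    truth.modules.rename("module").to_csv(
        outdir / "truth_modules.tsv", sep="\t", index_label="gene_id")
    truth.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
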