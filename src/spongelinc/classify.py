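"""Tiered evidence cascade separating coding transcripts from lncRNA candidates.

The cascade mirrors the standard lincRNA discovery recipe for a de novo
transcriptome: (1) transcripts with a long ORF are set aside as coding;
(2) short transcripts are dropped; (3-5) transcripts with protein homology
evidence (BLASTX vs a protein database, Pfam domain hits on six-frame
translations, BLASTP of translations) are dropped; (6) the survivors are
scored for coding potential and high scorers are dropped.  What remains is
the lncRNA candidate set handed to the genomic-context filter.

Homology searches are consumed as tabular hit files, never executed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .codons import codon_log_odds

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_STOPS = frozenset({"TAA", "TAG", "TGA"})

HIT_SOURCES = ("blastx_refseq", "pfam_hmm", "blastp_refseq")

#: Cascade discard reasons in the order the rules fire.
DISCARD_REASONS = (
    "long_orf",  # rule 1 labels the transcript coding, not discarded
    "too_short",
    "blastx_hit",
    "pfam_hit",
    "blastp_hit",
    "coding_potential",
)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with its gene identity."""

    id: str
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfCall:
    """An ATG-initiated, in-frame-stop-terminated span on one of six frames.

    Coordinates are 0-based offsets on the frame's own strand (frames 4-6
    index into the reverse complement).  ``length_nt`` includes the stop
    codon, so the minimal ORF (ATG + stop) has length 6.
    """

    start: int
    end: int  # exclusive
    frame: int  # 1..3 forward, 4..6 reverse
    length_nt: int

    def __post_init__(self):
        assert self.length_nt == self.end - self.start
        assert self.length_nt % 3 == 0 and self.length_nt >= 6


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
    return seq


def revcomp(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def find_orfs(sequence: str, allow_no_stop: bool = False) -> list[OrfCall]:
    """Every ATG paired with its first in-frame stop, on all six frames.

    Nested ORFs sharing a stop are all reported (one per ATG).  With
    ``allow_no_stop`` an ATG with no downstream in-frame stop yields an ORF
    running to the last complete codon (length then counts no stop codon).
    Codons containing N are treated as neither start nor stop.

    Returns calls sorted by decreasing length, ties broken by (frame, start).
    """
    seq = _check_sequence(sequence)
    strands = (seq, revcomp(seq))
    calls: list[OrfCall] = []
    for frame in range(1, 7):
        s = strands[0] if frame <= 3 else strands[1]
        off = (frame - 1) % 3
        n_codons = (len(s) - off) // 3
        starts, stops = [], []
        for k in range(n_codons):
            codon = s[off + 3 * k: off + 3 * k + 3]
            if codon == "ATG":
                starts.append(k)
            elif codon in _STOPS:
                stops.append(k)
        stop_arr = np.asarray(stops, dtype=int)
        for k in starts:
            j = int(np.searchsorted(stop_arr, k))
            if j < len(stop_arr):
                end_codon = stop_arr[j] + 1  # include the stop codon
            elif allow_no_stop:
                end_codon = n_codons
                if end_codon - k < 2:
                    continue
            else:
                continue
            start_nt = off + 3 * k
            end_nt = off + 3 * end_codon
            calls.append(OrfCall(start_nt, end_nt, frame, end_nt - start_nt))
    calls.sort(key=lambda o: (-o.length_nt, o.frame, o.start))
    return calls


def translate_six_frames(sequence: str) -> list[str]:
    """Translate in frames +1, +2, +3, -1, -2, -3 (standard code, stops '*').

    Trailing partial codons are dropped; codons containing N translate to X.
    """
    seq = _check_sequence(sequence)
    rc = revcomp(seq)
    peptides = []
    for s in (seq, rc):
        for off in range(3):
            sub = s[off: off + 3 * ((len(s) - off) // 3)]
            peptides.append(str(Seq(sub).translate()))
    return peptides


# ---------------------------------------------------------------------------
# Coding-potential score
# ---------------------------------------------------------------------------

# Fickett-style TESTCODE lookup tables: positional asymmetry and base
# content mapped to empirical coding probabilities, combined with fixed
# weights.  Position parameter thresholds run 1.9 .. 1.1 then 0.
_POS_THRESH = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONT_THRESH = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)
_POS_PROB = {
    "A": (0.22, 0.20, 0.34, 0.45, 0.68, 0.58, 0.93, 0.84, 0.68, 0.94),
    "C": (0.23, 0.30, 0.33, 0.51, 0.48, 0.66, 0.81, 0.70, 0.70, 0.80),
    "G": (0.08, 0.08, 0.16, 0.27, 0.48, 0.53, 0.64, 0.74, 0.88, 0.90),
    "T": (0.09, 0.09, 0.20, 0.54, 0.44, 0.69, 0.68, 0.91, 0.97, 0.97),
}
_CONT_PROB = {
    "A": (0.21, 0.81, 0.65, 0.67, 0.49, 0.62, 0.55, 0.44, 0.49, 0.28),
    "C": (0.31, 0.39, 0.44, 0.43, 0.59, 0.59, 0.64, 0.51, 0.64, 0.82),
    "G": (0.29, 0.33, 0.41, 0.41, 0.73, 0.64, 0.64, 0.47, 0.54, 0.40),
    "T": (0.58, 0.51, 0.69, 0.56, 0.75, 0.55, 0.40, 0.39, 0.24, 0.28),
}
_POS_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}

# Linear combination turning the three components into one score whose
# decision point sits at 1: long-ORF coverage dominates, codon-pair bias and
# positional asymmetry refine borderline cases.
_W_ORF_COV = 2.0
_W_HEXAMER = 0.35
_W_FICKETT = 0.30
_FICKETT_CENTER = 0.95


def fickett_testcode(sequence: str) -> float:
    """Fickett-style TESTCODE statistic (positional asymmetry + composition)."""
    seq = _check_sequence(sequence)
    score = 0.0
    n = len(seq)
    for base in "ACGT":
        counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                counts[i % 3] += 1
        pos = max(counts) / (min(counts) + 1.0)
        content = seq.count(base) / n
        for p_val, thr in zip(_POS_PROB[base], _POS_THRESH):
            if pos >= thr:
                score += p_val * _POS_WEIGHT[base]
                break
        for c_val, thr in zip(_CONT_PROB[base], _CONT_THRESH):
            if content >= thr:
                score += c_val * _CONT_WEIGHT[base]
                break
    return score


@dataclass(frozen=True)
class CodingPotential:
    """Coding-potential score with its individually reported components."""

    score: float
    orf_coverage: float
    fickett: float
    hexamer: float


def _hexamer_log_odds(orf_seq: str, base_freq: dict[str, float]) -> float:
    """Mean log2 odds of in-frame codon pairs vs a composition background."""
    table = codon_log_odds(base_freq)
    vals = []
    for i in range(0, len(orf_seq) - 5, 3):
        c1, c2 = orf_seq[i: i + 3], orf_seq[i + 3: i + 6]
        if c1 in table and c2 in table:
            vals.append(table[c1] + table[c2])
    return float(np.mean(vals)) if vals else 0.0


def coding_potential_score(
    sequence: str, orfs: Sequence[OrfCall] | None = None
) -> CodingPotential:
    """Deterministic coding-potential score; larger means more coding-like.

    Components: coverage of the transcript by its longest ORF, a
    Fickett-style TESTCODE statistic, and the mean in-frame hexamer
    (codon-pair) log-odds of the longest ORF against a background derived
    from the transcript's own base composition.  The weighted combination is
    calibrated so that the decision threshold sits at 1.
    """
    seq = _check_sequence(sequence)
    if len(seq) < 6:
        raise ValueError("sequence shorter than 6 nt")
    if orfs is None:
        orfs = find_orfs(seq)
    fick = fickett_testcode(seq)
    if not orfs:
        cov, hexamer = 0.0, 0.0
    else:
        longest = orfs[0]
        cov = longest.length_nt / len(seq)
        strand_seq = seq if longest.frame <= 3 else revcomp(seq)
        orf_seq = strand_seq[longest.start: longest.end]
        n = len(seq)
        base_freq = {b: max(seq.count(b), 1) / n for b in "ACGT"}
        hexamer = _hexamer_log_odds(orf_seq, base_freq)
    score = (
        _W_ORF_COV * cov
        + _W_HEXAMER * hexamer
        + _W_FICKETT * (fick - _FICKETT_CENTER)
    )
    return CodingPotential(score=float(score), orf_coverage=float(cov),
                           fickett=float(fick), hexamer=float(hexamer))


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def _hits_by_query(
    hits: pd.DataFrame | None, known_ids: set[str]
) -> dict[str, list[tuple[str, float]]]:
    """Index hit rows by query id, dropping hits to unknown transcripts."""
    out: dict[str, list[tuple[str, float]]] = {}
    if hits is None or len(hits) == 0:
        return out
    required = {"query_id", "source", "evalue"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    unknown = 0
    for query, source, evalue in zip(
        hits["query_id"], hits["source"], hits["evalue"]
    ):
        if source not in HIT_SOURCES:
            raise ValueError(f"unknown hit source {source!r}")
        if float(evalue) < 0:
            raise ValueError(f"negative e-value for query {query!r}")
        if query not in known_ids:
            unknown += 1
            continue
        out.setdefault(query, []).append((source, float(evalue)))
    if unknown:
        log.warning("ignored %d hits referencing unknown transcript ids", unknown)
    return out


def classify_transcripts(
    transcripts: Iterable[TranscriptRecord],
    hits: pd.DataFrame | None = None,
    cp_threshold: float = 1.0,
    min_orf: int = 300,
    min_nc_len: int = 600,
    evalue_blastx: float = 10.0,
    evalue_pfam: float = 0.01,
    evalue_blastp: float = 10.0,
    cp_scores: Mapping[str, float] | None = None,
    allow_no_stop: bool = False,
) -> pd.DataFrame:
    """Run the six-rule cascade; first firing rule decides and is recorded.

    Rules, in order: (1) longest ORF >= min_orf nt -> coding; (2) shorter
    than min_nc_len -> discarded too_short; (3) any BLASTX hit with e-value
    < evalue_blastx -> discarded; (4) any Pfam hit < evalue_pfam ->
    discarded; (5) any BLASTP hit < evalue_blastp -> discarded; (6) coding
    potential > cp_threshold -> discarded; otherwise lncRNA_candidate.

    ``cp_scores`` optionally supplies externally computed per-transcript
    coding-potential scores keyed by transcript id, overriding the built-in
    score.  Returns one row per transcript with the decision, the reason,
    the longest ORF length and the coding-potential score (NaN where the
    cascade never reached rule 6).
    """
    if min_orf <= 0 or min_nc_len <= 0:
        raise ValueError("thresholds must be positive")
    records = list(transcripts)
    hit_index = _hits_by_query(hits, {t.id for t in records})
    gate = {
        "blastx_refseq": ("blastx_hit", evalue_blastx),
        "pfam_hmm": ("pfam_hit", evalue_pfam),
        "blastp_refseq": ("blastp_hit", evalue_blastp),
    }
    rows = []
    for t in records:
        orfs = find_orfs(t.sequence, allow_no_stop=allow_no_stop)
        longest = orfs[0].length_nt if orfs else 0
        label, reason, cp = None, "", math.nan
        if longest >= min_orf:
            label = "coding"
        elif t.length < min_nc_len:
            label, reason = "discarded", "too_short"
        else:
            for source in HIT_SOURCES:
                reason_name, cut = gate[source]
                if any(
                    s == source and e < cut for s, e in hit_index.get(t.id, ())
                ):
                    label, reason = "discarded", reason_name
                    break
            if label is None:
                if cp_scores is not None and t.id in cp_scores:
                    cp = float(cp_scores[t.id])
                else:
                    cp = coding_potential_score(t.sequence, orfs).score
                if cp > cp_threshold:
                    label, reason = "discarded", "coding_potential"
                else:
                    label = "lncRNA_candidate"
        rows.append(
            {
                "transcript_id": t.id,
                "gene_id": t.gene_id,
                "label": label,
                "discard_reason": reason,
                "longest_orf_nt": longest,
                "cp_score": cp,
            }
        )
    return pd.DataFrame(rows)
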