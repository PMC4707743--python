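"""Codon-level constants shared by the coding-potential score and the simulator.

The codon-usage prior is a generic eukaryotic usage table (frequencies per
1000 codons). It serves two roles: the synthetic-data generator samples
coding ORF codons from it, and the coding-potential score uses the implied
hexamer (codon-pair) log-odds against a composition-derived background.
Real-data users with a trained hexamer model can bypass the built-in score
via an external score table (see `classify.classify_transcripts`).
"""

from __future__ import annotations

import numpy as np

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

# Generic eukaryotic codon usage, frequency per 1000 codons.
CODON_USAGE = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "TAA": 1.0, "TAG": 0.8,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGA": 1.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}

SENSE_CODONS = tuple(c for c in CODON_USAGE if c not in STOP_CODONS)

# Normalised sense-codon probabilities (stop codons excluded: they terminate
# an ORF rather than occur inside it).
_sense_w = np.array([CODON_USAGE[c] for c in SENSE_CODONS], dtype=float)
SENSE_CODON_P = dict(zip(SENSE_CODONS, _sense_w / _sense_w.sum()))


def codon_log_odds(background: dict[str, float] | None = None) -> dict[str, float]:
    """Per-codon log2 odds of the usage prior vs a background.

    background maps base -> probability; default is uniform (0.25 each).
    Stop codons are assigned the background probability itself (log-odds 0)
    so they never dominate a score.
    """
    if background is None:
        background = {b: 0.25 for b in "ACGT"}
    out = {}
    for codon in SENSE_CODONS:
        p_bg = 1.0
        for b in codon:
            p_bg *= background[b]
        out[codon] = float(np.log2(SENSE_CODON_P[codon] / p_bg))
    for codon in STOP_CODONS:
        out[codon] = 0.0
    return out
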