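"""Pause-motif register mapping and U-tract logo statistics.

NusG elicits a sequence-specific pause when RNA polymerase has
incorporated U residues at transcript positions -12, -11, -8, -7 and
-6 relative to the 3' end at position -1; these Us correspond to the
T-rich (TTNTTT-like) element in the non-template DNA strand of the
paused transcription bubble.  Positions -10 and -9 are unconstrained.
The explicit five-position list governs here; reconciling it with the
six-letter TTNTTT label would require assuming a register the data do
not pin down.

U-tract sequence logos are summarised as position frequency matrices
(PFMs) over the 9-nt window downstream of the predicted hairpins and
compared position-wise with the Jensen-Shannon divergence, in bits by
default (0 <= JS <= 1 for a four-letter alphabet).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

REQUIRED_U_POSITIONS = (-12, -11, -8, -7, -6)
ALPHABET = ("A", "C", "G", "U")
_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class MotifMatch:
    """Outcome of mapping the NusG pause register onto a transcript tail."""

    matched: bool
    observed: dict[int, str]
    n_matching: int

    required_u_positions = REQUIRED_U_POSITIONS


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix over (A, C, G, U), rows summing to 1."""

    freqs: np.ndarray  # shape (L, 4)
    n_seqs: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("PFM needs shape (L, 4)")
        if (f < 0).any() or not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PFM rows must be non-negative and sum to 1")
        object.__setattr__(self, "freqs", f)

    @property
    def length(self) -> int:
        return int(self.freqs.shape[0])


def map_pause_motif(transcript_tail: str) -> MotifMatch:
    """Check the NusG pause register on a transcript 3'-end tail.

    ``transcript_tail`` is transcript-sense sequence whose last
    character is the 3'-end nucleotide (position -1) and must be at
    least 12 nt long.  Residues at -12, -11, -8, -7, -6 must be U for a
    match; -10 and -9 never influence the outcome.
    """
    tail = transcript_tail.upper().replace("T", "U")
    if len(tail) < 12:
        raise ValueError("transcript tail must be >= 12 nt")
    observed = {pos: tail[pos] for pos in range(-12, 0)}
    n_matching = sum(1 for pos in REQUIRED_U_POSITIONS if observed[pos] == "U")
    return MotifMatch(
        matched=n_matching == len(REQUIRED_U_POSITIONS),
        observed=observed,
        n_matching=n_matching,
    )


def build_pfm(seqs, L: int = 9, pseudocount: float = 0.0) -> PFM:
    """Column-wise base frequencies of equal-length sequences.

    DNA input is accepted (T maps to U).  No pseudo-counts by default;
    a Laplace ``pseudocount`` is available for divergence stability on
    tiny cohorts.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("empty sequence set")
    counts = np.full((L, 4), float(pseudocount))
    for seq in seqs:
        rna = seq.upper().replace("T", "U")
        if len(rna) != L:
            raise ValueError(f"sequence {seq!r} is not {L} nt")
        for i, ch in enumerate(rna):
            if ch not in _INDEX:
                raise ValueError(f"non-ACGU character {ch!r} in {seq!r}")
            counts[i, _INDEX[ch]] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return PFM(freqs=freqs, n_seqs=len(seqs))


def _entropy(p: np.ndarray, base: float) -> np.ndarray:
    return -xlogy(p, p).sum(axis=-1) / np.log(base)


def js_divergence(pfm1: PFM, pfm2: PFM, base: str = "bits") -> np.ndarray:
    """Per-position Jensen-Shannon divergence between two PFMs.

    ``JS(p, q) = H(m) - (H(p) + H(q)) / 2`` with ``m = (p + q) / 2``;
    entropies are base-2 (bits) by default, or natural-log with
    ``base="nats"``.  Symmetric, and bounded by 1 bit for point masses
    on disjoint letters.
    """
    if pfm1.length != pfm2.length:
        raise ValueError("PFMs must have equal lengths")
    log_base = {"bits": 2.0, "nats": np.e}.get(base)
    if log_base is None:
        raise ValueError("base must be 'bits' or 'nats'")
    p, q = pfm1.freqs, pfm2.freqs
    m = 0.5 * (p + q)
    js = _entropy(m, log_base) - 0.5 * (_entropy(p, log_base) + _entropy(q, log_base))
    return np.clip(js, 0.0, None)
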