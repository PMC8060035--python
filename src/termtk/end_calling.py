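"""Transcript 3'-end identification from strand-specific tracks.

The coverage-variation statistic C_V is the one-step coverage drop in
the direction of transcription, clipped at zero:

* plus strand:  ``C_V(i) = max(0, cov(i) - cov(i+1))``
* minus strand: ``C_V(i) = max(0, cov(i) - cov(i-1))``

with 0 used for the out-of-range neighbour.  Its local maxima mark
transcript 3' ends; the C_V magnitude at a 3' end tracks 3'-end
abundance.  When a track already holds 3'-end pileup counts
(``kind == "termseq_ends"``) the counts themselves are the C_V
landscape — both backends are provided because either coverage drops or
end pileups can carry the 3'-end signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import STRANDS, CoverageTrack, ThreePrimeEnd

DEFAULT_CV_THRESHOLD = 10.0
DEFAULT_REGION_RADIUS = 3


@dataclass(frozen=True)
class CvTrack:
    """Per-nucleotide C_V landscape for one strand."""

    strand: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("empty C_V track")
        object.__setattr__(self, "values", arr)


def compute_cv(track: CoverageTrack) -> CvTrack:
    """Coverage variation at each nucleotide of a strand-specific track.

    For ``rnaseq`` tracks this is the clipped one-step drop in the
    direction of transcription; for ``termseq_ends`` tracks the end
    counts are used directly.
    """
    if track.kind not in ("rnaseq", "termseq_ends"):
        raise ValueError(f"C_V is undefined for track kind {track.kind!r}")
    v = track.values
    if v.size == 0:
        raise ValueError("empty track")
    if track.kind == "termseq_ends":
        return CvTrack(strand=track.strand, values=v.copy())
    shifted = np.empty_like(v)
    if track.strand == "+":
        shifted[:-1] = v[1:]
        shifted[-1] = 0.0
    else:
        shifted[1:] = v[:-1]
        shifted[0] = 0.0
    return CvTrack(strand=track.strand, values=np.maximum(0.0, v - shifted))


def _downstream_key(strand: str):
    """Sort key ranking positions by how far downstream they are."""
    return (lambda p: p) if strand == "+" else (lambda p: -p)


def call_ends(
    cv: CvTrack,
    threshold: float = DEFAULT_CV_THRESHOLD,
    end_counts: CoverageTrack | None = None,
) -> list[ThreePrimeEnd]:
    """Local maxima of the C_V landscape at or above ``threshold``.

    Positions are partitioned into maximal runs where ``C_V >=
    threshold``; the position of maximal C_V within each run is emitted
    (ties broken toward the most downstream position in the direction
    of transcription).  ``end_counts`` optionally supplies raw 3'-end
    pileup counts for the emitted ends; otherwise ``end_count`` equals
    the C_V.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = cv.values
    above = v >= threshold
    if not above.any():
        return []
    downstream = _downstream_key(cv.strand)
    # run boundaries of the boolean mask
    padded = np.concatenate(([False], above, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    stops = np.flatnonzero(~padded[1:] & padded[:-1])
    ends: list[ThreePrimeEnd] = []
    for i0, i1 in zip(starts, stops):
        run = v[i0:i1]
        best = run.max()
        candidates = [int(i0 + k) + 1 for k in np.flatnonzero(run == best)]
        pos = max(candidates, key=downstream)
        count = end_counts.value_at(pos) if end_counts is not None else float(best)
        ends.append(
            ThreePrimeEnd(x=pos, strand=cv.strand, cv=float(best), end_count=count)
        )
    ends.sort(key=lambda e: e.x)
    return ends


def select_region_representative(
    ends: Sequence[ThreePrimeEnd], radius: int = DEFAULT_REGION_RADIUS
) -> list[ThreePrimeEnd]:
    """Keep the most abundant 3' end within each region.

    Genomic regions with a transcript terminus usually hold multiple
    adjacent 3' ends; ends are clustered by single linkage with gap <=
    ``radius`` and the end with the greatest ``end_count`` represents
    each cluster (ties: greatest C_V, then most downstream in the
    direction of transcription).
    """
    if not ends:
        return []
    strands = {e.strand for e in ends}
    if len(strands) > 1:
        raise ValueError("select_region_representative takes a single strand")
    strand = strands.pop()
    downstream = _downstream_key(strand)
    ordered = sorted(ends, key=lambda e: e.x)
    clusters: list[list[ThreePrimeEnd]] = [[ordered[0]]]
    for end in ordered[1:]:
        if end.x - clusters[-1][-1].x <= radius:
            clusters[-1].append(end)
        else:
            clusters.append([end])
    reps = [
        max(c, key=lambda e: (e.end_count, e.cv, downstream(e.x))) for c in clusters
    ]
    return reps


def merge_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Position-wise sum of replicate tracks (merge before peak calling).

    Replicates are summed, not averaged, mirroring the merging of
    replicate alignments before coverage computation; values may end up
    fractional if the inputs were.
    """
    if not tracks:
        raise ValueError("no tracks to merge")
    first = tracks[0]
    for t in tracks[1:]:
        if (
            t.length != first.length
            or t.strand != first.strand
            or t.kind != first.kind
            or t.genome_id != first.genome_id
        ):
            raise ValueError("replicate tracks must share genome, strand and kind")
    total = np.sum([t.values for t in tracks], axis=0)
    return CoverageTrack(
        genome_id=first.genome_id, strand=first.strand, kind=first.kind, values=total
    )
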