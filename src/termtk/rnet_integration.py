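"""Nascent (RNET-seq) 3'-end assignment, normalisation and NusG scoring.

RNET-seq maps the 3' ends of nascent transcripts in actively
transcribing RNA polymerases and is immune to the 3'-5' exonucleolytic
trimming that shifts steady-state (Term-seq) 3' ends upstream.  For a
Term-seq terminator 3' end ``x``:

* nascent end counts are tabulated over the proximal window [x, x+4]
  and the upstream window [x-150, x+4] (transcript sense; the upstream
  window includes the proximal one);
* a peak is assigned only when the proximal window holds a nascent end
  and the 75th percentile of end counts across the upstream window is
  > 0; the most abundant proximal position becomes the nascent 3' end;
* normalised abundance = peak count / upstream 75th percentile, and
  peaks are kept only when their normalised abundance exceeds the
  cohort 25th percentile;
* NusG dependency of the pause = log2(norm_WT / norm_dnusG), with the
  dnusG normalised abundance set to 0.01 when that strain has no
  corresponding peak.

Percentiles use linear interpolation between order statistics; the
cohort filter applies a strict ``>``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .io_formats import CoverageTrack, GenomeSeq
from .terminator_annotation import (
    Hairpin,
    TerminatorCall,
    UTract,
    extend_stem_into_tract,
    find_utract_start,
    predict_hairpin,
    utract_seq9,
    validate_utract,
)

PROXIMAL_NT = 4
UPSTREAM_NT = 150
ABSENT_NORM_FLOOR = 0.01


@dataclass(frozen=True)
class RNETPeak:
    """A nascent 3'-end assignment to a Term-seq terminator."""

    terminator_id: str
    x_nascent: int
    offset: int                 # x_nascent - x_termseq, transcript sense (0..4)
    raw: float                  # nascent end count at x_nascent
    upstream_p75: float
    norm: float

    def __post_init__(self) -> None:
        if not 0 <= self.offset <= PROXIMAL_NT:
            raise ValueError("offset outside [0, 4]")
        if self.upstream_p75 <= 0:
            raise ValueError("upstream 75th percentile must be > 0")
        if self.norm <= 0:
            raise ValueError("normalised abundance must be > 0")


def assign_rnet_peak(
    x_termseq: int,
    rnet: CoverageTrack,
    terminator_id: str = "",
    include_zero_positions: bool = True,
) -> RNETPeak | None:
    """Assign the most abundant proximal nascent 3' end to a terminator.

    Returns ``None`` when no nascent end lies in [x, x+4] or the
    upstream 75th percentile is 0 (ties between equal proximal counts
    go to the most downstream position).  ``include_zero_positions``
    keeps zero-count nucleotides inside the upstream window when
    computing the percentile (the dense-track default).
    """
    sign = 1 if rnet.strand == "+" else -1
    prox_positions = [x_termseq + sign * k for k in range(PROXIMAL_NT + 1)]
    up_positions = [x_termseq + sign * k for k in range(-UPSTREAM_NT, PROXIMAL_NT + 1)]
    if not all(1 <= p <= rnet.length for p in prox_positions + up_positions):
        raise IndexError("RNET windows fall outside the genome")
    up_counts = np.array([rnet.value_at(p) for p in up_positions])
    if not include_zero_positions:
        up_counts = up_counts[up_counts > 0]
        if up_counts.size == 0:
            return None
    p75 = float(np.percentile(up_counts, 75))
    if p75 <= 0:
        return None
    prox_counts = [rnet.value_at(p) for p in prox_positions]
    best = max(prox_counts)
    if best <= 0:
        return None
    # most downstream among ties: the last index in transcript order
    offset = max(k for k, c in enumerate(prox_counts) if c == best)
    x_nascent = x_termseq + sign * offset
    return RNETPeak(
        terminator_id=terminator_id,
        x_nascent=x_nascent,
        offset=offset,
        raw=float(best),
        upstream_p75=p75,
        norm=float(best) / p75,
    )


def filter_by_cohort(peaks: list[RNETPeak]) -> list[RNETPeak]:
    """Keep peaks whose normalised abundance exceeds the cohort p25.

    The 25th percentile is computed over all normalised abundances with
    linear interpolation; the comparison is strictly ``>``, so a cohort
    of identical norms is emptied (boundary behaviour of the strict
    inequality).
    """
    if not peaks:
        raise ValueError("empty peak cohort")
    norms = np.array([p.norm for p in peaks])
    p25 = float(np.percentile(norms, 25))
    return [p for p in peaks if p.norm > p25]


def nusg_dependency(norm_wt: float, norm_dnusg: float | None) -> float:
    """log2 ratio of WT to dnusG normalised pause abundance.

    Terminators with no corresponding nascent 3' end in the dnusG
    strain are kept by flooring the missing value at 0.01; the floor is
    never applied to an observed abundance.
    """
    if norm_wt <= 0:
        raise ValueError("WT normalised abundance must be > 0")
    denom = ABSENT_NORM_FLOOR if norm_dnusg is None else norm_dnusg
    if denom <= 0:
        raise ValueError("dnusG normalised abundance must be > 0 when present")
    return float(np.log2(norm_wt / denom))


def revise_terminator(
    term: TerminatorCall, peak: RNETPeak, genome: GenomeSeq
) -> tuple[Hairpin | None, UTract | None]:
    """Re-annotate a terminator at its nascent (RNET-seq) 3' end.

    The U-tract search, hairpin fold and tract validation are rerun
    anchored at ``x_nascent``.  Unlike the primary prediction, the
    revised hairpin may extend into the U-tract with terminal A-U/G-U
    pairs; terminal weak-pair counts are evaluated on the extended
    stem.
    """
    end = replace(term.end, x=peak.x_nascent)
    s = find_utract_start(genome, end)
    if s is None:
        return None, None
    hairpin = predict_hairpin(genome, end, s)
    if hairpin is None:
        return None, None
    hairpin = extend_stem_into_tract(genome, hairpin, peak.x_nascent)
    seq9, start = utract_seq9(genome, hairpin)
    return hairpin, validate_utract(seq9, start=start)


def weak_pair_enrichment(
    nusg_dependent_weak_runs: list[int],
    si_of_nusg_weak_runs: list[int],
) -> tuple[np.ndarray, float | None, float]:
    """Terminal A-U/G-U enrichment in NusG-dependent vs SI-of-NusG stems.

    Tabulates terminators with >= 1 consecutive terminal A-U/G-U pairs
    at the revised stem bottom vs those with 0 into a 2x2 table
    ``[[dep_weak, dep_zero], [si_weak, si_zero]]`` and applies a
    two-sided Fisher's exact test (p from summing hypergeometric
    probabilities <= the observed table's).  Returns ``(table,
    odds_ratio, p)``; the odds ratio is ``None`` when a cell is zero
    and p is 1 for degenerate (zero-margin) tables.
    """
    if not nusg_dependent_weak_runs or not si_of_nusg_weak_runs:
        raise ValueError("both cohorts must be non-empty")
    a = sum(1 for r in nusg_dependent_weak_runs if r >= 1)
    b = len(nusg_dependent_weak_runs) - a
    c = sum(1 for r in si_of_nusg_weak_runs if r >= 1)
    d = len(si_of_nusg_weak_runs) - c
    return fisher_exact_2x2(np.array([[a, b], [c, d]]))


def fisher_exact_2x2(table: np.ndarray) -> tuple[np.ndarray, float | None, float]:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The two-sided p sums the probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed
    one.  Degenerate tables (a zero row or column margin) give p = 1;
    the odds ratio ``(a*d)/(b*c)`` is ``None`` whenever a cell is 0.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    if min(a + b, c + d, a + c, b + d) == 0:
        return t, _odds_ratio(a, b, c, d), 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return t, _odds_ratio(a, b, c, d), float(p)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float | None:
    if 0 in (a, b, c, d):
        return None
    return (a * d) / (b * c)
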