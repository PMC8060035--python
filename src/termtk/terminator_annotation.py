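"""Intrinsic-terminator anatomy: hairpin, U-tract and A-tract calls.

An intrinsic terminator is a GC-rich RNA hairpin followed immediately
by a U-rich tract; some terminators also carry an A-rich tract upstream
of the hairpin.  Annotation proceeds transcript-sense from a called 3'
end ``x``:

1. the U-rich tract is assumed to start at the first U residue within
   the 12 nt ending at ``x`` (:func:`find_utract_start`);
2. the 50 nt upstream of the tract start are folded iteratively with a
   single stem-loop thermodynamic model (:func:`predict_hairpin`) —
   because the hairpin is taken to end before the first U, the primary
   prediction never pairs U-tract residues;
3. the 9-nt window after the hairpin must begin with at least two
   consecutive U residues to count as a viable U-rich tract
   (:func:`validate_utract`);
4. the terminator is confirmed only when termination efficiency in the
   wild-type strain is >= 5 % (:func:`confirm_terminator`).

Termination normally occurs 7-9 nt downstream of the terminal hairpin
nucleotide; calls outside that distance are flagged atypical, not
rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

from . import _fold
from ._fold import StemLoop, fold_hairpin, to_rna
from .io_formats import GenomeSeq, ThreePrimeEnd, transcript_upstream

logger = logging.getLogger(__name__)

UTRACT_SEARCH_NT = 12
HAIRPIN_WINDOW_NT = 50
MIN_FOLDABLE_NT = 15
MAX_END_GAP_NT = 3          # 3' stem base must lie within this of the window end
TYPICAL_DISTANCE = (7, 9)   # hairpin-to-3'-end distance of a canonical POT
WT_PT_THRESHOLD = 5.0
WEAK_PAIRS = {"AU", "UA", "GU", "UG"}


@dataclass(frozen=True)
class Hairpin:
    """A folded terminator hairpin in genomic coordinates.

    ``stem_pairs`` lists (5' position, 3' position, pair type) from the
    stem bottom (outermost pair, adjacent to the U-tract side) inward;
    positions are 1-based forward-genome coordinates regardless of
    strand.  ``terminal_weak_run`` counts consecutive A-U/U-A/G-U/U-G
    pairs from the stem bottom upward, stopping at the first G-C/C-G.
    """

    strand: str
    stem_pairs: tuple[tuple[int, int, str], ...]
    loop_len: int
    dg: float
    seq: str

    def __post_init__(self) -> None:
        if not self.stem_pairs:
            raise ValueError("hairpin needs at least one base pair")
        if self.loop_len < _fold.MIN_LOOP:
            raise ValueError("loop too short")
        if self.dg > 0:
            raise ValueError("accepted hairpins must have dG <= 0")

    @property
    def stem_bp(self) -> int:
        return len(self.stem_pairs)

    @property
    def terminal_weak_run(self) -> int:
        run = 0
        for _, _, ptype in self.stem_pairs:
            if ptype in WEAK_PAIRS:
                run += 1
            else:
                break
        return run

    @property
    def stem_end3(self) -> int:
        """Genomic position of the 3'-most stem nucleotide (stem bottom)."""
        return self.stem_pairs[0][1]

    @property
    def stem_start5(self) -> int:
        """Genomic position of the 5'-most stem nucleotide (stem bottom)."""
        return self.stem_pairs[0][0]

    def dotbracket(self) -> str:
        """Dot-bracket string over ``seq`` (transcript sense)."""
        n = len(self.seq)
        chars = ["."] * n
        for t in range(self.stem_bp):
            chars[t] = "("
            chars[n - 1 - t] = ")"
        return "".join(chars)


@dataclass(frozen=True)
class UTract:
    """The 9-nt window downstream of a predicted hairpin."""

    seq9: str
    n_us: int
    valid: bool
    start: int | None = None  # 1-based genomic position of the tract's first nt


@dataclass(frozen=True)
class ATract:
    present: bool
    run_len: int = 0
    run_end_offset: int = 0  # nt upstream of the stem's 5' base


@dataclass(frozen=True)
class TerminatorCall:
    """A confirmed intrinsic terminator with its annotation."""

    end: ThreePrimeEnd
    hairpin: Hairpin
    utract: UTract
    atract: ATract
    pT_wt: float
    distance: int          # hairpin-to-3'-end distance d = x - last stem nt
    atypical: bool         # d outside the canonical 7-9 nt range


def find_utract_start(genome: GenomeSeq, end: ThreePrimeEnd) -> int | None:
    """Genomic position of the first U of the U-rich tract, or ``None``.

    Scans the transcript-sense 12 nt ending at ``x`` from 5' to 3' and
    returns the most upstream U (T on the coding strand); the U-rich
    tract is assumed to start at the first U residue.
    """
    tail = transcript_upstream(genome, end.x, UTRACT_SEARCH_NT, end.strand)
    idx = tail.find("T")
    if idx < 0:
        return None
    offset_from_x = len(tail) - 1 - idx  # 0 means x itself
    return end.x - offset_from_x if end.strand == "+" else end.x + offset_from_x


def _window_mapper(strand: str, end_g: int, length: int) -> Callable[[int], int]:
    """Map a transcript-sense window index to a genomic position.

    The window has ``length`` nt and its last (3'-most) nucleotide sits
    at genomic position ``end_g``.
    """
    if strand == "+":
        return lambda i: end_g - (length - 1) + i
    return lambda i: end_g + (length - 1) - i


def _stemloop_to_hairpin(
    sl: StemLoop, window: str, strand: str, end_g: int
) -> Hairpin:
    to_g = _window_mapper(strand, end_g, len(window))
    # outermost pair (i5, j3) is the stem bottom, listed first
    ordered = [(to_g(sl.i5 + t), to_g(sl.j3 - t), sl.pairs[t]) for t in range(sl.n_pairs)]
    return Hairpin(
        strand=strand,
        stem_pairs=tuple(ordered),
        loop_len=sl.loop_len,
        dg=sl.dg,
        seq=to_rna(window[sl.i5 : sl.j3 + 1]),
    )


def predict_hairpin(
    genome: GenomeSeq,
    end: ThreePrimeEnd,
    s: int,
    window_nt: int = HAIRPIN_WINDOW_NT,
    min_stem: int = _fold.MIN_STEM,
    backend: str = "builtin",
) -> Hairpin | None:
    """Fold the 50-nt window upstream of the U-tract start ``s``.

    The window ends at ``s - 1`` (transcript sense).  If the best
    structure's 3'-most paired base lies more than 3 nt upstream of the
    window end, windows ending 1 and 2 nt further upstream are retried
    and the best-dG structure whose 3' stem base lies within 3 nt of
    its window end is kept.  Accepted hairpins need a stem of >=
    ``min_stem`` bp, a 3-12 nt loop and dG < 0.  Near the genome edge
    the available suffix is folded if it is at least 15 nt, otherwise
    ``None`` is returned.
    """
    fold = fold_hairpin if backend == "builtin" else _vienna_fold
    strand = end.strand
    results: list[tuple[StemLoop, str, int]] = []
    for shift in range(MAX_END_GAP_NT):
        end_g = s - 1 - shift if strand == "+" else s + 1 + shift
        window = transcript_upstream(genome, end_g, window_nt, strand)
        if len(window) < MIN_FOLDABLE_NT:
            continue
        if shift == 0:
            free = fold(window, min_stem=min_stem)
            if free is not None and (len(window) - 1 - free.j3) <= MAX_END_GAP_NT:
                logger.debug("hairpin found on first window (no retry)")
                return _stemloop_to_hairpin(free, window, strand, end_g)
        constrained = fold(
            window, min_stem=min_stem, min_j3=len(window) - 1 - MAX_END_GAP_NT
        )
        if constrained is not None:
            results.append((constrained, window, end_g))
    if not results:
        return None
    sl, window, end_g = min(results, key=lambda r: r[0].dg)
    logger.debug("hairpin kept from shifted window ending at %d", end_g)
    return _stemloop_to_hairpin(sl, window, strand, end_g)


def _vienna_fold(window: str, min_stem: int = _fold.MIN_STEM, min_j3: int = 0):
    """Optional MFE backend via the ViennaRNA python bindings.

    Folds the window with RNAfold and extracts the 3'-most contiguous
    (bulge-free) helix ladder as the terminator stem; dG is the ladder
    nearest-neighbor energy of that stem so results stay comparable to
    the builtin backend.
    """
    import RNA  # deferred: optional dependency

    seq = to_rna(window)
    structure, _ = RNA.fold(seq)
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    if not pairs:
        return None
    j3 = max(j for _, j in pairs)
    if j3 < min_j3:
        return None
    by_j = {j: i for i, j in pairs}
    ladder: list[tuple[int, int]] = []
    j = j3
    i = by_j[j]
    while j in by_j and by_j[j] == i:
        ladder.append((i, j))
        i += 1
        j -= 1
    if len(ladder) < min_stem:
        return None
    (i5, j3top), loop = ladder[0], ladder[-1][1] - ladder[-1][0] - 1
    loop = max(loop, _fold.MIN_LOOP)
    if loop > _fold.MAX_LOOP:
        return None
    ptypes = tuple(_fold.pair_type(seq[a], seq[b]) for a, b in ladder)
    dg = _fold.stem_energy(list(ptypes), loop)
    if dg >= 0:
        return None
    return StemLoop(i5=i5, j3=j3top, pairs=ptypes, loop_len=loop, dg=dg)


def utract_seq9(genome: GenomeSeq, hairpin: Hairpin) -> tuple[str, int]:
    """9-nt transcript-sense window after the hairpin's last nucleotide.

    Returns ``(seq9, start)`` where ``start`` is the genomic position
    of the tract's first nucleotide; truncated only at the genome edge.
    """
    if hairpin.strand == "+":
        start = hairpin.stem_end3 + 1
        stop = min(genome.length, start + 8)
        return to_rna(genome.slice(start, stop)), start
    start = hairpin.stem_end3 - 1
    stop = max(1, start - 8)
    from .io_formats import revcomp

    return to_rna(revcomp(genome.slice(stop, start))), start


def validate_utract(seq9: str, start: int | None = None) -> UTract:
    """Apply the viable-U-rich-tract rule to a 9-nt tract sequence.

    At least two U residues count as viable when appropriately
    positioned and consecutive, i.e. the tract begins with a run of
    >= 2 consecutive Us; ``n_us`` is the length of that leading run.
    """
    rna = to_rna(seq9)
    run = 0
    for ch in rna:
        if ch == "U":
            run += 1
        else:
            break
    return UTract(seq9=rna, n_us=run, valid=run >= 2, start=start)


def detect_atract(
    genome: GenomeSeq, hairpin: Hairpin, window_nt: int = 10, min_run: int = 3
) -> ATract:
    """A-rich tract within the 10 nt upstream of the stem's 5' base.

    Present iff a run of >= 3 consecutive A (transcript sense) occurs in
    the window; the longest such run is reported together with the
    distance from its 3'-most A to the stem's 5' base.
    """
    upstream = transcript_upstream(
        genome, hairpin.stem_start5, window_nt, hairpin.strand, include_x=False
    )
    best_len = 0
    best_end = -1
    run = 0
    for i, ch in enumerate(upstream):
        run = run + 1 if ch == "A" else 0
        if run > best_len:
            best_len = run
            best_end = i
    if best_len < min_run:
        return ATract(present=False)
    return ATract(
        present=True, run_len=best_len, run_end_offset=len(upstream) - best_end
    )


def confirm_terminator(
    end: ThreePrimeEnd,
    hairpin: Hairpin | None,
    utract: UTract | None,
    pT_wt: float | None,
    atract: ATract | None = None,
) -> TerminatorCall | None:
    """Confirm a 3' end as an intrinsic terminator.

    Accepted iff a hairpin was found, the U-tract is viable and %T in
    the WT strain is >= 5.  The hairpin-to-3'-end distance ``d`` is
    recorded; d outside 7-9 nt is flagged atypical but not rejected.
    """
    if hairpin is None or utract is None or not utract.valid:
        return None
    if pT_wt is None or pT_wt < WT_PT_THRESHOLD:
        return None
    if end.strand == "+":
        d = end.x - hairpin.stem_end3
    else:
        d = hairpin.stem_end3 - end.x
    atypical = not (TYPICAL_DISTANCE[0] <= d <= TYPICAL_DISTANCE[1])
    if atract is None:
        atract = ATract(present=False)
    return TerminatorCall(
        end=end,
        hairpin=hairpin,
        utract=utract,
        atract=atract,
        pT_wt=pT_wt,
        distance=d,
        atypical=atypical,
    )


def count_terminal_weak_pairs(hairpin: Hairpin) -> int:
    """Consecutive A-U/G-U pairs at the stem bottom before the first G-C."""
    return hairpin.terminal_weak_run


def extend_stem_into_tract(
    genome: GenomeSeq, hairpin: Hairpin, x: int, min_distance: int = 7
) -> Hairpin:
    """Extend the stem bottom with downstream (U-tract) base pairs.

    Revised (nascent-3'-end anchored) hairpins may pair U-tract
    residues — typically adding terminal A-U/G-U pairs, often against
    an upstream A tract — which the primary prediction deliberately
    excludes.  Pairs are added outward while the bases form canonical
    or wobble pairs and the hairpin-to-3'-end distance stays >=
    ``min_distance`` (the biophysical floor set by the RNA-DNA hybrid).
    """
    strand = hairpin.strand
    step = 1 if strand == "+" else -1
    pairs = list(hairpin.stem_pairs)
    dg = hairpin.dg
    seq = hairpin.seq
    while True:
        p5, p3, _ = pairs[0]
        new5, new3 = p5 - step, p3 + step
        if not (1 <= new5 <= genome.length and 1 <= new3 <= genome.length):
            break
        distance = (x - new3) if strand == "+" else (new3 - x)
        if distance < min_distance:
            break
        b5 = to_rna(genome.base(new5) if strand == "+" else _comp(genome.base(new5)))
        b3 = to_rna(genome.base(new3) if strand == "+" else _comp(genome.base(new3)))
        if not _fold.can_pair(b5, b3):
            break
        ptype = _fold.pair_type(b5, b3)
        dg += _fold.STACK[(ptype, pairs[0][2])]
        pairs.insert(0, (new5, new3, ptype))
        seq = b5 + seq + b3
    if len(pairs) == hairpin.stem_bp:
        return hairpin
    return Hairpin(
        strand=strand,
        stem_pairs=tuple(pairs),
        loop_len=hairpin.loop_len,
        dg=min(dg, -0.0),
        seq=seq,
    )


def _comp(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base]
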