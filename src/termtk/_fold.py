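"""Minimal single-stem-loop RNA folding.

A hairpin here is a contiguous, bulge-free stem closing a terminal
loop.  Free energy is the sum of nearest-neighbor stack energies over
adjacent base pairs (Watson-Crick and G-U wobble) plus a hairpin-loop
initiation penalty, in kcal/mol at 37 degC.  Stack values follow the
Turner-2004 nearest-neighbor set; tandem G-U values are approximate.
This deliberately ignores bulges, internal loops and multibranch
structures: terminator hairpins are short contiguous stems, and the
classification logic downstream needs relative stabilities, not exact
Turner energies.  A full MFE backend can be plugged in instead (see
:mod:`termtk.terminator_annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass

PAIR_TYPES = ("GC", "CG", "AU", "UA", "GU", "UG")

_CANONICAL = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}

# Stack energy E[(outer, inner)] for outer pair (i, j) stacked on inner
# pair (i+1, j-1); remaining entries are filled by the helix symmetry
# E(p, q) = E(reverse(q), reverse(p)).
_BASE_STACK = {
    ("AU", "AU"): -0.93, ("AU", "CG"): -2.24, ("AU", "GC"): -2.08,
    ("AU", "UA"): -1.10, ("AU", "GU"): -0.55, ("AU", "UG"): -1.36,
    ("CG", "AU"): -2.11, ("CG", "CG"): -3.26, ("CG", "GC"): -2.36,
    ("CG", "UA"): -2.08, ("CG", "GU"): -1.41, ("CG", "UG"): -2.11,
    ("GC", "AU"): -2.35, ("GC", "CG"): -3.42, ("GC", "GC"): -3.26,
    ("GC", "UA"): -2.24, ("GC", "GU"): -1.53, ("GC", "UG"): -2.51,
    ("UA", "AU"): -1.33, ("UA", "CG"): -2.35, ("UA", "GC"): -2.11,
    ("UA", "UA"): -0.93, ("UA", "GU"): -1.00, ("UA", "UG"): -1.27,
    ("GU", "GU"): 0.47, ("UG", "UG"): 0.47,
    ("GU", "UG"): 1.29, ("UG", "GU"): -0.74,
}


def _rev(pair: str) -> str:
    return pair[::-1]


def _full_stack_table() -> dict[tuple[str, str], float]:
    table = dict(_BASE_STACK)
    for p in PAIR_TYPES:
        for q in PAIR_TYPES:
            if (p, q) not in table:
                table[(p, q)] = table[(_rev(q), _rev(p))]
    return table


STACK = _full_stack_table()

# Hairpin-loop initiation penalties by loop size (nt).
LOOP_PENALTY = {
    3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5,
    9: 6.4, 10: 6.5, 11: 6.6, 12: 6.7,
}

MIN_LOOP = 3
MAX_LOOP = 12
MIN_STEM = 4


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


def pair_type(a: str, b: str) -> str:
    if not can_pair(a, b):
        raise ValueError(f"{a}-{b} is not a canonical or wobble pair")
    return a + b


def stem_energy(pairs: list[str], loop_len: int) -> float:
    """Free energy of a contiguous stem (outermost pair first)."""
    dg = LOOP_PENALTY.get(loop_len)
    if dg is None:
        raise ValueError(f"loop length {loop_len} outside {MIN_LOOP}..{MAX_LOOP}")
    for outer, inner in zip(pairs, pairs[1:]):
        dg += STACK[(outer, inner)]
    return dg


@dataclass(frozen=True)
class StemLoop:
    """A folded hairpin in window coordinates (0-based indices).

    ``pairs[t]`` pairs window positions ``(i5 + t, j3 - t)``; the
    outermost ("bottom") pair is ``pairs[0]`` at ``(i5, j3)``.
    """

    i5: int
    j3: int
    pairs: tuple[str, ...]
    loop_len: int
    dg: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def last_paired(self) -> int:
        """3'-most paired window index."""
        return self.j3


def fold_hairpin(
    window: str,
    min_stem: int = MIN_STEM,
    min_loop: int = MIN_LOOP,
    max_loop: int = MAX_LOOP,
    min_j3: int = 0,
) -> StemLoop | None:
    """Best (lowest dG) single stem-loop within ``window``.

    ``min_j3`` constrains the 3'-most paired base to lie at window index
    >= ``min_j3`` (used to keep the hairpin adjacent to the U-tract).
    Only structures with ``dG < 0`` are returned; ties prefer more base
    pairs, then the more 3' closing base.
    """
    seq = to_rna(window)
    n = len(seq)
    best: StemLoop | None = None
    for j3 in range(n - 1, max(min_j3, min_stem) - 1, -1):
        for i5 in range(0, j3):
            span = j3 - i5 + 1
            if span < 2 * min_stem + min_loop:
                continue
            # grow a bulge-free stem inward from (i5, j3)
            pairs: list[str] = []
            a, b = i5, j3
            while b - a - 1 >= min_loop and can_pair(seq[a], seq[b]):
                pairs.append(pair_type(seq[a], seq[b]))
                a += 1
                b -= 1
            for k in range(len(pairs), min_stem - 1, -1):
                loop = j3 - i5 + 1 - 2 * k
                if loop < min_loop or loop > max_loop:
                    continue
                dg = stem_energy(pairs[:k], loop)
                if dg >= 0:
                    continue
                cand = StemLoop(
                    i5=i5, j3=j3, pairs=tuple(pairs[:k]), loop_len=loop, dg=dg
                )
                if (
                    best is None
                    or cand.dg < best.dg - 1e-12
                    or (
                        abs(cand.dg - best.dg) <= 1e-12
                        and (cand.n_pairs, cand.j3) > (best.n_pairs, best.j3)
                    )
                ):
                    best = cand
    return best
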