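"""Termination efficiency, factor dependence and dataset matching.

Termination efficiency at a 3' end ``x`` compares the median RNA-seq
coverage of the 10 nt upstream (U) to the median of the 10 nt
downstream (D), transcript sense::

    %T = 100 * (U - D) / U

The change upon losing an elongation factor is ``d%T = %T_WT -
%T_mutant``; a terminator is *dependent* on the factor(s) when
d%T >= 25 and *independent* when 10 >= d%T >= -10.  Combining the
dependence calls across the NusA-depletion, dnusG and double-mutant
strains yields the factor-dependence subpopulations (Req A, Req G,
Req A and G, Req A or G, and the strong-and-independent SI class with
%T_WT >= 70).

%T is not clipped: readthrough exceeding upstream coverage yields
negative values, which are preserved.  The upstream window includes
``x`` itself ([x-9, x]), keeping the terminated transcript's last
nucleotide upstream; the downstream window is [x+1, x+10].
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import CoverageTrack, ThreePrimeEnd

STRAIN_WT = "WT"
MUTANT_STRAINS = ("nusAdep", "dnusG", "double")
STRAINS = (STRAIN_WT,) + MUTANT_STRAINS

DEPENDENT_MIN_DT = 25.0
INDEPENDENT_BAND = (-10.0, 10.0)
SI_MIN_PT_WT = 70.0
WINDOW_NT = 10

SUBPOPULATIONS = ("ReqA", "ReqG", "ReqAandG", "ReqAorG", "SI", "other")


@dataclass
class StrainQuartet:
    """%T / d%T / dependence across the four-strain design."""

    pT: dict[str, float | None]
    dT: dict[str, float | None] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)
    subpopulation: str = "other"

    @classmethod
    def from_pt(cls, pT: dict[str, float | None]) -> "StrainQuartet":
        q = cls(pT=dict(pT))
        for strain in MUTANT_STRAINS:
            q.dT[strain] = delta_t(pT.get(STRAIN_WT), pT.get(strain))
            q.category[strain] = (
                classify_dependence(q.dT[strain])
                if q.dT[strain] is not None
                else "undefined"
            )
        q.subpopulation = assign_subpopulation(q)
        return q


def termination_efficiency(
    rnaseq: CoverageTrack, x: int, strand: str, window_nt: int = WINDOW_NT
) -> float | None:
    """%T at the 3' end ``x`` from flanking median coverage.

    Raises :class:`IndexError` when either 10-nt window falls outside
    the genome (windows are never truncated); returns ``None`` when the
    upstream median is zero (%T undefined).
    """
    if strand == "+":
        up = rnaseq.window(x - window_nt + 1, x)
        down = rnaseq.window(x + 1, x + window_nt)
    else:
        up = rnaseq.window(x, x + window_nt - 1)
        down = rnaseq.window(x - window_nt, x - 1)
    u = float(np.median(up))
    d = float(np.median(down))
    if u == 0.0:
        return None
    return 100.0 * (u - d) / u


def delta_t(pt_wt: float | None, pt_mut: float | None) -> float | None:
    """d%T = %T_WT - %T_mutant; ``None`` when either input is undefined."""
    if pt_wt is None or pt_mut is None:
        return None
    return pt_wt - pt_mut


def classify_dependence(dt: float) -> str:
    """dependent iff d%T >= 25; independent iff -10 <= d%T <= 10."""
    if dt >= DEPENDENT_MIN_DT:
        return "dependent"
    if INDEPENDENT_BAND[0] <= dt <= INDEPENDENT_BAND[1]:
        return "independent"
    return "intermediate"


def assign_subpopulation(quartet: StrainQuartet) -> str:
    """Factor-dependence subpopulation from the three mutant categories.

    Req rules are evaluated before SI: requiring-both needs dependence
    in all three mutants, Req A / Req G dependence in the matching
    single mutant plus the double, Req A or G dependence in the double
    only.  SI needs %T_WT >= 70 and independence in the double mutant.
    """
    dep = {s: quartet.category.get(s) == "dependent" for s in MUTANT_STRAINS}
    if dep["nusAdep"] and dep["dnusG"] and dep["double"]:
        return "ReqAandG"
    if dep["nusAdep"] and dep["double"] and not dep["dnusG"]:
        return "ReqA"
    if dep["dnusG"] and dep["double"] and not dep["nusAdep"]:
        return "ReqG"
    if dep["double"] and not dep["nusAdep"] and not dep["dnusG"]:
        return "ReqAorG"
    pt_wt = quartet.pT.get(STRAIN_WT)
    if (
        pt_wt is not None
        and pt_wt >= SI_MIN_PT_WT
        and quartet.category.get("double") == "independent"
    ):
        return "SI"
    return "other"


def si_of_factor(quartet: StrainQuartet, factor: str) -> bool:
    """Strong and independent of a single factor.

    True iff %T_WT >= 70 and the single-mutant d%T for that factor lies
    within [-10, 10] (e.g. SI of NusG uses the dnusG strain).
    """
    strain = {"NusA": "nusAdep", "NusG": "dnusG"}.get(factor)
    if strain is None:
        raise ValueError("factor must be 'NusA' or 'NusG'")
    pt_wt = quartet.pT.get(STRAIN_WT)
    dt = quartet.dT.get(strain)
    if pt_wt is None or dt is None:
        return False
    return pt_wt >= SI_MIN_PT_WT and INDEPENDENT_BAND[0] <= dt <= INDEPENDENT_BAND[1]


# window_nt -> matching half-width |x_a - x_b| used for dataset overlap;
# the 4-nt steady-state window maps to the [x-3, x+3] reconciliation
# half-width, the 15-nt in-silico-prediction window to |delta| <= 7.
MATCH_HALF_WIDTH = {4: 3, 15: 7}


def match_terminators(
    set_a: list[ThreePrimeEnd],
    set_b: list[ThreePrimeEnd],
    window_nt: int = 4,
    prefer_b_coordinate: bool = True,
):
    """Greedy one-to-one nearest-position matching of two terminator sets.

    Only same-strand pairs within the half-width implied by
    ``window_nt`` are accepted (ties go to the smaller coordinate).
    When ``set_b`` is the prior study, the reported coordinate of a
    matched pair is b's position (coordinate reconciliation).  Returns
    ``(matches, unmatched_a, unmatched_b)`` where each match is
    ``(a, b, reported_x)``.
    """
    half = MATCH_HALF_WIDTH.get(window_nt, window_nt // 2)

    def dedupe(ends: list[ThreePrimeEnd], label: str) -> list[ThreePrimeEnd]:
        seen: set[tuple[int, str]] = set()
        out = []
        for e in ends:
            key = (e.x, e.strand)
            if key in seen:
                warnings.warn(
                    f"duplicate position {e.x}{e.strand} in set {label}; keeping first",
                    stacklevel=3,
                )
                continue
            seen.add(key)
            out.append(e)
        return out

    a_list = dedupe(set_a, "a")
    b_list = dedupe(set_b, "b")
    candidates = [
        (abs(a.x - b.x), a.x, b.x, i, j)
        for i, a in enumerate(a_list)
        for j, b in enumerate(b_list)
        if a.strand == b.strand and abs(a.x - b.x) <= half
    ]
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = a_list[i], b_list[j]
        matches.append((a, b, b.x if prefer_b_coordinate else a.x))
    unmatched_a = [a for i, a in enumerate(a_list) if i not in used_a]
    unmatched_b = [b for j, b in enumerate(b_list) if j not in used_b]
    return matches, unmatched_a, unmatched_b


EXHAUSTIVE_LIMIT = 20_000


def fisher_pitman_permutation(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided Fisher-Pitman permutation test on the mean difference.

    Group labels are permuted; the statistic is ``mean(a) - mean(b)``.
    All label assignments are enumerated when there are at most 20 000
    of them, giving an exact p; otherwise ``n_perm`` Monte-Carlo draws
    are used with the add-one estimator ``p = (1 + #{|perm| >=
    |observed|}) / (1 + n_perm)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = float(a.mean() - b.mean())
    tol = 1e-12
    if math.comb(n, na) <= EXHAUSTIVE_LIMIT:
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            total += 1
            if abs(stat) >= abs(observed) - tol:
                extreme += 1
        return observed, extreme / total
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[:na].mean() - perm[na:].mean()
        if abs(stat) >= abs(observed) - tol:
            extreme += 1
    return observed, (1 + extreme) / (1 + n_perm)


def group_compare(
    values_a,
    values_b,
    method: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided comparison of two %T / dG / stem-length samples.

    ``wilcoxon_signed_rank`` is paired (equal lengths required and
    zero differences rank-split so identical vectors give p = 1);
    ``mann_whitney_u`` and ``fisher_pitman_permutation`` are unpaired.
    Returns ``(statistic, p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if method == "wilcoxon_signed_rank":
        if a.size != b.size:
            raise ValueError("paired test needs equal lengths")
        res = stats.wilcoxon(a, b, zero_method="zsplit", alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney_u":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "fisher_pitman_permutation":
        return fisher_pitman_permutation(a, b, n_perm=n_perm, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjustment (optional; raw p-values are the default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
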