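"""End-to-end orchestration of the Term-seq terminator analysis.

Thin glue over the stage modules: call 3' ends per strand, annotate
and confirm intrinsic terminators, quantify %T across the four-strain
design and score NusG-dependent pausing from nascent-end tracks.  The
CLI and the reproduction script are built on these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .end_calling import (
    DEFAULT_CV_THRESHOLD,
    DEFAULT_REGION_RADIUS,
    call_ends,
    compute_cv,
    select_region_representative,
)
from .io_formats import CoverageTrack, GenomeSeq, ThreePrimeEnd
from .rnet_integration import (
    RNETPeak,
    assign_rnet_peak,
    filter_by_cohort,
    nusg_dependency,
    revise_terminator,
)
from .terminator_annotation import (
    TerminatorCall,
    confirm_terminator,
    detect_atract,
    find_utract_start,
    predict_hairpin,
    utract_seq9,
    validate_utract,
)
from .termination_metrics import (
    MUTANT_STRAINS,
    STRAIN_WT,
    StrainQuartet,
    termination_efficiency,
)


def call_strand_ends(
    track: CoverageTrack,
    threshold: float = DEFAULT_CV_THRESHOLD,
    radius: int = DEFAULT_REGION_RADIUS,
    end_counts: CoverageTrack | None = None,
) -> list[ThreePrimeEnd]:
    """C_V computation, local-maxima calling and region collapse."""
    cv = compute_cv(track)
    ends = call_ends(cv, threshold=threshold, end_counts=end_counts)
    return select_region_representative(ends, radius=radius)


@dataclass(frozen=True)
class AnnotatedTerminator:
    call: TerminatorCall
    quartet: StrainQuartet


def screen_terminators(
    genome: GenomeSeq,
    ends: list[ThreePrimeEnd],
    rnaseq_by_strain: dict[str, dict[str, CoverageTrack]],
) -> list[AnnotatedTerminator]:
    """Confirm intrinsic terminators among called 3' ends.

    For each end: locate the U-tract start, fold the upstream hairpin,
    validate the tract, compute %T per strain and keep the end when the
    terminator modules are present and %T_WT >= 5.  Ends whose %T
    windows fall off the genome are skipped.
    """
    out: list[AnnotatedTerminator] = []
    for end in ends:
        s = find_utract_start(genome, end)
        if s is None:
            continue
        hairpin = predict_hairpin(genome, end, s)
        if hairpin is None:
            continue
        seq9, start = utract_seq9(genome, hairpin)
        utract = validate_utract(seq9, start=start)
        pT: dict[str, float | None] = {}
        try:
            for strain, tracks in rnaseq_by_strain.items():
                pT[strain] = termination_efficiency(
                    tracks[end.strand], end.x, end.strand
                )
        except IndexError:
            continue
        atract = detect_atract(genome, hairpin)
        call = confirm_terminator(
            end, hairpin, utract, pT.get(STRAIN_WT), atract=atract
        )
        if call is None:
            continue
        out.append(AnnotatedTerminator(call=call, quartet=StrainQuartet.from_pt(pT)))
    return out


def terminator_dataframe(terminators: list[AnnotatedTerminator]) -> pd.DataFrame:
    """Flatten annotated terminators into the supplementary-table layout."""
    rows = []
    for t in terminators:
        call, q = t.call, t.quartet
        row = {
            "coordinate": call.end.x,
            "strand": call.end.strand,
            "cv": call.end.cv,
            "hairpin_seq": call.hairpin.seq,
            "structure": call.hairpin.dotbracket(),
            "dG": call.hairpin.dg,
            "stem_bp": call.hairpin.stem_bp,
            "loop_len": call.hairpin.loop_len,
            "terminal_weak_run": call.hairpin.terminal_weak_run,
            "utract": call.utract.seq9,
            "utract_n_us": call.utract.n_us,
            "atract": call.atract.present,
            "hairpin_to_end_nt": call.distance,
            "atypical_distance": call.atypical,
            "subpopulation": q.subpopulation,
        }
        for strain, pt in q.pT.items():
            row[f"pT_{strain}"] = pt
        for strain in MUTANT_STRAINS:
            row[f"dT_{strain}"] = q.dT.get(strain)
            row[f"category_{strain}"] = q.category.get(strain)
        rows.append(row)
    return pd.DataFrame(rows)


def score_nusg_pausing(
    genome: GenomeSeq,
    terminators: list[AnnotatedTerminator],
    rnet_wt: dict[str, CoverageTrack],
    rnet_dnusg: dict[str, CoverageTrack],
    apply_cohort_filter: bool = True,
) -> pd.DataFrame:
    """Assign nascent peaks, filter, and score NusG pause dependency.

    WT peaks define the cohort; the 25th-percentile abundance filter is
    applied to the WT normalised abundances.  A missing dnusG peak is
    floored at 0.01 normalised abundance.  Revised hairpin anatomy
    (anchored at the WT nascent end, stem extension into the tract
    allowed) is reported per terminator.
    """
    wt_peaks: list[tuple[AnnotatedTerminator, RNETPeak]] = []
    for idx, t in enumerate(terminators):
        end = t.call.end
        try:
            peak = assign_rnet_peak(
                end.x, rnet_wt[end.strand], terminator_id=f"term{idx}"
            )
        except IndexError:
            continue
        if peak is not None:
            wt_peaks.append((t, peak))
    if not wt_peaks:
        return pd.DataFrame()
    if apply_cohort_filter:
        kept_ids = {p.terminator_id for p in filter_by_cohort([p for _, p in wt_peaks])}
        wt_peaks = [(t, p) for t, p in wt_peaks if p.terminator_id in kept_ids]
    rows = []
    for t, peak in wt_peaks:
        end = t.call.end
        dn_peak = assign_rnet_peak(end.x, rnet_dnusg[end.strand])
        dep = nusg_dependency(peak.norm, dn_peak.norm if dn_peak else None)
        hairpin, utract = revise_terminator(t.call, peak, genome)
        rows.append(
            {
                "coordinate": end.x,
                "strand": end.strand,
                "x_nascent": peak.x_nascent,
                "offset": peak.offset,
                "raw": peak.raw,
                "upstream_p75": peak.upstream_p75,
                "norm_WT": peak.norm,
                "norm_dnusG": dn_peak.norm if dn_peak else None,
                "nusg_dependency": dep,
                "revised_stem_bp": hairpin.stem_bp if hairpin else None,
                "revised_dG": hairpin.dg if hairpin else None,
                "revised_terminal_weak_run": (
                    hairpin.terminal_weak_run if hairpin else None
                ),
                "revised_utract": utract.seq9 if utract else None,
                "subpopulation": t.quartet.subpopulation,
            }
        )
    return pd.DataFrame(rows)
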