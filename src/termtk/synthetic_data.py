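"""Synthetic genomes and sequencing tracks with planted terminators.

The generator emulates the statistical structure the analysis assumes,
so every downstream stage is testable without deposited sequencing
data:

* a random (i.i.d. uniform ACGT) genome carrying planted intrinsic
  terminators — GC-rich reverse-complement stem, loop, 9-nt U-tract
  starting immediately after the stem, optional upstream A-tract and
  optional NusG pause motif (U at transcript positions -12 and -11,
  realised as two A-U pairs at the stem bottom);
* strand-specific RNA-seq coverage with a step drop of the planted
  release fraction at each terminator 3' end, per strain, with
  optional per-nucleotide Poisson read noise;
* Term-seq 3'-end count pileups concentrated at the planted point of
  termination (POT), with <= 10 % of the mass jittered to +-1 nt when
  noise is enabled;
* RNET-seq nascent 3'-end pileups offset 0-4 nt downstream of the POT,
  with pause-motif terminators carrying a configurable WT : dnusG mass
  ratio (default 4).

Everything is a pure function of ``(config, seed)``: the same seed
reproduces byte-identical genomes and tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import CoverageTrack, GenomeSeq, revcomp
from .termination_metrics import STRAINS

# Default per-strain release fractions by planted subpopulation
# (WT, nusAdep, dnusG, double), chosen to land squarely inside the
# d%T >= 25 dependence band and the 10 >= d%T >= -10 independence band.
DEFAULT_RELEASE_FRACTIONS: dict[str, dict[str, float]] = {
    "SI": {"WT": 0.9, "nusAdep": 0.9, "dnusG": 0.9, "double": 0.9},
    "ReqA": {"WT": 0.8, "nusAdep": 0.3, "dnusG": 0.8, "double": 0.3},
    "ReqG": {"WT": 0.8, "nusAdep": 0.8, "dnusG": 0.3, "double": 0.3},
    "ReqAandG": {"WT": 0.8, "nusAdep": 0.4, "dnusG": 0.4, "double": 0.1},
    "ReqAorG": {"WT": 0.8, "nusAdep": 0.75, "dnusG": 0.75, "double": 0.2},
}

SUBPOP_CYCLE = ("SI", "ReqA", "ReqG", "ReqAandG", "ReqAorG")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted terminator."""

    terminator_id: str
    x_true: int                       # 1-based POT position (3'-terminal nt)
    strand: str
    stem_bp: int
    loop_len: int
    utract: str                       # 9-nt tract (DNA alphabet, transcript sense)
    has_atract: bool
    has_pause_motif: bool
    release_fraction: dict[str, float]
    expression_level: float
    subpopulation: str
    hairpin_distance: int             # planted hairpin-to-3'-end distance (7-9)

    def __post_init__(self) -> None:
        if len(self.utract) != 9:
            raise ValueError("utract must be exactly 9 nt")
        for strain, rf in self.release_fraction.items():
            if not 0.0 <= rf <= 1.0:
                raise ValueError(f"release fraction for {strain} outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the defaults are the study conditions."""

    genome_length: int = 100_000
    n_terminators: int = 50
    depth: float = 200.0              # mean upstream coverage (expression level)
    noise: str = "poisson"            # {"none", "poisson"}
    seed: int = 0
    rnet_offset_range: tuple[int, int] = (0, 4)
    spacing: int = 300                # minimum distance between planted POTs
    unit_upstream: int = 160          # transcribed nt upstream of each POT
    unit_downstream: int = 50         # readthrough nt downstream of each POT
    jitter_fraction: float = 0.1      # Term-seq pileup mass moved to +-1 nt
    rnet_bg_lambda: float = 4.0       # background nascent end counts per nt
    rnet_peak_mass: float = 60.0      # nascent pileup mass at a POT
    pause_factor: float = 4.0         # WT:dnusG pileup ratio at motif terminators
    stem_bp_range: tuple[int, int] = (6, 12)
    loop_len_range: tuple[int, int] = (3, 8)
    atract_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")
        if self.spacing < 200:
            raise ValueError("terminators must be spaced >= 200 nt")
        lo, hi = self.rnet_offset_range
        if not (0 <= lo <= hi <= 4):
            raise ValueError("rnet_offset_range must lie within 0..4")


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


_STRAIN_INDEX = {s: i for i, s in enumerate(STRAINS)}


def _cassette(
    record_rng: np.random.Generator,
    stem_bp: int,
    loop_len: int,
    utract: str,
    has_atract: bool,
    has_pause_motif: bool,
) -> tuple[str, int]:
    """Transcript-sense terminator cassette and the tract offset within it.

    Layout: [A-tract] stem5' loop stem3' tract(9).  Returns the DNA
    string and the index of the tract's first nucleotide.  Pause-motif
    cassettes carry A-U pairs at the second and third stem positions
    from the bottom, so the transcript has U at -12/-11 when the POT
    lies 9 nt from the hairpin.
    """
    gc_weighted = ["G", "C", "G", "C", "G", "C", "A", "T"]
    arm5 = [gc_weighted[i] for i in record_rng.integers(0, len(gc_weighted), stem_bp)]
    # An A in the bottom five 5'-arm positions would put a T (a U in the
    # transcript) in the 3' arm inside the 12-nt first-U search window
    # and shift the apparent tract start; keep those positions A-free.
    no_a = ["G", "C", "G", "C", "G", "C", "T"]
    for t in range(min(5, stem_bp)):
        if arm5[t] == "A":
            arm5[t] = no_a[int(record_rng.integers(0, len(no_a)))]
    if has_pause_motif:
        # With the 9-nt tract at transcript -9..-1 the stem bottom sits
        # at -10; three terminal A-U pairs put U residues at -12/-11
        # (the pause-motif register) and give the weak-bottom anatomy
        # of NusG-dependent terminators.
        arm5[0] = "A"
        arm5[1] = "A"
        arm5[2] = "A"
    arm5 = "".join(arm5)
    arm3 = revcomp(arm5)
    # all-A loop: A cannot pair A, so the fold cannot creep into the loop
    loop = "A" * loop_len
    atract = "AAAA" if has_atract else ""
    cassette = atract + arm5 + loop + arm3 + utract
    tract_index = len(atract) + 2 * stem_bp + loop_len
    return cassette, tract_index


def generate_genome_with_truth(
    config: SimulationConfig,
) -> tuple[GenomeSeq, list[TruthRecord]]:
    """Random genome with ``n_terminators`` planted terminators.

    Terminators are placed one per equal-length genome block with at
    least ``spacing`` nt between points of termination, alternating
    subpopulations through the default release-fraction table; strand
    is random.  Raises :class:`ValueError` when the genome is too short
    for the requested count and spacing.
    """
    L = config.genome_length
    n = config.n_terminators
    rng = _rng(config, 0)
    genome_arr = _BASES[rng.integers(0, 4, L)].copy()
    truth: list[TruthRecord] = []
    if n > 0:
        block = L // n
        margin = max(config.spacing // 2, config.unit_upstream) + 20
        if block <= 2 * margin:
            raise ValueError(
                f"genome of {L} nt too short for {n} terminators at "
                f">= {config.spacing} nt spacing"
            )
        for i in range(n):
            rec_rng = _rng(config, 1, i)
            x = int(rec_rng.integers(i * block + margin, (i + 1) * block - margin))
            strand = "+" if rec_rng.random() < 0.5 else "-"
            subpop = SUBPOP_CYCLE[i % len(SUBPOP_CYCLE)]
            has_pause_motif = subpop in ("ReqG", "ReqAandG")
            stem_bp = int(rec_rng.integers(*config.stem_bp_range, endpoint=True))
            if has_pause_motif:
                # the primary prediction stops before the first U (at -12),
                # so motif stems need >= 7 bp to keep >= 4 predictable pairs
                stem_bp = max(stem_bp, 7)
            loop_len = int(rec_rng.integers(*config.loop_len_range, endpoint=True))
            d = 9 if has_pause_motif else int(rec_rng.integers(7, 9, endpoint=True))
            has_atract = bool(rec_rng.random() < config.atract_probability)
            utract = "T" * 9
            cassette, tract_index = _cassette(
                rec_rng, stem_bp, loop_len, utract, has_atract, has_pause_motif
            )
            # POT is the d-th tract nucleotide (transcript sense)
            pot_index = tract_index + d - 1
            if strand == "+":
                start = x - pot_index  # genomic position of cassette[0]
                seq_bytes = np.frombuffer(cassette.encode(), dtype="S1")
                genome_arr[start - 1 : start - 1 + len(cassette)] = seq_bytes
            else:
                placed = revcomp(cassette)
                end_g = x + pot_index
                seq_bytes = np.frombuffer(placed.encode(), dtype="S1")
                genome_arr[end_g - len(cassette) : end_g] = seq_bytes
            truth.append(
                TruthRecord(
                    terminator_id=f"T{i + 1:04d}",
                    x_true=x,
                    strand=strand,
                    stem_bp=stem_bp,
                    loop_len=loop_len,
                    utract=utract,
                    has_atract=has_atract,
                    has_pause_motif=has_pause_motif,
                    release_fraction=dict(DEFAULT_RELEASE_FRACTIONS[subpop]),
                    expression_level=config.depth,
                    subpopulation=subpop,
                    hairpin_distance=d,
                )
            )
    genome = GenomeSeq(id="synthetic", sequence=genome_arr.tobytes().decode())
    return genome, truth


@dataclass(frozen=True)
class StrainTracks:
    """Per-strain strand-keyed RNA-seq and Term-seq end tracks."""

    rnaseq: dict[str, CoverageTrack]
    termseq_ends: dict[str, CoverageTrack]


def _unit_bounds(rec: TruthRecord, config: SimulationConfig, L: int):
    """(upstream_start, downstream_end) genomic bounds of the unit."""
    if rec.strand == "+":
        return (
            max(1, rec.x_true - config.unit_upstream),
            min(L, rec.x_true + config.unit_downstream),
        )
    return (
        max(1, rec.x_true - config.unit_downstream),
        min(L, rec.x_true + config.unit_upstream),
    )


def simulate_tracks(
    genome: GenomeSeq,
    truth: list[TruthRecord],
    strain: str,
    config: SimulationConfig,
) -> StrainTracks:
    """RNA-seq coverage and Term-seq 3'-end pileups for one strain.

    Coverage within each transcription unit is ``expression_level``
    upstream of the POT and ``expression_level * (1 - release
    fraction)`` downstream of it; the Term-seq track receives ``release
    fraction * expression_level`` counts at the POT.  Poisson noise, if
    configured, is applied per nucleotide; minus-strand records are
    mirrored.
    """
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r}; expected one of {STRAINS}")
    L = genome.length
    cov = {s: np.zeros(L) for s in ("+", "-")}
    ends = {s: np.zeros(L) for s in ("+", "-")}
    for rec in truth:
        rf = rec.release_fraction[strain]
        expr = rec.expression_level
        lo, hi = _unit_bounds(rec, config, L)
        x = rec.x_true
        c = cov[rec.strand]
        if rec.strand == "+":
            c[lo - 1 : x] = expr
            c[x : hi] = expr * (1.0 - rf)
        else:
            c[x - 1 : hi] = expr
            c[lo - 1 : x - 1] = expr * (1.0 - rf)
        mass = rf * expr
        e = ends[rec.strand]
        if config.noise == "none" or config.jitter_fraction == 0.0:
            e[x - 1] += mass
        else:
            jit = config.jitter_fraction
            e[x - 1] += mass * (1.0 - jit)
            nbr = 1 if rec.strand == "+" else -1
            e[x - 1 - nbr] += mass * jit / 2.0
            if 1 <= x + nbr <= L:
                e[x - 1 + nbr] += mass * jit / 2.0
    if config.noise == "poisson":
        si = _STRAIN_INDEX[strain]
        for k, s in enumerate(("+", "-")):
            cov[s] = _rng(config, 2, si, k).poisson(cov[s]).astype(float)
            ends[s] = _rng(config, 3, si, k).poisson(ends[s]).astype(float)
    rnaseq = {
        s: CoverageTrack(genome_id=genome.id, strand=s, kind="rnaseq", values=cov[s])
        for s in ("+", "-")
    }
    termseq = {
        s: CoverageTrack(
            genome_id=genome.id, strand=s, kind="termseq_ends", values=ends[s]
        )
        for s in ("+", "-")
    }
    return StrainTracks(rnaseq=rnaseq, termseq_ends=termseq)


def rnet_offsets(truth: list[TruthRecord], config: SimulationConfig) -> list[int]:
    """Planted nascent-end offset delta per terminator (strain-independent).

    The nascent 3' end sits ``delta`` nt downstream of the steady-state
    POT, emulating 3'-5' exoribonuclease trimming of released
    transcripts; delta is drawn once per terminator so WT and dnusG
    peaks coincide.
    """
    lo, hi = config.rnet_offset_range
    out = []
    for i, _ in enumerate(truth):
        rng = _rng(config, 4, i)
        out.append(int(rng.integers(lo, hi, endpoint=True)))
    return out


def simulate_rnet(
    genome: GenomeSeq,
    truth: list[TruthRecord],
    strain: str,
    config: SimulationConfig,
) -> dict[str, CoverageTrack]:
    """RNET-seq nascent 3'-end tracks (one per strand) for one strain.

    Background nascent ends of ``rnet_bg_lambda`` per nt cover the
    transcript-sense window from 150 nt upstream of each POT to the
    nascent peak, so the upstream 75th-percentile normaliser is well
    defined; the nascent pileup replaces the background at x+delta.  Pause-motif terminators carry
    ``pause_factor`` times the pileup mass in WT relative to dnusG;
    all other pileups are equal across strains.
    """
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r}; expected one of {STRAINS}")
    L = genome.length
    lam = {s: np.zeros(L) for s in ("+", "-")}
    offsets = rnet_offsets(truth, config)
    for rec, delta in zip(truth, offsets):
        x = rec.x_true
        sign = 1 if rec.strand == "+" else -1
        peak = x + sign * delta
        w_lo = min(x - sign * 150, peak)
        w_hi = max(x - sign * 150, peak)
        w_lo, w_hi = max(1, min(w_lo, w_hi)), min(L, max(w_lo, w_hi))
        arr = lam[rec.strand]
        arr[w_lo - 1 : w_hi] = config.rnet_bg_lambda
        mass = config.rnet_peak_mass
        if rec.has_pause_motif and strain == "WT":
            mass *= config.pause_factor
        if 1 <= peak <= L:
            arr[peak - 1] = mass
    if config.noise == "poisson":
        si = _STRAIN_INDEX[strain]
        for k, s in enumerate(("+", "-")):
            lam[s] = _rng(config, 5, si, k).poisson(lam[s]).astype(float)
    return {
        s: CoverageTrack(genome_id=genome.id, strand=s, kind="rnet_ends", values=lam[s])
        for s in ("+", "-")
    }


def truth_table(truth: list[TruthRecord]):
    """Truth records as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    rows = []
    for rec in truth:
        row = {
            "terminator_id": rec.terminator_id,
            "x_true": rec.x_true,
            "strand": rec.strand,
            "stem_bp": rec.stem_bp,
            "loop_len": rec.loop_len,
            "utract": rec.utract,
            "has_atract": rec.has_atract,
            "has_pause_motif": rec.has_pause_motif,
            "expression_level": rec.expression_level,
            "subpopulation": rec.subpopulation,
            "hairpin_distance": rec.hairpin_distance,
        }
        for strain, rf in rec.release_fraction.items():
            row[f"release_{strain}"] = rf
        rows.append(row)
    return pd.DataFrame(rows)
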