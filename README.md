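# termtk

Identification and factor-dependence analysis of bacterial intrinsic
transcription terminators from 3'-end sequencing data.

## The problem

Intrinsic (Rho-independent) terminators — a GC-rich RNA hairpin followed
immediately by a U-rich tract — release bacterial RNA polymerase at the point
of termination (POT). In *Bacillus subtilis*, the elongation factors NusA and
NusG stimulate termination at most of these "factor-independent" signals.
Quantifying that stimulation genome-wide requires:

1. calling transcript 3' ends from Term-seq / RNA-seq coverage,
2. deciding which 3' ends are intrinsic terminators (hairpin + U-tract),
3. measuring termination efficiency (%T) in wild-type and factor-depleted
   strains and classifying each terminator's factor dependence, and
4. relating termination to NusG-dependent RNA polymerase pausing measured by
   RNET-seq (nascent-transcript 3' ends).

`termtk` implements this pipeline as a tested, reusable library with a thin
CLI, plus a seeded synthetic-data generator that plants terminators with
known anatomy and per-strain release fractions so every stage can be
validated without any sequencing download.

## The statistics

* **Coverage variation.** `C_V(i) = max(0, cov(i) − cov(i+1))` in the
  direction of transcription (mirrored on the minus strand). Local maxima of
  runs with `C_V ≥ 10` are called as 3' ends; the most abundant end within
  ±3 nt represents each region.
* **Termination efficiency.** With `U`/`D` the median coverage over the 10 nt
  upstream `[x−9, x]` / downstream `[x+1, x+10]` of a 3' end,
  `%T = 100·(U − D)/U`.
* **Factor dependence.** `Δ%T = %T_WT − %T_mutant`; *dependent* when
  `Δ%T ≥ 25`, *independent* when `10 ≥ Δ%T ≥ −10`. Dependence across the
  NusA-depletion, ΔnusG and double-mutant strains yields the subpopulations
  Req A, Req G, Req A and G, Req A or G, and SI (strong — `%T_WT ≥ 70` — and
  independent).
* **Pause scoring.** For each terminator `x`, the most abundant RNET-seq 3'
  end in `[x, x+4]` is normalised by the 75th percentile of end counts over
  `[x−150, x+4]`; NusG dependency of the pause is
  `log2(norm_WT / norm_ΔnusG)`, with missing ΔnusG peaks floored at 0.01.
* **Anatomy & motifs.** Single stem-loop hairpin folding with
  nearest-neighbor stacks (Watson-Crick + G-U), the first-U / leading-UU
  U-tract rules, terminal A-U/G-U weak-pair counting with Fisher's exact
  enrichment, the NusG pause register (U at −12, −11, −8, −7, −6), and
  per-position Jensen–Shannon divergence between U-tract logos.

## Worked example

```python
from termtk.synthetic_data import (
    SimulationConfig, generate_genome_with_truth, simulate_tracks, simulate_rnet,
)
from termtk.pipeline import (
    call_strand_ends, screen_terminators, terminator_dataframe, score_nusg_pausing,
)
from termtk.termination_metrics import STRAINS

cfg = SimulationConfig(genome_length=20_000, n_terminators=5, noise="poisson", seed=42)
genome, truth = generate_genome_with_truth(cfg)
tracks = {strain: simulate_tracks(genome, truth, strain, cfg) for strain in STRAINS}

ends = [e for strand in "+-"
        for e in call_strand_ends(tracks["WT"].termseq_ends[strand])]
terminators = screen_terminators(genome, ends, {s: tracks[s].rnaseq for s in STRAINS})
print(terminator_dataframe(terminators)[
    ["coordinate", "strand", "stem_bp", "loop_len", "dG",
     "pT_WT", "dT_dnusG", "category_dnusG", "subpopulation"]
].round(2).to_string(index=False))
```

```
 coordinate strand  stem_bp  loop_len     dG  pT_WT  dT_dnusG category_dnusG subpopulation
       2502      +       11         8 -16.81  89.39     -0.08    independent            SI
       4964      -       10         6 -15.74  78.27     -1.93    independent          ReqA
      11639      -        6         3  -8.07  82.08     52.38      dependent          ReqG
      14899      -        6         8  -9.16  78.34     32.76      dependent      ReqAandG
      18650      -       10         3 -22.62  77.78      2.20    independent       ReqAorG
```

All five planted terminators are recovered at their exact POT; %T estimates
sit within a few points of the planted release fractions (e.g. 89.4 vs a
planted 90 for the SI terminator), and every factor-dependence label matches
the planted subpopulation. Scoring pausing against nascent-end tracks:

```python
rnet = {s: simulate_rnet(genome, truth, s, cfg) for s in ("WT", "dnusG")}
pauses = score_nusg_pausing(genome, terminators, rnet["WT"], rnet["dnusG"])
print(pauses[["coordinate", "offset", "norm_WT", "norm_dnusG",
              "nusg_dependency"]].round(3).to_string(index=False))
```

```
 coordinate  offset  norm_WT  norm_dnusG  nusg_dependency
      11639       0     43.2        12.2            1.824
      14899       3     49.4        11.8            2.066
      18650       4     13.6        12.8            0.087
```

The two pause-motif terminators (Req G and Req A and G) carry a planted 4:1
WT:ΔnusG nascent pileup and score a NusG dependency near `log2 4 = 2`, while
the motif-free terminator scores near 0. The nascent ends sit 0–4 nt
downstream of the steady-state 3' ends, reflecting exonucleolytic trimming
of released transcripts.

The same pipeline is available from the shell:

```bash
termtk simulate --seed 42 --n-terminators 5 --genome-length 20000 --outdir sim/
termtk call-ends --genome sim/genome.fa \
    --termseq sim/termseq_WT_plus.bg sim/termseq_WT_minus.bg --out ends.bed
termtk quantify --genome sim/genome.fa --ends ends.bed \
    --rnaseq WT:+:sim/rnaseq_WT_plus.bg --rnaseq WT:-:sim/rnaseq_WT_minus.bg \
    --rnaseq dnusG:+:sim/rnaseq_dnusG_plus.bg ... --out quartets.tsv
```

## Layout

| module | role |
| --- | --- |
| `termtk.io_formats` | FASTA/bedGraph/BED6 I/O; coordinate and strand conventions |
| `termtk.synthetic_data` | seeded genomes, truth tables and tracks with planted terminators |
| `termtk.end_calling` | C_V landscapes, local-maxima 3'-end calling, region collapse |
| `termtk.terminator_annotation` | hairpin folding, U-tract/A-tract rules, terminator confirmation |
| `termtk.termination_metrics` | %T, Δ%T, dependence categories, dataset matching, group tests |
| `termtk.rnet_integration` | nascent-peak assignment, normalisation, NusG dependency, revision |
| `termtk.motif_stats` | pause-motif register, PFMs, Jensen–Shannon divergence |
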