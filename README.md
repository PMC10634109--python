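# turnover15n

Protein turnover-rate inference from partial ¹⁵N metabolic labeling, for
targeted (PRM) proteomics time-course studies of the kind used to follow
plant growth–defense transitions: seedlings growing in liquid culture are
switched to a heavy-nitrogen medium, and the drift of each peptide's isotope
envelope over the sampling times reports how fast the protein pool is
replaced.

The package is aimed at proteomics researchers who have peptide-level
isotope-envelope (or pre-computed RIA) tables, culture fresh weights, PRM
area-under-curve abundance tables and optionally transcript levels, and want
per-protein synthesis and degradation rate constants with the standard QC
filters, plus the accompanying abundance and transcript statistics.

## Model

After the medium switch, every peptide is a mixture of a pre-existing
("light", natural-abundance) and a newly synthesized ("heavy",
¹⁵N-enriched) molecule population.  The **relative isotopic abundance**

    RIA = ¹⁵N / (¹⁵N + ¹⁴N)

is the heavy fraction of the envelope signal, recovered here by non-negative
least-squares mixture fitting of the two theoretical population envelopes.
Synthesis is zero-order (rate `K_s`, amount·day⁻¹), degradation first-order
(rate constant `K_d`, day⁻¹), and the growing culture dilutes the light pool
at the rate `K_dil` fitted from fresh weights, `A_t = A_0·e^{K_dil·t}`.
Under steady growth,

    K_loss·t = −ln(1 − RIA)          (slope of the incorporation curve)
    K_d      = K_loss − K_dil
    K_s/A    = (FCP − e^{−K_d·t}) / (1 − e^{−K_d·t}) · K_d

with `FCP` the protein-abundance fold change versus 0 h (`e^{K_dil·t}` in
balanced growth; evaluated at t = 2 days).  During the transition into
induced immunity the abundance is no longer growth-balanced and

    K_d·t = −ln(FCP(t)·(1 − RIA(t)))

is used instead, with `FCP(t)` from a quadratic model of the measured median
fold changes at 0, 1, 3 and 16 h.  QC filters: peptide/protein coverage
(≥ 5 time points in one replicate for steady state, ≥ 4 for the transition),
replicate RSTDE ≤ 40%, median regression R² ≥ 0.5, non-negative K_loss for
steady-state conditions, and an FCP responsiveness gate (> 1.5 or < 0.75)
for transition-phase estimates.  Degradation classes: slow (< 0.055 day⁻¹),
intermediate (0.055–0.22), fast (> 0.22).

A seeded virtual-experiment generator (`turnover15n.synthetic`) produces
complete labeling studies — growth curves, peptide RIA/envelope tables,
PRM AUC tables with technical duplicates, transcript tables — with known
ground truth, so the whole pipeline is testable without any instrument data.

## Worked example

The numbered scripts under `analysis/` run a complete virtual study
(40 proteins, 3 replicates, 10% intensity CV, `K_dil` = 0.25 day⁻¹):

```
$ python analysis/01_simulate_experiments.py --seed 1
$ python analysis/02_turnover_rates.py
K_dil: growth 0.256/day, treated window 0.252/day (truth 0.25)
C1: 40/40 proteins pass QC; classes {'fast': 17, 'slow': 13, 'intermediate': 10}
C1 recovery: median relative K_d error 10.0%
C3: 40/40 proteins pass QC
C2: 21/40 proteins pass the FCP gate, 14 pass QC
C2 FCP quadratic fits: mean R^2 0.94
```

The growth-dilution constant is recovered from noisy fresh weights, all 40
proteins pass the steady-state filters, and the median degradation-constant
error at 10% measurement noise is 10%.  In the transition phase only
proteins whose abundance actually moved (past the 1.5/0.75 gate) get rate
constants, and the replicate-consistency filter removes the rest.  The third
script adds abundance statistics:

```
$ python analysis/03_abundance_transcripts.py
t tests vs 0 h: 158/240 protein-time contrasts significant
permutation FDR on K_d (C3 vs C1): 17/40 proteins change significantly (cutoff |d| >= 1.52)
FCP profile clusters (k=2): sizes {2: 25, 1: 15}
transcript-protein correlation at    0 h: R^2 = 0.44 (slope +)
transcript-protein correlation at   16 h: R^2 = 0.39 (slope +)
```

The transcript–protein correlation is strongest in the growth state and
degrades as treatment decouples the two — the behavior the statistics are
designed to quantify.

The same steps are available as a CLI (`turnover15n simulate | ria |
turnover | abundance | validate | all`) and as one orchestrated run,
`turnover15n.pipeline.run_pipeline(RunConfig(...))`, which writes every
table plus a manifest recording the config hash and per-stage attrition.

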