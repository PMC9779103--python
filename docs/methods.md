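# Methods

## Data model

An experiment is a catalogue of proteins (accession, monomer MW in kDa,
optional sequence) plus an ordered list of SEC fractions, each carrying
its calibrated mean MW and the emPAI of every protein identified in it.
Fractions are stored in elution order, i.e. strictly decreasing mean MW;
elution profiles are read out on the ascending MW grid. All MWs are kDa;
values that look like daltons are rejected unless the manifest declares
`# units: Da`, because a silent Da/kDa mixup is the dominant practical
failure mode for this kind of input.

Column calibration is a least-squares fit of log10(MW/kDa) against
elution volume — the standard log-linear SEC behaviour. The slope must be
negative (larger species elute earlier); predictions outside the
standards' volume span are flagged as extrapolations. Sequence-derived
MWs use average (not monoisotopic) residue masses plus one water; a
declared MW disagreeing with the sequence by more than 1% is an error,
never silently overridden.

## Dimer hypothesis generation

Stage 1 enumerates, per fraction, every unordered pair (self-pairs
included, at twice the monomer MW) whose MW sum falls within
±`tolerance` (default 0.10) of the fraction mean. The window is closed at
both edges: a sum of exactly 40.5 or 49.5 kDa in a 45-kDa fraction
passes. The edges are computed as `M ± t·M` so the canonical example is
exact in floating point. Stage 2 keeps pairs whose emPAI quotient
(larger/smaller) is ≤ `ratio_max` (default 1.5, inclusive, since the rule
is "does not exceed"). Homodimers get quotient 1 by definition; a pair in
which either member has zero emPAI has an undefined quotient and fails
stage 2 — the filter's premise is comparable quantification of both
members. Output order is deterministic (|deviation| then accession pair),
so runs are diffable. No multiple-testing correction is applied: list #2
is a hypothesis list for downstream verification, not a set of
statistical calls. Higher-order (trimer+) enumeration is out of scope —
its redundancy grows combinatorially and the binary case is what
in-vitro verification can realistically consume.

The per-experiment report carries the list #2 / list #1 retention ratio.
On real lysate data this is typically around 10%; on synthetic data it
depends on the background abundance spread, so the package reports it and
does not assert it.

## Oligomeric-state taxonomy

The size class of one observation is `k = round(M_fraction / MW_protein)`
with ties rounding half up: k = 1 monomer, k = 2 dimer, k ≥ 3 oligomer.
`r < 0.5` (protein heavier than its fraction) is anomalous — consistent
with proteolytic fragments or high-adhesion species — and is recorded in
the evidence but excluded from typing. Rounding to the nearest integer
stoichiometry is our rule choice; it reproduces all the exemplar
monomer/dimer/oligomer placements on the standard fraction grids. The
class set maps to types I–VI exactly as listed in the README; any other
non-empty set (e.g. dimer + oligomer without monomer) is reported as
OTHER with its raw class set, never coerced.

Presence uses a relative threshold: a fraction counts only if its
abundance reaches `rel_threshold` (default 0.10) of the protein's own
maximum, suppressing trace carry-over. This is the main sensitivity knob:
raising it can only prune classes (monotone), never add them, and the
classification is invariant to uniform rescaling of a profile. A single
profile cannot distinguish homo- from heterodimers; heterodimer identity
comes from the dimer module.

The taxonomy summary reports per-type counts and percentages over typed
proteins, and the coarse split used in interactome surveys: multimeric
(types III/V/VI), dimeric (II/IV), monomer-only (I). OTHER is counted
separately and excluded from the three groups.

## Co-elution similarity

Similarity is the Pearson correlation of two profiles restricted to the
union of their presence (nonzero) fractions, so the many fractions where
both proteins are absent do not inflate the score; a full-grid mode is
available. The correlation is undefined — reported as such, not dropped —
when fewer than 3 support points remain or either restricted vector is
constant; `min_shared` defaults to 3 for the same reason. Candidates are
ranked by similarity with undefined values last and lexicographic
tie-breaks. Pearson is the field's default profile-similarity metric; the
choice is ours, made once. Co-occurrence alone is weak evidence, which is
why each score also carries the MW-sum fraction match.

## Synthetic lysate generator

The simulator emulates a whole-lysate SEC run under realistic study
conditions, which are its defaults:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 500 | catalogue size |
| `mw_median_kda` | 42 | lognormal monomer-MW median (typical proteome average) |
| `mw_sigma_log` | 0.5 | natural-log sigma; central 68% ≈ 25–69 kDa |
| grid | 22 fractions, 15–700 kDa log-spaced | fraction mean MWs |
| `elution_sigma` | 0.05 | Gaussian elution spread, log10-MW units |
| `empai_noise_cv` | 0.10 | CV of multiplicative lognormal emPAI noise |
| `free_fraction` | 0.30 | share of each complexed protein left monomeric |
| `abundance_sigma_log` | 1.0 | lognormal spread of background abundances |
| `planted_abundance` | 1.0 | molar abundance of each planted assembly |
| `min_empai` | 0.01 | detection floor |

Assemblies are the planted complexes (at fixed molar abundance, so
planted heterodimers are equimolar by construction) plus free monomers:
the `free_fraction` share of each complexed protein and the full
lognormal abundance of every unplanted protein. Each assembly elutes as a
Gaussian in log10-MW centred at its total MW, truncated to the grid and
renormalised so abundance is conserved exactly (with `elution_sigma` = 0
the kernel degenerates to the nearest fraction). A protein's emPAI per
fraction is the multiplicity-weighted sum of its assemblies'
contributions times lognormal noise with unit mean; values below
`min_empai` are unobserved. The grid's log-spacing ratio (≈1.20) is
smaller than the width of the ±10% window (1.1/0.9 ≈ 1.22), so any
assembly MW inside the column range falls within some fraction's window —
planted dimers are recoverable wherever their MW lands.

Ground truth (assembly compositions, MWs, abundances, and each protein's
expected state type computed from the noiseless, detection-floored
signal) is emitted before noise. Recovery scoring treats a planted binary
complex as found if its pair reaches list #2 in any fraction; precision
counts any non-planted list #2 pair as false — on a dense background it
is deliberately low, since stage 2 is a redundancy filter, not a
classifier.

What the generator does *not* emulate: peptide-level identification (emPAI
is drawn directly, not via peptide counts), peak tailing or adhesion
artefacts, shared peptides / protein inference, proteoforms, and
correlated noise across fractions. Passing recovery tests therefore shows
the pipeline's logic is sound under idealised elution and independent
multiplicative noise, not that real lysate data will reach the same
recall.

## Numerical and scale choices

Tests and the worked examples run at deliberately small problem sizes
(tens to hundreds of proteins, 20 seeds for stochastic checks), which the
package treats as its standard benchmark scale. The published retention
(~10%) and interactome-split (65/25/10) figures stem from specific liver
lysate datasets and are not reproducible from synthetic data; the package
computes and reports the same quantities, and the summary arithmetic is
verified on constructed inputs. The packaged reference distribution
matrix carries one internal inconsistency in its source: the 90-kDa
column's printed entries sum to 308, not the printed total 307; the
matrix builder counts what is present (308). Ties in stoichiometry
rounding go half up; window and quotient thresholds are inclusive; all
orderings are deterministic.
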