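# cofrac

Interpretation of size-exclusion-chromatography (SEC) co-fractionation
proteomics data: generation and filtering of dimeric protein-complex
hypotheses, classification of each protein's oligomeric state from its
elution profile, per-fraction molecular-weight distribution matrices, and
co-elution-based partner ranking — plus a forward simulator of whole-lysate
SEC runs with planted complexes for benchmarking.

## The problem

When a tissue or cell lysate is fractionated on an SEC column, stable
protein complexes survive and elute at the molecular weight (MW) of the
whole assembly, not of their subunits. LC-MS/MS identification of each
fraction therefore yields, for every protein, an *elution profile* —
abundance (emPAI) as a function of the fraction's calibrated mean MW. A
37-kDa protein showing up in a 150-kDa fraction is evidence that it is
part of a complex. `cofrac` is for proteomics groups who have such
per-fraction identification tables and want to turn them into testable
protein–protein interaction hypotheses.

## The core method

**Two-stage dimer hypothesis generation.** For a fraction with mean MW
*M*, stage 1 enumerates all unordered protein pairs (i, j), homodimers
included, whose summed monomer MW satisfies

    (1 − t)·M ≤ MWᵢ + MWⱼ ≤ (1 + t)·M,        t = 0.10 by default,

giving *list #1* (for *M* = 45 kDa this window is 40.5–49.5 kDa). Stage 2
keeps only pairs with comparable abundance: with emPAI = 10^(observed /
observable peptides) − 1, the quotient max(eᵢ,eⱼ)/min(eᵢ,eⱼ) must not
exceed 1.5 — subunits of an equimolar dimer should be present in
near-equal amounts. Survivors form *list #2*, the hypotheses worth
downstream verification.

**Oligomeric-state taxonomy.** For each fraction where a protein of
monomer MW *p* passes a presence threshold (10% of its own peak by
default), the apparent stoichiometry *r* = *M*/*p* is rounded to an
integer *k*: monomer (*k* = 1), dimer (*k* = 2), oligomer (*k* ≥ 3), or
anomalous (*r* < 0.5, heavier than the fraction — likely a fragment or a
high-adhesion protein). The set of classes across fractions maps to six
state types: I monomer-only, II dimeric, III oligomeric, IV = I+II,
V = I+III, VI = I+II+III.

**Partner ranking.** Candidate partners of a target are proteins sharing
≥ 3 presence fractions with it, ranked by the Pearson correlation of
their profiles on the union of their presence fractions, annotated with
the fraction (if any) whose mean MW matches the pair's summed MW.

## Worked example

```python
from cofrac import (DimersConfig, FractionObservation, FractionTable,
                    ProteinRecord, filter_list2, generate_list1)

proteins = {"X": ProteinRecord("X", 20.0), "Y": ProteinRecord("Y", 25.0),
            "Z": ProteinRecord("Z", 24.5), "W": ProteinRecord("W", 60.0)}
fraction = FractionTable("F45", 45.0, (
    FractionObservation("X", empai=1.4), FractionObservation("Y", empai=1.0),
    FractionObservation("Z", empai=4.0), FractionObservation("W", empai=0.5)))

list1 = generate_list1(fraction, proteins, DimersConfig())
list2 = filter_list2(list1, fraction, DimersConfig())
```

Running `python examples/01_dimer_hypotheses.py` prints:

```
MW acceptance window for a 45-kDa fraction: 40.5-49.5 kDa

list #1 (4 MW-compatible pairs):
  X+Y  sum  45.0 kDa  deviation +0.0%
  X+Z  sum  44.5 kDa  deviation -1.1%
  Z+Z  sum  49.0 kDa  deviation +8.9%
  Y+Z  sum  49.5 kDa  deviation +10.0%

list #2 (2 pairs also passing the emPAI quotient <= 1.5):
  X+Y  emPAI 1.4/1  quotient 1.40
  Z+Z  emPAI 4/4  quotient 1.00
```

Four pairs fit the 40.5–49.5 kDa window; the abundance filter keeps X+Y
(quotient 1.4 ≤ 1.5) and the Z homodimer (quotient 1 by definition) while
rejecting X+Z and Y+Z, whose members differ ~3–4-fold in emPAI. The other
scripts in `examples/` walk through state classification, the
distribution matrix, simulation with planted complexes (10/10 planted
dimers recovered at default noise), and partner ranking.

## Command line

```bash
cofrac simulate --seed 7 --out run/          # synthetic lysate + ground truth
cofrac dimers   --experiment run/manifest.tsv --out dimers.tsv
cofrac classify --experiment run/manifest.tsv --out states.tsv
cofrac matrix   --experiment run/manifest.tsv --out matrix.tsv
cofrac profile  --experiment run/manifest.tsv --target SIM0000 --out partners.tsv
```

Input formats (tab-separated, `#` comments) are documented in
`cofrac/io.py`.

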