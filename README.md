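# msiedit

Quantitative analysis of coding-microsatellite (cMS) mutations in
mismatch-repair-deficient (MSI) cancers: stutter-corrected indel allele
quantification from fragment-length peak profiles, frameshift-peptide
construction, population-weighted immunogenicity scores, and the
statistics needed to test for tumor immunoediting.

## The problem

PCR amplification of a mononucleotide repeat produces stutter bands —
fragments one or more bases shorter (rarely longer) than the template —
that look exactly like the somatic indels MSI tumors accumulate at cMS.
An observed capillary-electrophoresis profile is therefore a mixture of
true allele signal and amplification artifact. `msiedit` separates the
two with a regression approach:

1. On MMR-proficient controls, the main-band fraction is fitted as a
   logistic function of repeat length, `p(L) = 1/(1+exp(a(L−b)))`, and a
   per-locus reference stutter shape `p_ref(δ)` is measured.
2. Each locus is anchored to its control behaviour through an effective
   length `L_eff = p⁻¹(p_ref(0))`; a true allele with indel Δ keeps the
   fraction `p_effective(Δ) = p(L_eff+Δ)` of its signal in its own band
   and spreads the rest over neighbours in proportion to the control
   stutter shape, giving a 9×9 column-stochastic operator `C` over the
   offset window Δ ∈ [−4,+4].
3. True allele fractions solve `argmin ‖C p − p_obs‖₂` subject to
   `0 ≤ p ≤ 1`, renormalized to the simplex.

Indels are pooled by reading frame (Δ mod 3: M0 in-frame, M1 from 1-bp
deletions/2-bp insertions, M2 from 2-bp deletions/1-bp insertions),
tumors are called wild-type / mutant / biallelic at 15% and 50% allele
fraction, and cohorts are summarized with explicit missing-data
handling.

Downstream, each cMS yields M1/M2 frameshift peptides (8 wild-type
residues of upstream context + the neo-sequence to the first stop), and
MHC-binding predictions are aggregated into a score hierarchy:

- `ELS_H(n) = (1−(1−f_H)²)·(1−(1−p_binding)^|E_H(n)|)` — probability
  that a random individual carries HLA allele H and the peptide has at
  least one true binder among its `|E_H(n)|` predicted epitopes,
- `GELS_X(n) = 1 − ∏_H (1−ELS_H(n))` over the HLA-A / HLA-B supertype
  panels, combined as `GELS = GELS_A + GELS_B − GELS_A·GELS_B`,
- `IRS(n) = p_mut(n) · GELS(n)`.

The immunoediting layer correlates GELS with per-cMS mutation frequency
(Pearson r with Fisher-z confidence intervals), stratified by B2M and
HLA-A\*02:01 status, with repeat-length adjustment, exact binomial tests
for M1/M2 frame bias, Ward clustering of frame-abundance features and
RBF kernel-PCA embeddings. A seeded synthetic-data module generates
peak profiles, cohorts with a planted editing signal of calibrated
strength, and prediction tables, so every stage is testable end to end.

## Worked example

`examples/04_immunoediting_recovery.py` simulates 100 tumors over a
41-candidate panel with an editing strength calibrated to plant a
candidate-level GELS–mutation correlation of −0.4, then tests for it:

```
calibrated editing strength beta = 4.49 (planted candidate-level r = -0.400)
  b2m_wt : r=-0.423 [-0.646, -0.133], p=0.00587, n=41 (b2m_wt)
  b2m_mut: r=+0.003 [-0.305, +0.311], p=0.984, n=41 (b2m_mut)
  all    : r=-0.323 [-0.574, -0.017], p=0.0392, n=41 (all)
```

The significant inverse correlation appears only among B2M-wild-type
tumors — immunoediting acts through HLA class I presentation, which
B2M-mutant tumors have lost — exactly the planted structure. The other
examples show single-profile deconvolution (`01`), frameshift-peptide
construction (`02`) and the score hierarchy (`03`).

A command-line interface mirrors the pipeline:

```bash
msiedit simulate --seed 1 --outdir sim/
msiedit reframe --peaks sim/peaks.tsv --controls sim/controls.tsv \
                --loci sim/loci.tsv --out alleles.tsv
msiedit score   --ic50 preds.tsv --hla-freq freq.csv \
                --pbinding 0.5 --threshold 500 --out scores.tsv
msiedit editing --alleles alleles.tsv --annotations sim/annotations.tsv \
                --scores scores.tsv --out report.tsv
```

File formats (peak tables, locus catalogs, annotation tables, generic
and NetMHCpan-style prediction tables, HLA frequency CSVs) are
documented in the corresponding module docstrings.

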