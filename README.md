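# acylquin

A Python toolkit for identifying **malonyl-acyl-quinic acids** and **flavonoid
malonyl-glucosides** from LC-MS/MS and NMR evidence.

Quinic acid (1,3,4,5-tetrahydroxycyclohexanecarboxylic acid) esterified with
two caffeic and one malonic acid can form twelve regioisomeric
malonyl-dicaffeoylquinic acids (MDiCQAs), all sharing the molecular formula
C₂₈H₂₆O₁₅ and — because collision-induced dissociation (CID) only strips whole
residues — the same fragment *m/z* set. Telling them apart without authentic
standards requires three orthogonal keys, all implemented here:

1. **Exact mass and neutral-loss grammar.** Deprotonated ions ([M−H]⁻,
   electron mass included) are computed from pinned monoisotopic masses; the
   fragment tree applies the losses malonyl residue (C₃H₂O₃, 86.0004 Da),
   caffeoyl residue (C₉H₆O₃, 162.0317 Da), glucosyl residue (C₆H₁₀O₅,
   162.0528 Da, only after demalonylation of the sugar), CO₂ and H₂O, and
   reproduces the observed series *m/z* 601 → 557/515/439/395/377/353/233 and
   the terminal ions 191/179/173.
2. **Two-stage CID intensity key.** At 25 eV the total-ion-current (TIC)
   fractions of *m/z* 233 and 395 separate three groups (233 ≈ 70% → isomer
   group {4,7}; 395 ≈ 35% with 233 in traces → compound 5; both comparably
   high → compound 6). At 45 eV the ratio R = I(173)/I(233) splits the
   remaining pair: R ≈ 1.3 → compound 7, R ≈ 0.3 → compound 4.
3. **NMR coupling-constant key.** In DMSO-d₆ the largest H-4 coupling (the
   trans-diaxial ³J₄,₅ candidate) reads the core stereochemistry: ≥ 8.3 Hz →
   quinic, < 8 Hz → *epi*-quinic, with an explicit indeterminate gap. A D₂O
   re-measurement must *increase* the diagnostic coupling (conformational
   shift), and an anomeric doublet ≥ 7 Hz certifies a β-glucoside.

Around these sit supporting stages: detection of **in-source catechol
oxidation** satellites (−2H/−4H per catechol, eluent-pH dependent), 4PL
**IC50 fitting** for radical-scavenging and viability assays, catechol-based
activity flagging, organ × phase **tissue-abundance summaries**, and seeded
**synthetic-data generators** so the whole pipeline is testable offline.

## Worked example

Enumerate the MDiCQA regioisomers — all twelve share one formula and one
[M−H]⁻ *m/z*:

```text
$ acylquin enumerate --caffeoyl 2 --malonyl 1
QA[1:caf,3:caf,4:mal]  C28H26O15  [M-H]- 601.1199
QA[1:caf,3:caf,5:mal]  C28H26O15  [M-H]- 601.1199
QA[1:caf,3:mal,4:caf]  C28H26O15  [M-H]- 601.1199
QA[1:caf,3:mal,5:caf]  C28H26O15  [M-H]- 601.1199
...
total: 12 regioisomers
```

Simulate a noisy 25/45 eV spectrum pair of isomer 7 (5% intensity CV, 3 ppm
jitter) and run the decision key:

```text
$ acylquin simulate msms --isomer cpd7 --cv 0.05 --jitter-ppm 3 --seed 7 --out cpd7.mgf
$ acylquin classify --mgf cpd7.mgf
[
  {
    "title": "cpd7 25eV",
    "label": "cpd7",
    "confidence": "high",
    "I233": 0.6899,
    "I395": 0.0211,
    "stage2_ratio": 1.2657
  }
]
```

Reading the output: at 25 eV the *m/z* 233 ion carries 69% of the TIC with
*m/z* 395 in traces, placing the spectrum in the {4,7} group; the 45 eV ratio
I(173)/I(233) = 1.27 (≥ 0.7) resolves it to compound 7, and every rule fired
with ≥ 20% margin, hence high confidence.

The same commands expose the other stages: `acylquin mass C28H26O15` prints
`m/z 601.1199`, `acylquin oxidation` classifies −2H/−4H satellite series,
`acylquin nmr-key` applies the coupling-constant rules, `acylquin ic50` fits
dose-response curves and `acylquin run` executes the full per-precursor
pipeline on an MGF file. The `acylquin` Python package offers all of this as
a library (`from acylquin import classify, generate_fragments, ...`).

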