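# Methods

This note documents the models, rules and numerical choices behind
`acylquin`, and what its synthetic-data generators do and do not emulate.

## Mass model

Ion *m/z* values are computed from pinned monoisotopic masses of the most
abundant isotopes (IUPAC 2021; C 12 exactly, H 1.00782503207,
O 15.99491461957, N and S available) so results are bit-stable with no
runtime dependency. Singly charged (de)protonated species only:
[M−H]⁻ = M − m(H) + m(e⁻) and [M+H]⁺ = M + m(H) − m(e⁻), with the electron
mass (0.000548580 Da) included — omitting it shifts fourth-decimal values
(e.g. 601.1193 instead of 601.1199 for deprotonated C₂₈H₂₆O₁₅). Reported
*m/z* uses round-half-up: full precision internally, 4 decimals in reports,
nearest integer for nominal *m/z*. Average masses, isotope patterns and
adducts other than ±H are out of scope.

## Structure model

Acyl-quinates are a core label ({quinic, *epi*-quinic} — stereochemistry is
metadata for the NMR key, never a formula term) plus an acyl map over
hydroxyl positions {1, 3, 4, 5}; each ester condenses out one H₂O. The C-1
carboxyl is never esterified by another acid, but the C-1 hydroxyl is
acylatable, matching the known 1-acyl compounds. Flavonoid glycosides are an
aglycone (quercetin C₁₅H₁₀O₇; luteolin/kaempferol C₁₅H₁₀O₆), one β-glucosyl
unit at position 3 or 7, and 0–2 malonyl esters at the sugar 2″/6″ hydroxyls.
Regioisomer enumeration is exhaustive over the four quinate positions
(multinomial 4!/(a!·b!·(4−a−b)!); 12 for two caffeoyl + one malonyl) and
deliberately does not count core epimers as a separate dimension — the
epimer flag multiplies, it does not interact with regiochemistry.

Catechol counting: one per caffeoyl ester; one for a quercetin or luteolin B
ring; zero for kaempferol. This single integer drives both the oxidation
series bound and the radical-scavenging activity flag.

## Fragmentation grammar

Negative-mode CID is modelled as sequential whole-residue eliminations with
per-molecule budgets: one malonyl residue (C₃H₂O₃, 86.0004 Da — the
ketene-type ester cleavage; the 104 Da malonic-acid loss is never generated)
per malonyl ester, one caffeoyl residue (C₉H₆O₃) per caffeoyl ester, one
glucosyl residue (C₆H₁₀O₅) per glycosidic bond *after* all sugar malonyls
are lost (demalonylation-first, matching the observed 619 → 533 → 447
series), one CO₂ from the free carboxyl (acyl-quinates only) and one H₂O.
Trees are expanded breadth-first to a depth limit and deduplicated by
remaining formula, so alternative elimination orders of the same residues
collapse; an exhaustive enumeration over admissible loss multisets
reproduces the grammar output exactly (tested). Where the mechanism is
ambiguous (e.g. whether H₂O loss may precede CO₂ loss en route to *m/z*
233), the grammar permits both orders and lets deduplication absorb the
difference — this is a bookkeeping stance, not a mechanistic claim.

Terminal marker ions of acyl-quinates (deprotonated quinic acid 191, caffeic
acid 179, dehydrated quinic acid 173) are appended at any depth ≥ 1; they
are tagged `terminal:` and exempt from the path-mass conservation invariant
that grammar nodes satisfy to 10⁻⁶ Da.

Annotation matches each observed peak to the nearest theoretical node within
a ppm tolerance (default 5 ppm, Orbitrap-class); `explain_loss` searches
multisets of ≤ 3 losses against a precursor–fragment delta within 10 mDa.
Positive mode is supported only for precursor/aglycone masses — positive
fragment trees are out of scope. Intensity prediction from structure is
explicitly not attempted; intensities enter only through the decision key.

## Oxidation flagging

Each catechol can lose two hydrogens in the source, so satellites are
searched at base − k × 2.01565 Da (exact 2×H, not nominal 2 Da; default
tolerance 10 ppm) for k up to the catechol count. One position beyond the
budget is probed solely to raise an anomaly flag — a satellite the structure
cannot explain is never claimed as oxidation (it may be an isotope artifact).
A missing base peak is an error distinct from "no satellites". Dominant-state
ties resolve to the lower oxidation state with a tie flag. The module does
not deconvolve −2H satellites from M−2 isotope envelopes (documented
limitation) and does not model the redox chemistry; eluent dependence enters
only through generator presets (below).

## The two-stage isomer key

Intensities are **fractions of TIC** (base-peak normalisation is not used),
summed over peaks rounding to the nominal key ion. Thresholds:

* trace = 0.05 of TIC — separates the printed 1–2% trace levels from the
  ≥ 20% diagnostic signals;
* stage 1: I233 ≥ 0.5 with I395 trace → group {4,7}; I395 ≥ 0.25 with I233
  trace → compound 5; both ≥ 0.2 with 0.5 ≤ I233/I395 ≤ 2 ("comparably
  high") → compound 6; else inconclusive;
* stage 2 (45 eV): R = I(173)/I(233); R ≥ 0.7 → compound 7, R ≤ 0.5 →
  compound 4. The reference ratios are 1.3 and 0.3; a dead band around
  their geometric midpoint (≈ 0.62) avoids overclaiming near the boundary.

Confidence is `high` only when every fired rule cleared its threshold by
≥ 20%; an unrefined group call is always `low`. Because every rule is a
ratio of TIC fractions, verdicts are invariant to the intensity unit and to
common scaling. The key does not address the eight regioisomers never
isolated, positive-mode spectra, or co-eluting isomer mixtures (coelution is
a chromatographic problem).

## NMR keys

Input is extracted coupling constants, not raw FIDs. Core rule (DMSO-d₆,
largest H-4 coupling): ≥ 8.3 Hz → quinic, < 8.0 Hz → *epi*-quinic,
[8.0, 8.3) → indeterminate. The quinic floor sits at the smallest coupling
actually observed on a confirmed quinic core (8.3 Hz); the gap below it is
unobserved territory that forces human review rather than a guess. The
solvent-shift check requires the diagnostic coupling to increase in D₂O
(³J₄,₅ for quinic, ³J₃,₄ for *epi*-quinic cores), consistent with the
conformational-equilibrium shift; it is a consistency check only, never the
assignment. The β-anomeric floor of 7.0 Hz covers the observed 7.3–8.1 Hz
doublets with margin below the smallest. Chemical-shift interpretation,
Karplus fitting and absolute configuration are out of scope.

## Dose-response fitting

The four-parameter logistic f(d) = bottom + (top−bottom)/(1 + (IC50/d)^hill)
is fitted by least squares in log-IC50 parameterisation (positivity
implicit, near-quadratic likelihood), with data-driven starting values and
wide bounds ([−50, 150]% plateaus, hill ∈ [0.05, 10]). Rising (% inhibition)
and falling (% viability) curves share the machinery via a direction flag.
At least five dose levels are required; curves never reaching 50% effect
return `censored_above_max`; non-convergence returns `failed` with the
solver message. `se_ic50` is the delta-method transform of the asymptotic
log-IC50 standard error. A log-linear interpolation crossing at 50% is
provided as a model-free cross-check, never the default. Whether a reported
± is SD or SEM in external data is the data provider's concern; the fitter
reports standard errors.

Tissue summaries are plain groupby means per organ × phase with the argmax
record and the fold difference between extreme positive organ means; they
operate on any conforming table and make no attempt to reproduce any
particular survey.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

* **MS/MS templates** encode the study conditions of the key: 25 eV —
  {4,7}: I233 = 0.70 with I395 = 0.02; 5: I395 = 0.35, I233 = 0.01; 6:
  I233 = 0.35, I395 = 0.30; 45 eV — 7: I173/I233 = 0.40/0.30; 4: 0.08/0.30.
  Residual template mass is spread uniformly over the co-occurring
  background fragments (557/515/439/377/353/191/179) because their true
  energy-dependent proportions are not modelled. Noise: Gaussian *m/z*
  jitter (ppm), lognormal intensity scatter (unit-mean, given CV), and
  uniform decoy peaks over [150, precursor] kept ≥ 0.5 Da from the key ions
  so robustness measurements isolate intensity noise.
* **MS1 oxidation presets** give relative member intensities (state
  0/−2H/−4H): 0.1% formic acid 100/60/7.5 (satellite midpoints of the
  observed 30–90% and 5–10% ranges — a modelling choice, since per-compound
  values are unavailable); water-only 10/30/100 (doubly oxidized dominant);
  0.3% formic acid 100/15/2 (suppressed). Satellites are truncated at the
  structure's catechol count.
* **Dose-response curves** draw Gaussian noise around the 4PL closed form;
  the default design is eight three-fold dose steps centred on the true IC50
  with four parallel measurements per level — the replication scheme of the
  assays emulated. (With a single well per level the asymptotic standard
  error rests on 4 residual degrees of freedom and its ±2·se interval
  under-covers; that is a property of the design, not the fitter.)
* **Tissue tables** draw lognormal records (unit-mean scaling) around
  organ × phase cell means.

What the generators do **not** emulate: chromatographic peak shapes and
retention times, isotope envelopes, intermediate CID energies between 25 and
45 eV, correlated inter-well noise, and real biological organ contrasts.
Passing tests therefore demonstrate the correctness and robustness of the
decision logic under the stated noise model, not instrument-level
performance on real extracts.

## Problem sizes

The test suite measures key-ion classification accuracy over 1000 labeled
spectrum pairs (250 seeds × 4 isomers at 5% CV, 3 ppm jitter, 5 decoys) and
IC50 recovery over 200 simulated curves per condition (hill ∈ {0.8, 1, 2},
σ ∈ {1, 3}% subsets); both finish in seconds and their measured quantities
(accuracy ≥ 95%, |bias of log IC50| < 0.02, ≥ 90% coverage of ±2·se) are
asserted by the acceptance tests.

## Known limitations

* The fragment grammar predicts which ions exist, never their intensities.
* The −2H oxidation satellite is indistinguishable from an M−2 isotope
  contribution at this resolution model.
* The isomer-key thresholds encode the printed single-compound percentages;
  a full intensity matrix across CID energies would allow re-derived,
  tighter thresholds.
* Core-epimer combinatorics beyond the quinic/epi-quinic flag are not
  enumerated.
* The CLI reads MGF and CSV only; mzML support would go through pyteomics
  the same way.
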