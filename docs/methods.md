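# Methods

This note documents the models, parameters and design decisions behind
`neomhc`, in the spirit of a methods supplement: what is computed, under
which assumptions, and what the synthetic test substrate does and does
not show about real data.

## Variant filtering

A somatic SNV enters the pipeline with per-caller status (five callers),
tumor-DNA allele fraction, alt-supporting read counts split by mate
(read 1 vs read 2), RNA-seq depth/alt/spanning counts and a gene-level
expression value. Three pure stages are applied in order, and a variant's
verdict names the first failing stage:

1. **Consensus.** Most somatic callers are DNA-centric, so a variant is
   allowed through if at most `max_caller_rejects = 2` of the reporting
   callers rejected it. Callers with no opinion are not counted as
   rejections; a variant with no caller evidence at all is an error.
2. **Artifact (OxoG).** Library-preparation oxidation of guanine produces
   low-allele-fraction C>A / G>T calls supported predominantly by one
   read of the pair. Two clauses: (a) alt support solely from read 1 or
   solely from read 2 → dropped; (b) allele fraction strictly below 0.1
   with zero RNA alt reads → dropped. Clause (a) is applied to *all*
   substitution classes — the chemistry motivates the filter but the rule
   is stated generally — and the verdict annotates whether the change is
   OxoG-consistent (C>A/G>T). "No RNA-seq coverage" in clause (b) is read
   strictly as "no ALT-supporting RNA reads".
3. **Expression.** Unexpressed proteins cannot be displayed: dropped when
   gene expression ≤ 0 (threshold configurable; the expression metric is
   caller-defined), when RNA reads span but none cover the position
   (splice variant), or when the ALT allele has no RNA evidence.

## Peptide windowing

A missense change at protein position p is expanded, per epitope length
n ∈ {9, 10, 15}, into the 2n−1 residues centred on p; protein termini
truncate the context rather than discarding the candidate (this keeps
epitopes near chain ends; the alternative would silently lose them).
Every length-n substring containing the mutation is a candidate — exactly
n of them for an untruncated context. Each is paired with its self
counterpart (the reference residues at the same coordinates), which by
construction differs at exactly one position. Identical peptides arising
from several transcripts are merged with their origins unioned. 15-mers
(class II length) are windowed but only scored if a predictor for them is
plugged in.

## Binding calls and IARs

The predictor interface takes (peptide, allele) and returns a percentile
rank: 100 × the fraction of a background score set that is *strictly
better*, so 0 is the best possible peptide and lower is stronger. Calls
with rank > 5.0 are discarded (the boundary value 5.0 is kept, a literal
reading of "greater than 5%"). Self peptides are scored with the
identical predictor and background; a mutant that scores worse than its
self counterpart is retained but flagged, since tolerance makes it a poor
target.

The bundled `PSSMScorer` is a seeded position-specific scoring model:
log-odds matrices drawn deterministically per (allele, length) with
anchor positions (2 and the C terminus) given a three-fold score spread,
calibrated against 100 000 random peptides drawn from uniform residue
frequencies. It makes the pipeline runnable and testable end to end but
is **not** a trained predictor: its percentile values carry no
immunological meaning, and real predictor output can be substituted as a
(peptide, allele, percentile) table via `TablePredictor`.

Kept calls are grouped by (mutation, transcript set) into ImmunoActive
Regions. Per IAR: best contained rank, transcript expression, promiscuity
(distinct alleles with a contained binder), and the number of 10-mers
overlapping a 9-mer bound to the same allele at similar affinity
(|Δrank| ≤ 2 percentile points by default; the notion of "similar" is not
standardised, so it is configurable). The composite ranking is a weighted
sum — w·(1 − best_rank/100) plus min–max-normalised expression,
promiscuity and overlap with default weights (0.4, 0.3, 0.2, 0.1) — with
deterministic ties by mutation id. The weighting is a design choice, not
an established constant; all four weights are configurable.

## Threading protocol

* **Trim.** The template complex keeps the peptide chain plus heavy-chain
  residues numbered ≤ 180, the conventional end of the α1/α2 platform;
  β2-microglobulin and the α3 domain are removed.
* **Groove.** Heavy-chain residues with any heavy atom within 3.5 Å of
  any peptide atom.
* **Threading.** The target allele sequence is globally aligned to the
  template heavy chain (BLOSUM62, gap open/extend 11/1, via
  `Bio.Align.PairwiseAligner`). Matched positions keep the template side
  chain; mismatches are rebuilt from the most probable rotamer of the new
  residue type on the fixed backbone; an alignment gap at a groove
  position rejects the allele (modelling across groove indels would
  require backbone remodelling, which is out of scope).
* **Repacking.** Metropolis simulated annealing over the discrete
  rotamers of groove + peptide side chains, backbone fixed. Candidate 0
  of every repackable residue is its current side chain; rotamer priors
  enter the objective as −0.3·log p. Geometric cooling from T = 5 to 0.2
  over max(15, 4 × residues) sweeps, followed by a deterministic greedy
  coordinate-descent polish; the best state visited is returned, so the
  final objective never exceeds the initial one. All randomness flows
  from an explicit seed; trajectories are bit-reproducible. Interaction
  tables (rotamer-vs-environment and rotamer-vs-rotamer) are precomputed
  once per threaded model and shared across the model pool.
* **Scoring.** ΔE = E(complex) − E(MHC) − E(peptide) with the unbound
  parts *frozen* in their bound coordinates (no separate relaxation —
  simpler, and stated explicitly since either convention is defensible).
  The per-residue map assigns half of each pair term to each participant
  and burial penalties to the owning residue, so it sums to ΔE exactly.
* **Screen.** Per allele, `n_models = 100` independently seeded repack
  trajectories; the mean ΔE of the `top_k = 10` lowest is reported. The
  polyAla control replaces every groove residue — including Gly and
  Pro — with Ala.

### Energy model

A simplified physics score in arbitrary model energy units; it is not a
calibrated force field and no absolute energy is ever interpreted — only
orderings (native vs polyAla, neoepitope vs self) are used, and the test
suite asserts exactly those. Terms: softened 12-6 Lennard-Jones on
element vdW radii (distances clamped below 0.55·r₀ so overlapping atoms
stay finite); a −1 hydrogen-bond bonus for donor/acceptor heavy-atom
pairs at 2.6–3.4 Å (ramped to zero at 2.4/3.6 Å, gated on a >90°
base–donor–acceptor angle); screened Coulomb (332·q₁q₂/4r², ε = 4r) on
formal side-chain charges; and a burial penalty for polar atoms with more
than 12 heavy-atom neighbours within 5 Å. Pairs within a residue, and
backbone–backbone pairs of adjacent residues, are excluded as fixed by
construction. Default term weights (1, 2, 1, 0.05) ship in the code and
are logged with every screen. The annealer's objective uses the pairwise
terms only; the reported ΔE uses the full function.

### Rotamers and side-chain geometry

Side chains are built from internal coordinates (Engh & Huber-style bond
lengths/angles) by natural-extension-reference-frame placement; the
builder reproduces the CCD ideal residue coordinates to < 0.45 Å per
atom, which the test suite checks against biotite's independently
curated templates. The bundled backbone-independent rotamer library has
≤ 8 modal rotamers per type with prior probabilities; it is intentionally
tiny for reproducibility and speed, and any richer library can be passed
wherever a rotamer mapping is accepted.

## Structure metrics

Superposition is a standard Kabsch least-squares fit (proper rotations
only). Cross-structure comparisons superpose on a *frame* selection
(default: heavy-chain backbone, residues ≤ 180) and measure RMSD over a
second selection without refitting; atoms pair by (chain, residue
number, insertion code, atom name) and unpairable atoms are dropped with
a warning. SASA is Shrake–Rupley with a deterministic golden-spiral point
set (default 960 points, 1.4 Å probe); doubling the point count changes
totals by < 1% on the fixtures. BSA = SASA(A) + SASA(B) − SASA(A∪B).
Contacts are typed by a simple distance rule — polar: N/O–N/O ≤ 3.5 Å;
hydrophobic: C–C ≤ 4.5 Å with both atoms side-chain carbons or carbons
of apolar residues — which is a documented simplification; counts are
reported, never asserted against published interface tables. 3₁₀-helix
classification uses φ ∈ [−90°, −40°], ψ ∈ [−45°, 0°] with runs of ≥ 3
residues; the window is a conventional Ramachandran region choice.

## Biophysics

Peptide masses are sums of the standard IUPAC average (or monoisotopic)
residue masses plus one water, reported to 2 decimals; the average table
reproduces the expected masses of the ALK nonamer (1086.17 Da) and
decamer (1249.35 Da). DSF melt curves are fitted to the Boltzmann sigmoid
F(T) = F_min + (F_max − F_min)/(1 + exp((Tm − T)/k)) by Levenberg–
Marquardt least squares with an automatic initial guess (min, max,
argmax dF/dT, 2 °C); Tm is the fitted parameter, not the max-derivative
point, and a fitted Tm outside the scanned range (default 25–95 °C) is an
error. At 2% amplitude noise, 50 replicate fits recover a planted Tm to
within 0.2 °C.

## Synthetic fixtures

Every generator is a pure function of its seed and returns
machine-readable planted truth.

* **Variant sets** plant unambiguous cases per filter clause (read-1-only
  / read-2-only OxoG-consistent artifacts, low-AF-no-RNA, unexpressed
  gene, clean passers), so filter sensitivity/specificity against the
  labels is 100% by construction. They exercise the rules, not the
  messiness of real calls — borderline allele fractions, conflicting
  evidence and multi-clause failures are only covered by the ordering
  contract (first failing stage wins).
* **The micro-groove** is an idealised ~250-atom peptide/MHC-like
  complex: the 9-mer in an extended conformation (φ −120°, ψ +120°),
  five single-residue floor pads below, and four short helical wall
  segments on the flanks, each rigid part slid along its approach
  direction until it reaches van der Waals contact (3.2 Å minimum
  heavy-atom distance). Per-residue rotamers are chosen greedily at build
  time to avoid internal clashes. It runs the full 100-model screen in
  seconds and reproduces the qualitative physics the protocol needs
  (native > mutated family member > polyAla; groove definition;
  repacking), but it is *not* a realistic groove: passing tests on it
  demonstrates correctness of the machinery, not predictive accuracy on
  real HLA structures.
* **The occluded variant** adds a shell of positively charged amine-like
  pseudo-atoms (single-NZ lysine residues, radius 7.4 Å, ~1.6 Å spacing,
  omitting points within 3.6 Å of existing atoms) around the second
  peptide position: a geometric and electrostatic caricature of a B
  pocket that accommodates Gln but excludes the longer, charged Arg side
  chain. The exhaustive rotamer scan is its own oracle: every bundled Arg
  rotamer clashes, Gln's minimum-strain rotamer is clash-free, and the
  self (Arg2) complex scores far worse than the neoepitope (Gln2)
  complex in the screen.
* **Allele families** mutate a reference sequence at a controlled rate
  outside a conserved-position set, giving planted conservation for the
  KL-logo analytics and a controlled identity gradient for the landscape.
* **Melt curves** come from the Boltzmann model plus seeded Gaussian
  noise over the 25–95 °C scan.

## Known limitations

* Discrete rotamer repacking only: no continuous χ minimisation and no
  backbone flexibility, so subtle accommodation effects are invisible.
* The energy model is uncalibrated; inter-allele ΔE gaps have no
  physical unit and should only be read as orderings.
* The bundled PSSM predictor is a stand-in; real applications should
  supply external predictor tables.
* Groove indels are rejected rather than modelled.
* Contact typing approximates unavailable curation criteria; published
  polar/hydrophobic counts are not reproduced.
* The VCF dialect carries all evidence in INFO fields of a single file, a
  simplification of multi-BAM pipelines.
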