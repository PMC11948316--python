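# Methods

## The protocol

`linkdock` implements a protein–peptide docking protocol for single-chain
structure predictors (ESMFold-style language-model folders that accept one
polypeptide and no MSA). Because such predictors cannot model two chains
directly, the receptor and peptide sequences are fused into one chain around a
flexible polyglycine linker; the linker is excised from the predicted
structure and the remainder is split into a two-chain complex (receptor =
chain A, peptide = chain B, each renumbered from 1).

Single-chain predictors are close to deterministic per input sequence, so seed
variation alone yields no conformational diversity. Diversity is created by
*random masking*: each of `n_variants` copies of the fused sequence has a
fixed fraction of its residues replaced by a reserved placeholder (`X`) before
prediction. Candidate models are then ranked by predictor confidence (pLDDT),
the top model per complex is kept, clearly misdocked models (peptide more than
8 Å from the receptor) are discarded, and surviving models are scored against
a native reference with CAPRI/DockQ metrics.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| linker length | 30 residues | polyglycine spacer; 100/200 and N-terminal placement supported but not better |
| linker placement | peptide at C-terminus | fused text = receptor + Gₙ + peptide |
| masking rate | 0.25 | fraction of eligible positions masked per variant |
| variants per complex | 8 | best-of-n sampling budget |
| eligible set | receptor + peptide | the linker is scaffold; masking it cannot diversify the interface |
| recycles | 3 (adaptive: 3→12, step 3) | continuation only while the peptide is > 8 Å from the receptor |
| dock cutoff | 8 Å (min heavy-atom) | boundary inclusive: exactly 8 Å counts as docked |
| interface cutoff (scoring) | 5 Å | peptide residues "in contact" for pLDDT schemes |
| high-confidence threshold | mean pLDDT > 70 (strict) | over both chains |

Masking uses a fixed count, `round(rate × n_eligible)` (Python/banker's
rounding at exact .5 ties), sampled without replacement with a per-variant RNG
seeded `seed + variant_index`. A fixed count was chosen over per-position
Bernoulli draws so that every variant perturbs the same amount of sequence and
runs are exactly reproducible; the alternative reading of "masking rate" would
only add binomial noise around the same mean.

## Ranking schemes

All three schemes are built from peptide per-residue pLDDT:

* `mean_peptide` — mean over all peptide residues;
* `interface_only` — mean over peptide residues within 5 Å of the receptor
  (0 when nothing is in contact, so detached peptides sort last);
* `contact_weighted` — sum of contacting-residue pLDDT divided by peptide
  length, i.e. the interface mean × the contact fraction. Identity:
  `contact_weighted = interface_only × (n_contacting / n_peptide)`.

The default direction is *maximize* for all schemes. A minimize direction is
exposed because deliberately chasing low-confidence placements has been
floated as a diversity heuristic; we treat that phrasing as most likely a
typo and do not default to it. The contact cutoff inside the scoring schemes
is 5 Å — the interface definition — while 8 Å is reserved for the misdock
filter; conflating the two would let barely-touching models score as if they
had an interface.

Ties are broken by higher `mean_peptide`, then by lower variant index; sorting
is stable, so the output is always a permutation of the input with exactly one
selected model.

## DockQ evaluation

Residue correspondence is by chain id + residue number (guaranteed by the
post-processing renumbering); paired residues must share the amino acid, with
`X` (the mask placeholder / unknown residue) matching anything. The metrics
use the community-standard constants: FNAT contacts at 5 Å (any heavy-atom
pair), interface definition at 10 Å, backbone atom set N/CA/C/O, and

    DockQ = ( FNAT + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²) ) / 3

classified as incorrect [0, 0.23), acceptable [0.23, 0.5), medium [0.5, 0.8),
high [0.8, 1] (left-closed bins). Superposition is the SVD-based Kabsch
algorithm with the determinant sign correction; point sets with fewer than 3
points or rank < 2 (collinear) raise a degeneracy error rather than returning
an arbitrary rotation. A residue missing any backbone atom is dropped from
RMSD atom sets with a logged warning; evaluation fails if more than 10% of
residues are dropped. No claim of numerical parity with any particular
external DockQ executable is made — parity is at the formula level, and the
tests cross-check each component against independent brute-force oracles
(exhaustive pair scans; Horn's quaternion superposition).

## Summary bookkeeping

"Acceptable or better" means category ∈ {acceptable, medium, high}. Misdocked
(filtered) targets count toward the overall rate's denominator but not toward
the effective rate's denominator. Effective success rates are reported to the
nearest integer percent and overall rates to one decimal, both half-up — the
precision at which such benchmark figures are conventionally printed. With no
viable targets the effective rate is undefined (`None`), never 0.

## The synthetic backend and fixtures

The mock predictor and the fixture generator share one toy geometry: the
receptor is an ideal α-helix (rise 1.5 Å/residue, twist 100°/residue, backbone
N/CA/C/O plus Cβ for non-glycine residues) and the peptide an extended strand
(3.8 Å Cα steps). The peptide is placed by translating it along a radial
direction until its minimum heavy-atom distance to the receptor equals a
target value, solved by root bracketing (Brent's method, |error| < 1e-9 Å).
Natives sit at 4 Å; decoys are produced either by a rigid translation of known
magnitude (so LRMSD is known exactly) or calibrated to a prescribed minimum
distance (so the misdock filter's input is known exactly).

The mock backend keys its randomness on (sequence bytes, seed, recycle
count), so masked variants genuinely diversify the output while identical
requests are bit-reproducible — mirroring the determinism of real language-
model folders. Each call docks the peptide with a configurable probability;
docked poses draw a latent accuracy in [0, 1] that couples placement distance
(4–7 Å) and orientation error (σ from 3° up to ~38° per axis), yielding a
DockQ continuum from high to incorrect. An explicit recycle-count → distance
schedule overrides the draw for adaptive-recycling experiments. pLDDT profiles
are uniform, contact-correlated (docked peptide 75–95, misdocked 20–50,
receptor always high) or anticorrelated (bands swapped); masked positions are
capped into the low band.

The synthetic benchmark draws each target's dock probability from a bimodal
mixture — 36% "easy" targets at p = 0.97 and 64% "hard" at p = 0.03 — because
real peptide-docking benchmarks are bimodal: a minority of complexes dock on
almost every attempt while most resist regardless of sampling. Under this
mixture a single prediction docks ≈38% of targets and best-of-8 masking ≈51%,
so the bookkeeping exercises the same regime as a real benchmark without
trivializing (every target docks) or starving (masking never helps) the
protocol.

What the fixtures do **not** emulate: real secondary-structure diversity,
side-chain chemistry, predictor-specific error modes, or the weak and noisy
correlation between pLDDT and model quality on hard targets — the mock's
contact-correlated mode is an idealization, so pipeline success rates on
synthetic benchmarks (roughly 90% effective on viable targets) are upper
bounds that say nothing quantitative about real-structure performance. What
the tests *do* establish is the protocol's bookkeeping, geometry and selection
logic: masked variant accounting, linker excision round-trips, adaptive
recycling call schedules, metric correctness against brute-force oracles, and
that contact weighting is structurally robust to confidence miscalibration
(a detached peptide scores zero no matter how confident the predictor is).

## Numerical choices

* Distance-at-cutoff is inclusive (≤): "more than 8 Å away" is the misdocked
  side, so exactly 8 Å docks.
* Placement calibration: Brent root bracketing from the current position,
  expanding the bracket geometrically; tolerance 1e-9 Å.
* `interface_only` returns 0 (not NaN) with an empty interface so maximizing
  sorts detached models last, consistent with the weighted scheme.
* Kabsch: covariance SVD with `det` correction; degeneracy (n < 3 or rank
  < 2) raises instead of silently returning one of many minimizers.
* PDB coordinates round-trip at the format's 3-decimal precision; pLDDT is
  stored per atom in the B-factor column and averaged per residue on read.
* Hydrogens are excluded from heavy-atom policies; HETATM records are
  skipped; alternate locations take the first conformer.

## Problem sizes in the test suite

Unit and property tests run on 20–60-residue receptors with 5–10-residue
peptides; oracle-equivalence checks use 100+ random toys of ≤ 50 residues;
ranking behavior is measured over 50 seeded pools of 8 decoys; the end-to-end
run uses a 252-residue complex (240 + 12), the median size of the motivating
benchmark, and completes in about a second. These sizes were chosen so the
whole suite gives tight feedback in seconds while still exercising every code
path at realistic chain lengths.

## Known limitations

* Single peptide per receptor; two-chain complexes only (no multi-interface
  DockQ generalization, no fnonnat/clash analysis).
* The real-predictor adapter (subprocess producing PDB with confidence in
  B-factors) is documented plumbing, not tested here: it requires GPU-scale
  inference.
* mmCIF is not supported; PDB only.
* The synthetic benchmark's absolute rates are properties of the generator's
  study conditions, not predictions about any real predictor.
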