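# Methods

## The measurement and its model

Hydroxyl-radical protein footprinting exposes a protein solution to
millisecond X-ray pulses; radiolysis of water produces •OH radicals that
covalently oxidize solvent-exposed side chains (most commonly a +16 Da
single-oxygen addition). After quenching, proteolysis and LC-MS
quantification, each mapped site yields a dose–response series: the
unmodified fraction

    Y(t) = area_unmod / (area_unmod + Σ area_mod)

at each exposure time t. Oxidation follows pseudo-first-order kinetics,

    Y = Y0 · exp(−k t),

and the fitted k (s⁻¹) is the site's footprinting rate. Because residue
types differ enormously in intrinsic •OH reactivity (Cys ≫ Trp ≈ Tyr ≫ …
≫ Gly), the rate alone does not report burial; the protection factor

    PF = (Σᵢ Rᵢ) / k

divides out residue chemistry (summing Rᵢ over all residues an oxidation
event may belong to). On a state with a known structure, ln PF falls
linearly with fractional side-chain solvent accessibility,

    ln PF = a + b · fSASA,    b < 0,

and the Pearson correlation R of this regression is the standard quality
readout. The fitted line is then inverted to convert ln PF measured in a
structurally uncharacterized (e.g. receptor-bound) state into predicted
fSASA, and two liganded states are compared directly by per-site rate
ratios log₁₀(k_A/k_B), averaged per residue and thresholded at a 1.4-fold
(>40%) change.

## Fitting choices

**Rate fitting** is two-stage: a log-linear regression of ln Y on t
(excluding Y ≤ 0) initializes a bounded nonlinear least-squares fit of
Y0·exp(−kt) with Y0 ∈ (0, 1.05] free and k ≥ 0. Peak-area noise is
multiplicative, so residuals are weighted by Y (σᵢ ∝ Yᵢ), which makes the
fit homoscedastic and its covariance — the source of sd_k — honest: on
simulated series (5% lognormal fraction noise, two replicates) the median
rate error is ≈1.2% and the ±2·sd_k interval covers truth ≈96% of the
time. Replicates are pooled into one fit by default (`pooled=False` fits
them separately and averages, for diagnostics). Input times are
milliseconds; rates are always reported in s⁻¹. A fit pinned at k = 0
against a rising Y series emits a warning rather than an error.

**Dose–response (BRET) fitting** uses the four-parameter logistic in
log₁₀ concentration with the Hill slope free but bounded in [0.3, 5].
Zero-dose wells cannot sit on a log axis, so they anchor the bottom
parameter as points three decades below the lowest dose. A fitted EC50
outside the tested range raises an extrapolation warning; a flat curve
short-circuits to Emax = 0 with pEC50 undefined.

**Calibration** regresses ln PF on fSASA by OLS and inverts algebraically
for prediction (an inverse-regression alternative would regress the other
way; the forward direction is the default because fSASA is the
error-free, structure-derived variable in the reference state).
Predictions are clipped to the physical [0, 1] with the raw value kept
alongside. No significance test is attached to burial changes Δ fSASA;
they are ranked, which is how interface candidates are read off.

## Surface areas

SASA is computed by the Shrake–Rupley point-counting method: each atom is
expanded by the probe radius (default 1.4 Å) and covered with a
deterministic golden-spiral lattice (default 960 points, minimum 92); a
point is accessible if it lies outside every neighbouring expanded
sphere, and area = 4π(r+probe)² × accessible fraction. The lattice is
anchored to the molecule's principal-axis frame with eigenvector signs
fixed by the third moment of the coordinates, so the result is invariant
under rigid motion of the input (verified to 1e−9); `orient=False`
reverts to a lab-frame lattice, under which per-atom areas are monotone
under atom addition. Accuracy: 0.06% against the analytic two-sphere
spherical-cap formula at 10,000 points, <0.5% against Monte-Carlo surface
sampling on random 2–5 sphere systems, and 960- vs 3840-point totals
agree within 0.02% on a 20-residue fixture.

Default per-residue SASA counts side-chain atoms only (backbone N, CA, C,
O, OXT excluded), since the footprinting chemistry is side-chain
oxidation; a backbone-inclusive mode is a flag. Van der Waals radii are a
small shipped element table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
H 1.10 Å), replaceable configuration.

**Weighted peptide SASA.** When one measured species covers several
residues, the observed area is the reactivity-weighted mean over the
peptide's oxidizable residues, wᵢ = Rᵢ/ΣⱼRⱼ — the residues that dominate
the measured rate dominate the area. A uniform-weighting switch exists
for sensitivity analysis. fSASA uses the same weights in numerator
(observed SASA) and denominator (reference areas), values above 1 are
flagged but not rejected.

**Reference tables.** Intrinsic reactivities default to the
free-amino-acid •OH rate-constant compilation (units 10⁹ M⁻¹ s⁻¹,
16 oxidizable residues; Gly/Ala/Asp/Asn treated as non-oxidizable).
Reference areas default to the Gly-X-Gly tripeptide side-chain standard.
Both are configuration with documented defaults, not constants: PF is
homogeneous of degree +1 in the reactivity scale, so substituting another
table shifts only the calibration intercept (by ln c), never the slope or
Pearson R — this invariance is asserted in the test suite.

## Digestion and mass bookkeeping

Trypsin cuts after Lys/Arg, AspN before Asp (no proline exception), LysC
after Lys; combined digests use the union of cut sites, and up to a
configured number of missed cleavages is enumerated. Pepsin at low pH is
modelled as nonspecific cleavage bounded by peptide length (default
5–30 residues, configurable — the bounds are a convention, not
chemistry). Peptide monoisotopic mass is the residue-mass sum plus water
(18.010565 Da); precursor matching uses a ppm tolerance (default 10 ppm)
and returns all isobaric candidates. At zero missed cleavages a specific
digest partitions the sequence exactly — a property tested on random
sequences.

## The synthetic-experiment generator

The generator inverts the analysis model so every stage has known ground
truth: given a structure and a calibration line (a, b), each oxidizable
residue becomes a +16 Da site with true rate k = ΣRᵢ / exp(a + b·fSASA),
fSASA computed from the structure's side-chain areas; dose–response
tables are emitted on a 0–15 ms five-point exposure grid (the
experimental dose range) in the exact schema the readers parse, plus a
JSON truth sidecar. Noise enters through two independent knobs: a
lognormal multiplier on each site's rate (site-level scatter; default
σ = 0.45, which on the standard fixture yields calibration R ≈ −0.85,
illustrative of the −0.7..−0.9 range of real calibrations) and a
multiplicative Gaussian on the fractions (peak-integration noise; default
0, used at 0.05 in the kinetics recovery study). The standalone decay
generator used for rate-recovery studies spans ~2 decay constants of the
simulated rate with 8 points — mirroring how a real dose series is tuned
to the rates it probes.

Fixture structures are ideal-geometry backbones (α-helix: 2.3 Å CA
radius, 100°/residue, 1.5 Å rise; antiparallel strand pair; or a
two-chain helix bundle packed face-to-face) with single C-β pseudo-atoms
for side chains — enough burial contrast for calibration studies without
rotamer modelling. The two-chain bundle's contact residues, identified by
their side-chain SASA drop between the separated chains and the complex,
are the known "interface" truth set for state-comparison and
bound-state-prediction tests. Sequences are drawn from a mixed residue
pool deterministically in the seed; all generators are seed-stable to the
byte.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: chromatographic peak integration
and its biases, secondary oxidation chemistry (+32 Da and ring-opening
products), dose heterogeneity between samples (the fluorophore-decay
dose control is an experimental QC outside this package's scope),
radical scavenging by buffers or detergent, side-chain rotamer
flexibility, and MS/MS localization ambiguity beyond the simple
two-residue ambiguous-site mechanism.

## Problem sizes and numerical conventions

Simulation studies use the scale of the motivating experiments: 25 sites
and two replicates for end-to-end calibration recovery (100 seeds;
median slope error ≈2%), 200 simulations per condition for kinetics,
classification and pharmacology recovery, 30 sites with a 10-residue
3-fold-protected subset for two-state classification. Residue numbering
is 1-based with closed intervals, as in PDB files; sites are written
`chain:CODEnumber` (ambiguous sites joined by `|`). Rate ratios are
oriented state A over state B and the classification threshold is a
strict inequality (a fold change of exactly 1.4 is "unchanged").
B-factor annotation clamps values to the PDB field range [−99.99,
999.99] with a warning. Alternate locations resolve to highest occupancy;
multi-model files default to model 1.

## Known limitations

Peptide-level sites larger than two residues are supported in the SASA
weighting but the rates-table site grammar carries at most an ambiguous
residue pair; true multi-residue peptide species should be pre-assigned.
The Shrake–Rupley implementation is O(atoms × neighbours × points) pure
NumPy — comfortable for single-domain proteins and the package's
simulation studies, not tuned for trajectories. No hypothesis testing is
attached to rate ratios or burial changes; the comparisons are
descriptive by design.
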