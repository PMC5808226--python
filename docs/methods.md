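# Methods

## Swelling kinetics

**Model.** A defolliculated oocyte in a hypotonic bath is treated as a
well-mixed compartment of volume *V(t)* behind a membrane of fixed area
*S* with osmotic water permeability *P*<sub>f</sub>:

    dV/dt = Pf · S · Vw · (c_in(t) − c_out),   c_in(t) = c_in(0) · V0 / V(t)

Internal solute is conserved (no leak), the bath is infinite, and the
surface area is held at the single constant *S* rather than recomputed
from *V* — the permeability formula the assay uses is written for a
constant *S*, and keeping the model consistent with its estimator matters
more than geometric nicety at ≤ 10% volume change.  The stationary point
is c_in = c_out, i.e. V_eq/V0 = Osm_in/Osm_out (≈ 3.424 with the default
constants), which the long-run simulator reproduces to 0.1%.

**Units.** Osmolalities are given in mmol/kg; the formula needs mol/cm³.
Taking 1 kg of water as 1000 cm³, 1 mmol/kg = 1e-6 mol/cm³.  This is the
only unit bridge in the package, and the arithmetic identity it produces
— slope 1.0e-3 s⁻¹ ⇒ Pf = 7.770e-3 cm/s with the default constants — is
pinned by tests.

**Integration.** Classical fixed-step RK4 with an internal step of at
most 1 s (configurable), resampled to the output grid.  The system is
smooth and non-stiff at physiological parameters; the integrator verifies
the noiseless trajectory is monotone under a hypotonic gradient and
raises rather than return a non-physical curve when the step is too
coarse (an adaptive integrator would hide the misuse instead of flagging
it).

**Estimation.** d(V/V0)/dt is the OLS slope of relative volume against
time over a configurable initial window, defaulting to 60 s (five 15-s
frames): the permeability is defined from the initial gradient, before
osmotic back-pressure bends the curve, and r² is reported so poor
linearity is visible.  The window trades bias for variance: the
mean derivative over a window of length T sits below the t = 0 derivative
by roughly T/2 × the curvature (about 2% per 30 s at Pf ≈ 8e-3 cm/s),
while the slope's noise scales inversely with the window's time spread.
The recovery benchmark (Pf uniform in [1e-3, 1e-2] cm/s, 15-s frames,
5 min, 0.5% area noise) therefore fits 120 s, which keeps the slope noise
at the weakest Pf and the curvature bias at the strongest both near or
below 10%; the benchmark's median absolute relative error is ~9%.

**Noise.** Multiplicative Gaussian noise on the projected area, with the
t = 0 frame pinned to exactly 1 because traces are normalized to their
own first frame.  A slight shrinkage seen in solute assays is represented
only as noise around a zero slope — no efflux mechanism is modeled.

**Group comparison.** Two-sided Student's t (equal variances) on the
per-oocyte permeabilities, mean ± SEM per group, fold = mean ratio.  Two
degenerate groups with equal means give p = 1 by convention.

## Silhouette imaging

Synthetic frames are a centered dark disc on a light background with
additive Gaussian noise; segmentation is a global Otsu threshold, the
minority intensity class taken as foreground (silhouettes may be
dark-on-light or the inverse; the object is assumed to cover less than
half the frame), the largest 8-connected component kept, interior holes
filled.  The render→extract round trip is accurate to <2% for radii of
20–200 px at noise up to 5% of the contrast.  Real micrographs bring
drift, vignetting, and non-spherical cells that none of this exercises;
passing tests show the geometry and normalization chain is right, not
that segmentation of laboratory footage would be.

## Sequence hallmarks

All coordinates are 1-based inclusive.  ORF search scans the three
forward frames for ATG…stop spans (mRNA/RACE products are oriented;
no reverse-strand search), longest span wins, ties to the smaller start.
Molecular weight uses the ExPASy average-mass table plus one water;
isoelectric point bisects the Henderson–Hasselbalch net charge with the
Bjellqvist pKa set (residue-specific terminal pKas) to |charge| < 1e-4.
Both tables ship as JSON data files so alternates can be swapped in.

Hydropathy is a centered Kyte–Doolittle sliding window (default 19,
threshold 1.6, merge gap 3 centers, minimum run 1), reported as intervals
of window-center positions.  It is a heuristic profile, deliberately not
a topology predictor: the canonical six-transmembrane aquaporin call is
not asserted anywhere.

Global alignment is Needleman–Wunsch with affine gaps (BLOSUM62, open 10,
extend 0.5); percent identity divides matches by all alignment columns,
a choice documented because published identity figures rarely state their
denominator.  Selectivity-filter mapping aligns query to template and
reads off the aligned residue at each template position (the vertebrate
AQP1 ar/R constriction 58/182/191/197 by default), reporting an explicit
gap marker when a position aligns to a gap.

In-silico PCR honors IUPAC degeneracy on the primer side only — template
N matches nothing — requires perfect matches (no mismatch tolerance: the
amplicon length must be exact), pairs every forward site with every
non-overlapping downstream reverse site, and reports lengths inclusive of
both primer footprints.

## qPCR expression

Technical replicates are averaged per biological replicate (cells with
technical SD > 0.5 cycles get a QC flag — a conventional threshold).
ΔCt = Ct_target − Ct_reference per biological replicate; ΔΔCt centers on
the calibrator condition's **mean** ΔCt (stable under unbalanced
replication), so the calibrator's mean ΔΔCt is 0 and its rq is 1 by
construction.  Amplification efficiencies are assumed equal; a Pfaffl
correction hook is deliberately absent.  When no calibrator is
configured, the lowest-expressing condition (largest mean ΔCt) is used.

Statistics run on log-folds: Shapiro–Wilk per group and Levene across
groups, then one-way ANOVA with Tukey HSD when variances are homogeneous
and pairwise Welch t-tests with Šidák adjustment otherwise — the latter
standing in for Dunnett's T3, whose studentized-maximum-modulus critical
values are approximated well by Šidák-adjusted Welch tests at these group
counts.  Two-condition designs use Student's t.  Pairwise outcomes are
summarized as compact letter displays at α = 0.05.

## Synthetic data

Generators are the package's study conditions, not adjustable fixtures:
swelling batches default to 10 expressing + 10 control oocytes with
lognormal per-oocyte Pf around 7.7e-3 vs 7.0e-4 cm/s (11-fold contrast,
cv 0.1) and 0.5% area noise at 15-s frames for 5 min; solute batches
default to ~5e-6 cm/s for both groups (a channel that does not conduct
the solute); transcripts default to a 258-codon ORF with NPA boxes at
residues 89 and 206, an SYDF terminus, UTRs of 150/489 nt, and a planted
431-bp degenerate amplicon; Ct tables default to four biological
replicates in triplicate with 0.2-cycle noise.  Lognormal biological
variation (positivity) and Gaussian measurement noise are the
conventional families at these scales.  Transcript generation re-scans
its own output (longest ORF, exact NPA set, unique amplicon) and
regenerates from a spawned seed on violation, so planted truth is
guaranteed, not merely probable.  Every generator is deterministic under
a fixed seed and writes its ground truth as JSON.

## Problem sizes

The test suite and the acceptance script use 200-draw Monte Carlo loops
for recovery/detection rates, 20 replicate batches for fold estimates,
and a 24-h simulated run for the equilibrium check; together they
complete in well under a minute on one CPU.

## Known limitations

- The solute-uptake model is the linear growth implied by the apparent-
  permeability definition; it has no saturation and no osmotic feedback.
- Percent identity depends on alignment parameters; published figures
  without a stated method (e.g. cross-species identity values) are not
  asserted against it.
- The hydropathy segment caller is not TMHMM and its segment count is not
  treated as a reproduction target.
- The Dunnett-T3 branch is an approximation (see above); exact SMM
  quantiles are not computed.
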