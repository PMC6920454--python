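# Methods

This note documents the models, the parameter defaults and why they were
chosen, what the synthetic generators do and do not emulate, numerical
choices, and known limitations. It states no empirical result beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## Pedigrees and fixtures

Pedigrees are 6-column PED (affection 2 = affected, 1 = unaffected,
0/−9 = unknown) plus extension columns 7 (haplotype L/U/?) and 8
(sequencing set WES/WGS/BOTH/NONE); absent extension columns default to
unknown/none, so plain PED remains readable. Individual ids are opaque
strings; generation labels are an optional side mapping, never inferred
from ids. Structural validation requires that every non-founder has
exactly two resolvable parents and that parentage is acyclic.

The packaged family fixtures are synthetic reconstructions: the named
individuals, their affection, haplotype labels, sequencing sets and the
genotypes at the three prioritized sites are encoded exactly as described
in the published family summaries, while connecting spouses/founders,
read depths, and the second family's variant position are invented and
flagged as such (`src/kerafam/data/README.txt`). Individuals whose state
was never described stay out of the fixture rather than being guessed.

## Variant annotation

HGVS parsing accepts the printed dialect (embedded spaces; hyphen,
en-dash, em-dash or minus sign for intronic offsets) and always emits the
compact canonical form. Only single-nucleotide substitutions are in
scope — no dup/del/ins/frameshift grammar, no genomic liftover.

Consequence calls use the standard nuclear genetic code (no
selenocysteine). An intronic offset within the splice window classifies as
`splice_region`; the window defaults to 20 nt — wide enough that an
acceptor−10 substitution (a plausible branch-point change) is flagged as
splice-proximal — and is configurable because no consensus cutoff exists.
A transcript base that contradicts the variant's stated reference raises a
loud reference-mismatch error rather than silently recoding.

The packaged PPIP5K2/PCSK1 transcripts are synthetic: the real reference
codons are not available in the source material, so deterministic
stop-free filler sequences are generated with the constraint that the
documented variants produce their documented amino-acid changes (codon
419 = TCT so T→G at its first base gives Ala; codon 843 = AAT so A→G at
its second base gives Ser). The domain map defaults to the one PPIP5K2
interval with published bounds — phosphatase, residues 363–909 inclusive;
kinase-domain bounds are deliberately not defaulted and can be supplied.

## The filtering cascade

Steps run in a fixed order (quality/depth → control absence → MAF →
consequence → affected heterozygosity → expression + locus), each
recording input count, surviving count and dropped keys; counts conserve
by construction and the trace validates it.

Decisions where the published description is ambiguous:

* **Depth/quality.** The printed criterion ">10–20" is resolved as depth
  ≥ 10 and genotype quality ≥ 20, per-sample and strict (a missing call in
  any sequenced sample fails the record), both thresholds configurable.
* **Controls.** A control is an *unaffected* individual with an *explicit*
  unlinked haplotype label. Unknown-haplotype individuals never veto a
  variant — otherwise an ungenotyped relative could silently kill a true
  candidate. Unaffected linked carriers are penetrance exceptions and are
  handled by the segregation report, not the filter.
* **MAF.** Missing population frequency means a novel variant — the
  prioritization target — and is kept. The boundary is inclusive (≤).
* **Genome mode.** WGS keeps splice-proximal variants everywhere, and
  intronic/`other` (regulatory-like) classes only in expression-listed
  genes; this relaxation is a config flag because the WGS arm of the
  original design is described only as "similar".
* **Locus.** "Within/adjacent" is a symmetric flank, default 2 Mb; window
  extension (e.g. from a narrow association region to the full linkage
  peak) is just a wider window, not a special case. Multi-allelic sites
  are split to biallelic records at the VCF reader; coordinates are
  1-based inclusive internally, BED converts at the boundary.

The segregation report scores only individuals with known genotype,
affection and haplotype; classification priority is
carrier-without-variant (linked, homozygous major) → variant-without-
haplotype (split by affection) → consistent (affected linked heterozygote
or unaffected unlinked non-carrier); an unaffected linked heterozygote is
a pure penetrance exception and lands in `unscored`. The penetrance
estimate is affected variant-carriers over all variant-carriers scored.

## The genomic cohort simulator

The generator reproduces the statistical structure the cascade assumes: a
founder disease haplotype gene-dropped through a four-generation pedigree
(transmission probability 1/2 per meiosis), one causal variant riding that
haplotype, affection assigned at the configured penetrance (default 1.0)
and phenocopy rate (default 0), and independent background variants with
Beta(0.5, 5) population frequencies and Hardy–Weinberg founder genotypes
dropped through the same pedigree. Read depths are negative-binomial with
mean 75 (echoing the deep exome coverage of the study design) and size 30;
genotype quality is clipped normal (60 ± 8). Genotyping noise (random
allele flips) is off by default and opt-in.

Two deliberate simplifications: no recombination between the causal site
and the haplotype label (Mb-scale locus, shallow pedigree; a recombination
fraction parameter exists for robustness tests), and unlinked background
variants (independent drops are sufficient for exercising the cascade).

Gene drops are **ascertainment-conditioned**: draws are rejected until the
sequenced samples include at least 3 affecteds and 1 unaffected-unlinked
control. This mirrors how multiplex families enter a study at all — a
family in which the founder haplotype died out in the first meiosis would
never have been collected — and it keeps the filtering problem well-posed
in every replicate. All randomness flows from one master seed through
named substreams, so each stage is independently reproducible; fixture
output (VCF 4.2 + PED + annotation sidecar + truth table) is byte-stable
for a fixed seed.

What the generator does **not** emulate: linkage disequilibrium among
background variants, sequencing error profiles correlated with depth,
population stratification, structural variation. Cascade-recovery results
on synthetic cohorts therefore demonstrate the logic of the filters, not
genome-scale specificity.

## OCT segmentation

Boundaries are detected per column as local axial intensity maxima
exceeding `median + 5·σ`, with σ the robust (MAD-based) frame noise;
surfaces occupy few rows, so frame-wide statistics are background-
dominated. On noise-free frames (MAD = 0) any maximum above 5% of the
dynamic range qualifies. The first qualifying maximum is the anterior
cornea, the next at least 25 µm deeper the posterior, an optional third
the lens. Peaks are refined to sub-pixel depth by parabolic interpolation
(exact for the symmetric rendered bands; bias ≪ 1 pixel generally).
Columns without a qualifying pair are masked and interior-interpolated;
boundaries are then smoothed across columns with a Savitzky–Golay filter
(window 11 columns, order 2). A frame with under 30% usable columns is
declared surface-free; a volume with over half its frames surface-free is
rejected with a diagnostic.

## Phenotype quantities

* **Pachymetry** is the direct z-axis difference of the boundary sheets —
  the layered-heights convention of OCT pachymetry — not distance along
  the surface normal (a normal-thickness variant exists but is never the
  default).
* **Apex** = global minimum of the lightly smoothed anterior sheet, ties
  broken toward the grid centroid. CCT is the pachymetry there; ACD the
  lens-to-endothelium axial distance at the same column, reported as
  missing (never zero) when no lens surface is available.
* **Sphere fit**: algebraic (Coope) linear initialization, then
  Levenberg–Marquardt refinement of Σ(‖pᵢ−c‖−R)²; coplanar/collinear
  point sets raise a degeneracy error. Radius is reported in mm.
* **Curvature maps**: 180 meridians through the apex, signed radial
  sampling at the lateral pitch over the optical zone (default one third
  of the mapped half-width — the nominal zone for mouse is not
  standardized, so it is configurable). Profiles are resampled with cubic
  grid interpolation — a C¹ surface keeps second derivatives clean, where
  bilinear kinks would corrupt them at the grid scale — and derivatives
  come from Savitzky–Golay fits (window 11 samples, order 4; order 2
  introduces a percent-level systematic underestimate of circle curvature
  over wide windows). Radii in mm; keratometric diopters (index 1.3375)
  exist behind a flag but are off by default — the human keratometric
  convention is dubious for mouse optics.
* **Irregularity**: RMS deviation of the anterior sheet from its
  least-squares sphere over the optical zone (sphere fitted on the full
  valid sheet so a localized lesion cannot drag its own baseline). The
  flag threshold is 3× the segmentation noise floor; the floor defaults
  to 1 µm, the sub-pixel jitter scale the segmenter leaves after
  smoothing at a 2 µm axial pitch. This score is an explicit
  operationalization of "irregular anterior surface" — scan-reader
  judgement in the motivating studies was not specified, and no
  equivalence is claimed.
* **Refractive index**: optical-path distances are reported uncorrected by
  default; an optional corneal group-index divisor (1.4) applies to
  thicknesses and ACD when enabled and is logged.

## OCT phantoms and rendering

Default geometry (anterior sphere radius 1.5 mm; concentric posterior
1.45 mm giving a 50 µm apical thickness; ACD 300 µm; lens radius 1.4 mm)
is a documented fixture choice at murine scale, not a measurement claim.
Lesions: `epithelial_bump` raises the anterior surface locally (Gaussian
footprint), `thinning_cone` thins the cornea locally from the posterior
side, `diffuse_thinning` scales thickness globally; lesions that drive
thickness non-positive are rejected. Tilt is applied as the center
displacement a small rigid rotation about the apex induces on spheres.

Rendering places a Gaussian axial point-spread band (FWHM 8 µm) at each
surface crossing, brightness 1.0, additive Gaussian background noise
σ = 0.05 by default, optional multiplicative speckle; deterministic per
seed, and the seed changes only the noise, never the truth surfaces. The
corneal surfaces must lie inside the axial field of view (error
otherwise); the lens band is clipped where it exits laterally, as in real
anterior-segment scans. Default volumes are 48 frames × 384 × 96 samples
at 2/15/30 µm pitches (axial/lateral/frame) — small enough that a
200-animal cohort renders and phenotypes in about a minute, large enough
that boundary recovery is sub-pixel.

The mutant-cohort generator lesions each animal independently at its
group prevalence (the packaged replication scenario: 40% in mutant
groups, n = 200) and records truth labels; volumes render lazily so large
cohorts do not hold hundreds of stacks in memory. Its default lesion law
draws epithelial bumps (amplitude 15–30 µm, width 80–150 µm, center
within 150 µm of the apex): the detectable anterior-surface phenotype.
Posterior-side thinning lesions exist but are not part of the default law
because the irregularity detector is, by design, anterior-surface-based.

What the renderer does not emulate: interferometric speckle statistics,
refraction at interfaces, motion artifacts, rectangular-vs-radial scan
registration, vendor file formats. Closed-loop agreement therefore
validates the geometry pipeline, not scanner physics.

## Futile-cycle model

First-order mass action on a conserved two-species pool is the simplest
closure consistent with a kinase (5-InsP7 → 1,5-InsP8) and phosphatase
(1,5-InsP8 → 5-InsP7) housed in one enzyme: `d[InsP8]/dt = k[InsP7] −
p[InsP8]`, steady state `InsP8* = T·k/(k+p)`, ratio `k/p`. A variant
scaling the activities by `(α_k, α_p)` scales the ratio by `α_k/α_p`,
independent of baseline rates — hence the synergy inequality
`α_k/α_p > max(α_k, 1/α_p)` whenever `α_k > 1 > α_p`. This is an
illustrative model: no Michaelis–Menten saturation, no upstream InsP6/IP6K
reactions, and no fit to enzymatic assay data (only the documented 15%
phosphatase reduction, `α_p = 0.85`, ships as an example parameter; the
kinase activation has no published magnitude and must be user-supplied).
The ODE cross-check integrates with LSODA at rtol 1e−12 for ~60 relaxation
times.

## Reporting statistics

Two-sample comparisons default to the classical equal-variance Student's
t (matching the stated convention of the motivating analyses), two-sided,
significance at p ≤ 0.05; Welch's correction is behind a flag. Group
summaries report mean ± SEM. No multiple-testing correction is applied by
default; a Bonferroni option exists and is marked in the output when
used.

## Problem sizes in the tests and acceptance script

Chosen as the package's own defaults: 100 seeded cohorts of 500
background variants for cascade recovery (brute-force oracle equivalence
is additionally checked on cohorts of ≤ 50 variants, where exhaustive
predicate evaluation is cheap); 10,000 meioses for the transmission
frequency check; 100 noise seeds for the sphere-fit band; 200 rendered
animals for prevalence recovery; 10,000 random draws for the synergy
property.

## Known limitations

* The co-segregation classifier assumes a biallelic site and a single
  founder haplotype; recessive and compound-heterozygous models are out
  of scope.
* Synthetic transcripts carry correct codon arithmetic but arbitrary
  filler sequence; consequence calls on other positions of these
  transcripts are internally consistent, not biologically meaningful.
* The irregularity threshold is calibrated to the default rendering
  noise; scans with substantially different noise floors need
  `noise_floor_um` adjusted.
* Curvature maps are anterior-surface only; posterior curvature and
  Zernike decompositions are not implemented.
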