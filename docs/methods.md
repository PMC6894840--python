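# Methods

This note documents the models, parameter choices and numerical
decisions behind `foramotu`, and what the synthetic generators do and
do not emulate.

## Molecular curation

The curation model treats a barcode read as an observation of an
underlying rDNA motif.  Two error processes matter: per-read sequencing
error (creates spurious singleton motifs) and contamination/PCR
artefacts (creates spurious within-individual co-occurrences).  The two
filters address them separately:

* **Replication filter** — a motif becomes a basetype only if the
  identical sequence was observed `min_replication` times (default 3)
  among full-quality reads.  Identity is exact string match after
  uppercasing and gap stripping; IUPAC ambiguity codes are compared
  literally with a warning, since a base-called ambiguity is treated as
  data, not as a wildcard.  Motif identity is assessed on the
  unaligned motif (sequences of unequal extent are distinct motifs
  unless flagged partial); alignment-column identity can be had by
  aligning upstream.
* **Co-occurrence filter** — an edge between two basetypes requires
  `min_cooccurrence_individuals` (default 2) distinct individuals in
  which both motifs were recovered.  Basegroups are connected
  components over accepted edges (networkx; a brute-force union-find
  oracle backs this in the tests).  The default of 2 encodes the
  asymmetry between accepting a 2-individual co-occurrence and
  rejecting a 1-individual one.

Partial reads are attributed by placing the fragment on the reference
motifs (prefix/suffix placement, minimum mismatches, 75% identity
floor), then walking the MOTU levels coarse → fine: a level is
assigned when the covered diagnostic sites point at exactly one
candidate taxon and contradict none of its sites; ambiguity or
contradiction stops the walk at the last safe level, and a level with a
single admissible child is assigned by implication.  This never assigns
deeper than the evidence allows.

## Delimitation

**K80 distances.** Pairwise complete deletion of columns holding
anything outside A/C/G/T, then the closed form with transition
proportion P and transversion proportion Q.  Pairs whose log arguments
hit the domain boundary are flagged saturated and carry d = +inf; they
never link groups.

**Barcode-gap partitioning.** For each prior P on a log-spaced ladder
(defaults Pmin = 0.001, Pmax = 0.1, 10 steps, the published tool's
defaults), the ranked pairwise distances are scanned for
discontinuities.  A gap between consecutive sorted distances d_i <
d_{i+1} is significant when its width exceeds X·max(d_i, P) with
X = 1.5: the jump must dominate both the local distance scale and the
assumed intraspecific divergence.  This "relative width" reading of X
replaces a sliding-window slope estimate, which proved fragile on tight
distance clusters (window-relative significance fires inside uniform
jitter).  The *initial* partition links pairs below the **widest**
significant gap — the dominant barcode gap, giving the coarsest
defensible split; the *recursive* partition re-applies the detector
within each group (groups below `min_group_size` = 3 taxa cannot
exhibit a gap and are left intact) until no significant gap remains,
giving the finest.  The retained pair is the one at the lowest prior
that exhibits a gap; if no prior does, the single-group partition is
returned with a warning.  Ties between equally wide gaps resolve toward
the higher threshold (fewer groups), matching the choice to break
prior ties toward fewer groups.

**Simplified PTP.** Branch lengths of the rooted input tree are
modelled as two exponential classes — speciation edges vs within-species
edges — where a delimitation is a set of species subtree roots (an
antichain covering all tips).  Class rates are MLE (n/Σb), zero-length
edges are excluded from the likelihood, and the criterion is AIC (k = 2
when both classes are populated, else 1).  The search hill-climbs with
split moves (species root → its children) and merge moves (sibling
roots → parent) from several deterministic starts: single species, all
singletons, and every branch-length-threshold delimitation.  Ties break
toward fewer species and preorder order, so results are reproducible.
This is a reimplementation heuristic, not the published tool; an import
path passes externally computed partitions through unchanged, and an
exhaustive enumerator over all antichain covers serves as the oracle
for small trees in the tests.

**Hierarchy.** Candidate partitions are validated against two hard
rules: no partition may split a basegroup (oversplit) and none may
merge morphospecies (lumping).  Among valid partitions the coarsest
becomes level 1 and the finest level 2; level 3 is the basegroups.
Labels are assigned deterministically in tree/lexicographic order:
lineages I, II, ...; genotypes a, b, ... within lineage; basegroups
1, 2, ... within genotype (so a basetype reads e.g. `Ia1`).

## Richness

Sample-based rarefaction uses the hypergeometric expectation with
log-gamma binomials for stability; resampling mode exists as a
Monte-Carlo cross-check and reports its standard error.  The
first-order jackknife uses S_e = S_o + f₁(n−1)/n and the
Heltshe–Forrester variance ((n−1)/n)(Σⱼ j²f_j − f₁²/n), where f_j is
the number of samples containing exactly j unique taxa; CI₉₅ =
1.96·√var.  The coverage test supports two readings of the reported
interval: the default (`half_width`) treats CI₉₅ as a **full** interval
width and tests S_o ∈ S_e ± CI₉₅/2 — the convention under which the
jackknife cells and their TRUE/FALSE coverage flags are mutually
consistent — while `full_width` tests S_o ∈ S_e ± CI₉₅.
"Samples" are stations by default; any column can serve via the
incidence builder.

## Ecology

Environmental lookups match on calendar month and a 0.5° spatial
tolerance, nearest cell first, ties broken by table order and logged.
VGPM uses the published 1997 parameterization: the 7th-order
polynomial for P_opt_B piecewise at −1 and 28.5 °C, and euphotic depth
from surface chlorophyll through the case-1 integrated-biomass
relations (C_tot = 38·chl^0.425 below 1 mg m⁻³, 40.2·chl^0.507 above;
Z_eu = 568.2·C_tot^−0.746, switching to 200·C_tot^−0.293 beyond
102 m).  Zero chlorophyll returns zero production directly.  Months
are hemisphere-normalized by a +6 shift south of the equator; the
equator counts as northern.  Mann–Whitney tests enumerate the full U
distribution when both groups have ≤ 8 values (average ranks handle
ties; two-sided p doubles the smaller tail) and fall back to scipy's
tie-corrected normal approximation otherwise; Bonferroni families
default to the set of pairs tested at one taxonomic level and are
configurable.

## Ontogeny

Chamber series are expressed in the coiling-axis frame.  α is the
angle between successive radius vectors projected onto the plane
perpendicular to the axis, signed by the right-hand rule; the dominant
sign defines the coiling direction, α is reported positive along it in
(0, 2π], and the whorl number is Σα/2π.  z is the signed distance from
the proloculus centroid along the axis (an absolute-value flag is easy
to add downstream; signed is the default because translation direction
is informative).  T is undefined (NaN, flagged) when |Δr| < 10⁻³ μm.
D uses the chamber length L as the generating-curve extent,
D = (r − L/2)/(r + L/2), clamped at 0 with a warning when a chamber
overlaps the axis.  Each algebraic form sits in its own few lines so a
different transcription can replace any one without touching callers.

Axis fitting minimizes helicospiral residuals — log r smooth
(quadratic) in chamber rank and z linear in r — over the axis direction
and its in-plane offset.  The direction seed is the principal normal of
the centroid cloud and the position seed the median curvature center of
consecutive centroid triplets; because the cost surface has local
minima when a trial axis threads the spiral at the wrong spot (or the
plane normal is badly tilted on high-translation shells), the optimizer
escalates through a deterministic grid of offset and tilt restarts and
stops at the first machine-precision optimum.  The rank-based radius
model deliberately avoids the winding angle inside the objective: angle
unwrapping is discontinuous in the axis parameters and wrecked
convergence on high-expansion shells.

Stage annotation is a heuristic layered on top of the quantitative
core, not part of it: chamber 1 is prolocular, the juvenile/neanic and
neanic/adult boundaries come from a rule table (defaults 10 and 14,
seeded from the published stage ranges of ~8–13 juvenile and ~12–16
neanic chambers), a kummerform final chamber is terminal, and an
optional change-point rule places the juvenile boundary at the break in
log-volume growth (two-regime least-squares split).

## Synthetic generators

The barcode generator plants a star-like substitution hierarchy: a
random root motif, then fixed expected substitution fractions per level
(defaults 0.08 / 0.02 / 0.004 for morphospecies / genotype /
basegroup, copy variants at 0.001).  The magnitudes are a calibration
choice — chosen once so that between-level distances separate by
roughly 5× and the barcode gap structure is unambiguous — not measured
values.  No indels by default; partial reads are contiguous prefixes or
suffixes (primer-limited coverage).  Randomness flows through numpy's
PCG64 generator; identical seeds give byte-identical outputs across
platforms.

`study_barcode_dataset` instantiates the generator with the design of
the published survey: 6 morphospecies whose genotype/basegroup/basetype
structure yields 17 basetypes in 15 basegroups, 147 curated reads, a
3-variant co-occurrence witnessed by two cloned individuals, one
single-individual co-occurrence (the contamination case), and a tail of
truncated low-quality reads.  The copy variants substitute at distinct
sites by construction so the planted counts hold for every seed.

The shell generator grows a log helicospiral: radii r_k =
r₀·W^(θ_k/2π), heights z = T·(r − r₀), volumes coupled to r³ by
default.  Two extensions cover features real specimens show that pure
r³ coupling cannot: a `deuteroconch_ratio` (the second chamber is
consistently smaller than the proloculus in the scanned specimens) and
an optional explicit per-chamber `volume_growth` ratio (species with
late-growth dominance allocate volume much faster than radius³).  The
kummerform terminal chamber is 0.6× the penultimate volume — any
factor < 1 expresses the biology; 0.6 is unambiguous.
`study_shell_configs` sets chamber counts, proloculus diameters and
kummerform flags to the published per-specimen values; the *G. ruber*
volume ratio is solved (Brent) so its three final chambers hold 94% of
the total inner volume, making the printed morphometric facts the
generator's calibration inputs.

What the generators do **not** emulate: rRNA secondary structure,
coalescent genealogies within taxa, alignment uncertainty or indels,
chimeras, geographic population structure (stations are assigned
uniformly), CT imaging noise or segmentation error.  Tests passing on
these data therefore demonstrate that the *algorithms* recover planted
structure under the stated noise models, not that real surveys are this
clean.

## Problem sizes

The defaults keep every stage desk-scale: ~190 synthetic reads of
1000 bp, 17-taxon distance matrices, 12-tip trees for the PTP oracle
suite, 50-seed shell round trips, 10⁴-replicate rarefaction
resampling.  These sizes are the package's own test design; all module
APIs accept larger inputs unchanged.

## Known limitations

* The barcode-gap detector is a clean-room design in the spirit of
  ABGD, not a port; on data without a dominant gap its initial/
  recursive pair can differ from the published server's.
* The simplified PTP is a heuristic; for publication-grade delimitation
  import the external tool's partition via the import path.
* Partial-read placement assumes truncation without indels; reads with
  internal gaps relative to the reference need upstream alignment.
* Exact Mann–Whitney enumeration grows combinatorially; above 8 per
  group the normal approximation is used (agreement within ~0.02
  spot-checked at the boundary).
* Stage annotation is descriptive; boundaries between ontogenetic
  stages are not sharp in the underlying biology.
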