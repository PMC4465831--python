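# Methods

`coopbind` quantifies cooperative protein–DNA recognition from molecular
ensembles.  The motivating system is the OCT4–SOX2 pair on a composite DNA
motif: OCT4 binds through two domains (the POU-specific domain, POU_S, and
the POU homeodomain, POU_HD) joined by a flexible linker, and SOX2 modulates
the DNA-binding strength of both — the first through a direct protein–protein
interface, the second through deformations propagated along the DNA.  The
package implements the full analysis chain for such systems: umbrella-sampling
free-energy profiles of domain unbinding, their reduction to macroscopic
binding free energies and a cooperativity, and the interface/orientation/
geometry/network analytics that characterize the bound ensembles.

## The unbinding coordinate and the bias model

The collective variable is d_min, the minimal heavy-atom distance between the
pulled domain and the DNA.  Hydrogens are excluded everywhere (contacts,
d_min, bias bookkeeping): the restrained pair list is defined over heavy
atoms, and distance criteria are applied consistently.

The restraint energy (`umbrella_fe.bias_energy`) is piecewise:

    U = Σ_ij k (d_ij − d_c)²   over pairs with d_ij < d_c,  if d_min < d_c
    U = k (d_min − d_c)²       on the minimal pair only,    otherwise

with no factor ½, so the stationary variance of a harmonically restrained
flat landscape is k_B T / 2k.  This shape forbids any pair from approaching
below the current window center while letting pairs separate freely, which
permits progressive, hierarchical unbinding.  The multi-pair branch cannot be
represented in a one-dimensional reweighting, so WHAM models the bias as
k (x − d_c)² in the scalar coordinate — the same approximation implicit in
reconstructing a 1D profile in d_min.  The exact multi-pair form is retained
in `bias_energy` for configuration-level checks.

Default window protocol: 60 windows every 0.05 Å covering d_min from 2.55 to
5.5 Å, k = 300 kcal/mol/Å² (`window_grid`).  The first 6/22.5 ≈ 26.7% of each
window's series is discarded as equilibration (configurable per window).

## WHAM, errors, and the θ diagnostic

`wham` solves the standard self-consistent weighted-histogram equations on a
0.01 Å grid (tolerance 10⁻⁶ k_BT on the window free energies, at most 10⁵
iterations), anchors min G = 0, and restricts the profile to sampled bins.
Non-overlapping neighbor histograms produce a warning, not an error — the
profile may then be defined only up to disjoint segments.

Per-bin uncertainties (`wham_error`) come from a Bayesian bootstrap: each
window's production series is subsampled at its statistical inefficiency
(initial-positive-sequence autocorrelation estimator), each replicate draws
Dirichlet(1,…,1) weights over those samples and re-solves WHAM.  A profile is
defined only up to an additive constant, so each replicate is aligned to the
base solution by a counts-weighted offset before the per-bin standard
deviation is taken; errors are therefore *shape* uncertainties, ≈ 0 in the
best-sampled region and growing toward the tails.  Aligning by the per-replicate
minimum instead would fold the anchor's own noise into every bin.

The sampling-consistency diagnostic θ (`theta_consistency`) compares, for
each pair of consecutive windows, the two locally unbiased density-of-states
estimates: each histogram is multiplied by exp(+U_i/k_BT), normalized over
the shared support, and θ is the L1 distance (0 = identical inferred
densities, 2 = disjoint support).  The published account of this diagnostic
defers its formula to prior work, so the L1 form here is this package's own
definition with the same diagnostic role.  The comparison region is
restricted to bins within 2 harmonic standard deviations of *both* restraint
centers: outside that region the exponential unbias factor amplifies
near-empty bins into pure noise, which would swamp genuine inconsistency
(converged pairs would otherwise score θ ≈ 1 from tail noise alone).

## Macroscopic ΔG

`pmf_to_dG` integrates the Boltzmann density ρ(x) ∝ exp(−G(x)/k_BT)
trapezoidally on the profile grid:

    ΔG = −k_B T · ln [ ∫_lower^threshold ρ dx / ∫_threshold^upper ρ dx ]

The lower limit is the lowest sampled bin; the upper limit defaults to
5.5 Å.  Note the sign in the exponent: a bound state must sit in a
free-energy *well*, i.e. ρ must be largest where G is smallest; a positive
exponent would invert the bound/unbound weighting and flip the sign of every
affinity.  (The source text's printed proportionality has the opposite sign;
it is treated here as a typographical slip, corrected openly rather than
silently.)  `threshold_sweep` evaluates the estimate at thresholds 3.1–4.3 Å
every 0.2 Å, the range over which the bound/unbound boundary is ambiguous in
practice.  ΔG errors propagate from per-bin profile errors either linearly
(first order through the log-ratio of trapezoidal sums, bins independent) or
by Monte-Carlo resampling; the two agree to first order for small errors.
The trapezoid rule is a choice — the quadrature used originally is not
stated.

## Cooperativity bookkeeping

With ΔG for each domain measured with and without the partner,

    ΔΔG_coop = [ΔG_S(+) − ΔG_S(−)] + [ΔG_HD(+) − ΔG_HD(−)]

assuming the partner changes neither the inter-domain cooperativity nor the
linker contribution.  Errors combine in quadrature (independent profiles);
this reproduces every printed error of the packaged reference table.  Values
are reported at 2 decimals, rounded half-away-from-zero.  `table_audit`
recomputes the cooperativity column from the four ΔG columns and flags rows
that disagree with a provided printed column by more than 0.01 kcal/mol, as
well as thresholds where a ΔG column reverses its monotone trend; in the
packaged reference table the two largest-threshold rows are flagged on both
counts (consistent with a sign-digit typo in one column), and are reported —
never corrected.

## Interface and geometry analytics

**Contacts** (`contacts`): an atom pair is in contact at ≤ 4.5 Å (tie
included); a contact is *recurrent* if present in strictly more than 50% of
frames.  Per-residue profiles count atom pairs (not partner residues) and
split DNA partners into base vs sugar-phosphate by atom name.  Unbinding
profiles report, per separation label, the fraction of reference recurrent
pairs still within the cutoff (intact = present in > 50% of that window's
frames) and the count of contact pairs outside the reference recurrent set.

**Orientation** (`orientation`): the DNA frame takes v_x between the centers
of the first and last base pairs of the binding site (base-atom centroids —
the hydrogen-bonded pair core straddles the helical axis), v_t across the
first base pair between the two strands' backbone reference atoms (P,
falling back to C3'), v_z = v_x × v_t, v_y = v_x × v_z.  The phrase defining
v_t admits several atom choices; the P-to-P reading is the one that yields a
transverse vector, and the atoms are configurable.  The docking-helix axis
is the principal component of its backbone positions, signed N→C — stable
for 8–12 residue helices and testable against parametric constructions,
unlike a rotational fit.  Rock is the signed angle (atan2) of the axis
projected on the v_y/v_z plane measured from v_y; Tumble the same in the
v_x/v_z plane from v_x.  A vanishing projection yields NaN for that angle
with a warning.  Conformational areas in the Rock/Tumble plane are compared
as sqrt(λ₁λ₂) of the 2D covariance (confidence-ellipse area up to a common
factor, which cancels in ratios).

**DNA geometry** (`dna_geometry`): groove widths use a deliberately simple
convention, tagged on every output: width at level i = minimal cross-strand
P–P distance within a signed register window (|offset| 2–5 for the minor
groove, 5–9 on the opposite side for the major), minus 5.8 Å for the
phosphate radii.  The register sign is auto-detected from the structure
(grooves are directional in an antiparallel duplex), and levels lacking the
full window — or within 2 of an end — are flagged undefined.  On the ideal
duplex this yields ≈ 5.6 Å (minor) and ≈ 12.1 Å (major), matching canonical
fiber-diffraction B-DNA; values are not comparable to curvilinear-axis
helicoidal analyses, which are out of scope.  Axis bending at level i is the
angle between the base-pair-center chords c_i − c_{i−2} and c_{i+2} − c_i.
Ensemble summaries carry block-averaged standard errors: block sizes double
from 1 and the SE is read at the largest size still leaving ≥ 8 blocks (the
plateau when the correlation time is resolved; an estimate with ~25%
intrinsic accuracy at these block counts).

**Dynamic network** (`dynnet`): nodes are Cα plus Cβ per protein residue
(one Cα node for Gly/Ala/Pro) and two per nucleotide — backbone anchored on
C3', base anchored on N3 (purines) or C4 (pyrimidines).  C_mn is the
dot-product-normalized covariance of the anchor-atom displacement vectors
after superposition (anchor atoms, not represented-set centroids — the
standard convention of dynamical-network implementations).  Edges require at
least one atom-atom contact between the represented sets persisting in
strictly more than 75% of frames, excluding trivially connected neighbors
(the two nodes of one residue, sequence-adjacent Cα nodes, sequence-adjacent
same-strand DNA backbone nodes); edge length is d_mn = −log|C_mn|, with
|C| = 0 edges dropped (infinite length).  Shortest paths use Dijkstra with a
lexicographic tie-break; suboptimal paths enumerate all simple paths within
a dimensionless offset (default 5, in the same −log units) of the optimum by
depth-first search with an admissible remaining-distance bound, reporting
per-edge traversal counts.  Communities are Girvan–Newman (edge betweenness
computed with the −log|C| lengths) cut at maximum modularity, evaluated on
the unweighted topology.

## Synthetic data: what it emulates and what it does not

The generators in `toy_systems` reproduce the *statistical structure* the
analyses consume, not molecular physics:

* `gen_ideal_bdna` — a regular helix (rise 3.38 Å, twist 36°) with five
  coarse atoms per nucleotide at fixed cylindrical coordinates chosen from
  canonical B-DNA geometry (P at radius 8.91 Å, azimuth ±71° from the
  base-pair dyad; sugar atoms between; base proxies straddling the axis).
  Cross-strand phosphate distances, groove widths, and frame vectors are
  realistic; base chemistry, sequence-dependent structure and sugar pucker
  are not represented.
* `gen_toy_complex_ensemble` — duplex plus pseudo-protein domains (five
  atoms per residue on an ideal α-helical path).  Designated protein–DNA
  atom pairs toggle between a bound (3.5 Å) and an unbound (6.5 Å) placement
  by independent Bernoulli draws with a prescribed persistence; the
  placement direction is chosen per contact to maximize clearance from all
  other DNA atoms, so toggling changes exactly the designed pair (plus, for
  partners deep in the duplex, occasional sub-percent noise-induced grazes).
  Correlated motion is injected as scalar Gaussian node displacements with a
  prescribed covariance along a common direction, plus isotropic N(0, σ²)
  positional noise (σ = 0.1 Å default).  Frame-to-frame displacements are
  independent — there is no kinetics, no solvent, no force field; passing
  tests demonstrate estimator correctness, not realism of dynamics.
* `gen_bd_umbrella` — overdamped Euler–Maruyama dynamics on a prescribed 1D
  free-energy curve plus the harmonic window restraint, with reflecting
  boundaries at the grid edges (boundary artifacts are excluded from the
  analysis range).  Defaults D = 0.1 Å²/ps, Δt = 0.01 ps.  Two stability
  guards are enforced: drift max|G′|·Δt·D/k_BT < 0.1 on the grid, and
  restraint stiffness 2k·D·Δt/k_BT < 0.25 — beyond that the discrete
  stationary variance is visibly biased (the k = 300 default restraint needs
  Δt ≲ 2×10⁻⁴ ps to reproduce Boltzmann variance within a few percent).  At
  the default production settings the residual discretization bias is a few
  percent of k_BT near well bottoms — visible as a small systematic
  component in ΔG recovery on top of the (much smaller) statistical error.
* `double_well_pmf` — the reference landscape for pipeline validation: a
  3 kcal/mol bound well at 3.05 Å, a barrier at 3.6 Å (4 kcal/mol measured
  from the well bottom), a shallow secondary well at 4.6 Å on an otherwise
  flat unbound plateau, and a soft short-range wall.  The shape mimics the
  sharp bound→unbound transition near hydrogen-bond distances seen in
  protein–DNA dissociation profiles while remaining integrable by the
  Brownian sampler across its full range.

All generators are seeded and bit-reproducible.

## Validation problem sizes

The free-energy pipeline is validated at 20 windows × 10⁶ Brownian steps
(k = 15 kcal/mol/Å², centers 2.75–5.25 Å) — enough for the WHAM profile to
track the reference landscape to ≲ 0.1 kcal/mol RMS, against an acceptance
bound of 0.3 — with 40 bootstrap replicates for errors.  Estimator-recovery
checks use 2000-frame toy ensembles (contact occupancy ± 0.03), 5000-point
orientation clouds (area ratios ± 5%), and 10⁵-point AR(1) series (block SE
± 25%).  An independent binless MBAR iteration, implemented separately in
the test suite, cross-checks the WHAM window free energies to < 0.05
kcal/mol on a common subsampled dataset.

## Known limitations

* The groove convention is phosphate-distance based; absolute values differ
  from curvilinear-axis methods by construction, and only the ideal-B-DNA
  anchor and relative changes are meaningful.
* Linear ΔG error propagation treats per-bin errors as independent;
  neighboring WHAM bins are in fact correlated, so the statistical error can
  undershoot — the Monte-Carlo option shares this assumption.  Systematic
  integrator bias in the synthetic data is not included in either.
* The θ diagnostic's restriction to well-sampled regions means it cannot
  flag inconsistencies that live purely in far tails.
* Community detection is fixed to Girvan–Newman + modularity; alternative
  algorithms are out of scope.
* Per-residue contact counting sums over partner atoms; counting over
  partner residues would give smaller numbers.
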