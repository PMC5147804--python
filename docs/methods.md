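# Methods

Models, parameter choices and limitations of the `ssrobust`
implementation. Nothing in this note is an empirical claim beyond what
the test suite and the acceptance script actually compute.

## Structural annotation

### Secondary structure (3-state) from backbone geometry

Residue conformations are assigned from backbone hydrogen bonds using
the classic electrostatic bond energy

```
E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]
```

with a bond when `E < -0.5`. Amide hydrogens are reconstructed at
`N + unit(C_prev - O_prev)` since most coordinate files lack them.
From the bond matrix, n-turns (CO(i)..NH(i+n), n = 3, 4, 5) with two
consecutive turn starts mark helical runs, and parallel / antiparallel
bridge patterns mark strands; helix takes priority over strand, and
everything else is coil. When reading 8-state assignments from DSSP
files instead, the reduction is H,G,I -> H; E,B -> E; rest -> C
(configurable; this mapping choice is stated rather than assumed
because G (3-10) and B (isolated bridge) sit on the class boundaries).

### Accessible surface area and RSA

Shrake-Rupley with a deterministic golden-spiral point set (default 960
points per atom), probe radius 1.4 A, van der Waals radii C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20, other 1.8 A. A single isolated atom
reproduces the closed form `4*pi*(r+1.4)^2` within 1% at 960 points
(tested). RSA divides a residue's ASA by its maximum in an extended
Gly-X-Gly tripeptide built with the same geometry and the same ASA
code, which makes the normalization self-consistent: the central X of
the reference tripeptide scores RSA ~ 1 by construction, and observed
RSA can exceed 1 (retained, not clipped - chain termini are genuinely
more exposed than the reference).

### Residue contacts

Two residues are in contact when any inter-atomic surface gap
`d - r_i - r_j` is below 0.25 A, excluding intra-residue pairs and the
peptide-bond C(i)-N(i+1) pair. The production path prunes candidate
pairs with a cKDTree; tests require bit-identical agreement with the
all-pairs double loop. Per-residue summaries are the contact count and
the mean chain separation |i - j| of the partners ("contact
distance"). Contacts are *counted*, not weighted by interaction
strength: the robustness analyses treat the presence of a constraint as
the unit of interest, and counting keeps the dual-route test oracle
exact.

## Ideal geometries

Backbones are constructed by natural-extension-of-reference-frame from
ideal bond lengths (N-CA 1.458, CA-C 1.525, C-N 1.329, C=O 1.231 A)
and angles, with omega fixed at 180. Helices use phi/psi = -57/-47.
Strands use (-138.707, 136.157), a *twist-free* extended conformation
found by minimizing the residue i -> i+2 frame rotation so the strand
has an exact two-fold screw symmetry; this is what allows a second,
rigidly placed antiparallel strand to sit at hydrogen-bond register
over arbitrary lengths (separation 4.0 A along the H-bond direction,
register shift 1.75 A along the axis). Natural strands are twisted;
the idealization trades realism for an exactly verifiable H-bond
ladder. Coil is sampled from the extended/PPII and left-handed
dihedral basins, deliberately avoiding the helical basin so that
"coil" structures annotate as all-C.

## Comparative metrics

- **Percent identity**: identical aligned (non-gap) columns over all
  aligned columns. Gap columns are excluded from the denominator - the
  indel signal is reported separately, not folded into identity.
- **Secondary-structure similarity (per class X)**: columns with X on
  both sides over columns with X on at least one side. Symmetric in
  the two sides (tested as a property).
- **Indel frequency (per class X)**: gap-opposed X residues over all X
  residues appearing on either side.
- **Filtering**: TM-score < 0.5 (same-fold threshold, normalized by
  the longer chain, i.e. the smaller of the two printed scores),
  either domain < 80 residues, antibody families b.1.1.1 / b.1.1.2,
  or non-monotonic residue numbering. Every exclusion is counted by
  reason and kept + excluded always sums to the input count.
- **Binning**: half-open [lo, lo+w) similarity bins, top bin closed at
  100. RSA conditioning uses the side-1 (reference) RSA; the top RSA
  bin is open-ended because RSA > 1 exists.

## Statistics

- **ANCOVA**: ordinary least squares of `y ~ group + covariate`
  against the covariate-only reduction; the group effect is the exact
  partial F-test. Rank-deficient designs raise rather than silently
  dropping columns.
- **Two-proportion test**: pooled z-test; when any expected cell count
  under the pooled proportion is below 5, Fisher's exact test is used
  instead. Points numerically on a fitted line in the
  contact-regression subsetting are treated as "on" (scale-relative
  1e-9 tolerance) rather than being classified by float noise.
- **Multiplicity**: Holm-Bonferroni for rejection decisions,
  Benjamini-Hochberg for adjusted values (both via statsmodels;
  cross-checked against direct step-down/step-up oracles in tests).
- **Predictor importance**: |Wald z| of each predictor in a joint
  logistic regression, rescaled so the larger equals 100. This is a
  deliberately simple, monotone summary; it is not variance decomposition,
  and separated or non-converged fits return "undefined" instead of
  numbers.
- Type-I calibration of ANCOVA and the proportion test is verified at
  alpha = 0.05 over 2,000 null replicates (binomial 95% band).

## Synthetic data generators

The generators exist so that every pipeline claim has a known truth to
recover. They emulate the *statistical shape* of diverged domain
pairs, not their physics.

**Diverged pairs** (`DivergenceConfig` defaults and why):

- `substitution_prob = 0.85`: substituted sites never retain their
  amino acid, so expected identity is exactly `1 - m`; 0.85 centers
  pairs in the 10-20% identity window where the comparative contrasts
  are computed.
- `p_flip = {H: 0.05, E: 0.15, C: 0.30}`: the qualitative robustness
  ordering helix > strand > coil is put in by hand; tests then check
  the pipeline recovers it, not that it is true of nature.
- `contact_lambda = 0.5`: flip probability is damped by
  `exp(-lambda * z(contacts))`, the contact-density mechanism. Setting
  `p_flip(H) = p_flip(E)` while keeping different contact models makes
  class differences flow *only* through contacts - the configuration
  used to test that contact-regression subsetting erases the gap.
- `rsa_beta`, `contact_model`, `indel_rate`,
  `contact_distance_model`: per-class Beta/linear/exponential shapes
  chosen to produce strands more buried than helices, helices with
  more contacts at equal RSA, helical contacts short-range (offset 3,
  scale 1) and strand contacts long-range (offset 5, scale 15), and
  indels concentrated in coil.
- Per-pair seeds are spawned from a single root `SeedSequence` and
  reduced mod 2^31, so runs are reproducible and pairs independent.

What the generator does **not** emulate: real fold topologies,
covariation between sites, alignment errors, or any energetic model of
stability - ddG values in the variant cohort are draws from two
normal distributions conditioned on the break flag, nothing more.

**Variant cohorts**: pathogenicity follows
`logit P = -2.0 + 1.2*break - 1.5*rsa + 0.35*ddg`; PolyPhen-2 scores
are Beta draws conditioned on the realized label. Coefficient recovery
within 2 standard errors at n = 20,000 is part of acceptance.

**Mutant sequence sets**: groups of near-identical sequences with 1-3
recorded substitutions; the expected scan output (>= 98% identity
pairing, indel-free substitution calls, >= 10-residue spacing,
homology-group dedup) is computed by direct positional comparison,
independent of the alignment-based production path.

## Numerical choices

- ASA point counts: 960 (default) balances the 1% single-atom error
  bound against runtime; the point set is deterministic so results are
  bit-reproducible.
- Mutation-scan prefilter: shared 8-mers. For substitution-only pairs
  at >= 98% identity over >= 64 residues the longest exact run is at
  least (L - d)/(d + 1) >= 8 by pigeonhole, so the prefilter is
  lossless in the regime the scan targets (and is tested against
  brute force).
- Alignment scoring for the scan: match 1, mismatch -1, gap open -5,
  extend -1 - heavily gap-averse because the target pairs are
  near-identical.
- Substitution spacing is measured in sequence-1 coordinates; for the
  indel-free near-identical pairs the scan accepts, the two coordinate
  systems agree.

## Limitations

- The secondary-structure assigner implements the hydrogen-bond core
  (helices via n-turns, strands via bridge ladders) without the full
  original tie-breaking cascade for overlapping 3-10/alpha/pi runs;
  on the ideal geometries used in testing the assignment is exact.
- RSA normalization constants depend on the chosen reference geometry;
  absolute RSA values are therefore comparable within this package but
  not necessarily to other tools' tables.
- All quantitative findings produced by the examples and tests concern
  synthetic data with planted effects; the package makes no empirical
  claim about real proteomes.
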