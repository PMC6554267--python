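# Methods

`macroconf` generates conformational ensembles for small molecules and
macrocycles by coupling a small set of physical ring movements to MMFF94s
energetics, optionally steered by square-well NMR restraints. This note
documents the model, the parameters that matter, the synthetic data used for
testing, and the numerical choices.

## Model and search procedure

Conformational search is template-free and non-stochastic. Starting from a
memory-free 3D structure (generated from the bond graph and recorded
stereochemistry only — any input coordinates are discarded), an evolving pool
of ring conformers is grown by repeatedly applying four movements until no
new conformer is found or a round cap is reached:

* **Bend** — for an eligible atom pair of a small-ring system, the torsion
  defined by (RHS-side centroid, axis pair, LHS-side centroid) is negated by
  rotating the smaller side and its pendant substituents about the axis.
  Eligibility: the pair is non-bonded, at least one pair atom belongs to a
  non-planar ring, and the cut does not separate ring-fusion or bridgehead
  atoms onto both sides. After the rotation the ring atoms are pinned with a
  quadratic positional penalty (to prevent reversion), minimized, released
  and minimized again.
* **Twist** — for each single bond whose smallest enclosing ring has ≥ 9
  atoms (the macrocycle threshold, used consistently everywhere) and that is
  not an amide C–N bond, the flanking window (a1, a2, a3, a4) is taken along
  the main cycle; a1–a3 are pinned and the end atom is forced around the
  bond axis to targets of ±60°, ±120° and 180° from its current position,
  each followed by pinned then free minimization. Both ends are twisted.
* **Flip** — pairs of rotatable main-cycle bonds whose midpoints are ≥ 4.0 Å
  apart and whose bond vectors V1, V2 and midpoint vector V3 satisfy
  min(V1·V2, V1·V3, V2·V3) > 0.3 (≈ 70° of allowed deviation from
  co-linearity) define a flip axis; the arc between the bonds (both arcs are
  tried; arcs crossing a bridge attachment are skipped) is rotated exactly
  180° about the midpoint axis, the end atoms pinned, and the conformer
  relaxed.
* **Bridge flip** — bridge atoms (e.g. a disulfide) are mirrored across the
  least-squares plane of the main cycle and relaxed with signed-volume
  chirality-enforcing terms active, then without.

Candidates are kept when they preserve every recorded stereo configuration,
fall inside the energy window, and are non-redundant against the pool by
ring-atom RMSD under **fixed atom labeling** (proper-rotation Kabsch, no
symmetry correction, threshold 0.3 Å). Fixed-labeling redundancy is
deliberate: two mirror-image chairs of cyclohexane, or rotated labelings of
a symmetric ring, are distinct search states even when geometrically
congruent, and the worked-example conformer counts are defined this way.
Symmetry-corrected RMSD is used only for evaluation against references.

For macrocycles with hydrogen-bond donors, trans-annular hydrogen-bond
networks are explored explicitly. Donor/acceptor pairs of the same
macrocyclic system qualify when the shortest non-bridging main-cycle path
between their anchors has at least 8 atoms (inclusive) and crosses no bridge
attachment. All pair triplets whose consecutive donor-side ring-index deltas
are exactly the negated acceptor-side deltas (modulo ring wrap) are
topologically able to form three simultaneous cross-ring hydrogen bonds.
Each triplet is minimized under three one-sided 2.0 Å distance wells, the
eight triplets with the lowest mean H···acceptor distance are retained, a
fresh constrained structure is embedded for each, and full ring searches run
from each constrained start plus the unconstrained ("agnostic") start. The
pools are merged by energy after re-scoring against the data restraints only
— the triplet wells are search scaffolding, not data.

After ring search, exocyclic rotatable bonds are elaborated greedily
(sp3–sp3: ±60°/180°; conjugated: 0°/180°), each variant minimized,
deduplicated by heavy-atom RMSD and windowed. The final ensemble is sorted
by the combined objective, windowed (20 kcal/mol for macrocycles, 10
otherwise), pruned by heavy-atom redundancy keeping the lowest-energy
exemplar of each cluster, and truncated to the mode cap.

The search objective everywhere is the **combined energy**: force-field
energy plus the restraint violation energy (zero when no restraints are
given). NMR restraints, when supplied, are active from initial structure
generation through every minimization.

## Force field and restraints

Energies and minimization use RDKit's MMFF94s. Restraints map onto RDKit's
flat-bottomed constraint contributions, rescaled so the package's documented
forms hold exactly:

* distance well: `penalty · max(0, |d − dist| − wiggle)²` (kcal/mol,
  penalty in kcal/mol/Å²),
* torsion well: zero inside [lo, hi], `penalty · Δ²` outside (Δ = periodic
  angular distance to the nearest bound, degrees; penalty in kcal/mol/deg²),
* positional pin: `k · |r − r₀|²`, default k = 100 kcal/mol/Å².

Both are continuous and once-differentiable at the well edges. Centroid
(`qnmr`) group wells and chirality-enforcing signed-volume terms have no
native RDKit contribution; minimization for those restraint sets switches to
an L-BFGS-B loop over the force-field energy/gradient plus analytic custom
terms. The profiler and the minimizer evaluate the same closed forms, so
reported violation energies equal the restraint energies the minimizer saw.

Convergence tolerance is a 1e-4 kcal/mol/Å gradient norm with a 2000
iteration cap. Stereo is recorded at import (CIP codes and double-bond
labels) and re-perceived from coordinates after every move; candidates that
invert any recorded center are discarded.

## Search modes

Seven modes trade depth for speed; pool caps follow the published mode
sizes: `pfastf`/`pfast` 50, `pscreen` 50 (120 when total flexibility > 8),
`pgeomf`/`pgeom` 250, `pquantf`/`pquant` 1000. Deep modes (`pgeom`,
`pquant`) enable flips and hydrogen-bond network exploration; shallow modes
skip both. Round caps (2–50 by mode) bound the fixed-point iteration; the
ring phase retains **and expands** conformers within the 20 kcal/mol window
(states 10–20 kcal/mol above the minimum are legitimate stepping stones
whose neighbours often fall back inside), while 10 kcal/mol is the final
window for non-macrocycles. Exact depth knobs of the original tool are
unpublished; these defaults were fixed on the package's own fixtures.

Determinism: move enumeration is a pure function of (graph, conformer),
candidate processing follows enumeration order, and multi-threaded move
application merges results in task order — ensembles are byte-identical
across thread counts and independent of any coordinates on the input.

## NMR constraints and RDC validation

The constraint dialect is whitespace-separated records with 1-based atom
indices (`nmr i j dist= wiggle= penalty=`, `qnmr i1,i2,.. j,..`,
`torsion a b c d lo= hi= penalty=`, `#` comments); `qnmr` measures from the
centroid of a degenerate proton group. Profiling reports per-conformer
force-field and violation energies with discrete violation counts (distance
thresholds 0.2/0.5 Å beyond the allowance, torsion 5°/15°) and
per-constraint violation frequency and magnitude.

RDC validation fits the five independent Saupe elements by least squares
(SVD) on the direction-cosine design matrix, with reduced couplings
`D = bᵀ S b` (unit prefactor — per-nucleus dipolar prefactors are absorbed
into the observed values, adequate for single-type backbone RDC sets), and
reports `Q = rms(D_obs − D_calc) / rms(D_obs)`. Rank-deficient geometries
(fewer than five independent directions) are rejected with a diagnostic.

## Synthetic data

The fixtures module builds everything the tests need:

* cycloalkanes C3–C60 (cyclononane is the smallest macrocycle; cyclooctane
  is below the threshold);
* public-structure SMILES constants (benzene, decalin, tetracycline);
* toy head-to-tail cyclic peptides: per residue the main ring gains N (or an
  ester O), Cα and carbonyl C (3n-atom ring), with a minimal sidechain
  alphabet (H, methyl, hydroxyl, phenyl, thiol), optional N-methylation,
  proline, ester linkages and a disulfide bridge. A 9-residue AbA-like
  depsipeptide (27-atom ring, three backbone N–H donors) and a 14-residue
  disulfide-bridged SFTI-like peptide (42-atom main ring) are provided.
* synthetic NOE-like constraints: fold-defining long-range pairs (polar H →
  acceptor, plus H–H pairs ≥ 6 bonds apart, < 5 Å in the reference) sampled
  seeded from a reference conformer, emitted with the standard ±0.5 Å
  allowance. Sequential short-range pairs are excluded because they carry no
  fold information and defeat the generator's purpose (parameter-recovery
  testing).
* synthetic RDCs forward-calculated for every C–H/N–H bond from a known
  alignment tensor with optional multiplicative noise.

What the toy peptides do not emulate: real sidechain chemistry and charge
states, solvent, cis/trans amide isomerism control, and crystallographic
references. Passing the recovery tests shows the machinery concentrates
ensembles when restraints are informative; it does not certify accuracy on
real NMR data.

## Worked-example counts and their caveats

The cyclodecane count is measured by running the standard macrocycle mode
(`pgeom`) twist-and-bend search from a memory-free start: the pool saturates
the mode's 250-conformer cap (the uncapped labeled-minimum space keeps
growing far beyond it, so the cap is the operative convergence criterion).
The tetracycline bend search converges at ≈ 52 ring conformers under the
same windows and the 0.3 Å redundancy default. Both counts depend on the
force field (MMFF94s here, not the original's proprietary MMFF94s variant)
and on the unpublished redundancy threshold, so they are reported as
computed, with order-of-magnitude checks in the test suite.

## Known limitations

* Aromatic-mediated macrocycle bridges are detected only when the mediating
  path is a single junction-to-junction chain; more deeply fused mediating
  systems fall back to fused-ring handling.
* Ring RMSD for macrocycles is computed over macrocyclic-system atoms only;
  exocyclic atoms fused to the ring are excluded.
* mol2 files are read (via RDKit) but ensembles are written as SDF only.
* The numeric (L-BFGS-B) minimization path is an order of magnitude slower
  than the native path; it is used only when centroid wells or chirality
  terms are present.
* Heuristic protonation on import relies on RDKit sanitization plus explicit
  hydrogen addition; unusual charge states should be supplied pre-protonated.
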