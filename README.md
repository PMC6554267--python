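# macroconf

Template-free, non-stochastic conformer generation for small molecules and
macrocycles, driven by MMFF94s energetics and physical ring movements, with
optional square-well NMR restraints and RDC-based ensemble validation.

Macrocycles (rings of nine or more atoms) are hard for torsion-library
conformer generators because ring closure couples every ring torsion.
`macroconf` instead manipulates rings the way a chemist manipulates a
plastic model: it **bends** small-ring systems across non-bonded atom pairs,
**twists** macrocyclic bonds by forcing an atom around the bond axis,
**flips** near-colinear sub-cycles 180° about the axis between two ring
bonds, and flips **bridges** (e.g. disulfides) to the opposite face — each
move followed by pinned, then free, force-field minimization. For peptidic
macrocycles it additionally enumerates topologically compatible triplets of
trans-annular hydrogen bonds directly from the graph and seeds constrained
searches from them. Ensembles are energy-windowed (ΔE ≤ 20 kcal/mol for
macrocycles, 10 otherwise relative to the discovered minimum), redundancy
pruned, and capped per search mode (50/120/250/1000 conformers).

Sparse NMR data plug in as square-well restraints — distance wells
`penalty·max(0, |d−dist|−wiggle)²` between protons (`nmr`) or proton-group
centroids (`qnmr`), and torsion wells that are zero inside [lo, hi] and
quadratic outside — active from initial 3D generation through every
minimization, with the search ranking conformers by force-field energy plus
violation energy. Ensembles can be profiled against a constraint set and
validated against residual dipolar couplings via an SVD-fitted Saupe
alignment tensor and the Q-factor `rms(D_obs−D_calc)/rms(D_obs)`.

## Worked example

```python
from macroconf import fixtures, generate_conformers, SearchConfig
from macroconf.chemgraph import perceive_macrocycles

graph = fixtures.make_cycloalkane(10)           # cyclodecane, C10H20
print(perceive_macrocycles(graph)[0].ring_size)

ens = generate_conformers(graph, SearchConfig.from_mode("pgeom", seed=1))
print(len(ens), round(ens.min_energy, 2), round(ens.relative_energies().max(), 2))
ens.write_sdf("cyclodecane.sdf")
```

prints

```
10
250 17.56 12.13
```

— cyclodecane is perceived as a 10-atom macrocycle; the standard-mode
(`pgeom`) twist-and-bend search fills the 250-conformer pool, the lowest
MMFF94s energy found is 17.56 kcal/mol, and every retained conformer lies
within 12.13 kcal/mol of that minimum (inside the 20 kcal/mol macrocycle
window). The same call on a cyclic peptide with donors automatically runs the
hydrogen-bond network exploration; passing a `ConstraintSet` (from
`macroconf.nmr.parse_constraint_file`) makes the whole search
restraint-guided.

The same pipeline is exposed on the command line:

```bash
confgen generate mol.smi --mode pgeom -o out.sdf
confgen profile out.sdf constraints.txt myprefix --ref crystal.sdf
confgen evaluate out.sdf --ref crystal.sdf --ring-rmsd
confgen fixtures cycloalkane-10 -o cyclodecane.sdf
```

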