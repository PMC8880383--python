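# capsid

Geometry and RNA-contact analysis for the capsids of single-stranded RNA
bacteriophages, built around the polymorphic particles of phage Qβ.

The coat protein (CP) of an ssRNA phage assembles into several
quasi-equivalent shells: the canonical *T* = 3 icosahedron, a larger
*T* = 4 icosahedron, 5-fold elongated prolate and oblate particles, and a
small D3-symmetric prolate elongated along a 3-fold axis.  This package
provides, as a library plus a `capsid` command line:

* **lattice** — explicit Caspar–Klug cages for all of these forms.  An
  icosahedral cage with triangulation number *T* = *h*² + *hk* + *k*² has
  60·*T* CPs on 12 pentamers and 10(*T*−1) hexamers; a 5-fold elongated cage
  with cap number *T* and elongation number *Q* has 30·(*T*+*Q*) CPs
  (*Q* > *T* prolate, *Q* < *T* oblate); the 3-fold small prolate joins two
  *T* = 1 caps through rings of six hexamers (132 CPs for *Q*₁ = 2,
  *Q*₂ = 3).  Every capsomer-adjacency edge carries one CP dimer, classified
  A/B (pentamer–hexamer) or C/C (hexamer–hexamer); the single maturation
  protein replaces one C/C dimer and an extra CP dimer sits inside the
  virion.  Cages interconvert by inserting rings of five hexamers at the
  5-fold equator with a 36° hemisphere rotation, and unwrap losslessly into
  2D nets (JSON/SVG).
* **geometry** — hexamer curvature from the three arch angles θ, ϕ, Ψ
  across the opposite subunit pairs of a hexamer (180° = flat), with the
  four-way curvature classification (over-arched ≈130°, normal ≈155°,
  less-arched ≈170°, straight ≈180°) and CD/DE-loop displacement between
  hexamer conformations.
* **contacts** — stem-loop inventory from a secondary structure, a census of
  stem-loop/CP contacts at a heavy-atom distance cutoff (5 Å), and
  classification of each contact as operator-like, CP-sandwiched or
  CP-anchored relative to its CP dimer.
* **rna_pairs** — detection of kissing loops (antiparallel loop–loop
  Watson–Crick duplexes), branched kissing loops (loop-to-bulge) and
  fold-back pairings from sequence plus secondary structure.
* **synthetic_data** — deterministic generators for idealized capsid
  structures, hexamers with prescribed arch angles, stem-loop/dimer fixtures
  with planted binding modes, and RNA with planted kissing loops, so the
  whole pipeline is testable without downloading deposited models.

## Worked example

```python
import capsid
from capsid.lattice import composition, elongate_by_ring, hemisphere_twist

oblate = capsid.build_elongated_5fold(3, 2)
comp = composition(oblate)
print(oblate.n_cp, oblate.n_pentamer, oblate.n_hexamer)   # 150 12 15
print(comp.n_dimer_total, comp.n_dimer_AB, comp.n_dimer_CC)  # 75 55 20

t3 = elongate_by_ring(oblate)           # insert a ring of five hexamers
print(t3.n_cp, t3.n_hexamer)            # 180 20  (the T=3 composition)
print(hemisphere_twist(oblate), hemisphere_twist(t3))  # 0.0 36.0

virion = capsid.build_icosahedral(3)
c = composition(virion, mat_substituted=True, internal_dimer=True)
print(c.n_dimer_capsid_after_mat, c.n_dimer_with_internal)  # 89 90
```

The oblate shell has 150 CPs in 12 pentamers and 15 hexamers (75 dimers);
inserting five hexamers at the equator rotates one hemisphere by 36° and
yields the 180-CP *T* = 3 composition.  On the *T* = 3 virion, replacing one
C/C dimer with the maturation protein leaves 89 shell dimers, and the
internal dimer restores a 90-dimer total.

Hexamer curvature on the ideal prolate embedding:

```python
from capsid import geometry as geo
prolate = capsid.build_elongated_5fold(3, 4)
for g in geo.hexamer_geometries_from_cage(prolate):
    print(g.zone, round(g.theta, 1), g.curvature_class)
```

prints three hexamer environments — caps (θ ≈ 179.6°), tube wall
(θ ≈ 174.3°) and the five equatorial hexamers (θ ≈ 177.5°, classified
straight, the flat ring that lets the tube extend).

The same operations are available from the shell, e.g.

```sh
capsid build --symmetry 5fold --T 3 --Q 4 --out prolate.json
capsid compose prolate.json --mat --internal-dimer
capsid unwrap prolate.json --out net.svg
capsid simulate kissing --out-prefix kiss --n-hairpins 4 --planted 4
capsid kissing --seq kiss.fasta --ss kiss.dbn
```

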