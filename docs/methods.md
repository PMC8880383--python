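# Methods

## Capsid lattices

A cage is represented as a triangulated sphere whose vertices are capsomers
(12 pentamers and some number of hexamers), whose edges each carry one coat-
protein dimer, and whose triangular facets each contain three CP subunits.
This gives the bookkeeping identities used throughout:

    n_cp   = 5·n_pentamer + 6·n_hexamer = 3·F
    dimers = E = n_cp / 2,      V − E + F = 2.

**Icosahedral construction.** The Caspar–Klug lattice vector C = (h, k) on
the hexagonal lattice (T = h² + hk + k²) defines an equilateral tile
(0, C, rot60·C) laid onto each of the 20 faces of an icosahedron scaled so
its edge equals |C|.  Capsomer positions are the lattice points of each
tile mapped affinely onto its face and merged across shared edges.  Because
each 3D face is congruent to its tile, within-face lattice spacing is
exactly 1 and folding across edges only shortens distances, so adjacency is
recovered with a metric threshold of 1.2 lattice units (the closest
non-adjacent pair on any supported form is > 1.4).  Every face triple is
oriented counterclockwise as seen from outside; this keeps chiral (skew)
lattice classes such as T = 7 glued coherently — with mixed orientations the
tiles meet mirror-inverted at folds and the lattice tears.  Every
constructed cage is audited: exactly 12 degree-5 vertices, all others
degree 6, E = 3V − 6, and F = 2V − 4 triangles; a failed audit raises.

**5-fold elongated construction.** The polyhedron keeps the two icosahedral
pentagonal caps (5 faces each) and replaces the middle band by 10 body
triangles between the two pentamer rings.  In the unrolled tube strip the
southern ring is offset from the northern one by a lattice vector B with
|cross(C, B)| = Q, so each body triangle carries a tile of lattice area Q
and n_cp = 30·(T + Q).  B is reduced modulo C (a pure relabeling of the
southern ring) so each facet pairs with its nearest ring vertex, and is laid
with the handedness matching the caps' outward-CCW orientation.  The ring
twist τ and axial drop d solve the two chord equations
2ρ²(1 − cos τ) + d² = |B|², 2ρ²(1 − cos(τ − 72°)) + d² = |B − C|²; of the
two roots the one nearest the twist predicted by the unrolled strip
(360°·⟨B, Ĉ⟩ / 5|C|) is geometric, the other is its mirror.  Q is valid
when Q ≥ 1, Q ≡ T (mod gcd(h, k)) and the chord system has a real axial
solution; other values are rejected.  Consecutive Q values alternate the
ring registry between staggered and eclipsed, i.e. each inserted ring of
five hexamers rotates one hemisphere by 36°, which is how
`elongate_by_ring` realizes the oblate → T=3 → prolate series.

**3-fold (D3) small prolate.** The published small prolate has 132 CPs,
12 pentamers and 12 hexamers with D3 symmetry and T = 1 caps.  Those counts
fix the combinatorics: V = 24, E = 66, F = 44, and the unique simple
realization is two 4-facet T = 1 caps (six pentamers each, boundary a
hexagon alternating top/ring pentamers) joined by two staggered rings of six
hexamers.  The builder generalizes this to r rings with alternating 30°
registry, mapping the elongation labels as r = Q1 + Q2 − 2T − 1 (with
Q1 = Q2 = T the degenerate icosahedron, r = 0), so (1, 2, 3) → 132 CPs as
observed and (1, 2, 2) → 96 CPs.  Each cap/ring and ring/ring interface is
a triangulated band of 12 crossing edges whose per-vertex counts alternate
1/3 — forced by the pentamer degrees (top pentamers take one belt edge, ring
pentamers three) — and the closed cage passes the same audit as above.
Caps other than T = 1 (not observed) are rejected.  This construction is
validated by D3 symmetry, the Euler audit and the published composition;
the original facet-layout drawing of the particle is not reproduced here.

**Dimer classes and subunit frames.** Each edge's dimer class follows the
capsomer kinds at its ends: pentamer–hexamer → A/B, hexamer–hexamer → C/C;
pentamer–pentamer contacts (T = 1-like caps, strongly oblate tubes) are
labeled A/B by convention since no C environment exists.  Each capsomer
places one pseudo-subunit per incident edge at 35% of the way to the edge
midpoint, projected onto the embedding surface (circumsphere for
icosahedra; a sphero-cylinder — cap spheres plus a tube cylinder through the
pentamer rings — for elongated forms), with an orthonormal triad (toward
partner, in-surface, outward).  The maturation-protein substitution removes
one C/C dimer from the shell tally (89 on T = 3) and the internal dimer adds
one back (90 total); requesting the substitution on a cage with no C/C
dimer is an error.

**Unwrapping.** The facet triangulation is unfolded along a BFS spanning
tree of facet adjacency; facets glued across tree edges share welded
capsomer copies, cut-edge capsomers appear as multiple boundary copies, and
every dimer edge is drawn exactly once.  The net carries site ids, so
reconstruction of the adjacency graph from the net is exact, which is the
losslessness property the tests check.  Pentamers are numbered I–XII from a
configurable anchor (default: the pentamer of greatest z), ordered by
descending z then azimuth; stem-loop markers attach to edge midpoints with a
genome-order color index.

## Arch angles

The arch angle of an opposite subunit pair (a,d), (b,e) or (c,f) is the
angle at the hexamer centroid m — the mean of the six subunit centroids
(backbone-atom centroids, to suppress side-chain noise) — between the
vectors to the two pair centroids.  A flat hexamer measures (180°, 180°,
180°) exactly; θ is assigned to the pair that leaves the other two angles
most similar (|ϕ − Ψ| minimal, matching the observation that ϕ and Ψ are
symmetry-equal), with ties broken toward the angle most deviant from the
mean.  Ring order a–f comes from an angular sweep about the ring normal
(smallest principal axis, oriented outward).  Curvature classes partition
(0°, 180°] at 142.5°, 162.5° and 175° — the midpoints between the observed
~130/~155/~170/~180 anchors — so each anchor sits safely inside its class.

Two properties of this centroid-based definition are worth knowing.  First,
it measures *asymmetric* doming: a perfectly C6-symmetric dome has all six
centroids on one circle and measures flat, so the synthetic hexamer
generator realizes symmetric angle triples like (155°, 155°, 155°) with an
asymmetric tilt embedding (solved per up/down sign pattern in a cotangent
form; among valid embeddings the best-conditioned one — largest minimum
tilt component — is used for noise robustness).  Second, on a curved
embedding the four off-axis subunits pull m radially inward, so the
equatorial hexamer of the ideal prolate measures θ ≈ 177.5° rather than
exactly 180°; the published value is quoted as ~180° and all comparisons of
measured angles use a ±5° band that absorbs this definition choice.  On
ideal embeddings the absolute angles also scale with the subunit inset
(default 0.35), so tests assert symmetry, zone structure and the equatorial
band rather than the atomic-model class anchors.

Loop displacement between two hexamer conformations superposes the anchor
subunit's backbone by least squares, then reports the distance between the
loop centroids of the opposite subunit and a toward/away direction relative
to the anchor's C-terminal residue.  Default CD/DE/FG loop ranges for the
132-residue coat protein ship as a data file and are approximate;
they are configuration, not measurement.

## Stem-loop census and binding modes

Stem-loops are maximal helices of ≥ min_helix (default 3) stacked pairs,
allowing ≤ max_bulge (default 2) bulged nucleotides between consecutive
pairs; junction helices count as separate stems, crossing (pseudoknotted)
helices are kept and flagged, and ids follow genome order.  The census
measures the minimum heavy-atom distance from each stem-loop's residues to
the protein components (CP dimers, Mat, internal dimer); "in contact" is
strictly below the 5 Å cutoff.  The binding mode of an in-contact stem-loop
against its dimer is decided in the dimer frame (origin at the dimer
centroid, dyad axis from least-squares monomer superposition, oriented
outward from the protein shell): operator-like if the arclength-resampled
backbone is within trace_rmsd_max (default 8 Å) of the canonical operator
trace under either monomer orientation; else CP-sandwiched if the apical
loop centroid lies within axis_tol (default 6 Å) of the dyad axis with both
monomers contacted; else CP-anchored if exactly one monomer is contacted.
The thresholds operationalize a visual criterion and are configuration with
these defaults.  The canonical operator trace ships as a synthetic pose
(`canonical_operator_trace`), the same pose the fixture generator plants, so
classifier and generator agree by construction at zero noise; with a
deposited virion model the trace can be replaced by the measured operator
backbone.

## Kissing loops

The duplex model is ungapped and antiparallel: the pair count of two
strands is the maximum number of Watson–Crick matches over all ungapped
offsets of one strand against the reverse of the other.  G-U wobbles are
off by default (both observed kissing duplexes are pure Watson–Crick).
Candidates are all apical×apical and apical×internal-strand pairs with at
least min_pairs (default 4, the smaller observed duplex) matches; the
loop-to-bulge case is flagged branched.  Fold-back pairing scores two
equal-length subsequences at fixed antiparallel alignment.

## Synthetic data

Generators are deterministic under their seed and emit ground truth.  The
pseudo coat protein is a rigid 10-residue CA-only motif (not a biological
model); capsid fixtures place one such chain per subunit on the cage
embedding, scaled to 60% of the inter-subunit spacing.  The stem-loop/dimer
fixture uses a two-monomer dimer (centroids ±8 Å, exact 2-fold about the
outward dyad) and phosphate-trace hairpins in the three canonical poses;
poses are separated by ≥ 14 Å trace RMSD, and at noise σ = 1 Å the planted
mode is recovered in ≥ 95% of seeded fixtures (100% in the shipped tests).
At σ = 2 Å the hexamer generator's angles stay within ±4° of the planted
values over 100 seeds.  Kissing-RNA fixtures are re-sampled until the
structure contains exactly the planted candidates, so "no spurious
candidate" is guaranteed at generation time.  Noise is isotropic Gaussian
on atom positions.  What the fixtures do not emulate: real CP sterics and
side chains, RNA helical geometry, sequence-dependent stem-loop shapes, or
cryo-EM coordinate error structure — so passing tests demonstrate the
correctness of the geometry and logic, not atomic-model accuracy.

## Problem sizes and limitations

The shipped tests and the acceptance script run entirely on the idealized
forms (up to 240 CPs per cage, grids of (T, Q) up to T = 13) and on
20-residue RNA fixtures; everything completes in seconds.  Analyses of the
deposited virion and VLP models (PDB 7LGE/7LGF/7LGG/7LGH/7LHD) are
implemented — mmCIF reading, chain clustering into capsomers, the census and
angle pipelines — but the coordinate files are not redistributable with the
package; the two tests that consume them report exactly what is missing.
Known limitations: 3-fold elongated cages support T = 1 caps only; the
2D net layout is automatic (faces may overlap visually for strongly
elongated forms, though the graph is always exact); and ideal-embedding
arch angles depend on the subunit-inset convention, so only the deposited
atomic models can reproduce the measured ~130/~155/~170 class anchors.
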