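# Methods

## Model

`aquabridge` predicts explicit bridging waters from geometry alone and
scores them with a simple directional hydrogen-bond term. The model
rests on the empirical observation that water–protein contact geometry
in high-resolution crystal structures is tightly distributed, so a
water bridging two polar atoms can be *constructed* rather than
searched for:

- ideal contact distances: d(H₂O–O) = 2.73 Å, d(H₂O–N) = 2.87 Å
  (element of the partner atom decides; sulphur is excluded — too few
  observations for reliable statistics);
- eligible bridged-atom separation: 3.65 Å < d(Xi–Xj) < 5.57 Å
  (μ ± 2σ of the 4.61 ± 0.48 Å survey fit; strict mode μ ± 1σ =
  4.13–5.09 Å), strict inequalities at the boundaries;
- water internal geometry: O–H = 0.96 Å, H–O–H = 104.45°;
- coordination counting: polar protein atoms within 2.99 Å (closed
  ball).

The constructed oxygen lies on the circle of points at ideal distance
from both partners (centre and radius via Heron's formula on the
triangle Xi–Xj–W). Among perimeter points, the one nearest the
projected midpoint of the shortest segment between the two sites'
orbital vectors is chosen, i.e. ideal distances exactly, orbital
deviation minimal. Distances to the partners are therefore exact to
machine precision by construction; only the *direction* of the water
from the Xi–Xj axis is inferred.

### Orbital vectors

Donors contribute one unit vector per polar hydrogen (X→H). sp²
acceptors carry two in-plane lone pairs at 120° from the X→parent
bond; ring nitrogens one lone pair along the external bisector; sp³
acceptors tetrahedral lone pairs completing the valence around the
known bonds. When a site offers several orbital vectors, all
combinations are evaluated and the one with the smallest summed
angular deviation at the constructed oxygen wins — deterministic, and
exact on fixtures whose lone pairs are aimed at the planted water.

Polar hydrogens are rebuilt uniformly (input hydrogens are discarded on
read): amide/guanidinium/ring N–H at ideal planar geometry, NH₃⁺
staggered against its parent chain, hydroxyls sampled at six 60°
torsions and fixed to the best summed H-bond score against neighbour
sites (first candidate on ties — isolated hydroxyls are deterministic).
Histidine carries a single neutral H on NE2 by default; both ring
nitrogens are typed as donor/acceptor-capable and degrade to the
correct effective role from the presence or absence of that hydrogen.

### Orientation variants

Two pure acceptors: one variant, hydrogens aimed at the partners by a
least-squares alignment of the rigid water frame (Kabsch on the two
O–H target directions). Two pure donors: one variant, lone pairs face
the donors. Any mixed combination: exactly two variants — if both
partners can accept, each serves once as acceptor of a water hydrogen;
a pure donor partner instead receives the water lone pair in two
mirror-image variants.

### Energy and gating

The packing program this algorithm descends from does not publish its
force-field formula, so a standard 12–10 hydrogen-bond potential with
squared-cosine angular weights stands in:

E = −|ε| · [5(d₀/d)¹² − 6(d₀/d)¹⁰] · cos²θ_don · cos²θ_acc

with ε = −5 kcal/mol well depth, d₀ the element-specific ideal
distance, θ_don the deviation from linearity at the donated hydrogen,
θ_acc the angle between the acceptor's best orbital and the incoming
hydrogen. E is clamped to zero beyond 3.5 Å, when any cosine is
non-positive, and in the short-range repulsive regime (a geometric
clash filter — oxygen ≥ 2.4 Å from every non-partner heavy atom —
handles sterics instead). A water is accepted when *both* legs pass
the threshold (default −2 kcal/mol; presets −4, −5; a `sum` gate mode
is available). Because the construction pins d = d₀ exactly, gating
depends only on angular quality and thresholds — no conclusion in the
test suite depends on the absolute energy scale.

## Packing integration

Rotamers are idealised residue templates (chemical component
dictionary via biotite) superimposed on the fixed backbone N/CA/C,
with χ angles set from a small bundled backbone-independent library
(2–3 most common conformers per residue; the TSV format is documented
so richer libraries can be swapped in). Accepted bridge waters are
duplicated onto both partner rotamers as solvated copies, competing
with the retained unsolvated originals. Duplicated waters are
half-weighted in self and pairwise energies so the physical water
counts once when both copies are chosen, and `emit_model` collapses
shared bridges to a single HOH. Waters bridging to fixed context atoms
(backbone outside the design shell, a retained ligand pose) attach to
the rotamer only. Goldstein dead-end elimination runs to a fixed
point; a single-flip Metropolis chain over a geometric cooling
schedule (T 15 → 0.05, step count scaled to problem size, seeded)
returns the best-seen assignment. Validation of the packer is strictly
oracle-based: exhaustive enumeration on problems of ≤ 1000 assignments.

## Synthetic data

The fixture generator plants bridges with analytically known waters:
legs at the exact ideal distances, bridge angles drawn from the
observed Normal(111°, 16.7°) and redrawn until the implied separation
lies strictly inside the eligibility window (the generator plants
geometries the algorithm is defined over). Sites are minimal real
fragments — carbonyls (CA–C=O) and imidazole-like ring nitrogens
(16% nitrogen, matching the 10,000/61,000 survey ratio) — with one
lone pair aimed exactly at the planted water. Bridges sit on a 12 Å
grid so cross-bridge pairs can never be eligible; carbon decoys are
kept ≥ 3 Å from all planted geometry.

Jitter models coordinate uncertainty as a rigid displacement of each
planted constellation (one isotropic Gaussian draw per bridge or
coordination cluster; decoys move individually). Under this model the
predicted-vs-truth deviation is exactly the 3-D |N(0, sd)| norm of the
constellation shift — measured median 0.48 Å at sd = 0.3 vs the
theoretical 0.46 Å. Independent per-atom noise was rejected: at 0.3 Å
it implies bond-length distortions (~0.4 Å) no crystal structure
exhibits, and it degrades orbital directions by ~20°, which is a
statement about broken input chemistry, not about the algorithm.

What a green fixture test establishes: the geometric construction,
orientation rules, gating logic and bookkeeping are exact and stable
under positional noise. What it does not establish: recovery rates on
real crystallographic spheres, which depend on dataset curation,
electron-density selection of central waters, and force-field quality
(the deposited 160,000-sphere dataset is required for that and is out
of test scope).

## Numerical choices

- Closed-ball convention (≤) for all radius filters; eligibility
  windows strict (<, >) as printed.
- Alt-locs resolve to the highest-occupancy conformer (ties: first in
  file).
- Parallel orbital vectors: fallback midpoint of the origins' mutual
  projections, flagged on the placement.
- Degenerate projection onto the circle centre: 1° perimeter scan
  minimising summed angular deviation from the orbital vectors.
- Posterior de-duplication: waters closer than 1.0 Å merge to the
  lower-energy one (deterministic order).
- Symmetry expansion applies the bundled space-group operators (P1,
  P2₁, C2, P2₁2₁2₁, P2₁2₁2, P222) plus lattice translations in a
  −2..2 cube — sufficient for 20 Å neighbourhoods at protein cell
  sizes; other space groups raise a configuration error rather than
  silently degrading.
- Greedy unique matching (ascending distance, ties by predicted index)
  is the default mesh-scoring assignment; the Hungarian optimum is an
  alternative mode used as the test oracle. At realistic mesh density
  (≈ 0.02 waters/Å³) greedy attains the optimal cardinality on ~99% of
  random instances; density is the controlling variable.
- Distribution fits are MLE on raw samples, not histogram curve fits;
  immaterial at the survey's 10⁴–10⁵ sample sizes.

## Known limitations

- The H-bond parameterisation is a stand-in; absolute energies are not
  comparable to any published force field.
- The bundled rotamer library is deliberately coarse; χ1 recovery on
  real spheres will track library quality.
- Second-shell waters (water–water-only contacts) are not constructed;
  `allow_water_partners` is off by default.
- No pKa-dependent protonation, metal coordination, or electron-density
  handling; curated central-water lists stand in for 2σ density
  selection.
- mmCIF reading covers atoms, cell and space group; exotic dialect
  features are untested.
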