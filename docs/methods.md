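# Methods

`xcquad` evaluates the exchange-correlation (XC) energy

E_xc = ∫ ε({ρ(r), σ(r)}) ρ(r) d³r,  σ = ‖∇ρ‖²,

and its basis representation V^xc_{μν} = ∂E_xc/∂P_{μν} for a spin-restricted
Gaussian-basis Kohn–Sham density, by molecular quadrature. This note records
the model, the numerical choices, and what the tests do and do not establish.

## Quadrature model

**Radial.** Mura–Knowles ("Log3") grids: x_i = i/(n+1), r_i = −α ln(1−x_i³),
with weights that absorb both the map Jacobian and the r² volume element,
so Σ w_i f(r_i) ≈ ∫ f r² dr. The scale α defaults to 5.0 Bohr, raised to
7.0 Bohr for alkali and alkaline-earth elements whose valence shells are
more diffuse; both are overridable per element. These are conventional MK
values; different codes tune them differently, which is why they are
configuration rather than constants.

**Angular.** Lebedev–Laikov grids for the supported point counts
{6, 14, 26, 38, 50, 86, 110, 194, 302, 590, 974}. The grids are stored as
octahedral-symmetry generator parameters (one or two geometric parameters
and a weight per symmetry class) and expanded to full point sets at run
time. At build time every table was checked against the exact sphere
moments ∫ x^{2i} y^{2j} z^{2k} dΩ for all monomials up to the grid's
algebraic order (degree 3 for 6 points up to degree 53 for 974); residuals
are at machine precision (≤ 2·10⁻¹⁶ on normalized weights). Stored weights
sum to 1 and are scaled by 4π at construction.

**Presets.** FG = (75, 302), UFG = (99, 590), SFG = (175, 974) radial ×
angular points, i.e. 22,650 / 58,410 / 170,450 points per atom. No angular
pruning is applied, so per-atom counts are exact products.

**Atomic partitioning.** Stratmann–Scuseria–Frisch weights: with
μ_AB(r) = (|r−R_A| − |r−R_B|)/|R_A − R_B|, the unnormalized cell function
is s_A = Π_{B≠A} g(μ_AB), where g is 1 below −a, 0 above +a (a = 0.64),
and ½(1 − z(μ/a)) in between with the seventh-order polynomial
z(t) = (35t − 35t³ + 21t⁵ − 5t⁷)/16. The partition p_A = s_A/Σ_B s_B sums
to 1 identically. Because g saturates to exact 0/1 in floating point, a
point closer to its parent nucleus than (1−a)/2 times the parent's
nearest-neighbor distance has p_A = 1 exactly; the implementation exploits
this as a fast path that is bit-identical to the full product (covered by
a dedicated test). Coincident nuclei are rejected.

## Basis functions

Shells are contracted Cartesian Gaussians with L ≤ 3 (s, p, d, f).
Each contracted Cartesian component is normalized to unit self-overlap:
the contraction coefficients absorb primitive normalization and the
(L,0,0)-component contraction norm, and the per-component double-factorial
factor √[(2L−1)!!/((2l−1)!!(2m−1)!!(2n−1)!!)] is applied at evaluation.
Component order is x-power-descending lexicographic (d: xx, xy, xz, yy,
yz, zz); spherical components run m = −L…+L. The paper-independent
convention choice here is normalization, which no basis-dimension count
depends on.

Spherical (pure) shells are produced by a (2L+1)×(L+1)(L+2)/2 transform
built from real solid harmonics expressed in the normalized-component
basis and renormalized row-by-row under the Cartesian self-overlap metric;
rows are then orthonormal under that metric, so pure functions have unit
norm and vanishing mutual overlap by construction (verified on a dense
atomic quadrature to 10⁻¹⁰).

**Screening radii.** A shell is negligible beyond
r_cut = max_ξ √[(ln α_ξ/2 − ln η)/α_ξ] with default η = 10⁻¹⁰. For
pathologically diffuse primitives the bracket can go non-positive; the
code then falls back to the conservative √(−ln η/α), preserving the
guarantee |φ| < η outside the sphere. The guarantee is property-tested,
not assumed.

## Batching and compression

The grid's bounding box is subdivided recursively. A cuboid with at most
512 points (configurable) becomes a batch. A cuboid containing a nucleus
(half-open membership, lo ≤ c < hi) splits into 3×3×3 equal thirds —
nuclei sit at accumulation centers of the radial grids, and an octant cut
through the nucleus would give badly skewed children; all other cuboids
split into midpoint octants. Points are assigned half-open per axis with
the outermost bin closed, so every point lands in exactly one batch.
Degenerate inputs (all points coincident, or a cuboid below float
resolution) terminate as a single batch even above the threshold.

Per batch, a shell survives screening iff the distance from its center to
the closest point of the cuboid (componentwise clamp) is ≤ r_cut, with
ties kept — soundness over sparsity. Compression extracts the surviving
shells' rows/columns of N_b×N_b matrices contiguously; scatter-add
increments the full matrix blockwise. Batches with identical shell lists
may be merged (point-list union, bounding-box cuboid), which changes
nothing but the work layout.

## Functionals

* **LDA** — Slater exchange ε_x = −(3/4)(3/π)^{1/3} ρ^{1/3}.
* **PBE** — exchange enhancement F = 1 + κ − κ/(1 + μs²/κ) with κ = 0.804,
  μ = 0.2195149727645171; correlation = PW92 unpolarized local part
  (A = 0.0310907, α₁ = 0.2137, β₁…β₄ = 7.5957, 3.5876, 1.6382, 0.49294)
  plus the gradient term H = γ ln[1 + (β/γ) t² (1+At²)/(1+At²+A²t⁴)],
  γ = (1−ln2)/π², β = 0.06672455060314922.

Derivative channels follow the σ-convention: v_ρ = ∂(ρε)/∂ρ and
v_σ = ∂(ρε)/∂σ, which with Z_{μi} = ½ v_ρ Φ_{μi} + 2 v_σ (∇ρ·∇Φ_{μi})
reproduces the standard GGA potential and makes V^xc the exact derivative
of E_xc with respect to P — the property the end-to-end finite-difference
test asserts. (A ‖∇ρ‖-convention with the same "2 ∂ε/∂γ ∇ρ·∇φ" Z-matrix
would be dimensionally inconsistent; the σ reading is the one under which
the equations close.)

Numerical safety: densities in (−10⁻¹⁴, 0) — quadrature noise — are
clamped to zero, more negative values are an error; a 10⁻³² floor guards
correlation logarithms at grid tails; correlation roundoff at gradient
saturation (where H → −ε_c^loc) is clamped so ε_c ≤ 0 holds exactly. All
channels are validated against central finite differences; the comparison
carries the oracle's own resolution floor (roundoff ε|f|/(2hx) and a
scale floor at derivative zero crossings), since a difference quotient
cannot certify relative error below those.

## Pipeline and parallel model

Per batch: compressed collocation Φ^j and analytic gradient; X^j = P^jΦ^j
(GEMM); ρ_i = Σ_μ Φ_{μi}X_{μi} and ∇ρ_i = 2Σ_μ ∇Φ_{μi}X_{μi}; functional
channels folded with the SSF-scaled weights; Z^j; V^j = Z^jΦ^{j,T} +
Φ^jZ^{j,T} (SYR2K); E_xc += Σ_i ε_i ρ_i. Accumulation is in ascending
batch-id order so results are reproducible run to run; batch-size and
group-size invariance are tested at 10⁻¹².

A GPU-style device-saturation loop is abstracted as "batch groups":
batches are processed through fixed-size groups whose size cannot affect
results. Multi-rank execution is simulated in one process: each simulated
rank independently re-derives the identical batch→rank assignment
(replication contract — no communication), merges its same-shell-list
batches, integrates, and partials meet in a single associative reduction.
The cost model W_j = N_g^j(N_A² + 9N_b^j + 2(N_b^j)² + 3) + (N_b^j)²
feeds a deterministic greedy longest-processing-time scheduler (descending
cost, ties by batch id; least-loaded rank, ties by rank id). LPT is an
implementation choice satisfying the replication and merging contracts;
it carries the classical 4/3 − 1/(3R) makespan guarantee and is tested
against exhaustive optima on small instances.

## Synthetic fixtures

Toy molecules (H, H₂ at ±0.7 Bohr, HeH⁺-like pair, a water-like
triatomic) and three hand-written bases (minimal s, s+p, s+d — the last
exercises the spherical transform) keep every code path exercisable
offline. Random densities are P = 2CCᵀ with the occupied block
orthonormalized against the quadrature-grid overlap, so the grid electron
count Σ w_i ρ_i reproduces the target exactly up to grid error — a
property the acceptance tests use at 10⁻⁶ on UFG. These densities are
valid closed-shell idempotent-like test inputs but are not SCF solutions;
green tests establish quadrature, screening, and algebra correctness, not
chemical accuracy of any particular molecule.

## Known limitations

* L ≤ 3 (no g shells), no ECPs, no general-contraction optimization.
* Spin-restricted GGA only; no meta-GGA ingredients (τ, ∇²ρ), no hybrid
  exchange, no Coulomb/core terms, no SCF loop.
* One-process simulation of the rank model; a real MPI launcher can reuse
  the same assignment code unchanged but is not bundled.
* The 27-way split uses equal thirds; the alternative (atom-centered
  inner cube) would also satisfy the partition contract.
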