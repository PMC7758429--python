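# xcquad

Batched molecular-quadrature evaluation of the exchange-correlation (XC)
energy and potential for Gaussian-basis Kohn–Sham density functional
theory.

In Gaussian-basis KS-DFT the XC contribution to the Fock matrix cannot be
integrated analytically: E_xc = ∫ ε({ρ, σ}) ρ d³r (with σ = ‖∇ρ‖²) and its
matrix representation V^xc_{μν} = ∂E_xc/∂P_{μν} are computed on an
atom-centered molecular grid. `xcquad` implements that pipeline the way
modern batched-linear-algebra XC engines are structured, at desk scale:

* **Grids** — Mura–Knowles radial × Lebedev–Laikov angular product grids
  (FG/UFG/SFG presets: 22,650 / 58,410 / 170,450 points per atom), with
  Stratmann–Scuseria–Frisch (SSF) atomic partition weights.
* **Batching & screening** — recursive cuboid subdivision of the grid
  (27-way through nuclei, octants elsewhere, ≤ 512 points per batch) and
  per-batch basis-shell screening via cuboid–sphere closest-point tests
  with shell cutoff radii r_cut(η), η = 10⁻¹⁰.
* **Local integration** — per batch, in compressed dimensions:
  X^j = P^jΦ^j (GEMM), ρ and ∇ρ by columnwise dots,
  Z^j = ½ v_ρ Φ^j + 2 v_σ (∇ρ·∇Φ^j), V^j = Z^jΦ^{j,T} + Φ^jZ^{j,T}
  (SYR2K), scatter-added into the full V^xc.
* **Functionals** — LDA (Slater exchange) and PBE (exchange +
  PW92-based correlation) with analytic derivative channels.
* **Load balancing** — the FLOP cost model
  W_j = N_g^j(N_A² + 9N_b^j + 2(N_b^j)² + 3) + (N_b^j)² with a
  deterministic, replicated greedy-LPT batch→rank assignment,
  same-shell-list batch merging, and a single end-of-integration
  reduction (ranks simulated in-process).

Users: method developers and students who need a transparent, fully
tested reference implementation of grid-based XC integration — every
stage is exposed as a library function with a dense unscreened oracle
alongside the production path.

## Worked example

```bash
xcquad --fixture H2 --basis sto-min --grid FG --functional PBE \
       --density random:1 --out demo
```

prints

```
Exc = -0.729259108219 Hartree
N_el estimate = 2.0000000000
rank 0: load 1497636 (684 batches)
max/mean load ratio: 1.0000
wrote demo.summary.txt and demo.vxc.txt
```

Here `Exc` is the PBE exchange-correlation energy of a seeded random
closed-shell test density (2 electrons in the minimal H₂ basis) on the FG
grid; the electron-count line is the quadrature estimate Σᵢ wᵢ ρ(rᵢ),
which reproduces the electron count because the density was
orthonormalized against the grid overlap; the load line reports the cost
model summed over the 684 quadrature batches. `demo.vxc.txt` holds the
symmetric 2×2 XC potential matrix and `demo.summary.txt` the machine-
readable summary with per-phase timings (load balance / local
integration / other).

The same computation through the library:

```python
import xcquad as xq
from xcquad.fixtures import fixture_system, random_density

atoms, basis = fixture_system("H2", "sto-min")
P = random_density(atoms, basis, 2, seed=1)
res = xq.integrate_xc(atoms, basis, P, "FG", "PBE")     # screened/batched
ref = xq.reference_integrate(atoms, basis, P, "FG", "PBE")  # dense oracle
assert abs(res.exc - ref.exc) < 1e-8
```

Geometries can also come from XYZ files (`--xyz file.xyz`, Ångström) and
bases from Gaussian94-format files or the bundled `sto-3g`; `--pure`
selects spherical (2L+1) shells.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch — toy triatomic fixture, UFG grid,
PBE, simulated 4-rank load balance with a single reduction — and
cross-checks the distributed result against the serial path and the dense
unscreened oracle before writing the results file.

See `docs/methods.md` for the model details, numerical choices, and known
limitations.
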