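# Methods

## Model

`pnpbik` implements a molecular mean-field theory of ionic solutions in
which ions *and water* are hard particles of physical volume
`v_i = (4π/3) a_i³` with interstitial voids. The void fraction
`Γ(x) = 1 − Σ v_i C_i(x)` must stay strictly positive, and crowding relative
to the bulk defines the steric potential `S(x) = ln(Γ/Γ_B)`. Equilibrium
concentrations follow the saturating (classical Fermi) law

    C_i = C_i^B exp(−z_i φ + w_i S),

which is bounded above by `v0/v_i²` (or `1/v_i` for particles larger than
the mean volume `v0`) for *any* electric potential — in contrast to the
Boltzmann distribution, which it recovers exactly as all volumes tend to
zero. The electrostatics is the fourth-order operator

    ε_s (l_c² Δ − 1) Δ φ = ρ_ion,

whose single parameter, the correlation length `l_c`, encodes ion–ion and
ion–water correlations; `l_c = 0` recovers the classical Poisson equation.
Transport couples a Nernst–Planck flux with an extra steric drift term
`−(w_i) C_i ∇S` to the same electrostatics; water (z = 0) is transported by
the steric term alone.

### Units

Lengths in Å, energies in kBT, potentials in kBT/e, number densities in
Å⁻³ (1 M = 6.02214×10⁻⁴ Å⁻³). All electrostatic constants enter through
the Bjerrum length `l_B = e²/(4π ε_s kB T)` (≈7.15 Å for ε=78.45 at
298.15 K); the reduced Poisson equation is `−Δφ = 4π l_B ρ` with ρ in
e·Å⁻³. This removes SI bookkeeping and matches how the results are usually
plotted. Conversion helpers live in `pnpbik.constants`.

### Steric-energy weights

The general theory weights each species' steric energy by `w_i = v_i/v0`.
The original Bikerman distribution is the special case `w_i = 1` (identical
steric energies), appropriate for equal-sized binary electrolytes. Both are
supported (`ElectrolyteComposition(steric_mode="volume" | "uniform")`);
`volume` is the default. The planar double-layer preset
(`fixtures.edl_1to4_scenario`) uses `uniform`: for that equal-sized 1:4
electrolyte it is the convention under which the three correlation-free
model variants nearly coincide (as the reference results describe) and the
published contact potential is reproduced; under `volume` weights the
variants spread apart and the contact potential is ~13% high.

### Self-consistency of (C, Γ)

The Fermi law is implicit (S depends on Γ depends on C depends on S). Per
grid node the steric potential solves the scalar equation
`Γ_B e^t + Σ exp(ln v_i C_i^B − z_i φ + w_i t) = 1`, whose left side is
strictly increasing in `t`; we bisect in log space (120 halvings,
residual far below 1e−12), which is overflow-free for |φ| up to 10⁶ and
beyond — infinite potentials reach the analytic saturation limit instead of
overflowing. A last-ulp clamp keeps `Σ v_i C_i ≤ 1` exactly in floating
point.

## Equilibrium solver (planar double layer)

The fourth-order PDE is decomposed into two second-order problems,
`(l_c² Δ − 1) ψ = 4π l_B ρ(φ)` and `Δφ = ψ`, discretized by central finite
differences on a uniform grid (default n=801 on L=40 Å). Boundary
conditions: `−φ'(0) = 4π l_B σ` at the charged wall (or a Dirichlet value
for the transport driver), `φ(L)` fixed at the far-field value;
`ψ'(0) = 0` and `ψ(L) = 0`. The zero-flux wall condition for ψ was chosen
because the alternative `ψ(0) = 0` produces an unphysically large contact
potential (12+ kBT/e on the 1:4 fixture); the reference formulation states
ψ's wall condition only for molecular boundaries.

Nonlinearity is handled by Newton linearization of ρ(φ) with the void
fraction lagged (frozen Γ in the derivative, `ρ' = −4π l_B Σ z_i² C_i`),
under-relaxation (ω = 0.5), and two continuation ramps: the steric switch
λ_s scales all particle *volumes* from 0 to 1 (radii by λ_s^⅓, so the λ_s=0
state is exactly Boltzmann with S≡0), then the correlation switch λ_c
scales l_c. Ramping correlations before steric saturation diverges (the
point-ion correlated 1:4 problem is unbounded), so the steric ramp always
runs first. Default tolerance 1e−6 kBT/e on the max-norm potential update.

A dielectric-interface stencil (ghost-value extension with prescribed
potential and flux jumps, interfaces constrained midway between nodes)
keeps the scheme second-order across material jumps; jumps are oriented
right-minus-left.

Derived outputs: polarization `P = [l_c² φ''' − ((ε−1)/ε) φ']/(4π l_B)`
(e/Å²) by repeated central differencing, and the output dielectric function
`ε̂ = ε_s (φ̃'/φ')` with `φ̃ = φ − l_c² φ''`, masked where |φ'| is below
1e−3 of its maximum. In strongly correlated (oscillatory) profiles ε̂ is a
diagnostic, not a smooth material property: the ratio is only close to ε_s
where the tail decays monotonically (error ~l_c²/l_D²).

## Transport

The generalized Scharfetter–Gummel scheme treats `t = z Δφ − w ΔS` as
constant on each edge and integrates the flux ODE exactly:
`J = −(D/h)[B(−t) C_R − B(t) C_L]` with the Bernoulli function
`B(t) = t/(e^t − 1)` (series for |t| < 1e−4). Off-diagonals are strictly
negative, so each species' system is an M-matrix: concentrations stay
positive at any voltage and the discrete flux is exactly
divergence-free (current preserving). One edge spanning the domain with a
constant field is algebraically the Goldman–Hodgkin–Katz flux. The
stability margin `|−zΔφ + ΔS|` vs the bound 2 is reported as a diagnostic
of where naive central differencing would fail; the SG scheme is used
regardless. Diffusion coefficients are per-species in Å²/time with the
time unit left to the user (currents are reported in e·Å⁻²·time⁻¹); a
pore region can scale D by a factor θ. Gummel outer iteration alternates
NP solves with the two electrostatic solves, relaxing φ (ω = 0.5) until
the update is below tolerance; voltage is ramped in 0.5 kBT/e steps.
Reservoir boundary data are the bath concentrations (a zero-concentration
boundary would contradict every scenario the model is used for).

## Generalized Debye–Hückel activity model

For one ion in a binary salt plus water the closed-form model composes:

* `Λ = C₁(v₁−v₂)² / {Γ_B [v0 + v₁²C₁ + v₂²C₂ + v_w²C_w]}` (0 for equal
  volumes), giving the generalized Debye length
  `l_D⁴ᴾ = [4π l_B C₁((1−Λ)z₁² − z₁z₂)]^(−1/2)`;
* the correlation length `l_c = (l_B l_D⁴ᴾ/48)^(1/2)` — the printed flat
  form is dimensionally consistent only under the square root, and the
  generalized Debye length is used in the product (it coincides with the
  classical one at infinite dilution, where the analytic limits live);
* spectral roots `λ_{1,2} = {[1 ∓ (1−4l_c²/l_D²)^(1/2)]/(2l_c²)}^(1/2)`
  (Vieta: λ₁²+λ₂² = 1/l_c², λ₁²λ₂² = 1/(l_c l_D)²), with the l_c→0 limit
  (1/l_D, ∞) taken analytically;
* the interface factor Θ, evaluated through the equivalent form
  `(λ₁+λ₂)/(λ₁+λ₂+λ₁λ₂R_sh)`, which continues smoothly through
  coalescing roots and gives `lim_{l_c→0} Θ = 1/(1+R_sh/l_D)`, hence the
  classical DH screening term `(Θ−1)/R_sh → −1/(R_sh+l_D)`;
* the hydration-shell radius from the steric condition
  `ln[(V−v_w O)/(V Γ_B)] = (v0/v_w) ln[O/(V C_w)]` (bracketed Brent
  solve; O = 18 waters by default, bulk water 55.5 M — the value under
  which the published dilute-limit chloride shell radius 5.123 Å is
  reproduced), with `V = (4π/3)(R_sh³ − a_i³)`, a_i the Pauling radius;
* the concentration-dependent Born radius `R^B = R⁰(1 + α₁√C + α₂C +
  α₃C^{3/2})` with three fitted parameters per ion and salt (presets for
  eight 1:1 salts in `pnpbik.presets`);
* finally `ln γ = (z² l_B/2)[1/R^B − 1/R⁰ + (Θ−1)/R_sh]`, identical to the
  excess chemical potential in kBT. Classical DH (1923) and the extended
  DH–Born power-series form (1925) are alternative modes.

`fit_activity_parameters` estimates the α's from (concentration, γ) tables
by Levenberg–Marquardt least squares in ln γ.

## Binding-site energetics

The electric potential felt by an ion at a spherical site is the
probe-averaged screened Coulomb sum over the structure's point charges plus
the ion's Born term, with the distance-dependent dielectric
`ε_p(r) = 1 + 77r/(27.7+r)` evaluated at each atom's distance to the site
*center*. The six probe points sit at ±a_site along the coordinate axes —
any rigid-body-invariant symmetric set works; the axis set cancels the
quadrupole term, so the probe average converges to the center value at
O((a/d)⁴) for distant charges. The site steric potential is
`ln[(1 − v_ion/V_site)/Γ_B]` — the site's void fraction relative to bulk;
the `w_i` weighting of the bulk theory is exposed as an option but the
reported quantity is S itself, which is the reading that matches the
published site values. ΔG/ΔΔG bookkeeping combines externally supplied
per-ion pore and bulk free energies; the selectivity ΔΔG is reported as
unfavored-minus-favored (non-negative).

## Synthetic data

`pnpbik.fixtures` generates all test inputs: the 1:4 planar double-layer
scenario (the study conditions: 0.4 M C⁺/0.1 M A⁴⁻ of radius 4.65 Å,
55.5 M water of radius 1.4 Å, l_c = 1.6×4.65 Å, σ = 1e/50 Å², ε = 80,
L = 40 Å), activity tables synthesized from known α's (optionally with
Gaussian noise in ln γ), uniform random charge clouds, and a toy 4-site
binding pocket. Everything is seeded and byte-reproducible. These fixtures
exercise the numerics and the closed forms; they do not emulate real
structural disorder, polarizable water, or experimental noise spectra, so
green tests validate the implementation, not the theory's fit to any
particular dataset.

## Numerical choices and problem sizes

Grids of 801 nodes for the 40 Å double layer (grid-converged: doubling n
changes the contact potential by <1e−4), 1601 nodes for the 80 Å
Gouy–Chapman comparison, 121–241 nodes for transport checks. Tolerances:
1e−6 kBT/e (potential updates), 1e−12 (shell-radius Brent), bisection to
~1e−30 in the steric fixed point. Tie-breaks and degenerate inputs: Θ at
coalescing roots via the equivalent form; B(t) by series near 0; Λ set to
0 exactly when the ionic volumes are equal; point-particle species are
excluded from Γ.

## Known limitations

* Geometry is strictly planar 1D; no 3D protein solves, molecular-surface
  meshing, or transient dynamics.
* The overscreening-region potential of the 1:4 reference double layer
  computed here is ~20% shallower than the published curve at the stated
  correlation length; the depth matches only at a larger l_c (≈2a), and the
  parameters behind the published profile could not be fully pinned down.
* The activity model covers binary salts plus water with a constant solvent
  dielectric; no Pitzer-style multi-salt mixing or T/p-dependent ε.
* The correlation-length divisor 48 and the coordination number 18 are
  empirical constants of the reference formulation, not fitted here.
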