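# Methods

## The model

`mbwater` implements an analytical statistical-mechanical model of
liquid water in two dimensions. Each molecule is a Lennard-Jones disk
with three hydrogen-bonding arms at 120° (the Mercedes-Benz geometry).
Bookkeeping is done on the hexagonal lattice underlying the ice-like
structure: the elementary unit is the relation between a molecule and
its clockwise neighbour on a hexagon, which is in one of four states,

| state | energy | volume / molecule | default |
|-------|--------|-------------------|---------|
| HB    | −(ε_HB + ε_LJ) + k_s θ², \|θ\| ≤ θ_max | v_HB | 0.8 |
| LJ    | −ε_LJ (orientation-independent)         | v_LJ | 0.49 |
| 0     | 0                                       | v_0  | 1.3 |
| c     | HB energy − ε_c per molecule, all six bonds bonded | v_c | 1.2 |

with ε_HB = 1, r_HB = 1 defining the reduced units (k_B ≡ 1,
T\* = k_B T/|ε_HB|, p\* = p r_HB²/|ε_HB|), ε_LJ = 0.1, σ_LJ = 0.7,
k_s = 10, ε_c = 0.03, θ_max = π/3.

Each bond state receives an isothermal–isobaric statistical weight
Δ_i = exp(−β(E_i + p v_i)), with the HB weight carrying the normalised
orientational integral
I(β) = (1/2θ_max) ∫ exp(−β k_s θ²) dθ
(evaluated in closed form through the error function). The hexagon
partition function treats the six bonds as independent except that the
all-HB configuration is promoted to the cooperative cage channel:

    Ψ = (Δ_HB + Δ_LJ + Δ_0)⁶ − Δ_HB⁶ + (δ Δ_c)⁶,   δ = exp(−β ε_c),

and Q = Ψ^(N/6) (six bonds per hexagon; the 1/6 corrects for the three
interaction sites per molecule and double counting), so the Gibbs
energy per molecule is g = −(T\*/6) ln Ψ. Populations are exact
logarithmic derivatives f_i = (1/6) ∂lnΨ/∂lnΔ_i; they sum to one
structurally because Ψ is homogeneous of degree six in the weights.

A consequence of the promotion of the all-HB hexagon worth knowing:
in the limit Δ_LJ, Δ_0, δΔ_c → 0 the surviving configurations are five
HB bonds plus one defect, so f_HB → 5/6, not 1. If instead the cage
channel stays finite, f_c → 1.

Thermodynamics: v = ∂g/∂p and s = −∂g/∂T are computed by 5-point
central differences with one Richardson level (relative step 1e−4) and
cross-checked against the exact analytic forms (v is the
population-weighted mixture Σ f_i v_i; the temperature derivative runs
through β with −dlnI/dβ equal to the mean angular spring energy). The
response functions κ_T, α_p and c_p are central differences of the
analytic first derivatives (step 1e−3), which keeps second-derivative
noise below ~1e−5; c_v follows from c_p − c_v = T v α_p²/κ_T. All
weight arithmetic is carried out in log space (log-sum-exp), so the
theory is evaluable down to β ≈ 50 without overflow.

## Transport extension

Molecules are random walkers whose step size and hop frequency depend
on their bond state: λ_HB = λ_c = r_HB, λ_LJ = σ_LJ, λ_0 = √v_0 (the
2D mean intermolecular spacing), and ν_i = C exp(β⟨E_i⟩) with ⟨E_i⟩ the
thermal-average bond energy (⟨E_HB⟩ is the Boltzmann-weighted harmonic
well average, ⟨E_LJ⟩ = −ε_LJ, ⟨E_0⟩ = 0, ⟨E_c⟩ = ⟨E_HB⟩ − ε_c, taking
the cooperativity once per molecule). Then D_i = λ_i² ν_i and
D = Σ f_i D_i; the 2D random-walk prefactor (¼) is absorbed into the
unit-fixing constant C (`c_freq`).

Viscosity inverts the Stokes–Einstein relation, η = T\*/(c_se D d),
with the population-averaged diameter d = (f_HB+f_LJ+f_0) r_HB +
f_c · 2 r_HB (a caged molecule drags its hexagon) and c_se = 3π by
default (2D hydrodynamics fixes no unique Stokes constant, so c_se is
a parameter). The identity η·D·d·c_se = T\* therefore holds to
round-off by construction; the physically meaningful statement is that
equal η/T\* at different state points does not imply equal D, which the
`trends` machinery exposes rather than asserts.

Speed of sound uses the thermodynamic identity c_s = √(c_p/(c_v ρ κ_T))
with unit molecular mass; thermal conductivity a two-dimensional
analogue of Bridgman's equation, κ = 2 ρ^½ c_s (spacing is ρ^(−1/2) in
2D, hence exponent ½ for the 3D ⅔ and prefactor 2 for 3; both
overridable); thermal diffusivity is a = κ/(ρ c_p).

## Choice of the per-state volumes

The four per-state volumes are genuinely open parameters of the model
family. They were fixed once, by requiring the qualitative water
anomalies the model family is known for, and give a coherent physical
picture: v_LJ = σ_LJ² = 0.49 (tightest contact) < v_HB = 0.8 (the
liquid hydrogen-bond network — denser than the ideal lattice, as
liquid water is denser than ice) < v_c = 1.2 (the open ice-like cage)
< v_0 = 1.3 (unbound molecules at gas-like spacing). With this
ordering, compression at cold temperatures crushes cages into faster
mobile states (the anomalous rise of D with p), while at warm
temperatures it mainly converts fast free molecules into slower bonded
contacts (the normal fall of D with p); heating always accelerates
diffusion and thins the liquid (η falls). A density anomaly
(α_p < 0) appears at cold temperatures and low pressure.

## Numerical choices

- Angular integrals: closed-form via `scipy.special.erf`; validated
  against adaptive quadrature (`scipy.integrate.quad`) and a
  100 000-node composite trapezoid oracle to 1e−8.
- Enumeration oracle: uniform angular grid on [−θ_max, θ_max]
  (odd node count so θ = 0, the well minimum, is a node) with trapezoid
  weights; populations by direct summation over discretized hexagon
  configurations. The six-bond sum is collapsed by per-bond
  factorization (exact because bonds are independent and the cage
  correction factorizes); the explicit (n_θ+2)⁶ product enumeration is
  retained behind `full=True` as a slow cross-check and refuses more
  than ~2·10⁶ configurations. n_θ > 21 is always refused.
- The discretization error is dominated by the trapezoid rule on a
  near-Gaussian integrand and falls steeply with the node count; at
  n_θ = 15 the populations agree with the analytic route to better
  than 1e−3 across the liquid range.
- Pseudo-random validation state points use the fixed seed 1234
  (T\* ∈ [0.15, 0.35], p\* ∈ [0, 1]).
- Default property grid: 50 temperatures × 20 pressures on
  T\* ∈ [0.12, 0.40], p\* ∈ [1e−4, 1.0]. Trend checks for the transport
  coefficients use the liquid window T\* ∈ [0.2, 0.4]; below ≈ 0.2 at
  low pressure the model is cage-dominated (the frozen/supercooled
  regime). The two-regime structure of cold-water D(p) is assessed on
  p\* ∈ [0, 0.6]: at still higher pressures a third, weak regime
  appears in which converting the remaining hydrogen bonds into LJ
  contacts speeds diffusion slightly.
- Sweeps are fully deterministic; CSV output uses 10 significant
  digits, so repeated runs are byte-identical.

## Known limitations

- All interaction and volume parameters are effective 2D quantities in
  reduced units; nothing is fitted to real (3D) water data, so only
  qualitative trends are meaningful.
- Because each state has a fixed volume, all compressibility comes
  from population interconversion: volume fluctuations vanish as the
  liquid purifies into a single state at low temperature, so κ_T → 0
  and the speed of sound grows toward the cold end of any isobar.
  With the 2D Bridgman form κ = 2ρ^½ c_s the density cancels exactly
  (κ = 2√(γ/κ_T)), so the thermal conductivity always falls from the
  cold side of an isobar. The model therefore reproduces the
  monotonic low-pressure κ(T) but not an interior κ(T) maximum at
  high pressure; producing one would require an intrinsic per-state
  compressibility (e.g. a continuum of cell volumes per state), which
  is outside the present fixed-volume weights. The corresponding trend
  test asserts the interior maximum and currently fails; the limitation
  lies in this conductivity route, not in the numerics.
- No phase-boundary location, spinodals, interfacial properties,
  time-correlation-function transport theory, or 3D geometry.
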