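# Methods

This note documents the physical model behind `pureshift`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic benchmarks do and do not demonstrate about real protein data.

## Spin model and propagation

Spin systems are limited to six spins-1/2 (Hilbert dimension 64), enough
for one amide fragment (H_N, ¹⁵N, Hα and neighbours); larger "proteins"
are lists of independent fragments whose FIDs add. Evolution is computed
in the Zeeman product basis of a doubly rotating frame (one transmitter
per isotope). Couplings are isotropic (`2πJ I·I`) between like spins and
secular (`2πJ IzSz`) for ¹H–¹⁵N pairs — exact in the doubly rotating
frame. Propagators come from eigendecomposition and are cached per
(Hamiltonian, duration).

Sign conventions, fixed and tested: a spin at higher ppm than the carrier
has positive offset and its signal evolves as `exp(+i2πνt)`; a 90°x pulse
takes z-magnetisation to −y; detection is the slice-averaged ⟨I⁺⟩
normalised so one fully polarised proton gives unit amplitude.

**Relaxation** is phenomenological. Every coherence ρ_ab decays at
Σᵢ 1/T₂ᵢ over the spins whose Zeeman state differs between a and b, so a
single-quantum coherence of spin i decays at exactly 1/T₂ᵢ (linewidth
1/(πT₂)) and multiple-quantum coherences at the sum of the participating
rates. Populations relax toward thermal equilibrium at 1/T₁ᵢ through the
Walsh (product-of-2Iz) decomposition of the diagonal; spins without a T₁
have frozen longitudinal order, which is the default for the protein
fixtures — the experiments of interest are far shorter than amide T₁.
A consequence worth knowing: inside the 11-ms BIRD core one transverse
quadrature of the active spin is stored as longitudinal two-spin order
(no decay) while the orthogonal one stays transverse (T₂ decay). With T₁
frozen this anisotropy is maximal, and it is why sensitivity-enhanced
(echo/antiecho) simulations are cleanest with the short BASHD element —
mirroring the experimental observation that BASHD outperforms BIRD.

**Gradients** act on a 1D ensemble of slices (default 64 over 1.6 cm,
midpoints, symmetric about the coil centre): slice k acquires phase
γᵢ·g·z_k·τ per unit coherence order; z-magnetisation is untouched; free
evolution and relaxation run concurrently. γ(¹H) is the CODATA value,
γ(¹⁵N) = −0.10137·γ(¹H).

**Water** is classical and one-way coupled: per-slice Bloch vectors on a
finer grid (default 257–513 slices — a 350-rad gradient phase spread
aliases on 64 discrete slices), integrated with fixed-step RK4 (step
≤ 10 µs), added to the receiver but never entering the quantum state.
Radiation damping rotates each slice about the **coil-mean** transverse
magnetisation with rate |⟨M⊥⟩|/(τ_rd·M₀): it damps transverse water when
M_z > 0, regrows it exponentially from an inverted state, and — because
the feedback field is the coil mean — stops when water is dephased, which
is precisely the mechanism by which CTP gradients rescue water
suppression. Per-slice (rather than mean-field) feedback would let fully
dephased water keep regrowing, masking that mechanism.

## Elements

Both families are double spin echoes: echo A (hard 180°, inverts every
proton, EXORCYCLE-cycled) followed by a discriminating echo B that
re-inverts only the active protons — the BIRD core
`90°₋y – Δ – 180°y(¹H)·180°(¹⁵N) – Δ – 90°₋y` with Δ = 1/(2·¹J_NH), or a
reBURP 180° centred on the amide band. Net contract (tested as a
propagator fidelity ≥ 0.999 BIRD / ≥ 0.99 BASHD): identity on active
protons with zero net shift *and* J_NH evolution, 180° on passive
protons. The small hardware delays (δ₁ = 20 µs blanking, δ₂ = 50 µs power
switching, δ₃ = 208 µs ¹⁵N-180° time correction) are placed so the signed
shift and J_NH evolution of the active proton cancel exactly; in the
gradient-selected versions the closing g2 lobe sits after the trailing
¹⁵N 180° for the same reason. The passive 180° is left with an arbitrary
azimuth (its axis does not matter while passive spins are longitudinal),
and the contract fidelity is maximised over that azimuth.

Default ¹J_NH is 90 Hz (core duration 11.11 ms); the actual coupling may
be set per system, and a mismatch degrades the contract measurably.
¹⁵N inversion is ideal (hard) rather than a composite broadband pulse;
for amide ¹⁵N spectral widths the difference is negligible.

**Phase cycling.** The element cycle is a phase-inversion cycle: 2 steps
flip the echo-A 180° between +x and −x (receiver unchanged); 4 steps also
flip the discriminating 180°. Classic EXORCYCLE's 90° step multiplies the
active coherence by −1 at *every* element firing, which a per-transient
receiver sign cannot undo in real-time acquisition (with an even number
of elements it cancels the signal outright); the phase-inversion form
keeps the ideal pathway invariant for any element count while imperfect,
non-inverted pathways change sign and cancel.

**CTP gradients** (defaults 16.6 and 13.6 G cm⁻¹, 0.5 ms, 200 µs
stabilization) form matched same-sign pairs around each echo. Both echoes
invert the observed coherence, so the pairs refocus it exactly; water is
inverted only by echo A, so the g2 pair dephases it. The polarity of the
whole wrap alternates between successive elements: with static signs,
transverse water created in one chunk is gradient-echoed back into
coherence by a later element (verified numerically), and alternation
makes the cumulative dephasing moment grow monotonically instead.

## Real-time acquisition loop

The chunked loop uses the midpoint-refocused arrangement: half chunk,
then (element + full chunk) × (n−1), element, half chunk. Each chunk of
duration 1/sw_ps is centred between element firings, the net J_HH phase
is a zero-mean triangle wave, the decoupled singlet sits at the true
shift, and sidebands appear at ±k·sw_ps — verified against an analytic
triangle-phase model to machine precision. `sw_ps` must be an integer
submultiple of `sw` (chunks are whole numbers of points); one chunk
degenerates to plain acquisition. Stored chunk records live on the
equal-length 1/sw_ps grid regardless of the internal half-chunk timing.

The `ideal` element is the sw_ps → ∞ oracle: instantaneous perfect
passive inversion *and* active–passive J_HH suppressed during chunks.
With any physical element, intra-chunk J_HH evolution (the sideband
mechanism) makes the pure shift FID differ from the J-free FID at first
order in J·T_chunk; the ideal element removes exactly that term, so the
oracle-equivalence tests check the chunking/concatenation/interferogram
plumbing, not J physics.

Heteronuclear decoupling during chunks is ideal (J_HN zeroed); no
explicit WALTZ/GARP.

## HSQC modes

`ideal_start` prepares in-phase active-¹H x-coherence amplitude-modulated
by cos/sin(Ω_N t₁) (or the echo/antiecho pair), then runs the loop — the
fastest faithful route to F1 behaviour. `explicit` runs INEPT
(τ = 1/(4·J_NH)) → t₁ with a mid-t₁ ¹H 180° → back-INEPT with a two-step
isotope filter on the first ¹⁵N 90°; both place the peak at (ν_N, ν_H),
with explicit-mode amplitudes reduced by transfer and relaxation losses.

## Shapes

reBURP is generated from its published 16-term Fourier-cosine coefficient
table (constant phase, symmetric envelope, negative lobes). Calibration
maximises on-resonance refocusing fidelity by golden-section search over
peak B1, taking the lowest-B1 local optimum (the 540° solution is not a
calibration); for a rectangular pulse this reproduces B1 = 1/(2T).
Inversion efficiency is reported on a [0, 1] scale, (1 − ⟨Iz⟩f/⟨Iz⟩₀)/2,
and bandwidth is the contiguous region with efficiency ≥ 0.8. Under
these conventions the measured time–bandwidth product is 4.80 ± <1 %
across 1–5 ms, within 2 % of the reference settings pairing (both
reference bandwidth/duration pairs give 4.88).

## Processing

First point of each FID scaled by 0.5 before FT (flat baseline for
truncated Lorentzians; disable for Parseval checks); FFT such that
+offset appears at +Hz; ppm presentation follows the usual high-to-low
convention. 2D: States hypercomplex, or Rance–Kay conversion
(cos = (E+A)/2, sin = (E−A)/2i) of echo/antiecho records, then a real F1
transform; F1 apodization is Gaussian `exp(−t²/gf1²)` (gf1 = 0.085 s
default) or 90°-shifted sine-squared — short, non-decaying model
interferograms need the latter to keep truncation leakage below the 1 %
quadrature-image criterion. A referencing correction (`reference_shift`)
handles the small systematic shift that short gradient-stabilization
delays cause on real hardware; the engine's ideal gradients do not
produce it.

## Sensitivity theory

Collapse gain: 100·(Σa/max a − 1) % for multiplet intensities a —
+100 % for doublets and 1:2:1 triplets, +166.7 % for 1:3:3:1 quartets.
Lorentzian doublet vs equal-integral singlet: while the doublet is
unresolved (πJT₂ < 1/√3) its maximum is at the centre and the gain is
exactly (πJT₂)², ≈ 10 % at J·T₂ = 0.1 — the classic threshold where
homodecoupling stops paying; the numeric lineshape maximisation agrees
with this closed form to the digit and extends it to the resolved
regime. Time-shared decoupling sampling a fraction f of each dwell costs
100·(1 − √f) % of S/N: 6.7 % at f = 0.87.

## Water-residual study

`analysis.water_residual_study` runs the classical water model through
the full acquisition loop at the reference scale (1024 points, 5 kHz,
8 chunks ≈ 205 ms), τ_rd = 5 ms, M₀ = 100 (arbitrary solute-relative
units), water 1775 Hz upfield of the amide carrier, and a 2° coherent
residual water tip as the radiation-damping seed left by the preceding
HSQC. Figure of merit: integral of |S(ν)| within ±50 Hz of water. The
element-gradient-free scheme lets the seed regrow coherently every time
water is inverted (residual bounded only by the RD cycle), while the
CTP-wrapped schemes re-dephase it at every element: the simulated
off/on ratio is ≈ 20 (criterion: ≥ 10). The z- and xy-gradient schemes
are identical in this 1D model; real triaxial advantages (B₀ recovery,
convection) are outside scope. Residuals are flat across t₁ because each
increment is prepared identically — the simulation reproduces the suppression
*ratio*, not the t₁-dependence of the real instrument.

## What the synthetic benchmarks do not show

Fixtures are three-spin fragments with uniform random shifts, one
passive coupling, and a single style-wide T₂ — no shift correlations,
no multiple Hα/Hβ couplings, no NH₂ side chains, no chemical exchange,
no B₀/B₁ inhomogeneity, no spectrometer artifacts. Passing tests
demonstrate the method's mechanics (element contracts, chunking algebra,
sideband systematics, suppression mechanisms) at the reference acquisition
parameters, not quantitative agreement with any particular protein's
spectra; the real-sample S/N enhancements (~30–40 %) depend on per-peak
couplings and measurement windows that are not reproducible at the desk
and are deliberately asserted only as a direction (decoupled > coupled).

## Problem sizes used by the test suite

Simulations are sized for a laptop-class run: 8-dimensional fragments,
1008–4096 complex points, 64-slice solute ensembles, 129–513-slice water
grids, 16–64 t₁ increments. These choices are stated here once; they are
the package's defaults for its own validation, and every physical claim
tested was checked to be insensitive to them (slice-count and zero-fill
convergence tests are part of the suite).
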