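# Methods

## Model and assumptions

The tissue is modelled as a single uniformly thick layer of a 2D
compressible inviscid continuum, observed in a fixed Eulerian frame.  Three
mechanical ingredients set its motion: an elastic coupling of the cells
(residual stretching modulus k, absorbing fast cytoskeletal rearrangement),
a drag-like adhesion to the substrate (constant b), and a net outward force
per unit edge length F produced by lamellipodia, concentrated at the free
edge.  F, k and b enter the equations only as the ratios F/k and k/b, so
only the ratios are identifiable and only they are carried.

Density ρ(x, t) diffuses with effective diffusivity k/b inside the tissue.
The free edge holds the Dirichlet density ρ_u·e^(−F/k) (edge tissue
stretched below its relaxed density ρ_u by the edge force) and moves with
normal speed v·n = −(k/b)(e^(F/k)/ρ_u)·∇ρ·n.  Because the edge density is
exactly ρ_u·e^(−F/k), this front law is equivalent to v = −(k/b)∇ρ·n/ρ_edge:
the material flux arriving at the edge is converted into new area at the
edge density, so **total mass is conserved when the source term is off**.
This identity is the backbone of the solver's verification.

Visible material is added by radial intercalation and active cell shape
change, not by volumetric growth: the source q = αρ(1 − ρ/ρ̃), with limiting
(compressed) density ρ̃ = ρ_u·e^(F/k), runs only until the cumulative added
mass reaches half the initial mass (the cap comparison is inclusive).  The
logistic expression is applied literally and may be negative where ρ > ρ̃ —
with the default initial density 4700 cells/mm² and prior ρ_u ≤ 2000 this is
the common early-time regime, and the interior then relaxes downward toward
ρ̃.  Consequently the cumulative added mass m(t) can decrease; only the cap
behaviour (q ≡ 0 once m ≥ m₀/2) is guaranteed.

### Units

The canonical density unit is cells/mm².  The initial interior density is
0.0047 cells/µm² = 4700 cells/mm², and prior values of ρ_u (1000–2000) are
read in cells/mm², which places the edge density below the interior density
and yields outward spreading.  `ModelConfig.density_unit_scale` rescales the
prior convention for users who need a different one; it defaults to 1.

## Numerics

Fixed square grid (default 10 µm spacing, domain chosen to enclose the
explant with generous margin); the tissue is the negative region of a
level-set field φ maintained as an approximate signed distance.

* **Diffusion** — explicit five-point FTCS.  Where a neighbour lies outside
  the interface, the stencil uses a ghost value from linear extrapolation
  through the interface Dirichlet point at cut fraction
  θ = φ_i/(φ_i − φ_nb), clamped to [0.25, 1].  The diffusion update is
  sub-stepped so that dt_sub ≤ 0.9·h²·θ_min/(4·k/b), making every update a
  convex combination of old values and the boundary value — a discrete
  maximum principle holds by construction.
* **Front speed** — at interior nodes within 1.5h of the interface, the
  interface point x_I = x − φn is located along the normal and the density
  is sampled (bilinearly) one grid spacing inside it; the normal gradient is
  the two-point form (ρ_edge − ρ₁)/h.  This deliberately mirrors the
  diffusion flux discretisation: testing against the exact planar similarity
  solution and the mass-conservation identity showed that a higher-order
  one-sided gradient here persistently over-drives the front (~3% spurious
  mass gain), while the flux-consistent form conserves mass and converges to
  the similarity solution.  The speed is extended to a 6h band by
  nearest-source copy and φ is advected with first-order Godunov upwinding.
* **Reinitialisation** — every 20 steps φ is rebuilt as the exact signed
  distance to the marching-squares zero contour.
* **Time step** — 0.9·min(h²/(4·k/b), h/(2·v_max), 1/(4α)), with v_max
  tracked adaptively (seeded by the worst one-cell density drop).
* **Newly engulfed nodes** get the extrapolated edge density, preserving
  continuity of ρ.
* **Mass bookkeeping** — tissue mass integrates ρ·h² with a linear subcell
  weight (1/2 at φ = 0); m₀ is this integral at t = 0.

Verification: a relaxed uniform disk (F = 0, α = 0) is a fixed point (front
displacement ≈ 1 µm, mass drift < 0.3% over 10 h at h = 10 µm); on circular
explants the level-set radius tracks an independently written 1D polar
front-tracking solver (`epispread.radial`) within 2% at every 5-minute frame
over 10 h; the final-contour error against an h/4 reference halves when h is
halved (first-order front tracking).

## Strain mapping

Registration output u(X) between frames j and j+δ is differentiated with
second-order central differences (one-sided at borders; exact on affine
fields), giving F_def = ∇u + I per pixel.  Under local conservation of mass
det F_def = ρ_j/ρ_{j+δ}, the experimental density ratio ξ_exp.  The model
side computes ξ_comp as the node-wise ratio of stored density snapshots.
Ratios are defined only where the tissue is present in both frames; off-mask
nodes carry a 0 sentinel.  Experimental maps are interpolated bilinearly to
the computational grid, a node staying valid only if all four surrounding
pixels are valid.  δ defaults to 5 frames (25 min), the smallest increment
at which changes between images are detectable.

## Error function and ABC

Per frame j ≥ 1, D_j is the RMS over computational edge points of the
minimum point-to-segment distance to the experimental edge polyline
(z_d = Σ D_j up to t_end; the t = 0 frame is the shared initial condition
and is excluded).  Per pair (j, j+δ), P_j is the RMS of ξ_comp − ξ_exp over
the **whole** L₁×L₂ grid with 0 sentinels in both maps — nodes covered by
tissue in only one of the two maps contribute their full squared ratio,
penalising shape mismatch (z_p = Σ P_j for j = 1 … t_end − δ).  The total is
z = z_d + w·z_p with w = 1000, putting both terms on a comparable scale.  A
simulation that touches the domain edge, or whose centre density (node
nearest the initial centroid) rises frame-to-frame by more than a relative
1e-6, scores NaN and can never be accepted.

ABC rejection samples each parameter independently from its uniform prior
and accepts candidates with z ≤ threshold.  The default threshold is 1500;
for desk-scale recovery studies on synthetic data a pilot quantile
(`calibrate_threshold`, default the 15% quantile of ~60 pilot candidates)
gives a threshold with a predictable acceptance rate.  Posterior summaries:
histograms with Gaussian-KDE smoothing (Silverman bandwidth, the smoothed
argmax as the mode), all-pairs 2D histograms, means, the three smallest-z
sets, central percentile credible intervals, and Pearson correlations over
the smallest-z 20% of samples.

## Synthetic data generator

The generator emulates the *derived* data products of a spreading
experiment, not micrographs.  It simulates the model at a known θ*, then:
edge contours are resampled at 3× the computational point density
(experimental segmentations are denser than simulated contours) with i.i.d.
Gaussian jitter per coordinate, default σ = 13 µm ≈ 5 px at 2.6 µm/px —
inside the stated segmentation error bound of ~40 µm; density-ratio maps get
multiplicative log-normal noise (σ_ξ = 0.02) on-mask.  The dataset's
designated initial contour is the noise-free shape: i.i.d. jitter at dense
point spacing does not produce a simple polygon, so a jittered frame-0 edge
cannot seed a level set.  Initial shapes are circles, ellipses, or
Fourier-perturbed blobs, with areas in the observed explant range
(~0.14–2.23 mm²).

What the generator does **not** emulate: spatially correlated segmentation
error, registration artefacts near the tissue edge, asymmetric spreading,
and biological heterogeneity.  Recovery results on synthetic data therefore
demonstrate the machinery (identifiability structure, calibration of the
error function, sampler correctness), not real-data performance.

## Problem sizes

Unit and property tests run 1–2 h scenarios on a 20 µm grid.  The recovery
study uses a 1.5×1.5 mm domain at h = 20 µm, a 0.2 mm² explant, 10 h of
5-minute frames, and a few hundred candidate simulations — a deliberate
desk-scale version of a study whose full form (10,000 accepted sets per
explant at threshold 1500) is a supercomputer workload.  At this scale the
posterior is broad but the diagnostic structure is already present:
credible intervals cover the truth and F/k–k/b are negatively correlated.

## Known limitations

First-order accuracy of the front tracking; uniform thickness and isotropic,
non-viscous constitutive behaviour; growth caps on total added mass rather
than locally; single connected tissue region (the largest zero contour is
taken); no re-entrant behaviour after the tissue touches the domain edge
(the run stops and is flagged).
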