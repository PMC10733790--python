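# Model and methods

`callusim` simulates the early inflammatory phase of long-bone fracture
healing (up to 5 days post-injury) in a 2D mid-axis section of the callus,
coupling a discrete immune-cell layer to a continuum molecular layer, and
ships the analysis stack used to screen, calibrate and validate such a
model: an orthogonal-array sensitivity screen with signed %TSS ANOVA, a
genetic-algorithm (GA) calibration loop, and an in silico
immunofluorescence layer for direct comparison with stained sections.

## Geometry

The bone is idealized as a hollow cylinder and the callus as a spheroid, so
the mid-axis section shows two cortical walls (outer radius 0.5 mm,
thickness 0.2 mm) flanking the medullary canal, interrupted by a fracture
gap (1.0 mm for the calibration geometry, 0.7 mm for the validation femur),
all enclosed in an elliptical callus (semi-axes 1.0 mm axial × 0.8 mm
transverse) on a 2 × 2 mm domain. The healing region is the callus minus
cortex minus marrow canal; it is rasterized at the molecular resolution
(10 µm). Cells are recruited across the *marrow interface* (the canal
openings at the gap) and the *periosteal boundary* (the curved callus
surface); the cortex is a zero-flux wall for both cells and cytokines.
The geometry is mirror-symmetric, and a `quarter=True` flag restricts the
simulation to one quadrant with the cut axes acting as no-flux mirror
planes; per-area outputs are unaffected in distribution, and the package's
replicate studies use this mode.

## Cellular level

Four phenotypes: non-polarized (M0), pro-inflammatory (M1) and
anti-inflammatory (M2) macrophages, and neutrophils (PMN). Cells occupy
1 µm lattice positions with a hard exclusion radius r_ex = 7.5 µm
(≈ half a macrophage diameter) between centres. Each 1 min iteration runs,
in order: recruitment, the stochastic event lottery, migration.

**Recruitment.** New M0 arrive at rate
`k_R(M0) · (1 − [MΦ]/[MΦ]max) · [Debris]` per unit area, with [MΦ] the
macrophage count over the healing-region area and [Debris] the region-mean
debris concentration; the expected count per iteration is realized as a
Poisson draw placed at uniformly random unoccupied recruitment-boundary
voxels. PMN influx follows the same law with its own ratio (default equal
to k_R(M0)) and shares the saturation ceiling. Recruitment stops when
debris is exhausted or the compartment is full.

**Event lottery.** Apoptosis, proliferation and polarization are
per-iteration probabilities; each event gets an independent uniform draw
quantized to 10⁻⁶, and the evaluation order is apoptosis → proliferation →
polarization with apoptosis preempting the rest. Apoptosis probability is
`k_a0 · (1 + α_d·load + α_n·n_neighbors) · Δt` — baseline mortality scaled
up linearly by accumulated phagocytosed debris and by crowding (cells
within 30 µm); the linear form is the simplest monotone choice and both
coefficients are screened parameters. Polarization follows saturating laws
in the local voxel concentrations: TNFα drives M0→M1 and the rare M2→M1,
IL-10 drives M0→M2 and M1→M2, each `k · c/(a + c) · Δt`. A proliferating
cell places its daughter one exclusion radius away in a random unoccupied
cardinal direction — 4-adjacency at the cell scale; placing daughters on
1 µm-adjacent lattice sites would violate the exclusion radius by
construction, so the cell-scale reading is used. PMNs never proliferate.

**Migration.** A cell performs `round(k_v·Δt / 1 µm)` unit jumps per
iteration (a PMN at 5 µm/min makes five). Each jump screens the four
lattice neighbours for being inside the healing region and unoccupied;
without chemotaxis the choice is uniform. With chemotaxis the candidate
with the highest *sensed* debris signal wins (deterministic ascent, uniform
tie-break). The sensed signal is a mask-normalized Gaussian blur of the
debris field (default range 40 µm), sampled bilinearly at the candidate
position: phagocytes perceive debris through diffusible damage-associated
signals rather than by contact, and a strictly local (1 µm) lookahead
leaves cells blind to debris pockets more than one site away — under that
rule the region is never fully cleared. Engulfment and every debris
invariant act on the raw, non-diffusing field; only the migration choice
uses the smoothed view.

## Molecular level

TNFα, IL-10, TGFβ and IFNγ live on a 10 µm grid and evolve with a 1 s step:
per-cell secretion into the containing voxel, explicit 5-point finite-volume
diffusion with no-flux boundaries at the region border and cortex, then
exponential decay. The explicit step is substepped automatically to respect
`dt ≤ h²/(4D)`; at the default D = 20 µm²/s no substepping is needed and
halving the step changes trajectories by well under 1%. Secretion follows
phenotype-specific source terms: M0 and PMN drive TNFα (M0 with a sigmoidal
IFNγ amplification `1 + k_TNI/(1+e^(a_TNI−[IFNγ]))`); M1 TNFα output is
additionally damped by two exponential inhibition factors in IL-10 and TGFβ
(`k·e^(−a·c) + b`, a sensitive share decaying onto an insensitive floor) —
this product-of-inhibitions × IFNγ-amplification form is fixed as the
normative parse of the M1 source term; M0 and M2 secrete IL-10; M0, M1 and
M2 secrete TGFβ; M0, M1 and PMN secrete IFNγ with exponential TNFα
suppression. All other (phenotype, cytokine) pairs secrete nothing.

Debris neither diffuses nor decays; it is removed only by phagocytosis.
Each phagocyte engulfs over its voxel plus 4-neighbours at fractional rate
k_e per minute; when several cells cover a voxel the voxel loses
`debris · (1 − exp(−Σ k_e·dt))` — the order-independent limit of sequential
engulfment — shared among the cells in proportion to their rates and added
to their debris loads. Because debris changes through removal only, the
60 one-second engulfment steps of a cellular interval compose exactly into
a single call with dt = 60 s, which the scheduler exploits.

## Two-clock coupling

The cellular clock (Δt = 1 min) advances after every 60 molecular steps
(Δt = 1 s); cell positions are frozen within the molecular block, so
secretion sources are static between cellular updates. The inner block and
the per-jump migration loop are numba kernels; a plain-NumPy reference
implementation of every operation is kept and the two paths are
cross-checked by the test suite. A single seeded `numpy` Generator drives
all randomness (kernels consume pre-drawn arrays), so runs are bitwise
reproducible per seed. Replicate statistics use n = 5 seeds and report
mean ± SD; calibrated-vs-literature contrasts use a one-tailed Welch
t-test. Trajectories are recorded hourly.

## Parameters

All constants live in a validated registry with value, units, source tag
and a screened flag; exactly 36 parameters form the sensitivity set
(recruitment and initial conditions, per-phenotype kinetics, polarization,
apoptosis coefficients, leading secretion constants). Four literature
values are reconstructed from their published calibrated counterparts and
percentage deviations: k_R(M0) = 2.10×10⁻² h⁻¹, k_p(M1) = 8.33×10⁻⁴ min⁻¹,
k_e(PMN) = 3.33×10⁻³ min⁻¹, [PMN]₀ = 1000.4 mm⁻² (the published [PMN]₀
carries µm⁻³ units that are inconsistent with a 2D model; the value is used
as a per-mm² model-units concentration without conversion). The remaining
constants are **provisional**: order-of-magnitude defaults chosen once so
that the model operates in the qualitatively reported regime — debris
cleared within ≈3 days, macrophage concentrations of order hundreds per
mm², a pro-inflammatory cytokine wave cresting before the anti-inflammatory
one — and then frozen; they are tagged `provisional` in the registry and
should be replaced wherever measured values are available. Cytokine and
debris concentrations are opaque "model units" (`mu`); only ratios to the
half-saturation and inhibition constants matter.

Key defaults: Db₀ = 2000 mu, [MΦ]max = 1000 mm⁻², macrophage speed
2 µm/min, macrophage k_e = 5×10⁻³ min⁻¹, k01 = 1.5×10⁻³ min⁻¹,
k02 = 7×10⁻⁴, k12 = 5×10⁻⁴, k21 = 5×10⁻⁵ min⁻¹ (M2→M1 interpolarization is
rare), half-saturations 0.3 mu, α_d = 10⁻⁴ mu⁻¹, α_n = 0.1 cell⁻¹,
baseline apoptosis 3–5×10⁻⁴ min⁻¹, D = 20 µm² s⁻¹, decay 1–2×10⁻⁴ s⁻¹.

Under the frozen defaults, five-seed quarter-domain runs give: day-1 total
macrophages ≈ 300 mm⁻² (published in silico reference 346.4 ± 9.3), day-3
≈ 405 mm⁻² (389.3 ± 36.5), M1 day-1→3 fold ≈ 2.1 (2.2 ± 0.3), M2 fold
≈ 4.8 (3.2 ± 0.8), M0 decrease ≈ 66% (84.4 ± 4.1%). Debris mass is > 95%
removed by day 3, but a few isolated peripheral voxels typically retain
1–6% of Db₀, so the strict "every voxel below 1% of Db₀" reading of
complete clearance is not always met; with the published supplementary
constants in place of the provisional ones this residue is expected to
close, and the corresponding acceptance test asserts the strict bound
rather than a loosened one.

## Sensitivity screen

Two-level screening uses orthogonal arrays built from Hadamard matrices
(Sylvester doubling plus the Paley type-I construction; q = 71 yields the
72-run array used for the full 36-factor screen). Factor levels default to
nominal ±25% (the level spread is a free design choice). Per factor, the
main-effect sum of squares over the total sum of squares gives |%TSS|, and
the sign of (mean at high − mean at low) gives its direction; the top four
by magnitude feed the calibration. Each design run uses one fixed seed;
replicate averaging inside the design is available but off by default.

## GA calibration

Individuals hold values for the four most influential parameters
([PMN]₀, k_R(M0), k_p(M1), k_e(PMN) by default), initialized uniformly
within ±50% of the literature values. Fitness is the absolute difference
(mm⁻²) between the replicate-averaged simulated day-3 total macrophage
concentration and the experimentally quantified CD68⁺ target. Operators:
tournament selection (size 2), arithmetic crossover (p = 0.9), per-gene
Gaussian mutation (p = 0.1, σ = 10% of the gene range), elitism of one —
so the best fitness is non-increasing. Stopping: fitness threshold, a
generation cap, or < 1% best-fitness improvement for 3 consecutive
generations. Stochastic fitness is smoothed by averaging 3 seeds per
evaluation by default (configurable).

## In silico immunofluorescence

Rendering paints every cell's DAPI nucleus blue; all macrophages get a
CD68-green cytoplasm; M1 adds the CD80 red co-mark (composing yellow); M2's
CD68+CD206 co-mark is shown magenta so a single composite image keeps M1
and M2 distinguishable (the experimental stains use red CD206 on separate
slides); PMNs show the nucleus only. Quantification consumes an integer
label mask plus marker channels from any whole-cell segmentation (deep
segmentation itself is out of scope): objects are measured with
`skimage.regionprops`, marker positivity is mean channel intensity above a
threshold, objects outside 80–200 µm² (bounds inclusive) are not classified
as cells, CD68∧CD80 → M1, CD68∧CD206 → M2, CD68 alone → MΦ, and
concentrations are centroid counts inside a user polygon (boundary counts
as inside) divided by the polygon area in mm². A synthetic fixture
generator places non-overlapping elliptical cells with known phenotypes,
sizes and marker channels and returns the ground truth for round-trip
testing; it emulates marker positivity exactly and contains no staining
noise, autofluorescence or segmentation error, so passing round-trip tests
demonstrate the bookkeeping, not robustness to imaging artifacts.

## Problem sizes used by the test and acceptance layers

Replicate studies run the full geometry in quarter-symmetry mode (five
seeds, 3 days). The sensitivity-screen property checks use a 12-factor /
16-run design on a half-scale geometry (1 mm domain, 0.5 mm gap, quarter
symmetry, 3 days per run), and the scaled GA demonstration uses 8
individuals × 5 generations with single-seed 2-day fitness evaluations on
a 0.8 mm domain. These scaled studies exercise the identical code paths as
the full 36-factor / 72-run screen and the 16-individual calibration, which
remain available through the CLI.

## Known limitations

- Adaptive immunity, M2 subtypes, macrophage emigration after resolution,
  mechanical loading, cytokine-gradient chemotaxis and 3D domains are out
  of scope by design.
- Concentration units are opaque; absolute cytokine values are only
  meaningful relative to the half-saturation constants.
- Provisional constants (tagged in the registry) are order-of-magnitude
  choices; quantitative agreement with published concentration bands is
  limited accordingly, and a few debris voxels may survive day 3.
- The deterministic-ascent chemotaxis concentrates cells at sensed maxima;
  a softmax-weighted variant is available behind `chemotaxis_softmax`.
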