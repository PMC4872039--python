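# Methods

## The system and the analysis model

A multi-domain protein whose moving domain (here called N, for the
nucleotide-binding domain of the motivating enzyme) swings rigidly against
a static core domain (C) opens and closes an inter-domain cleft. Two sites
in the cleft couple local hydration to that motion: a hydrophobic pocket
between an upper jaw (a phenylalanine ring) and a lower jaw (two
tryptophan rings) that alternates between water-occupied ("wet") and empty
("dry") states, and a hydrophilic crevice that holds a short column of
three to five waters exchanging one at a time. The package quantifies this
coupling through five linked analyses; each is described below with its
assumptions and tunable parameters.

## Domain PCA

Conformations are superposed on a reference (the first conformation;
an iterative mean-reference option was considered and rejected as
unnecessary for rigid-domain scenes) using only the *fit selection* — the
static-domain Cα atoms — and the 3M-dimensional Cartesian coordinates of
the *analysis selection* (the moving-domain core Cα atoms) are
eigendecomposed with (n − 1)-normalised covariance. Keeping the two
selections distinct is what makes the projection a pure inter-domain
coordinate: internal motion of the static domain cannot leak into it.

Eigenvector sign is arbitrary, so each component is oriented to correlate
positively with a *cleft-opening gauge*: the caller passes a
per-conformation opening measure (the pocket jaw distance d_HS1 is the
natural choice); absent one, the distance between analysis-set and fit-set
centroids is used as a geometric proxy. The proxy can fail on geometries
where opening is a nearly tangential swing — the library therefore always
prefers an explicit gauge, and the bundled pipeline passes d_HS1.
Degenerate eigenvalues are ordered by variance, then by the sign of the
first non-zero coefficient; this tie-break is documented, not meaningful.

Open/closed classification thresholds default to ±15 Å on the PC1
projection (projection zero is the ensemble mean — an offset convention;
absolute projection values are only comparable within one model).

The hinge axis is recovered as the Chasles screw decomposition of the
single best rigid transform taking the moving selection of the most open
conformation to that of the most closed one (after static-domain
superposition). This is deliberately simpler than a dynamic-domain
clustering over many rotation vectors; it is labelled "simplified" and
errors below a 1° rotation where the axis direction is ill-conditioned.

## Windowed solvent density maps and Q

For every sliding window (default length 50 ps, stride 1 ps; both
configurable) the frames are superposed on the window's first frame via a
local anchor selection — an α-helix next to the site of interest — and the
transform is applied to *all* atoms, waters included. Water-atom electrons
(O 8 e, H 1 e) are tallied into cubic voxels (1 Å default) by point
assignment of atom centres (no Gaussian smearing); voxels are half-open
intervals [low, high) on every axis, so a coordinate exactly on a boundary
belongs to the voxel whose low edge it is. Tallies are accumulated as
integers over the window and divided by the frame count once, making the
conservation identity Σ density = 10 e × n_waters, and Q = 10k e for k
fully resident waters, exact in floating point for any window length.
The time-average convention (rather than a frame sum) is what gives Q its
physical reading of "resident waters × 10 e" independent of window length.

Region masks for Q are built from sphere/box/cylinder primitives, either
in fixed coordinates or anchored to named atoms of each window's average
structure so the mask follows the site. The bulk density estimator
averages voxels farther than an exclusion distance (default 8 Å) from any
protein atom; contour levels are conventionally expressed as multiples of
it.

The window average low-pass-filters Q before state classification: a true
occupancy switch appears as a ramp of one window length, and dwells
shorter than the window are attenuated. No correction is applied; the
synthetic scenes quantify the residual bias empirically (it stays within
the statistical error of the dwell fits at the sizes used here).

## Hydration-state kinetics

HS1-type classification places each snapshot in one of four boxes in the
(d, Q) plane (d > 7 Å & Q > 8 e wet-open; 5 < d < 7 & Q > 8 wet-half-open;
5 < d < 7 & Q < 4 dry-half-open; d < 5 & Q < 4 closed). Everything outside
the boxes — including values exactly on a threshold and the deliberate Q
gap 4–8 e — is `boundary` and resolved to the temporally nearest
classified snapshot, ties to the earlier side; the resolution is
idempotent. HS2-type classification reads the crevice occupancy directly
from Q with plateaus at 30/40/50 e (±5 e bins, upper edges to the higher
level).

Dwell segments are maximal constant-label runs; a run of L samples at
spacing dt counts L·dt of residence. The first and last runs are censored
(their true extent is unobserved) and excluded from fitting; runs with
duration ≤ t_min (default 5 ps, the order of bulk-water relaxation) are
excluded from the fit set but kept in transition tallies, and are *not*
merged into their neighbours (an explicit merge mode exists). The default
τ estimator least-squares fits the empirical CDF of (t_res − t_min) at
Hazen plotting positions to 1 − exp(−t/τ); the truncated-exponential MLE,
mean(t_res) − t_min, is always reported as a diagnostic and available as
the estimator. Both are deterministic given the dwell set. For a state
with several successors the per-pair dwell distribution reflects the
*total* escape rate (competing risks), as it does in any per-pair survival
fit; two-state schemes are therefore used when exact recovery of a single
τ is the goal.

## Per-residue change maps

R_i = (⟨X_i⟩_closed − ⟨X_i⟩_open)/⟨X_i⟩_open for X = side-chain ASA and
X = hydration-water count; negative values mean packing/dehydration on
closure. The relative form was chosen (an absolute-difference mode exists
behind a flag) because a dimensionless R with this sign convention is the
natural quantity to map onto a structure; residues with ⟨ASA⟩_open below
10 Å² are flagged buried and carry no R values, as does any residue with
zero open-ensemble hydration (whose relative change is undefined).

ASA uses Shrake–Rupley point sampling (Fibonacci spheres, 960 points
default) through biotite's implementation, with the package's own Bondi
van-der-Waals radii table and probe radius 1.4 Å; backbone N/Cα/C/O and
their hydrogens are excluded from side-chain sums. Point-sampled ASA is
rotation invariant only up to sampling noise (~1–2 Å² per residue at 960
points). Water counting uses the water oxygen as the counted atom against
all side-chain atoms within 3.5 Å, counting each molecule once; using the
oxygen makes the count identical for hydrogen-less inputs.

The jaw gauge d_HS1 is the minimum over the upper-jaw ring hydrogens
(Hδ1/Hε1, chemically equivalent ring positions) of the distance to the
midpoint of the two lower-jaw ring atoms (Cδ1, Cγ); it requires hydrogens
and errors without them. The crevice gauge d_HS2 is a plain Cα–Oε1
distance. All residue numbers are configurable; defaults follow the
motivating system's crystal numbering (340 for the upper jaw, 89/92 lower,
190/354 for the crevice).

## Height distributions

The tip height is the projection of the centroid of a tip residue range
(default 277–287 Cα) onto a fixed unit normal — the observable a
scanning-probe topography of a crystal surface measures. The normal and
reference-plane point are user inputs (deriving them from a crystal
packing is out of scope). The distribution is fitted as a sum of two
Gaussians with a common σ, either to the binned histogram (default bin
width 1 Å) or to the empirical CDF at the sample points; σ and/or the
first component's weight can be held fixed. μ1 < μ2 is enforced after
fitting; a collapse onto one component sets a `unimodal` flag.

Estimator behaviour at strong overlap deserves a warning: when the true
separation is near 1σ, the free-weight histogram objective is badly biased
upward (spurious small-weight far-out components fit histogram noise), and
*every* estimator — including the MLE — has a replicate-level sampling SD
near 1 Å at n ≈ 130. Recovery experiments on such data should fix the
weights at their known generating values and prefer the binning-free CDF
objective; the median over replicates is then an unbiased-in-practice
summary, but individual replicates scatter widely. This is a property of
the statistical problem, not of the implementation.

## Synthetic scenes (what they emulate, and what they do not)

The generators produce: shifted-exponential dwell samples; event-driven
continuous-time Markov paths sampled on a uniform grid (competing
exponential clocks per outgoing edge); a programmatically built two-domain
template protein (ideal poly-alanine α-helices with N/CA/C/O/CB atoms,
plus explicitly placed jaw/crevice atoms laid out so the hinge angle maps
monotonically onto d_HS1 ≈ 4.5–7.9 Å and d_HS2 ≈ 9.5–11.7 Å over 0–20°,
and a tip helix 45 Å from the axis so 20° of hinge moves the tip ≈ 16 Å);
rigid hinge trajectories about a fixed axis with optional isotropic
coordinate noise; water scenes with uniform bulk at a configured number
density (default 0.0334 Å⁻³, liquid water) plus pocket waters whose
occupancy follows the Markov state; and Gaussian-mixture height samples.

Deliberate simplifications: bulk waters are independently resampled each
frame (correct stationary voxel statistics, no residence-time realism —
bulk residence analyses need the Brownian-free construction to be replaced,
and no water–water structure exists); pocket waters appear and disappear
instantaneously at state switches (unambiguous ground truth for Q and the
classifier, no diffusive entry path); waters have no excluded volume
against the protein; 3-site rigid water geometry with random orientation.
The total water count is constant across frames (bulk + maximum pocket
count), with pocket waters parking in the bulk when their state does not
demand them. A bulk keep-out region around the pocket keeps the Q mask
free of bulk noise, standing in for the protein interior that would
exclude bulk water in a real system. Grid sampling of the Markov path can
alias two jumps inside one frame into an apparent one-step transition, so
"forbidden" transitions are exactly absent only on the event log and
almost surely absent (and never fitted) on sampled series.

Passing tests on these scenes validate the estimators — counting,
alignment, spectral decomposition, survival fitting — under known ground
truth. They do not validate force-field realism, hydrogen-bond-network
mechanisms, or diffusive wetting pathways, none of which the generators
model.

All generators derive independent RNG streams from one seed through fixed
offsets; identical configuration and seed give identical output to the
byte.

## Pipeline defaults and problem sizes

The bundled pipeline runs 4000 frames at 1 ps by default, with a 10-ps
window at 2-ps stride for the density series: the synthetic Q signal is
noise-free (bulk is excluded from the mask), so the long 50-ps window
needed to suppress disordered-bulk noise in real data would only add
classification smoothing here; both parameters are plain configuration.
The solvent box covers the density grid around the pocket rather than the
whole protein. The end-to-end rate-recovery check uses a two-state
wetting/drying scheme (57/81 ps) over 4000–6000 ps, giving ≈ 30–45
uncensored dwells per direction and three-standard-error recovery bands of
roughly ±25–40 ps; the acceptance statistics use direct dwell samples at
n = 5000 where the bands are ±2.4, ±3.4 and ±0.6 ps for 57, 81 and 13 ps.

## Known limitations

- No periodic-boundary imaging, no mmCIF, no bond perception.
- Per-pair survival fits inherit competing-risk semantics (above).
- The crystal-ensemble PCA check runs on a synthetic six-conformation
  stand-in ensemble; validating against a real deposited hexamer requires
  downloading the structure and is left to the user (`fit_pca` accepts any
  coordinate stack plus residue-range selections).
- The window low-pass bias on dwell times is characterised empirically,
  not corrected analytically.
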