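# Methods

This note records the models, conventions and numerical choices behind
`vibronet`, and what the synthetic-data tests do and do not establish about
real data.

## Units and constants

Lengths are Å, times fs, velocities Å/fs, masses amu; spectra are reported in
wavenumbers (cm⁻¹) with ν̃ = ω/(2πc), c = 2.99792458 × 10¹⁰ cm/s. Spring
constants of the harmonic generators and elastic networks are amu/fs², so
ω = √(k/m) is in rad/fs. The default trajectory frame spacing is 100 fs — a
save interval at which the 0–160 cm⁻¹ band (Nyquist ≈ 167 cm⁻¹) is fully
resolved, which is exactly the far-infrared window of interest.

## Vibrational spectra

The VACF is normalized at lag zero,
C(τ) = ⟨Σ_i w_i v_i(t+τ)·v_i(t)⟩_t / ⟨Σ_i w_i |v_i(t)|²⟩_t, averaged over all
valid time origins with per-lag origin counts; weights are unity by default
and masses behind a flag (which atoms and weights enter a VACF is an
analysis choice, so the selection is a mandatory argument). The power
spectrum extends the correlation by even symmetry (autocorrelations of
stationary processes are even), applies a Hann window by default, zero-pads
so the wavenumber grid spacing is at most 4 cm⁻¹ (the customary reporting
resolution of far-infrared protein spectra; padding refines the grid, not
the physical resolution 1/(c·span), which is stored separately) and takes a
one-sided periodogram whose intensities satisfy Parseval's identity exactly.
Velocities absent from a trajectory can be approximated by central
differences of positions behind an explicit flag, with a warning.

Peak picking uses prominence relative to the spectrum maximum
(`scipy.signal.find_peaks`). Blue-shift assignment pairs simulated with
measured peaks greedily: a pairing is admissible when sim − exp lies in the
shift interval (default 10–15 cm⁻¹, the classical-MD blue shift against
measured far-infrared modes), and admissible pairs are consumed in order of
distance from the interval midpoint. Peaks without an admissible partner are
reported unmatched rather than force-assigned.

## Hydrogen bonds

A bond is present when all three criteria hold with strict inequalities:
donor–acceptor heavy-atom distance < 3.5 Å (the "center of mass" distance of
the geometric criterion read as the heavy-atom pair distance), H···acceptor
< 2.6 Å, and the angular criterion < 30°. The common shorthand for the angle
is ambiguous about its vertex, so two interpretations are implemented: the
default measures the deviation of D–H···A from linearity (the standard
convention); a flag switches to the ∠H–D···A angle at the donor heavy atom.
The existence autocorrelation is intermittent by default — a bond broken and
re-formed still correlates — with the continuous (must-persist) variant
behind a flag; h(t) ∈ {0,1} per bond per frame makes c(0) = 1 exact.
Weak-contact maps take a mandatory cutoff: what counts as a contact depends
on the interaction class screened, so no default is imposed.

Statistical checks against the telegraph closed form
c(τ) = p + (1−p)e^{−(k_on+k_off)τ} use a binomial standard error inflated by
the integrated autocorrelation factor √((1+ρ)/(1−ρ)), ρ = e^{−(k_on+k_off)dt}:
consecutive frames of a switching process are strongly correlated, and the
naive i.i.d. binomial error would be several-fold too small.

## PCA, cosine content, GNM

PCA operates on Cα Cartesian coordinates after least-squares superposition
onto a reference (frame 0 by default); the superposition is a weighted Kabsch
fit restricted to proper rotations, refusing fewer than three or collinear
points. Eigenpairs come from an SVD of the centered coordinate matrix
(population convention, so Σλ equals the covariance trace); each eigenvector
is oriented so its largest-magnitude entry is positive, making reports
reproducible. Filtering along mode k reconstructs mean + p_k(t)·e_k.

Cosine content uses the Hess form c_k = (2/T)(Σ p cos(kπt/T))²/Σp² on the
half-sample time grid t = (i+½)Δ, which scores an exact half-period cosine
as 1 to machine precision. Values near 1 indicate random-walk-like,
unconverged sampling; planted oscillatory modes score ≪ 0.5.

The GNM builds the Kirchhoff matrix of the Cα contact graph (cutoff default
10 Å), requires a connected graph (components are named otherwise), and
reports hinges as residue pairs bracketing sign crossovers of the slowest
nonzero modes (two modes by default). A degenerate slowest eigenvalue —
e.g. a fully connected contact graph — triggers a warning because the hinge
is then not unique.

## Structural alphabet and local–global coupling

Local structure is encoded by sliding four-residue Cα windows and assigning
each fragment the prototype of minimal proper-rotation RMSD (batched Kabsch
via SVD with determinant correction); ties go to the lowest prototype index,
and fragments spanning a chain break (consecutive Cα–Cα > 4.5 Å in any
frame) are excluded with a warning. The bundled default alphabet is
synthetic: 25 prototypes on a 5 × 5 grid of backbone bend angles (90°–150°)
and dihedrals (±120°, ±60°, 0°) at 3.8 Å spacing, covering compact through
extended and both handednesses. It is a stand-in with the same interface as
published fragment libraries — any 25-state alphabet in the same JSON layout
can be substituted, and all information-theoretic machinery is independent
of the specific prototypes.

MI between discrete state series is the plug-in estimator in nats; the LSF
matrix stores column entropies on its diagonal. The collective (GSF) state
discretizes the top-two PC projections into equal-frequency bins (10 per PC
by default; duplicate quantile edges collapse with a warning) and couples to
fragment states through nMI = MI/H_joint, the joint-entropy normalization
(identical series score 1, independent series 0); min-entropy normalization
is available behind a flag, and a shuffled-replicate estimate of the
finite-sample nMI floor can be requested (reported, not subtracted, by
default).

## Coevolution

Sequences cluster single-linkage at ≥ 62% identity and share unit weight per
cluster; pair frequencies add a uniform pseudocount of 0.05 × total weight
and exclude gaps pairwise; expected frequencies are products of the observed
tables' own marginals; MI is Σ f log(f/f_a f_b). The null permutes residues
within every column independently (composition preserved, covariation
destroyed), 100 randomizations by default, with moments pooled across pairs
— stabler than per-pair moments for short alignments, with per-pair moments
behind a flag. z ≥ 6.5 is the reporting threshold. The 62% / 0.05 / 100
defaults follow the conventions of the server-based implementations of this
analysis family and are all configurable. Conservation is per-column KL
divergence from a background profile (uniform by default), gaps excluded and
renormalized.

All-pairs MI is computed via a Gram product of weighted one-hot column
blocks (√w so each sequence contributes its weight once per pair), which
makes the 100-randomization null on a 500 × 100 alignment run in seconds.

## Networks

Community detection maximizes weighted Newman modularity with a resolution
parameter (γ = 1 standard). The search is deterministic: CNM-style greedy
agglomeration (largest ΔQ, ties to the lexicographically smallest
representative pair), followed by local-move refinement — sweeps that
relocate single nodes to their best neighbouring community, plus aggregation
levels — from both the agglomerated and the all-singletons start, keeping
the better Q. On the benchmark suite used in the tests (clique pairs, small
random weighted graphs, short paths) the result equals the exhaustive-search
optimum verified by enumerating all set partitions; as with any greedy
modularity heuristic there are graphs where it stops at a local optimum
(balanced partitions of longer paths and cycles are classic cases), which is
a known limitation, not a defect the tests hide.

Layouts compute shortest weighted path distances, seed with classical
scaling (spectral MDS), and refine by uniform-weight SMACOF majorization to
a relative stress change of 10⁻⁶; stress is non-increasing by construction.
Disconnected graphs are laid out per component with horizontal offsets.
Exports (GraphML, TSV edge list, JSON with layout) round-trip nodes, edges,
weights and community labels.

## Force distribution

The FDA here runs on an elastic-network potential: springs join all residue
pairs within a cutoff of a reference frame, with rest lengths equal to the
reference distances, and the signed scalar force along a pair axis is
−k(r − r⁰) (negative when stretched; the vector forces on the two members
are exact opposites). Punctual stress per residue sums |time-mean force|
over incident pairs; state differences rank residues by |Δstress|. This is
a deliberate methodological simplification relative to full-force-field
force decomposition: it preserves the bookkeeping (pairwise forces →
residue stress → state differences → PCA over pair-force space) while making
every quantity verifiable against closed-form references. Absolute stress
values are in spring-constant units and only differences and rankings are
meaningful.

## Synthetic generators — what they emulate and what they do not

All generators are bit-reproducible given their spec and seed and return a
`PlantedTruth` sufficient to score every downstream module.

- **Harmonic trajectories** evaluate exact normal-mode solutions (no
  integrator), so energy is conserved to machine precision and the planted
  spectrum is exact. Mode velocity amplitudes are uniform (velocity scale
  default 0.01 Å/fs); zero-stiffness modes drift at constant seeded
  velocities, with a separate scale (0 freezes them for clean spectra).
- **Telegraph H-bonds** sample the exact skeleton of the continuous-time
  two-state chain, so the existence autocorrelation is exactly exponential
  at any frame spacing — a naive per-step k·dt chain would bias the
  relaxation time by ~10% at k·dt = 0.1.
- **Fragment-switch chains** plant two slow continuous collective
  coordinates (bounded AR(1) processes, correlation time 50 frames): a
  sigmoidal longitudinal stretch of one chain half (amplitude 13 Å along the
  unit pattern) and a gentler compression wave (7 Å), both projected out of
  the rigid-body subspace so superposition cannot absorb them. Longitudinal
  patterns were chosen because lateral displacements of a near-linear chain
  are degenerate with rigid rotations. Fragment conformers are a
  mirror-image prototype pair sharing both endpoints, so toggles move only
  fragment interiors; fragment states copy the sign of the first collective
  coordinate with probability (1+coupling)/2. The second collective mode
  exists so that the top-two PCs are both genuinely global; without it the
  second PC is a fragment toggle and the discretized "global" state would
  leak local information. Jitter (0.05 Å) stands in for fast thermal noise.
- **Synthetic alignments** draw unplanted columns i.i.d. from a background
  profile; a planted pair mixes a permutation-coupled component (weight =
  coupling) with the independent product, and the analytic MI of that joint
  table is recorded for oracle use. Redundancy appends near-duplicate
  sequences with i.i.d. per-site mutations.
- **Two-domain structures** place residues on jittered 5 Å cubic lattices
  joined by an extended 3.8 Å linker; the planted hinge is the linker.

What passing these tests shows: the estimators, normalizations, thresholds
and search procedures do what they claim on data whose statistical structure
is known exactly. What they do not show: behaviour under force-field
artifacts, solvent and membrane coupling, alignment phylogeny (the
generators' sequences are exchangeable, so identity clustering is exercised
only through explicit duplicates), anharmonicity beyond two-state switching,
or real structural-alphabet geometry. Problem sizes in the test suite
(10⁴–10⁵ frames, 500 × 100 alignments, ≤ 43-residue structures) were chosen
so the full suite and the acceptance script each run in minutes on one CPU
while keeping sampling error well below the tested effect sizes.

## Degenerate inputs and tie-breaks (summary)

Zero velocities, empty existence matrices, zero-variance projections and
empty graphs raise errors naming the condition; empty selections, donors
without hydrogens, all-gap sequences/columns, collapsed quantile bins,
truncated mode requests and oversized top-k warn and continue. Ties break
deterministically everywhere: lowest prototype index, lower wavenumber
first, lexicographically smallest community pair, lower column index in
edge rankings.
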