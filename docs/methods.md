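# Methods

This note records the models, estimators, numerical choices and known
limitations behind `cholbind`, in the order the pipeline runs them.

## Units and conventions

Lengths are nanometres and times nanoseconds everywhere inside the
package; file formats with other conventions (PDB ångströms, XTC
picosecond timestamps) are converted at the I/O boundary. Only
orthorhombic boxes are supported — the bilayer systems in scope are
orthorhombic, and restricting to them keeps the minimum-image distance
exactly testable. Triclinic inputs are rejected with a clear message
rather than silently mishandled.

Residue-name classification (which residues are lipids, and of which
type) ships as a default table (CHOL/CHL1 → cholesterol, POPC/POPE/… →
phospholipid) and is user-extensible; unknown residue names are an error
in strict mode and are retained as protein-like residues (and reported)
otherwise. The designated cholesterol "head" particle is the
β₃-hydroxyl bead/atom, located by name (ROH, OH, O3, …).

## Dual-cutoff contact detection

A lipid–residue contact opens when the minimum distance over all particle
pairs drops **strictly below** the lower cutoff and closes at the first
frame the distance is **at or above** the upper cutoff; the closing frame
is not part of the event. The boundary convention is fixed so results are
bit-reproducible. Events still open at the last frame are closed there
and flagged *censored*: they enter occupancy statistics but are excluded
from kinetic fits by default, since treating a truncated duration as
complete biases the dissociation rate upward (τ downward). A
Kaplan–Meier-style "keep" policy is available behind a flag.

Default cutoffs are 0.475/0.70 nm, conventional values for coarse-grained
bead models; 0.35/0.55 nm suit atomistic systems. Both are configuration,
not constants.

The hysteresis rule is implemented as a vectorised forward-fill of
open/close triggers; the test suite checks it against an explicit
single-pass state machine on a thousand random distance series, plus a
hand-traced example.

## Residence-time kinetics

Event durations are summarised by the empirical survival function
S(t) = #{duration ≥ t}/N and modelled as a one- or two-component
exponential mixture; the residence time is τ = 1/k₂, defined from the
slower rate. The fast component absorbs short-lived rattling so that τ
reports the long engagements the survival tail encodes.

Estimation is by maximum likelihood **on the raw durations**, not least
squares on the survival curve: the empirical survival function is a
cumulative statistic whose point-wise residuals are strongly correlated,
which makes curve-space information criteria badly miscalibrated — in
development, curve-space selection accepted a spurious second component
on ~10% of genuinely mono-exponential datasets, and the fitted τ then
blew up by orders of magnitude as the "slow" component chased tail noise.
On the independent durations the likelihood is correctly calibrated. The
bi-exponential is accepted only when it lowers the BIC *and* both
components are identifiable: at least five events per component in
expectation and at least a two-fold rate separation. Under these rules
pure mono-exponential data select the mono model in ≥95% of replicates
(observed 100/100 in the suite's property test) while clearly separated
mixtures are always detected. Analytic curves supplied without raw
durations (e.g. closed-form examples) are fitted by weighted least
squares in log-survival space instead, with deterministic multistarts.

Uncertainty is a percentile bootstrap (default 200 resamples, seed
mandatory) over event durations, refitting only the selected model; the
reported interval is widened, if necessary, to bracket the point
estimate. Sites or residues with fewer than 20 events (configurable) are
fitted anyway but flagged low-confidence rather than erroring, so sparse
sites do not crash a pipeline run.

## Binding sites

The co-contact graph has an edge of weight w(r₁, r₂) = fraction of frames
in which **one and the same** lipid molecule is simultaneously bound to
both residues. Edges below a weight floor (default 0.05) are pruned and
Louvain modularity communities (resolution 1.0, fixed seed) become
candidate sites; communities smaller than 4 residues are discarded as
incidental. Sites are ranked by residence time with occupancy as
tie-break — the ranking statistic is a package choice, made because τ
separates specific sites from high-occupancy but fast-exchanging surface
patches.

Site-level binding events are maximal runs of the per-lipid OR over the
site's residues; site occupancy is the percentage of frames with at least
one lipid bound to at least one site residue (and is therefore never
smaller than any member residue's own occupancy).

Representative poses: bound-lipid coordinates are expressed in a
site-local frame by Kabsch superposition of the site residue particles
onto the first occupied frame (with minimum-image unwrapping around the
residue centroid), clustered agglomeratively (average linkage) at an
RMSD cutoff of 0.2 nm over lipid particles, ranked by cluster size with
the earliest frame breaking ties, and represented by the cluster medoid.
Occupied frames are subsampled evenly to 400 poses to bound the quadratic
RMSD matrix; this caps memory without biasing cluster proportions.

Orientation: the bilayer midplane is estimated per frame as the mean z of
all lipid particles (robust to bilayer drift); a pose is *flipped* when
its hydroxyl is closer to the midplane than its ring centre (the centroid
of its non-head particles), and the leaflet is the sign of the ring
centre's offset.

## Occupancy titration and apparent Kd

The free-cholesterol abscissa is defined as
x = 100 × ⟨# cholesterol not in dual-cutoff contact with any protein
residue⟩ / (total lipid molecules), time-averaged — i.e. normalised to
all lipids, correcting the nominal composition for protein-sequestered
cholesterol. This definition is deliberate and recorded in the output
metadata (`x_definition`), since alternatives (per-leaflet normalisation,
pooling versus averaging of replicates) change the scale. Replicates are
averaged per composition with the standard error across replicates.

The saturation fit Occ(x) = Occ_max·x/(K_d + x), optionally plus a linear
non-specific term m·x, profiles K_d: at fixed K_d the remaining
parameters are linear and solved in closed form, the point estimate
minimises the profiled RSS (coarse log-grid bracketing plus bounded
refinement to 10⁻¹⁰), and the 95% CI inverts the F-test on the profiled
RSS. The profile interval is used because K_d is a ratio-like parameter
whose Wald interval under-covers at small design sizes (5 compositions ×
3 replicates); in the suite's calibration study the profile CI covers the
true K_d in 91–93 of 100 seeded repeats across the tested affinity range.
Occ_max is reported truncated to the physical (0, 100] range. A fitted
K_d beyond five times the largest sampled composition is flagged
*non-saturable* — the behaviour expected of pure background binding,
which is reported as a distinct flagged curve rather than subtracted.

## Synthetic data generator

The generator's purpose is exact ground truth, not physical realism.

Binding is a site-level continuous-time Markov chain, discretised per
frame: an empty site binds with probability c·x·Δt (c the association
scale in μs⁻¹·%⁻¹, x the instantaneous free-cholesterol mole-%) and a
bound cholesterol unbinds with probability k_off·Δt. Stationary occupancy
is therefore exactly x/(x + K_d) with K_d = k_off/c, and bound durations
are memoryless with mean 1/k_off (verified by a Kolmogorov–Smirnov test
in the suite). The chain is initialised from its stationary law so
occupancy needs no burn-in. The lipid that binds is chosen uniformly at
random among free cholesterols and relocated onto the site — binding
propensity is deliberately independent of instantaneous positions, which
is what makes K_d exact by construction; coordinates are rendered
*afterwards*, consistently with the chain's ledger.

Rendering: protein beads are static (site residues on a 0.3 nm ring
around each site anchor, at ±0.7 nm from the midplane); free lipids
perform 2D Brownian motion (step SD 0.1 nm/frame) in their leaflet with
periodic wrapping; bound cholesterol sits on its site anchor with
clipped Gaussian jitter (SD 0.05 nm, |jitter| ≤ 0.1 nm), which places
every site residue within the lower contact cutoff. Free cholesterol is
pushed out of exclusion discs around all protein beads (1.2 nm around
site anchors, 0.9 nm around stray residues, mutually separated so a
single pass cannot cascade), so **no contact can occur outside the Markov
ledger** — detection on the rendered coordinates reproduces the chain's
occupancy exactly, frame by frame (asserted in the suite). Cholesterol is
three beads (hydroxyl, ring centre, tail) so orientation is exercisable;
a site may be designated *flipped*, writing its bound cholesterol with
the hydroxyl stack inverted. Phospholipids are single head beads whose
depth keeps them outside the contact cutoffs of all protein beads.

Default desk-scale system: 100 lipids at 25 mole-% cholesterol in a
12×12×4 nm box, two planted 6-residue sites — one flipped, τ = 0.8 μs,
K_d = 6.6 mole-%; one canonical, τ = 0.8 μs, K_d = 10.7 mole-% — plus two
stray residues, 20 000 frames at 1 ns/frame (≈5 s to generate and
analyse). These affinities and the residence time mirror the
coarse-grained reference values the package is designed to recover.

The titration template uses one site, a 1000-lipid reservoir and fast
exchange (k_off = 12.5 μs⁻¹, τ = 80 ns) over 8 μs per replicate.
Equilibrium occupancy depends only on K_d = k_off/c, so fast exchange is
the correct scale-down for a titration: it packs ~50 independent binding
cycles into each desk-scale replicate, bringing the Monte-Carlo error of
the occupancy at half-saturation within a few percent — the precision
that multi-microsecond sampling of slower kinetics achieves at cluster
scale. The large reservoir keeps depletion of free cholesterol by the
single bound copy below 0.1 mole-%, which matters because the fit's
abscissa is the *time-averaged* free fraction: with a small reservoir the
abscissa dips whenever the site is occupied, biasing K_d low by several
percent. For repeated-statistics studies the generator exposes a fast
path (`simulate_occupancy_titration`) that runs only the Markov chain and
reads occupancy and free fraction off its ledger; because rendering
cannot create or destroy contacts (above), this is exactly the quantity
the full render-and-detect route measures, as the suite asserts, at a
small fraction of the cost.

Dose-response data are the bell model plus i.i.d. Gaussian noise (default
SD 2 response units = 2% of the stimulatory span); the paired "PTX"
dataset contains the stimulatory component only, with independent noise.
Default truth: basal 5, stimulatory span 100 at EC₅₀ 10⁻¹⁰ M, inhibitory
span 75 at EC₅₀ 10⁻⁹ M — a ten-fold separation of the inhibitory from the
stimulatory arm, with the inhibitory span sub-maximal so the curve rises
and then falls.

**What the generator does not emulate** — and hence what passing tests do
and do not show: there are no forces, no membrane undulations, no
protein flexibility, no correlated or cooperative binding, no leaflet
asymmetry dynamics, and binding kinetics are positionally decoupled by
design. Tests against this generator validate the *estimators* (contact
logic, survival fits, community detection, saturation and dose-response
fits) under known truth; they do not validate the physical realism of
any particular force field or the transferability of default cutoffs to
a given real system.

## Pharmacology

Hill slopes are fixed at 1 in both dose-response models (3-parameter
logistic and bell); a free-slope variant is out of scope. The bell model
is the superposition R(c) = basal + span_s/(1 + EC₅₀ₛ/c) −
span_i/(1 + EC₅₀ᵢ/c), with EC₅₀ᵢ = EC₅₀ₛ·10^δ, δ ≥ 0, so the inhibitory
arm cannot slide below the stimulatory one — this reflects the underlying
biology (inhibition requires more agonist) and stabilises the fit. Both
fits run trust-region least squares in log₁₀-EC₅₀ parameterisation from
deterministic multistarts spanning the concentration range. A fitted
inhibitory span below 10⁻³ of the stimulatory span is reported as
collapsed to the plain logistic. The Gαi component is the pointwise
difference (PTX minus total), positive-signed as suppression, with its
AUC taken by the trapezoid rule over log₁₀ concentration. Responses are
treated as opaque units; any normalisation (e.g. to forskolin) happens
upstream. Inter-condition hypothesis testing (ANOVA, multiple
comparisons) is out of scope.

## Pipeline and reproducibility

The pipeline config is a validated schema that rejects unknown keys, and
every stochastic step (community detection, bootstraps, synthetic
generation) derives from the single top-level seed. Report floats are
rounded to six digits before serialisation with sorted keys, so a rerun
with an identical config is byte-identical. All tabular outputs are CSV;
representative poses are written as multi-model PDB.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- Contact distances are computed between particle positions; no
  hydrogen-bond or water-mediated contact criteria.
- Censored-event handling is exclusion (default) or naive inclusion;
  no full censored-likelihood survival fit.
- The co-contact graph uses binary bound states; contact *strength*
  (distance-weighted) is not used.
- Site ranking by τ is a convention; occupancy-ranked workflows need the
  caller to re-sort.
- The titration abscissa is normalised to all lipids; per-leaflet
  normalisation would rescale K_d^app.
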