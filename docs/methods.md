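# Methods

`voxnet` implements a voxelwise functional-network analysis: every voxel of
a 4D signal volume is a potential network node, edges are suprathreshold
temporal correlations, per-node graph measures become 3D images, and group
differences in those images are tested with nonparametric cluster-size
permutation statistics. A synthetic phantom generator supplies cohorts with
known planted structure so every stage can be exercised and calibrated
without external data. This note documents the model, the defaults, and the
design choices that were genuinely open.

## Temporal preparation

Raw sessions (default 128 acquisitions at TR 2.68 s) are trimmed by four
acquisitions at each end, leaving 120. The high-pass filter is a
discrete-cosine projection: DCT-II components with frequency below the
cutoff (default 1/42.88 ≈ 0.02 Hz), including the DC term, are zeroed.
Any DC-removing high-pass meeting the transfer-function contract (pass-band
amplitudes preserved within 5 %, deep-stop-band attenuation ≥ 90 %) would
be equivalent for this analysis; the DCT projection was chosen because it
is exactly linear, idempotent, and phase-free, which makes the filter's
algebraic properties testable rather than approximate.

Two analysis volumes are built per subject: a **task** volume — the
arithmetic mean of all trial windows (15 trials × 4 sessions = 60 windows
of 8 acquisitions, 21.44 s) — and a **rest** volume — the four trimmed
sessions concatenated (480 acquisitions). Trial averaging assumes the
responses to stimuli in rapid succession summate linearly, which is exactly
how the phantom generates them.

## Spatial normalization order

To study the effect of when spatial normalization happens, volumes can be
warped to a "standard" grid by a known native→standard voxel affine and
resampled back to the acquisition resolution (trilinear for data,
nearest-neighbour for label volumes). The two interpolation passes smooth
the data, which raises local spatial autocorrelation and therefore the
density of networks thresholded at a fixed critical correlation — the
package treats this inflation as a measurable artifact of the processing
order, not a property of the underlying signal. Because the standard grid
is resampled back to the native voxel counts, native and standard results
can be compared voxel for voxel.

## Network construction

Pearson correlations are computed between all pairs of included
(grey/white-matter) voxels. The edge threshold r_crit is derived at run
time from a two-tailed significance level α by the exact t transform
(t = r·√df/√(1−r²), df = n−2), never hard-coded: with n = 8 (task) the
levels α ∈ {1e−2, 1e−3, 1e−5} give r_crit ≈ {0.834, 0.90, 0.96}, and with
n = 480 (rest) α ∈ {1e−25, 1e−38, 1e−58} give ≈ {0.4535, 0.5465, 0.6490}.
Commonly quoted rounded values (0.82, 0.45, …) are kept in
`network.REFERENCE_R` purely as reference constants. Only positive
correlations at or above r_crit (ties included) form edges; zero-variance
voxels are flagged and can never carry an edge.

Pruning removes degree-0 nodes always; if the largest remaining component
holds ≥ 75 % of the connected nodes, minor components are removed too and
the network is marked non-fragmented. Otherwise all connected nodes are
kept and the network is flagged fragmented, which later excludes the
subject from clustering-coefficient and path-length statistics (degrees of
freedom adjusted accordingly). A network whose nodes are all isolated
prunes to an empty network rather than raising, so a no-signal subject
flows through the pipeline and simply contributes missing values.

## Graph measures

Per node: degree (neighbour count), clustering coefficient (density of the
neighbour-induced subgraph), characteristic path length (mean BFS hop count
to all other nodes; connected networks only), and local efficiency. Local
efficiency uses the Latora–Marchiori harmonic form — the mean over ordered
neighbour pairs of the inverse shortest-path distance within the
neighbour-induced subgraph, with 1/∞ = 0 — rather than the literal
"inverse of the mean neighbour-subgraph path length", because the literal
form is undefined whenever the neighbour subgraph is disconnected; the two
agree on connected neighbour subgraphs with equal distances. Nodes of
degree < 2 get clustering and local efficiency 0 (not missing), keeping
metric images dense. Path length is computed by per-node BFS rather than
all-pairs matrices for predictable memory on ~10⁴-node graphs.

Measures are materialized as 3D images with NaN as the explicit missing
marker and Z-normalized per subject, per measure, per space (population SD)
to absorb network size and density differences across subjects. All four
measures are verified to agree exactly with an independent brute-force
implementation (adjacency-matrix triangle counting, Floyd–Warshall
distances) on random graphs.

## Group statistics

Missing voxels of standard-space images can be imputed by *mean replacement
by random neighbor selection*: for each missing voxel, up to 5
(subject, voxel) candidates are drawn uniformly without replacement from
the images of all other same-group subjects at voxels within a 10 mm
(world-coordinate) sphere; if ≥ 90 % of the drawn candidates hold a value,
the mean of the present draws replaces the missing value. Candidates are
always read from the original images and present values are never altered.
Native-space images are not imputed. The "up to 5" draw is over
subject–voxel pairs, matching the description of sampling from the images
of all other subjects.

A voxel enters a two-group test only if ≥ 90 % of the (non-excluded)
subjects in each group carry a value there. The test statistic is the
pooled-variance two-sample t (first group minus second); df follows the
non-excluded subject counts, shrinking per voxel where values remain
missing. Clusters are formed at |t| ≥ 3.0 with 26-neighbourhood
connectivity (the common neuroimaging convention; the connectivity is
configurable), separately for each sign. The null distribution of the
maximal cluster size over both signs is built from label permutations
(default 10,000; the identity labeling is always a member, and when the
number of distinct relabelings is smaller the null is enumerated exactly).
A cluster is familywise-significant when the fraction of null maxima at
least as large as its size is ≤ 0.05. This max-statistic reading of the
"top 95th percentile" rule was chosen over a literal quantile cutoff
because heavy ties in discrete cluster sizes can make a quantile threshold
anticonservative; with the max-statistic form the familywise error rate is
bounded by construction, and empirically the procedure is conservative
(discrete sizes leave the attained level below nominal). Pooling signs in
the null maximum is the conservative two-sided reading; it is configurable
in principle because the single-threshold description leaves it open.

## Cross-space comparison

Native- and standard-space results are compared by the Pearson correlation
of their t images over jointly defined voxels and by the Dice coefficient
2|A∩B|/(|A|+|B|) of their significant-voxel sets (two empty sets give 0,
flagged by a warning; the historical adaptation of Dice used alongside this
analysis is not publicly specified and is deliberately not guessed).
Voxels significant in the same direction at ≥ 2 correlation thresholds form
consistency masks, and significant voxels are summarized per region of an
integer atlas as proportions normalized by region size. A synthetic
block atlas ships for testing; real atlas volumes load the same way.

## Random-graph reference

For supercritical Erdős–Rényi graphs the mean path length follows
l = (ln n − γ)/ln k + ½ (γ = 0.5772), and mean local efficiency follows
e = (w·c + x)/(1 + (c/y)^z) with published constants w ≈ 0.5, x ≈ 0.5,
y ≈ 0.07, z ≈ −3.9. The efficiency constants are treated as fixed: the
original fit depends on an unstated graph-size range, so re-estimation is a
diagnostic, never a gate. Simulated G(n, p = k/(n−1)) graphs match the
path-length form within 10 % for n ∈ {500, 2000}, k ∈ {10, 20, 50}
(path length estimated by BFS from 200 uniformly sampled sources, an
unbiased estimator of the node-mean). Joint histograms of per-node
(degree, path length) and (clustering, local efficiency) values — 5000 bins
by default — visualize how tightly the measured relationships track these
curves; in practice they track them closely enough that path length and
local efficiency act largely as proxies for degree and clustering in group
comparisons.

## The phantom

The generator reproduces the acquisition geometry the analysis assumes:
64×64×16 grids of 3.75×3.75×8 mm voxels, TR 2.68 s, four sessions of 128
acquisitions, 15 trials of 8 acquisitions starting at acquisition index 4
(so trimmed sessions tile exactly into trial windows), with roughly half
the trials carrying a second stimulus 2 acquisitions after the first and
all responses summating linearly through a unit-peak double-gamma HRF
(peak delay 5 s, dispersion 1 s, undershoot at 15 s with ratio 1/6 —
any smooth unimodal kernel peaking near 5 s would serve, since trial
averaging, not HRF modelling, is the analysis mechanism).

Planted structure is block-based, not anatomical: a "posterior" and an
"anterior" contiguous voxel box (fractional boxes on the grid, forced to
grey matter inside a synthetic elliptical brain mask). Per session each
block voxel receives

    m · (a·S_region + b·C_sub) + ρ·B + σ·ε,   plus a baseline of 100,

where S_region mixes the task regressor with a region-wide band-limited
(0.025–0.10 Hz) fluctuation, C_sub is a fluctuation shared by one of 4
contiguous sub-blocks, B is a weak brain-wide fluctuation (ρ = 0.25), and
ε is i.i.d. Gaussian noise (σ = 1). Defaults a = 2.4, b = 2.0 make the
group multiplier m the dial of the planted effect: the sub-block coherence
b keeps every block voxel connected (so reduced-connectivity groups survive
presence filtering) while m controls whether sub-blocks bind into one
densely connected block — i.e. node degree. m = 0 removes all structure,
leaving pure noise. The default effect table plants the posterior-anterior
shift: young {posterior 1.0, anterior 0.35}, aged {0.35, 1.0}, aged-AD
{0.2, 1.15}; default group sizes are 14/14/11. The resting fluctuations
are band-limited from construction so they sit inside the high-pass
pass-band; temporal autocorrelation of the noise, physiological artifacts,
motion and anatomy are deliberately not modelled.

What passing tests show, and do not show: the phantom demonstrates that the
pipeline recovers a planted connectivity contrast of this block-structured,
Gaussian-noise form with controlled familywise error, and that the
normalization-order density inflation arises from interpolation smoothing
alone. It does not show robustness to autocorrelated noise, imperfect
registration, partial-volume effects or anatomical variability.

## Problem sizes used in validation

Calibration and recovery experiments run at reduced grid sizes chosen to
keep the experiments routinely repeatable: familywise error is estimated
from 200 replicates of 8-vs-8 Gaussian image groups on a 24×24×8 grid with
500 permutations; edge-threshold calibration uses 10⁵ simulated pairs of
length 8; planted-effect recovery uses 20 seeded 8-vs-8 cohorts on a
16×16×6 grid via the resting-state route (the task route is uninformative
for this particular phantom: trial averaging raises all block correlations
toward 1, erasing the planted degree contrast); density inflation uses 20
subjects on a 12×12×6 grid. The full 64×64×16 grid is supported throughout
and used subject-by-subject when writing cohorts to disk; an all-voxel
64×64×16 correlation matrix (65,536² entries) is intentionally never
materialized in the validation suite.

## Numerical conventions

Voxel raster order is x fastest, then y, then z, 0-based. Presence
fractions are compared with a 1e−12 tolerance so the 9-of-10 boundary case
is included. Degenerate inputs raise: over-trimming, cutoffs at or beyond
Nyquist, all-zero-variance voxel sets, empty input networks, zero-spread
Z-normalization, fewer than 2 subjects per group. Every random draw flows
from an explicit seed (`numpy` `SeedSequence` spawning per stage); rerunning
any experiment or the full pipeline with the same configuration is
bit-reproducible.
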