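# Methods

## Model

The package treats whole-brain neural communication as a capacitated
routing problem on an undirected region graph. Structural connectivity
enters as link capacities `D_l` — streamline counts divided by the largest
off-diagonal count, so capacities lie in `(0, 1]` and the unit delivery
cost `1/D_l` has a stable scale. Functional data enter as nonnegative nodal
demands `R_iᵐ`, one column per functional mode. The decision variables are
per-mode link flows `f_lᵐ ≥ 0` and per-link capacity corrections
`P_l ≥ 0`; the program minimizes total delivery cost plus a correction
penalty `ρ (1 + 1/D_l) P_l`, subject to the link-capacity, node-demand and
feasibility constraints shown in the README. The constant bias `1` in the
correction penalty prevents cheap inflation of already-strong links; the
`1/D_l` part makes corrections expensive on links with no structural
evidence, acting as a probabilistic prior on pathway existence.

Three modeling assumptions matter:

- **Undirectedness.** Flow has no direction; effective or causal
  connectivity is out of scope.
- **Complete candidate set.** Every node pair is a candidate link, with
  absent pairs floored at `δ`. This is what lets the model recover pathways
  tractography missed entirely — at the cost of a mild degeneracy discussed
  below.
- **Demand proportionality.** The fMRI-derived activation of a region is
  assumed proportional to the information it sends/receives per mode; the
  conversion constant is absorbed into `γ` and the flow units
  ("activation-equivalent flow").

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `γ` | auto | activation / capacity | capacity→flow conversion; auto = largest nodal ratio of total activation to total incident capacity, the smallest value that guarantees feasibility for every input |
| `ρ` | 1.0 | dimensionless | correction penalty weight; larger = fewer corrections. Σ P is non-increasing in ρ (tested) |
| `δ` (capacity floor) | 1e-4 | capacity | keeps `1/D_l` finite and missing pathways recoverable |
| `flow_epsilon` | 1e-6 | flow | absolute circuit-inclusion threshold |
| solver tolerance | 1e-8 | — | accepted constraint violation; HiGHS dual simplex, deterministic |

With all-zero activation, `γ = 0` and the zero solution is returned rather
than an error. Modes whose activation column is all zero after masking are
dropped with a warning.

### Circuit extraction and the floor-capacity detour artifact

Auto-`γ` is set by the worst-provisioned active node, which means every
floored link carries a small free capacity `γδ` (equal to that node's
activation divided by its incident link count). The optimum may therefore
spread residual demand over arbitrary floored links at no correction cost.
These detour flows are bounded above by `γδ` per link, while genuine
circuit links carry flows on the order of the regional activations
(typically an order of magnitude larger). `extract_circuit` therefore
thresholds at `max(flow_epsilon, 1.5·γδ)` by default; the 1.5 margin
absorbs degenerate reallocation of detour mass near the bound. Pass
`filter_detours=False` to threshold at `flow_epsilon` alone.

## Input preparation

- **Correlation networks** are Pearson correlations of regional time
  courses; aggregation across runs or realizations happens on the Fisher-z
  scale (`tanh(mean(atanh r))`, with `|r|` clipped at `1 − 1e-7`).
- **Region activations** are the mean *absolute* spatial-map value within
  each region (ICA maps are signed); a flag selects raw-value averaging.
- **Activity masking**: per mode, regions are split active/inactive by
  2-means (k-means++, 10 restarts, fixed seed) and inactive regions are
  zeroed. An all-equal column is left fully active, since zeroing it would
  silently drop the mode. Masking is per-mode, never joint across modes.
- **Mode matching** to reference maps uses an optimal one-to-one assignment
  (Hungarian algorithm) on absolute spatial correlation, recording the
  match sign so sign-indeterminate ICA components can be oriented.
- **Top-k consistency** summaries break weight ties by canonical `(i, j)`
  edge order for reproducibility.

## The synthetic phantom world

The validation fixture emulates a physical diffusion phantom at the
connectivity level: 16 end-point regions (P1..P16) on a circle in a
64×64×3 voxel grid, 9 true end-point pairs carried by 7 bundles (two
bundles serve two pairs each: a crossing through P9 and a branch through
P15), partitioned into 5 functional sub-networks:
red {P1,P2}, green {P3,P4}, blue {P5,P6,P7,P9,P12}, orange {P8,P10},
cyan {P11,P13,P14,P15,P16}. Whether P4-P5 / P5-P6 are real bundles is
ambiguous in the source material describing the physical phantom; they are
excluded from the in-repo ground truth (they do appear in the GMM
baseline's FA-surrogate "connected" list, which is taken as given).

### Tractography emulation

Counts per link (before ±20% multiplicative jitter):

- deterministic: intact bundle (P13-P14) at 20 000; crossing/bending
  true links (P5-P7, P6-P9, P9-P12, P8-P10, P11-P15) at 10; fully missed
  true links (P1-P2, P3-P4, P15-P16) at 0; spurious track-jumping links
  (P6-P7, P7-P9, P8-P9, P9-P10, P12-P15) at 1.
- probabilistic: every true link nonzero (under-estimated set at 10),
  wider spurious set (additionally P11-P16, P4-P5, P5-P6) at 1.

The levels are calibrated so that, after max-normalization with floor
`δ = 1e-4`, the under-estimated true links sit just above the floor:
cheap enough to be preferred over arbitrary detours, weak enough that the
functional demand saturates them and forces a correction. Spurious links
fall below the floor, so they read as "present" in the count matrix but
carry no cost advantage over any other absent pair — what rejects them in
the joint model is not their count but the absence of a shared functional
demand at their two end points. A link whose both end points demand flow
in the same mode can serve both demands with one flow and is therefore
roughly twice as cost-effective as any single-demand alternative; this
cost-sharing is the mechanism that concentrates corrections on true
pathways.

One degeneracy is intrinsic and faithful to the modeled scenario: with
P15-P16 missed entirely, routes P15-P16 and P11-P16 for P16's demand have
identical cost, and the optimizer's choice between them is arbitrary. The
recovery property is therefore asserted as ≥ 8 of 9 true links.

### BOLD simulation

Each sub-network receives a base time course: 20 ON and 20 OFF blocks of
30 TRs (1200 time points), plus independent per-TR unit events with
probability 0.2, convolved with the canonical double-gamma HRF (response
peak 6 s, undershoot 16 s, unit dispersions, undershoot ratio 1/6,
unit-peak normalized). TR defaults to 0.72 s. Block order is a random
arrangement unique to each network; arrangements are redrawn (up to 60
deterministic attempts, best kept) until the convolved courses of
different networks correlate below 0.05, emulating independently designed
network activity — the separability of the functional modes is a premise
of the study design, not an outcome. An `alternating` block order is
available for classic designs. Regions inherit their group's course scaled
by an independent U(0.8, 1.2) draw, then receive Rician noise
(`√((x+n₁)² + n₂²)`); σ defaults to (mean ON amplitude)/SNR with target
SNR 20, or can be set directly. Voxel-level output (27 voxels per region,
independent noise) is available; region level is the default analysis
path.

### Source separation

ICA is performed with FastICA, estimating independence along the *time*
axis: at region resolution the spatial domain has only 16 samples, far too
few to estimate spatial independence, while the underlying network time
courses are independent by construction over 1200 samples. The spatial
maps are the mixing-matrix columns, normalized to unit variance across
locations. This is an estimator choice, not a change of contract: the
output is a locations × components spatial-map table with the usual
sign/permutation indeterminacy, resolved by mode matching.

What the generator does *not* emulate: scanner drift and physiological
confounds, spatially correlated noise, partial-volume mixing between
regions, haemodynamic variability across regions, and the actual diffusion
signal (tractography is emulated at the count level only). Passing tests
therefore demonstrate correctness of the model and pipeline mechanics
under idealized-but-noisy conditions, not robustness to real-scanner
artifacts.

## GMM baseline

The comparison method models each link's (structural, functional) feature
pair — a mean-FA surrogate and a correlation — with a six-component
bivariate Gaussian mixture fit by EM (k-means++ initialization, 10
restarts, covariance floored at 1e-6 of the per-feature variance;
log-likelihood is non-decreasing per iteration and the trajectory of the
winning restart is retained). Each link receives the maximal-posterior
component; posterior ties resolve to the lowest component index.

Component semantics are attached after fitting. Functional labels follow
the component's mean correlation (positive / negative / uncorrelated at
±0.2). For the anatomical call, the package follows the joint model's
generative premise — functional correlation implies an anatomical
substrate — so a component is "connected" when its structural mean falls
in the upper structural cluster *or* its functional label is not
"uncorrelated". This reproduces the baseline's characteristic behavior:
it recovers true links suppressed in the structural feature (high
correlation, near-zero FA) but also calls indirectly correlated pairs
connected, yielding systematically more false positives than the flow
model — the comparison the package is designed to exhibit. A purely
structural row assignment was rejected because suppressed links form their
own low-FA/high-correlation cluster and would never be recovered.

The FA surrogate samples N(0.6, 0.05²) on the eleven links whose mean-FA
reads "connected" in the phantom scenario and N(0.08, 0.05²) elsewhere
(clipped at 0); correlations come from the simulated-instance Pearson
network. No negative-correlation category is realized by this generator;
the corresponding components simply receive no mass.

## Numerical choices

- LP solved with `scipy.optimize.linprog` (HiGHS), deterministic;
  objective value is the only comparator across solvers because optimal
  flow patterns can be non-unique (e.g. symmetric capacities). An
  independently assembled dense formulation solved by interior point
  serves as the cross-check oracle in the tests.
- Solutions are validated post-hoc against all three constraint families;
  flows and corrections below the solver tolerance are snapped to zero.
- Streamline matrices must be symmetric within `1e-8` relative tolerance
  and are exactly symmetrized before normalization.
- Fisher-z clipping at `|r| ≤ 1 − 1e-7`; Hungarian assignment on `|r|`
  for mode matching; k-means and FastICA seeded everywhere.
- Floats serialize at 12 significant digits; all writers emit canonical
  row/column order so identical seeds give byte-identical artifacts.

## Known limitations

- The published objective is a weighted min-cost sum and is implemented as
  printed; descriptions of it as "min-max" elsewhere in the source
  material do not match the printed program.
- "TR = 72 ms" in the source material is treated as a typo for 720 ms;
  both are supported via the recipe.
- Corrections are nonnegative: the model can recover under-estimated links
  but cannot delete over-estimated ones (it only starves them of flow).
- Auto-`γ` ties the flow scale to the worst-provisioned node; the
  floor-capacity detour artifact described above is the practical
  consequence, handled at circuit-extraction time.
- The phantom experiment at the default study conditions uses 100 fMRI
  instances on a 16-node complete graph (720 LP variables); the whole
  experiment runs in seconds, so no scaling shortcuts are taken.
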