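"""Synthetic Fibercup-like validation world.

A physical diffusion phantom with a known bundle layout provides ground-truth
structural connectivity: sixteen end-point regions (P1..P16) joined by seven
fiber bundles, grouped into five functional sub-networks ("colour groups").
This module reconstructs that world at the connectivity level: the fixed
topology, emulated deterministic/probabilistic tractography with their
characteristic error patterns (false negatives at fiber crossings for
deterministic, spurious links for probabilistic), a block-design BOLD
simulation (square-wave task blocks plus random unit events, canonical
double-gamma HRF, per-region amplitude jitter, Rician noise), ICA source
separation, and the repeated-instance enhancement experiment that feeds the
joint flow model.

The ground-truth edge list is reconstructed from the bundle end-point
statements accompanying the phantom; it is the canonical in-repo truth:
true edges P1-P2, P3-P4, P5-P7, P6-P9, P8-P10, P9-P12, P11-P15, P13-P14,
P15-P16; known non-edges include P6-P7, P7-P9, P8-P9, P9-P10, P12-P15 and
P11-P16.  Whether P4-P5 / P5-P6 are real bundles is ambiguous in the source
material; they are excluded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from sklearn.decomposition import FastICA

from .connectivity import kmeans_activity_mask, match_modes, region_activation
from .flow_model import ActivationMatrix, ModelConfig, RegionGraph, canonicalize_graph, solve_joint_model

__all__ = [
    "PhantomSpec",
    "BoldRecipe",
    "TractogramEmulation",
    "EnhancementResult",
    "build_phantom",
    "block_design",
    "hrf_convolve",
    "canonical_hrf",
    "rician_noise",
    "simulate_instance",
    "emulate_tractography",
    "source_separation",
    "simulate_activation_matrix",
    "run_enhancement_experiment",
]

_NODES = tuple(f"P{i}" for i in range(1, 17))

# (node_a, node_b, bundle_id); bundles 4 and 6 each carry two end-point pairs
# (a crossing bundle through P9 and a branching bundle through P15).
_TRUE_EDGES: tuple[tuple[str, str, int], ...] = (
    ("P1", "P2", 1),
    ("P3", "P4", 2),
    ("P5", "P7", 3),
    ("P6", "P9", 4),
    ("P9", "P12", 4),
    ("P8", "P10", 5),
    ("P11", "P15", 6),
    ("P15", "P16", 6),
    ("P13", "P14", 7),
)

_COLOUR_GROUPS: dict[str, tuple[str, ...]] = {
    "red": ("P1", "P2"),
    "green": ("P3", "P4"),
    "blue": ("P5", "P6", "P7", "P9", "P12"),
    "orange": ("P8", "P10"),
    "cyan": ("P11", "P13", "P14", "P15", "P16"),
}

# Deterministic tractography error pattern: crossings/bends break streamline
# propagation, so under-estimated true links get near-zero counts and a few
# erroneous continuations create spurious links.  Probabilistic tractography
# finds every true link but adds a wider spurious set.
DETERMINISTIC_MISSED: tuple[tuple[str, str], ...] = (
    ("P1", "P2"), ("P3", "P4"), ("P15", "P16"),
)
DETERMINISTIC_LOW: tuple[tuple[str, str], ...] = (
    ("P5", "P7"), ("P6", "P9"), ("P9", "P12"), ("P8", "P10"), ("P11", "P15"),
)
DETERMINISTIC_SPURIOUS: tuple[tuple[str, str], ...] = (
    ("P6", "P7"), ("P7", "P9"), ("P8", "P9"), ("P9", "P10"), ("P12", "P15"),
)
PROBABILISTIC_SPURIOUS: tuple[tuple[str, str], ...] = DETERMINISTIC_SPURIOUS + (
    ("P11", "P16"), ("P4", "P5"), ("P5", "P6"),
)

# Count levels before normalization, chosen to emulate dense-seeding
# tractography: fully reconstructed bundles collect tens of thousands of
# streamlines, crossing/bending bundles only a handful, and spurious
# track-jumping continuations a stray streamline.  After max-normalization
# with the default capacity floor (1e-4) this puts crossing links just above
# the floor — cheap enough to be preferred over arbitrary detours, weak
# enough that fMRI demand saturates them and forces a correction — while
# spurious links fall below the floor and carry no cost advantage over any
# other absent pair.
COUNT_HIGH = 20000.0
COUNT_LOW = 10.0
COUNT_SPURIOUS = 1.0
COUNT_JITTER = 0.2  # +-20% multiplicative


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth topology and geometry of the synthetic phantom."""

    nodes: tuple[str, ...]
    ground_truth_edges: tuple[tuple[str, str, int], ...]  # (a, b, bundle_id)
    colour_groups: dict[str, tuple[str, ...]]
    region_geometry: dict[str, np.ndarray]  # node -> (n_voxels, 3) int coords
    grid_shape: tuple[int, int, int] = (64, 64, 3)

    @property
    def node_index(self) -> dict[str, int]:
        return {n: k for k, n in enumerate(self.nodes)}

    def edge_key(self, a: str, b: str) -> tuple[str, str]:
        """Canonical (a, b) ordered by node index."""
        ia, ib = self.node_index[a], self.node_index[b]
        return (a, b) if ia < ib else (b, a)

    @property
    def true_edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edge_key(a, b) for a, b, _ in self.ground_truth_edges)

    def group_of(self, node: str) -> str:
        for g, members in self.colour_groups.items():
            if node in members:
                return g
        raise KeyError(node)


@dataclass(frozen=True)
class BoldRecipe:
    """Block-design BOLD synthesis parameters.

    20 ON and 20 OFF blocks of 30 TRs each give 1200 time points.  Unit
    events occur independently at each TR with probability ``event_prob``.
    The per-region amplitude is scaled by a uniform draw from
    ``amp_scale_range`` to emulate structural variability, and Rician noise
    is added; ``rician_sigma=None`` derives sigma from ``target_snr``
    relative to the mean ON-block amplitude of the clean signal.  ``tr`` is
    in seconds (default 0.72, HCP-like).
    """

    n_on_blocks: int = 20
    n_off_blocks: int = 20
    block_len: int = 30
    event_prob: float = 0.2
    tr: float = 0.72
    amp_scale_range: tuple[float, float] = (0.8, 1.2)
    event_amplitude: float = 1.0
    rician_sigma: float | None = None
    target_snr: float = 20.0
    block_order: str = "shuffled"  # "shuffled" | "alternating"

    def __post_init__(self) -> None:
        if not 0.0 <= self.event_prob <= 1.0:
            raise ValueError("event_prob must lie in [0, 1]")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_timepoints(self) -> int:
        return (self.n_on_blocks + self.n_off_blocks) * self.block_len


@dataclass(frozen=True)
class TractogramEmulation:
    """Emulated streamline-count matrix with declared error sets."""

    method: str
    counts: pd.DataFrame  # node x node, symmetric, >= 0
    false_negatives: frozenset[tuple[str, str]]  # subset of true edges
    false_positives: frozenset[tuple[str, str]]  # disjoint from true edges


@dataclass(frozen=True)
class EnhancementResult:
    """Aggregated corrections and flows over repeated fMRI instances."""

    method: str
    n_instances: int
    edges: tuple[tuple[str, str], ...]
    mean_P: np.ndarray
    sd_P: np.ndarray
    mean_total_flow: np.ndarray
    per_instance_P: np.ndarray  # (n_instances, L)
    graph: RegionGraph
    seeds: tuple[int, ...]

    def summary(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.edges, names=["node_i", "node_j"])
        return pd.DataFrame(
            {"mean_P": self.mean_P, "sd_P": self.sd_P,
             "mean_total_flow": self.mean_total_flow},
            index=idx,
        )

    def edge_stat(self, stat: np.ndarray, a: str, b: str) -> float:
        key = {e: k for k, e in enumerate(self.edges)}
        if (a, b) in key:
            return float(stat[key[(a, b)]])
        return float(stat[key[(b, a)]])


def build_phantom(seed: int = 0) -> PhantomSpec:
    """Deterministic phantom fixture (seed only orients nothing: fixed layout).

    Region geometry places the 16 end points on a circle in a 64x64x3 grid,
    each region a 3x3x3 voxel block, mimicking the coronal-slab layout of the
    physical phantom.
    """
    geometry: dict[str, np.ndarray] = {}
    cx, cy, radius = 32.0, 32.0, 24.0
    for k, node in enumerate(_NODES):
        ang = 2.0 * np.pi * k / len(_NODES)
        x0 = int(round(cx + radius * np.cos(ang)))
        y0 = int(round(cy + radius * np.sin(ang)))
        vox = [(x0 + dx, y0 + dy, z)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for z in (0, 1, 2)]
        geometry[node] = np.array(vox, dtype=int)
    return PhantomSpec(
        nodes=_NODES,
        ground_truth_edges=_TRUE_EDGES,
        colour_groups=dict(_COLOUR_GROUPS),
        region_geometry=geometry,
    )


def block_design(recipe: BoldRecipe, network_id: int = 0, seed: int = 0,
                 attempt: int = 0) -> np.ndarray:
    """Activation time course: ON/OFF square wave plus random unit events.

    The 20 ON and 20 OFF blocks are arranged in a random order unique to
    ``network_id`` (default), so the five sub-networks' base time courses are
    close to mutually uncorrelated, as required for the functional networks
    to be separable; ``block_order="alternating"`` gives the classic
    OFF/ON/OFF/... design instead.  Independent Bernoulli(event_prob) events
    of ``event_amplitude`` are superposed at each TR from a stream unique to
    ``network_id``.  The ON fraction is exactly
    n_on_blocks / (n_on_blocks + n_off_blocks) in both arrangements.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(network_id, attempt)))
    n_blocks = recipe.n_on_blocks + recipe.n_off_blocks
    if recipe.block_order == "alternating":
        order = np.array([b % 2 for b in range(n_blocks)])  # OFF first
    elif recipe.block_order == "shuffled":
        order = rng.permutation(np.repeat([0, 1], [recipe.n_off_blocks,
                                                   recipe.n_on_blocks]))
    else:
        raise ValueError(f"unknown block_order {recipe.block_order!r}")
    tc = np.repeat(order.astype(float), recipe.block_len)
    events = rng.random(recipe.n_timepoints) < recipe.event_prob
    return tc + recipe.event_amplitude * events


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at TR spacing.

    Response peak at 6 s, undershoot peak at 16 s (unit dispersions),
    undershoot ratio 1/6; normalized to unit peak.
    """
    t = np.arange(0.0, duration, tr)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    peak = np.abs(h).max()
    return h / peak if peak > 0 else h


def hrf_convolve(tc: np.ndarray, tr: float) -> np.ndarray:
    """Linear convolution with the canonical HRF, truncated to input length."""
    if tr <= 0:
        raise ValueError("TR must be positive")
    tc = np.asarray(tc, dtype=float)
    return np.convolve(tc, canonical_hrf(tr), mode="full")[: tc.size]


def rician_noise(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((x + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2)."""
    if sigma == 0:
        return np.asarray(x, dtype=float).copy()
    n1 = rng.normal(0.0, sigma, size=np.shape(x))
    n2 = rng.normal(0.0, sigma, size=np.shape(x))
    return np.sqrt((x + n1) ** 2 + n2 ** 2)


def simulate_instance(phantom: PhantomSpec, recipe: BoldRecipe | None = None,
                      seed: int = 0, voxel_level: bool = False):
    """One synthetic fMRI realization at the region (default) or voxel level.

    Nodes in the same colour group share that group's base BOLD time course
    (block design convolved with the HRF); each region's amplitude is scaled
    by an independent U(amp_scale_range) draw and corrupted by Rician noise.
    Returns a regions x time DataFrame (plus a voxels x time DataFrame when
    ``voxel_level`` is requested).
    """
    recipe = recipe or BoldRecipe()
    groups = list(phantom.colour_groups)
    # draw each network's design so the base activity patterns stay nearly
    # mutually uncorrelated (independently designed task patterns); redraw a
    # network's block arrangement when it echoes an already-accepted one
    base = {}
    accepted: list[np.ndarray] = []
    for gid, group in enumerate(groups):
        best_bold, best_worst = None, np.inf
        for attempt in range(60):
            tc = block_design(recipe, network_id=gid, seed=seed, attempt=attempt)
            bold = hrf_convolve(tc, recipe.tr)
            if bold.std() == 0 or not accepted:
                best_bold = bold
                break
            # criterion on the convolved signal: that is what mixes at the
            # regions, and convolution inflates raw design correlations
            worst = max(abs(np.corrcoef(bold, prev)[0, 1]) for prev in accepted)
            if worst < best_worst:
                best_bold, best_worst = bold, worst
            if worst < 0.05:
                break
        accepted.append(best_bold)
        base[group] = best_bold
    if recipe.rician_sigma is not None:
        sigma = recipe.rician_sigma
    else:
        on = np.concatenate([b[np.abs(b) > 1e-12] for b in base.values()])
        mean_on_amp = float(np.abs(on).mean()) if on.size else 1.0
        sigma = mean_on_amp / recipe.target_snr
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1000,)))
    lo, hi = recipe.amp_scale_range
    data = np.empty((len(phantom.nodes), recipe.n_timepoints))
    for k, node in enumerate(phantom.nodes):
        scale = rng.uniform(lo, hi)
        data[k] = rician_noise(scale * base[phantom.group_of(node)], sigma, rng)
    region_ts = pd.DataFrame(data, index=list(phantom.nodes))
    if not voxel_level:
        return region_ts
    vox_rows, vox_index = [], []
    for node in phantom.nodes:
        clean = region_ts.loc[node].to_numpy()
        for v, coord in enumerate(phantom.region_geometry[node]):
            vox_rows.append(rician_noise(clean, sigma, rng))
            vox_index.append(f"{node}:{coord[0]}_{coord[1]}_{coord[2]}")
    return region_ts, pd.DataFrame(np.array(vox_rows), index=vox_index)


def emulate_tractography(phantom: PhantomSpec, method: str = "deterministic",
                         seed: int = 0) -> TractogramEmulation:
    """Streamline-count matrix with the method's characteristic error pattern.

    Deterministic: true links broken by crossings/bends appear at zero or
    near-zero counts and a small spurious set appears where streamlines jump
    tracks.  Probabilistic: every true link has a nonzero count but a wider
    spurious set appears.  Counts get multiplicative +-20% jitter.
    """
    if method not in ("deterministic", "probabilistic"):
        raise ValueError(f"unknown tractography method {method!r}")
    n = len(phantom.nodes)
    idx = phantom.node_index
    counts = np.zeros((n, n))
    true_edges = phantom.true_edge_set

    def put(a: str, b: str, value: float) -> None:
        counts[idx[a], idx[b]] = value
        counts[idx[b], idx[a]] = value

    if method == "deterministic":
        low = {phantom.edge_key(a, b) for a, b in DETERMINISTIC_LOW}
        missed = {phantom.edge_key(a, b) for a, b in DETERMINISTIC_MISSED}
        spurious = {phantom.edge_key(a, b) for a, b in DETERMINISTIC_SPURIOUS}
        for a, b in true_edges:
            if (a, b) in missed:
                put(a, b, 0.0)
            elif (a, b) in low:
                put(a, b, COUNT_LOW)
            else:
                put(a, b, COUNT_HIGH)
        for a, b in spurious:
            put(a, b, COUNT_SPURIOUS)
        fn = frozenset(missed | low)
    else:
        under = {phantom.edge_key(a, b)
                 for a, b in DETERMINISTIC_LOW + (("P15", "P16"),)}
        spurious = {phantom.edge_key(a, b) for a, b in PROBABILISTIC_SPURIOUS}
        for a, b in true_edges:
            put(a, b, COUNT_LOW if (a, b) in under else COUNT_HIGH)
        for a, b in spurious:
            put(a, b, COUNT_SPURIOUS)
        fn = frozenset(under)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2000,)))
    jitter = rng.uniform(1.0 - COUNT_JITTER, 1.0 + COUNT_JITTER, size=(n, n))
    jitter = np.triu(jitter, 1)
    jitter = jitter + jitter.T
    counts = counts * jitter
    frame = pd.DataFrame(counts, index=list(phantom.nodes),
                         columns=list(phantom.nodes))
    return TractogramEmulation(method=method, counts=frame,
                               false_negatives=fn,
                               false_positives=frozenset(spurious))


def source_separation(ts: pd.DataFrame, n_components: int, seed: int = 0,
                      max_iter: int = 1000) -> pd.DataFrame:
    """ICA source separation of a locations x time matrix into spatial maps.

    Independence is estimated over the time axis (each location's series is a
    mixture of the underlying network time courses), which is the
    well-conditioned direction when the location domain is a handful of
    regions; the spatial maps are the mixing-matrix columns, normalized to
    unit variance over locations.  Components carry the usual
    sign/permutation indeterminacy; resolve downstream with mode matching.
    """
    x = ts.to_numpy(dtype=float)
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds min(locations, time points)")
    ica = FastICA(n_components=n_components, random_state=seed,
                  max_iter=max_iter, whiten="unit-variance")
    ica.fit_transform(x.T)  # samples = time points, features = locations
    maps = ica.mixing_  # (locations, components): spatial patterns
    if not np.all(np.isfinite(maps)):
        raise RuntimeError("ICA decomposition failed (non-finite maps)")
    sd = maps.std(axis=0)
    sd[sd == 0] = 1.0
    maps = maps / sd
    return pd.DataFrame(maps, index=ts.index,
                        columns=[f"ic{k + 1}" for k in range(n_components)])


def reference_group_maps(phantom: PhantomSpec) -> pd.DataFrame:
    """Indicator spatial maps of the colour groups over the region domain."""
    data = {g: [1.0 if n in members else 0.0 for n in phantom.nodes]
            for g, members in phantom.colour_groups.items()}
    return pd.DataFrame(data, index=list(phantom.nodes))


def simulate_activation_matrix(phantom: PhantomSpec, recipe: BoldRecipe | None = None,
                               seed: int = 0, mask_seed: int | None = None):
    """Full functional pipeline for one instance: BOLD -> ICA -> R_i^m.

    Simulates region BOLD, separates 5 spatial components, matches them to
    the colour groups, averages map magnitudes per region and zeroes
    inactive regions with the 2-means mask.  Returns (ActivationMatrix with
    mode labels = matched colour groups, match table).
    """
    ts = simulate_instance(phantom, recipe, seed=seed)
    maps = source_separation(ts, n_components=len(phantom.colour_groups), seed=seed)
    match = match_modes(maps, reference_group_maps(phantom))
    # rename components to their matched group and order like colour_groups
    renamed = maps.rename(columns=match["reference"].to_dict())
    renamed = renamed[[g for g in phantom.colour_groups if g in renamed.columns]]
    R = region_activation(renamed)
    assert R.node_labels == tuple(phantom.nodes)
    R = kmeans_activity_mask(R, seed=mask_seed if mask_seed is not None else seed)
    return R, match


def run_enhancement_experiment(phantom: PhantomSpec, method: str = "deterministic",
                               n_instances: int = 100,
                               config: ModelConfig | None = None,
                               recipe: BoldRecipe | None = None,
                               seed: int = 0) -> EnhancementResult:
    """Repeat the functional pipeline + LP over many fMRI instances.

    The tractography emulation (hence the capacity graph) is fixed; each
    instance re-simulates the fMRI data, recomputes activations and solves
    the joint model.  Reports per-edge mean and SD of the correction P_l and
    the mean total (mode-summed) flow.
    """
    config = config or ModelConfig()
    recipe = recipe or BoldRecipe()
    emu = emulate_tractography(phantom, method, seed=seed)
    graph = canonicalize_graph(emu.counts, list(phantom.nodes), config)
    seeds = tuple(int(s) for s in
                  np.random.SeedSequence(seed).generate_state(n_instances) % (2 ** 31))
    P = np.zeros((n_instances, graph.n_edges))
    F = np.zeros((n_instances, graph.n_edges))
    for k, s in enumerate(seeds):
        try:
            R, _ = simulate_activation_matrix(phantom, recipe, seed=s)
            sol = solve_joint_model(graph, R, config)
        except Exception as exc:  # propagate with instance identity
            raise RuntimeError(f"enhancement experiment failed at instance {k}") from exc
        if not sol.is_optimal:
            raise RuntimeError(
                f"instance {k}: solver status {sol.solver_status}: {sol.message}")
        P[k] = sol.corrections
        F[k] = sol.flows.sum(axis=1)
    return EnhancementResult(
        method=method, n_instances=n_instances,
        edges=tuple(graph.edge_labels()),
        mean_P=P.mean(axis=0), sd_P=P.std(axis=0),
        mean_total_flow=F.mean(axis=0), per_instance_P=P,
        graph=graph, seeds=seeds,
    )
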