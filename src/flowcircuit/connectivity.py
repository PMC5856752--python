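"""Model inputs and comparison networks from fMRI-derived quantities.

Functional connectivity is the Pearson correlation between regional BOLD time
courses, averaged on the variance-stabilized Fisher-z scale when multiple
runs or realizations are combined.  Region activations R_i^m are the mean
magnitude of a mode's spatial map within each region, with regions classified
active/inactive per mode by 2-means and inactive regions zeroed.  Subject
modes are matched to reference spatial maps by optimal one-to-one assignment
on absolute spatial correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .flow_model import ActivationMatrix

__all__ = [
    "pearson_network",
    "fisher_average",
    "region_activation",
    "kmeans_activity_mask",
    "match_modes",
    "topk_and_consistency",
]

_ATANH_CLIP = 1.0 - 1e-7


def pearson_network(ts: np.ndarray | pd.DataFrame,
                    region_labels: list[str] | None = None) -> pd.DataFrame:
    """Region-by-region Pearson correlation network of BOLD time courses.

    ``ts`` is regions x time.  Constant rows are rejected by name, since their
    correlation is undefined.
    """
    if isinstance(ts, pd.DataFrame):
        if region_labels is None:
            region_labels = [str(i) for i in ts.index]
        x = ts.to_numpy(dtype=float)
    else:
        x = np.asarray(ts, dtype=float)
    n = x.shape[0]
    if region_labels is None:
        region_labels = [f"R{i + 1}" for i in range(n)]
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("time-series matrix must be regions x time with >= 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contain non-finite values")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = region_labels[int(np.argmax(sd == 0))]
        raise ValueError(f"region {bad} has a constant time course")
    r = np.corrcoef(x)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=region_labels, columns=region_labels)


def fisher_average(r_values) -> float:
    """Average correlations on the Fisher-z scale: tanh(mean(atanh(r))).

    Values are clipped to |r| <= 1 - 1e-7 so atanh stays finite.
    """
    r = np.asarray(list(r_values), dtype=float)
    if r.size == 0:
        raise ValueError("cannot Fisher-average an empty collection")
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_ATANH_CLIP, _ATANH_CLIP))
    return float(np.tanh(z.mean()))


def fisher_average_networks(networks: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise Fisher-z average of several correlation networks."""
    if not networks:
        raise ValueError("no networks to average")
    ref = networks[0]
    z = np.zeros_like(ref.to_numpy(dtype=float))
    for net in networks:
        z += np.arctanh(np.clip(net.to_numpy(dtype=float), -_ATANH_CLIP, _ATANH_CLIP))
    r = np.tanh(z / len(networks))
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ref.index, columns=ref.columns)


def region_activation(maps: pd.DataFrame, parcel_labels: dict | pd.Series | None = None,
                      magnitude: bool = True) -> ActivationMatrix:
    """Average spatial-map magnitude per region: R_i^m.

    ``maps`` is locations x modes (locations may be voxels or region labels);
    ``parcel_labels`` maps each location to its region.  When omitted, each
    location is its own region.  ``magnitude=True`` (default) averages
    absolute map values, since ICA maps are signed; ``magnitude=False``
    averages raw values instead.
    """
    if parcel_labels is None:
        parcel = pd.Series(maps.index, index=maps.index)
    elif isinstance(parcel_labels, dict):
        parcel = pd.Series(parcel_labels)
    else:
        parcel = parcel_labels
    missing = [loc for loc in parcel.index if loc not in maps.index]
    if missing:
        raise KeyError(f"locations {missing[:5]} labeled but absent from maps")
    # restrict to the parcellation mask before averaging
    masked = maps.loc[parcel.index]
    vals = masked.abs() if magnitude else masked
    # sort=False keeps regions in first-appearance order, matching the graph
    grouped = vals.groupby(parcel, sort=False).mean()
    counts = parcel.value_counts()
    empty = [r for r in grouped.index if counts.get(r, 0) == 0]
    if empty:
        raise ValueError(f"regions with zero locations: {empty}")
    return ActivationMatrix(
        values=grouped.to_numpy(dtype=float),
        mode_labels=tuple(str(c) for c in maps.columns),
        node_labels=tuple(str(i) for i in grouped.index),
    )


def kmeans_activity_mask(R: ActivationMatrix, seed: int = 0,
                         n_init: int = 10) -> ActivationMatrix:
    """Zero out inactive regions per mode via 2-means on that mode's values.

    The cluster with the smaller centroid is inactive.  If all values of a
    mode are equal, every region is kept active (zeroing all would silently
    drop the mode).  Never increases any value; idempotent.
    """
    vals = R.values.copy()
    for m in range(R.n_modes):
        col = vals[:, m]
        if np.allclose(col, col[0]):
            continue
        km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
        assign = km.fit_predict(col.reshape(-1, 1))
        low = int(np.argmin(km.cluster_centers_.ravel()))
        col[assign == low] = 0.0
    return ActivationMatrix(vals, R.mode_labels, R.node_labels)


def match_modes(subject_maps: pd.DataFrame, reference_maps: pd.DataFrame
                ) -> pd.DataFrame:
    """One-to-one assignment of subject modes to reference maps.

    Maximizes total absolute spatial correlation over the common location
    domain (optimal assignment, not greedy); the sign of each match is
    recorded so that sign-indeterminate ICA maps can be re-oriented.
    Returns a frame indexed by subject mode with columns
    ``reference``, ``correlation`` (signed) and ``sign``.
    """
    common = subject_maps.index.intersection(reference_maps.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common locations to correlate maps")
    s = subject_maps.loc[common].to_numpy(dtype=float)
    t = reference_maps.loc[common].to_numpy(dtype=float)
    ns, nt = s.shape[1], t.shape[1]
    if ns < nt:
        warnings.warn(
            f"only {ns} subject modes for {nt} references: partial assignment",
            stacklevel=2,
        )
    corr = np.zeros((ns, nt))
    for a in range(ns):
        for b in range(nt):
            corr[a, b] = np.corrcoef(s[:, a], t[:, b])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    out = pd.DataFrame(
        {
            "reference": [reference_maps.columns[b] for b in cols],
            "correlation": [corr[a, b] for a, b in zip(rows, cols)],
            "sign": [1 if corr[a, b] >= 0 else -1 for a, b in zip(rows, cols)],
        },
        index=[subject_maps.columns[a] for a in rows],
    )
    out.index.name = "subject_mode"
    return out


def topk_and_consistency(networks: list[pd.DataFrame], k: int) -> pd.Series:
    """Cross-subject frequency of each edge among per-subject top-k edges.

    Each network is a symmetric node-by-node weight table over an identical
    node set.  Per subject, the k largest-weight edges are selected (ties
    broken by canonical (i, j) lexicographic edge order); the result maps each
    edge to its identification frequency in [0, 1].
    """
    if not networks:
        raise ValueError("no subject networks given")
    nodes = list(networks[0].index)
    edges = [(nodes[i], nodes[j]) for i in range(len(nodes)) for j in range(i + 1, len(nodes))]
    if k > len(edges):
        raise ValueError(f"k={k} exceeds edge count L={len(edges)}")
    counts = pd.Series(0.0, index=pd.MultiIndex.from_tuples(edges, names=["node_i", "node_j"]))
    for net in networks:
        if list(net.index) != nodes:
            raise ValueError("subject networks have differing node sets or order")
        w = net.to_numpy(dtype=float)
        weights = np.array([w[nodes.index(a), nodes.index(b)] for a, b in edges])
        # stable sort on -weight keeps canonical edge order among ties
        top = np.argsort(-weights, kind="stable")[:k]
        for t in top:
            counts.iloc[t] += 1.0
    return counts / len(networks)
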