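"""Discriminative-feature selection for cue-reactivity decoding.

Two-condition trial ensembles are compared point-by-point (channels x time)
in the time-amplitude domain and in Morlet band-power domains.  Point-wise
two-sample t statistics get permutation p-values; supra-threshold points are
merged into spatio-temporal clusters whose summed statistic ("mass") is
tested against the permutation null of the maximum cluster mass, giving
family-wise error control.  Retained clusters become the per-trial feature
vector of the decoder.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage, signal, sparse
from scipy.sparse import csgraph

from .io import EpochSet
from .montage import chain_adjacency, montage_adjacency

__all__ = [
    "BandSet",
    "DEFAULT_BANDS",
    "BandPower",
    "StatMap",
    "Cluster",
    "ClusterFeatureSet",
    "band_power",
    "pointwise_permutation",
    "cluster_mass",
    "find_clusters",
    "select_features",
    "assemble_features",
    "assemble_window_features",
]

#: Frequency bands used for power features (Hz, inclusive edges).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 13.0),
    "low_beta": (14.0, 20.0),
    "high_beta": (21.0, 30.0),
    "low_gamma": (31.0, 48.0),
    "high_gamma": (52.0, 80.0),
}

BAND_DECIM = 5  # time decimation of power maps
MORLET_CYCLES = 7.0


@dataclass(frozen=True)
class BandSet:
    """Named, non-overlapping frequency bands."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: low edge must be below high edge")
        edges = sorted(self.bands.values())
        for (_a_lo, a_hi), (b_lo, _b_hi) in zip(edges, edges[1:]):
            if b_lo < a_hi:
                raise ValueError("bands must not overlap")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class BandPower:
    """Per-trial band power: trials x channels x bands x decimated time."""

    data: np.ndarray
    times_ms: np.ndarray
    band_names: list[str]
    channel_labels: list[str]

    def band(self, name: str) -> np.ndarray:
        return self.data[:, :, self.band_names.index(name), :]


def _morlet_kernel(freq: float, fs: float, n_cycles: float = MORLET_CYCLES) -> np.ndarray:
    sd = n_cycles / (2.0 * math.pi * freq)
    half = int(round(3.5 * sd * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * math.pi * freq * t) * np.exp(-(t**2) / (2.0 * sd**2))
    return w / np.abs(w).sum()


def band_power(
    epochs: EpochSet | np.ndarray,
    bands: BandSet | None = None,
    sampling_rate: float | None = None,
    times_ms: np.ndarray | None = None,
    decim: int = BAND_DECIM,
    n_cycles: float = MORLET_CYCLES,
) -> BandPower:
    """Morlet-wavelet band power of each trial, time-decimated.

    Power in a band is the mean squared wavelet amplitude over five
    frequencies spanning the band.  Accepts an :class:`EpochSet` or a raw
    (trials x channels x time) array with ``sampling_rate`` given.
    """
    bands = bands or BandSet()
    if isinstance(epochs, EpochSet):
        data = epochs.data
        fs = epochs.sampling_rate
        tms = epochs.times_ms
        labels = list(epochs.channel_labels)
    else:
        data = np.asarray(epochs, dtype=np.float64)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for array input")
        fs = float(sampling_rate)
        tms = (
            np.asarray(times_ms, dtype=float)
            if times_ms is not None
            else np.arange(data.shape[-1]) / fs * 1000.0
        )
        labels = [f"ch{i}" for i in range(data.shape[1])]
    nyq = fs / 2.0
    for name, (lo, hi) in bands.bands.items():
        if hi >= nyq:
            raise ValueError(f"band {name!r} upper edge {hi} Hz is at/above Nyquist")
        if data.shape[-1] / fs < 1.0 / lo:
            raise ValueError(f"epoch too short for one cycle of band {name!r}")

    out = np.empty(
        (data.shape[0], data.shape[1], len(bands.bands), len(tms[::decim])),
        dtype=np.float64,
    )
    for bi, (name, (lo, hi)) in enumerate(bands.bands.items()):
        freqs = np.linspace(lo, hi, 5)
        acc = np.zeros(data.shape, dtype=np.float64)
        for f in freqs:
            kern = _morlet_kernel(f, fs, n_cycles)[None, None, :]
            conv = signal.fftconvolve(data, kern, mode="same", axes=-1)
            acc += np.abs(conv) ** 2
        out[:, :, bi, :] = (acc / len(freqs))[:, :, ::decim]
    return BandPower(
        data=out,
        times_ms=np.asarray(tms[::decim], dtype=float),
        band_names=bands.names(),
        channel_labels=labels,
    )


# --------------------------------------------------------------------------
# Point-wise permutation statistics
# --------------------------------------------------------------------------


@dataclass
class StatMap:
    """Point-wise statistic map with its permutation null distribution."""

    domain: str
    tvals: np.ndarray  # channels x time
    p: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    channel_labels: list[str]
    times_ms: np.ndarray
    perm_t: np.ndarray  # n_perm x channels x time (float32)
    exact: bool


def _t_stats(group1_sel: np.ndarray, X: np.ndarray, X2: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Pooled-variance two-sample t for many label assignments at once.

    ``group1_sel`` is (n_assign, n_trials) float (1.0 where trial is in
    group 1); ``X``/``X2`` are (n_trials, n_points) data and squared data.
    Zero-variance points yield t = 0.
    """
    tot = X.sum(axis=0)
    tot2 = X2.sum(axis=0)
    s1 = group1_sel @ X
    s1sq = group1_sel @ X2
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    ss1 = s1sq - n1 * m1**2
    ss2 = (tot2 - s1sq) - n2 * m2**2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def pointwise_permutation(
    group1: np.ndarray,
    group2: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    domain: str = "amplitude",
    channel_labels: list[str] | None = None,
    times_ms: np.ndarray | None = None,
) -> StatMap:
    """Two-sample t map with label-permutation p-values.

    When the number of distinct label splits is at most ``n_perm`` the null
    is enumerated exhaustively; otherwise the identity assignment plus
    ``n_perm - 1`` random label permutations form the null.  Either way the
    observed split is one member of the null set and
    ``p = #{splits with |t| >= |t_obs|} / #splits`` (two-tailed);
    ``sig_mask = p < alpha``.
    """
    g1 = np.asarray(group1, dtype=np.float64)
    g2 = np.asarray(group2, dtype=np.float64)
    if g1.ndim != 3 or g2.ndim != 3 or g1.shape[1:] != g2.shape[1:]:
        raise ValueError("groups must be (trials x channels x time) with equal maps")
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per condition")
    n = n1 + n2
    n_ch, n_t = g1.shape[1:]
    X = np.concatenate([g1, g2]).reshape(n, -1)
    X2 = X**2

    n_comb = math.comb(n, n1)
    exact = n_comb <= n_perm
    if exact:
        sel = np.zeros((n_comb, n), dtype=np.float64)
        for j, idx in enumerate(combinations(range(n), n1)):
            sel[j, list(idx)] = 1.0
    else:
        rng = np.random.default_rng(seed)
        sel = np.zeros((n_perm, n), dtype=np.float64)
        sel[0, :n1] = 1.0  # identity split is always part of the null
        for j in range(1, n_perm):
            sel[j, rng.permutation(n)[:n1]] = 1.0

    obs_sel = np.zeros((1, n))
    obs_sel[0, :n1] = 1.0
    t_obs = _t_stats(obs_sel, X, X2, n1, n2)[0]

    perm_t = np.empty((sel.shape[0], X.shape[1]), dtype=np.float32)
    for lo in range(0, sel.shape[0], 256):
        perm_t[lo : lo + 256] = _t_stats(sel[lo : lo + 256], X, X2, n1, n2)
    abs_obs = np.abs(t_obs).astype(np.float32)
    count = (np.abs(perm_t) >= abs_obs[None, :]).sum(axis=0)
    p = count / sel.shape[0]
    sig = p < alpha

    return StatMap(
        domain=domain,
        tvals=t_obs.reshape(n_ch, n_t),
        p=p.reshape(n_ch, n_t),
        sig_mask=sig.reshape(n_ch, n_t),
        alpha=alpha,
        channel_labels=channel_labels or [f"ch{i}" for i in range(n_ch)],
        times_ms=np.asarray(times_ms, dtype=float)
        if times_ms is not None
        else np.arange(n_t, dtype=float),
        perm_t=perm_t.reshape(-1, n_ch, n_t),
        exact=exact,
    )


# --------------------------------------------------------------------------
# Cluster decomposition and mass correction
# --------------------------------------------------------------------------


@dataclass
class Cluster:
    """One signed spatio-temporal cluster of discriminative points."""

    domain: str
    sign: int  # +1: condition1 > condition2
    members: list[tuple[str, float]]  # (channel label, time ms)
    member_idx: np.ndarray  # (k, 2) channel/time indices in the source map
    mass: float
    corrected_p: float


@dataclass
class ClusterFeatureSet:
    """Retained clusters across all tested domains."""

    clusters: list[Cluster]
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.clusters)

    def domains(self) -> list[str]:
        return sorted({c.domain for c in self.clusters})

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "clusters": [
                {
                    "domain": c.domain,
                    "sign": c.sign,
                    "mass": c.mass,
                    "corrected_p": c.corrected_p,
                    "members": [[lab, ms] for lab, ms in c.members],
                }
                for c in self.clusters
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ClusterFeatureSet":
        try:
            payload = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        clusters = [
            Cluster(
                domain=c["domain"],
                sign=int(c["sign"]),
                members=[(str(l), float(m)) for l, m in c["members"]],
                member_idx=np.empty((0, 2), dtype=int),
                mass=float(c["mass"]),
                corrected_p=float(c["corrected_p"]),
            )
            for c in payload["clusters"]
        ]
        return cls(clusters=clusters, alpha=float(payload["alpha"]))


_GRAPH_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _point_graph(n_ch: int, n_t: int, adjacency: np.ndarray | None) -> sparse.csr_matrix:
    key = (n_ch, n_t, adjacency.tobytes() if adjacency is not None else None)
    if key in _GRAPH_CACHE:
        return _GRAPH_CACHE[key]
    rows, cols = [], []
    # time neighbours within a channel
    p = np.arange(n_ch * n_t).reshape(n_ch, n_t)
    rows.append(p[:, :-1].ravel())
    cols.append(p[:, 1:].ravel())
    if adjacency is not None:
        a, b = np.nonzero(np.triu(adjacency, 1))
        for i, j in zip(a, b):
            rows.append(p[i])
            cols.append(p[j])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    g = sparse.csr_matrix(
        (np.ones(len(r), dtype=np.int8), (r, c)), shape=(n_ch * n_t,) * 2
    )
    g = g + g.T
    if len(_GRAPH_CACHE) > 32:
        _GRAPH_CACHE.clear()
    _GRAPH_CACHE[key] = g
    return g


def find_clusters(
    tvals: np.ndarray, mask: np.ndarray, adjacency: np.ndarray | None
) -> list[tuple[np.ndarray, float, int]]:
    """Signed connected components of ``mask`` under the point graph.

    Points are adjacent along time within a channel and across channels (at
    the same time sample) when ``adjacency`` marks the channel pair as
    neighbours.  Positive- and negative-statistic points never merge.
    Returns ``(member_idx, mass, sign)`` triples, ``member_idx`` being (k, 2)
    channel/time index pairs.
    """
    n_ch, n_t = tvals.shape
    graph = _point_graph(n_ch, n_t, adjacency)
    out: list[tuple[np.ndarray, float, int]] = []
    for sign in (1, -1):
        m = mask & ((tvals > 0) if sign > 0 else (tvals < 0))
        flat = m.ravel()
        idx = np.flatnonzero(flat)
        if idx.size == 0:
            continue
        sub = graph[idx][:, idx]
        n_comp, labels = csgraph.connected_components(sub, directed=False)
        tflat = tvals.ravel()[idx]
        for comp in range(n_comp):
            members = idx[labels == comp]
            mass = float(tflat[labels == comp].sum())
            pairs = np.stack([members // n_t, members % n_t], axis=1)
            out.append((pairs, mass, sign))
    return out


def _perm_masks(perm_t: np.ndarray, alpha: float, exact: bool) -> np.ndarray:
    """Point-wise significance mask of every permutation against the null."""
    n_perm, n_ch, n_t = perm_t.shape
    a = np.abs(perm_t).reshape(n_perm, -1)
    order = np.argsort(a, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_perm)[:, None], axis=0)
    count_ge = n_perm - ranks  # ordinal ranks; ties broken arbitrarily
    p = count_ge / n_perm
    return (p < alpha).reshape(n_perm, n_ch, n_t)


def _is_chain(adjacency: np.ndarray | None, n: int) -> bool:
    if adjacency is None:
        return False
    from .montage import chain_adjacency as _chain

    return adjacency.shape == (n, n) and bool((adjacency == _chain(n)).all())


def _null_max_grid(perm_t: np.ndarray, masks: np.ndarray, chain: bool) -> np.ndarray:
    """Max |cluster mass| per permutation, vectorized over all permutations.

    Valid when the channel graph is a chain (grid connectivity) or absent
    (time-only): label the whole (perm, channel, time) stack at once with a
    structure that never connects across the permutation axis.
    """
    n_perm = perm_t.shape[0]
    plane = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if chain
        else np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])
    )
    structure = np.stack([np.zeros_like(plane), plane, np.zeros_like(plane)])
    null_max = np.zeros(n_perm)
    perm_idx = np.broadcast_to(
        np.arange(n_perm)[:, None, None], perm_t.shape
    )
    for sign in (1, -1):
        m = masks & ((perm_t > 0) if sign > 0 else (perm_t < 0))
        labels, n_comp = ndimage.label(m, structure=structure)
        if n_comp == 0:
            continue
        idx = np.arange(1, n_comp + 1)
        masses = np.abs(ndimage.sum_labels(perm_t, labels, idx))
        owners = ndimage.maximum(perm_idx, labels, idx).astype(int)
        np.maximum.at(null_max, owners, masses)
    return null_max


def cluster_mass(
    statmap: StatMap,
    adjacency: np.ndarray | None,
    alpha: float = 0.05,
    keep: str = "significant",
) -> ClusterFeatureSet:
    """Cluster-mass multiple-comparison correction of a permutation StatMap.

    Observed supra-threshold points are decomposed into signed clusters; each
    cluster's |mass| is compared with the null distribution of the maximum
    cluster |mass| over the permutations already stored in ``statmap``.
    ``keep='significant'`` returns clusters with corrected p below ``alpha``;
    ``keep='all'`` returns every observed cluster.
    """
    observed = find_clusters(statmap.tvals, statmap.sig_mask, adjacency)
    n_perm = statmap.perm_t.shape[0]
    masks = _perm_masks(statmap.perm_t, statmap.alpha, statmap.exact)
    n_ch = statmap.tvals.shape[0]
    if adjacency is None or _is_chain(adjacency, n_ch):
        perm_t64 = statmap.perm_t.astype(np.float64)
        null_max = _null_max_grid(perm_t64, masks, chain=adjacency is not None)
    else:
        null_max = np.zeros(n_perm)
        for j in range(n_perm):
            comps = find_clusters(
                statmap.perm_t[j].astype(np.float64), masks[j], adjacency
            )
            if comps:
                null_max[j] = max(abs(m) for _, m, _ in comps)

    clusters: list[Cluster] = []
    for pairs, mass, sign in observed:
        # the identity split is one member of the null, so cp >= 1 / n_perm
        cp = float((null_max >= abs(mass)).sum()) / n_perm
        if keep == "significant" and not cp < alpha:
            continue
        members = [
            (statmap.channel_labels[c], float(statmap.times_ms[t])) for c, t in pairs
        ]
        clusters.append(
            Cluster(
                domain=statmap.domain,
                sign=sign,
                members=members,
                member_idx=pairs,
                mass=mass,
                corrected_p=cp,
            )
        )
    return ClusterFeatureSet(clusters=clusters, alpha=alpha)


# --------------------------------------------------------------------------
# End-to-end selection and feature assembly
# --------------------------------------------------------------------------


def select_features(
    epochs: EpochSet,
    conditions: tuple[str, str] = ("smoking", "neutral"),
    domains: tuple[str, ...] = ("amplitude",) + tuple(DEFAULT_BANDS),
    bands: BandSet | None = None,
    adjacency: np.ndarray | None | str = "montage",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterFeatureSet:
    """Run permutation + cluster-mass selection over the requested domains.

    ``domains`` may contain ``"amplitude"`` and/or band names.  The first
    condition in ``conditions`` is the positive (cluster sign +1) class.
    """
    bands = bands or BandSet()
    kept = epochs.kept_only()
    m1 = kept.labels == conditions[0]
    m2 = kept.labels == conditions[1]
    if adjacency == "montage":
        adjacency = montage_adjacency(kept.channel_labels)
    elif adjacency == "chain":
        adjacency = chain_adjacency(len(kept.channel_labels))

    band_domains = [d for d in domains if d != "amplitude"]
    bp = None
    if band_domains:
        bp = band_power(kept, BandSet({b: bands[b] for b in band_domains}))

    all_clusters: list[Cluster] = []
    for di, dom in enumerate(domains):
        if dom == "amplitude":
            data = kept.data
            tms = kept.times_ms
        else:
            data = bp.band(dom)
            tms = bp.times_ms
        sm = pointwise_permutation(
            data[m1],
            data[m2],
            n_perm=n_perm,
            alpha=alpha,
            seed=None if seed is None else seed + di,
            domain=dom if dom == "amplitude" else f"band:{dom}",
            channel_labels=list(kept.channel_labels),
            times_ms=tms,
        )
        cfs = cluster_mass(sm, adjacency, alpha=alpha)
        all_clusters.extend(cfs.clusters)
    return ClusterFeatureSet(clusters=all_clusters, alpha=alpha)


def _band_names_needed(clusters: ClusterFeatureSet) -> list[str]:
    return sorted(
        {c.domain.split(":", 1)[1] for c in clusters.clusters if c.domain != "amplitude"}
    )


def assemble_features(
    epochs: EpochSet,
    clusters: ClusterFeatureSet,
    bands: BandSet | None = None,
) -> np.ndarray:
    """Per-trial feature vector: one value per cluster (mean over members)."""
    if not clusters.clusters:
        raise ValueError("no discriminative features - cannot build decoder")
    bands = bands or BandSet()
    ch_index = {l: i for i, l in enumerate(epochs.channel_labels)}
    t_index = {round(float(m), 3): i for i, m in enumerate(epochs.times_ms)}

    needed = _band_names_needed(clusters)
    bp = None
    bp_t_index: dict[float, int] = {}
    if needed:
        bp = band_power(epochs, BandSet({b: bands[b] for b in needed}))
        bp_t_index = {round(float(m), 3): i for i, m in enumerate(bp.times_ms)}

    feats = np.empty((epochs.n_trials, len(clusters.clusters)), dtype=np.float64)
    for k, c in enumerate(clusters.clusters):
        if c.domain == "amplitude":
            ci = [ch_index[l] for l, _ in c.members]
            ti = [t_index[round(m, 3)] for _, m in c.members]
            feats[:, k] = epochs.data[:, ci, ti].mean(axis=1)
        else:
            bname = c.domain.split(":", 1)[1]
            bi = bp.band_names.index(bname)
            ci = [ch_index[l] for l, _ in c.members]
            ti = [bp_t_index[round(m, 3)] for _, m in c.members]
            feats[:, k] = bp.data[:, ci, bi, ti].mean(axis=1)
    return feats


def assemble_window_features(
    window: np.ndarray,
    sampling_rate: float,
    channel_labels: list[str],
    clusters: ClusterFeatureSet,
    bands: BandSet | None = None,
) -> np.ndarray:
    """Feature vector for one 1-s online window.

    The window is treated as the 0-1000 ms post-stimulus period and
    mean-centred per channel; cluster members with negative (pre-stimulus)
    times are dropped.  A cluster left with no in-window member contributes
    0.
    """
    if not clusters.clusters:
        raise ValueError("no discriminative features - cannot build decoder")
    bands = bands or BandSet()
    w = np.asarray(window, dtype=np.float64)
    w = w - w.mean(axis=1, keepdims=True)
    ch_index = {l: i for i, l in enumerate(channel_labels)}
    fs = sampling_rate

    needed = _band_names_needed(clusters)
    bp = None
    if needed:
        bp = band_power(
            w[None], BandSet({b: bands[b] for b in needed}), sampling_rate=fs
        )

    out = np.zeros(len(clusters.clusters), dtype=np.float64)
    for k, c in enumerate(clusters.clusters):
        vals = []
        for lab, ms in c.members:
            if ms < 0 or lab not in ch_index:
                continue
            ci = ch_index[lab]
            if c.domain == "amplitude":
                si = int(round(ms * fs / 1000.0))
                if si < w.shape[1]:
                    vals.append(w[ci, si])
            else:
                bi = bp.band_names.index(c.domain.split(":", 1)[1])
                # decimated grid: sample ms 0, 20, 40, ... for 250 Hz, decim 5
                step = BAND_DECIM * 1000.0 / fs
                ti = int(round(ms / step))
                if 0 <= ti < bp.data.shape[-1]:
                    vals.append(bp.data[0, ci, bi, ti])
        if vals:
            out[k] = float(np.mean(vals))
    return out
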