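"""Binding-site occupancy and permeation cooperativity via state-specific
information (SSI).

Each binding site yields a per-frame occupancy series (ion id, or -1 when
vacant) on a 20-ps grid. Consecutive frames are classified into discrete
transition symbols, and the coupling between two sites is the plug-in
mutual information (in bits) between their transition streams. A shuffle
null — circular shifts that destroy cross-correlation while preserving
each stream's marginals and autocorrelation — gives a statistical noise
threshold; the excess above it (exSSI) is the reported cooperativity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .trajectory import IonTracks

VACANT = -1

#: Transition alphabet for consecutive occupancy frames.
STAY_OCCUPIED = 0
STAY_VACANT = 1
BIND = 2
RELEASE = 3
EXCHANGE = 4

SYMBOL_NAMES = {
    STAY_OCCUPIED: "stay-occupied",
    STAY_VACANT: "stay-vacant",
    BIND: "bind",
    RELEASE: "release",
    EXCHANGE: "exchange",
}


@dataclass
class BindingSiteDef:
    """Axial interval (and optional radial cutoff) defining a binding site."""

    label: str
    z_low: float
    z_high: float
    radial_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.z_low < self.z_high:
            raise ValueError(f"site {self.label}: z_low must be < z_high")

    @property
    def z_center(self) -> float:
        return 0.5 * (self.z_low + self.z_high)


@dataclass
class OccupancySeries:
    """Per-frame occupant id of one binding site; -1 encodes vacancy."""

    ids: np.ndarray
    dt_ps: float = 20.0
    site_label: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")
        if self.ids.size and self.ids.min() < VACANT:
            raise ValueError("occupant ids must be >= 0 or the vacancy sentinel -1")

    @property
    def n_frames(self) -> int:
        return self.ids.size


@dataclass
class SSIResult:
    """SSI decomposition for one pair of sites (all values in bits)."""

    ssi: float
    noise_threshold: float
    exssi: float
    n_frames: int
    n_shuffles: int
    seed: Optional[int] = None
    per_replica: list = field(default_factory=list)
    mean_exssi: Optional[float] = None
    se_exssi: Optional[float] = None


def build_occupancy(
    tracks: IonTracks, site: BindingSiteDef, dt_ps: float = 20.0
) -> OccupancySeries:
    """Occupancy series of one site from ion tracks.

    Frames are taken from the track grid at the stride nearest to
    ``dt_ps``. When several ions sit inside the site in a frame, the one
    nearest the site's z-center is recorded (tie broken by lower ion id).
    """
    z_lo, z_hi = site.z_low, site.z_high
    zmin, zmax = np.nanmin(tracks.z), np.nanmax(tracks.z)
    if z_hi < zmin or z_lo > zmax:
        raise ValueError(
            f"site {site.label} [{z_lo}, {z_hi}] lies outside the data range "
            f"[{zmin:.1f}, {zmax:.1f}]"
        )
    dt_track_ps = tracks.dt_ns * 1000.0
    stride = max(int(round(dt_ps / dt_track_ps)), 1)
    frames = np.arange(0, tracks.n_frames, stride)
    z = tracks.z[frames]
    inside = (z >= z_lo) & (z <= z_hi)
    if site.radial_cutoff is not None and tracks.has_xy():
        r2 = tracks.x[frames] ** 2 + tracks.y[frames] ** 2
        inside &= r2 <= site.radial_cutoff**2
    dist = np.abs(z - site.z_center)
    dist[~inside] = np.inf
    best = np.argmin(dist, axis=1)
    ids = np.where(np.isfinite(dist[np.arange(len(frames)), best]),
                   tracks.ion_ids[best], VACANT)
    return OccupancySeries(ids=ids, dt_ps=stride * dt_track_ps, site_label=site.label)


def transition_stream(series: OccupancySeries) -> np.ndarray:
    """Classify each consecutive frame pair into a transition symbol.

    Symbols: stay-occupied, stay-vacant, bind (-1 -> id), release
    (id -> -1), exchange (idA -> idB).
    """
    ids = series.ids if isinstance(series, OccupancySeries) else np.asarray(series)
    if ids.size < 2:
        raise ValueError("need at least 2 frames for a transition stream")
    a, b = ids[:-1], ids[1:]
    out = np.empty(ids.size - 1, dtype=np.int8)
    out[(a == VACANT) & (b == VACANT)] = STAY_VACANT
    out[(a != VACANT) & (b == a)] = STAY_OCCUPIED
    out[(a == VACANT) & (b != VACANT)] = BIND
    out[(a != VACANT) & (b == VACANT)] = RELEASE
    out[(a != VACANT) & (b != VACANT) & (a != b)] = EXCHANGE
    return out


def stream_entropy_bits(stream: np.ndarray) -> float:
    """Plug-in Shannon entropy of a symbol stream, in bits."""
    _, counts = np.unique(stream, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def ssi_bits(stream_a: np.ndarray, stream_b: np.ndarray) -> float:
    """Plug-in mutual information I(A;B) between two symbol streams, bits.

    I = sum_{a,b} p(a,b) log2 p(a,b) / (p(a) p(b)); symmetric and >= 0.
    """
    stream_a = np.asarray(stream_a)
    stream_b = np.asarray(stream_b)
    if stream_a.shape != stream_b.shape:
        raise ValueError(
            f"stream length mismatch: {stream_a.shape} vs {stream_b.shape}"
        )
    n = stream_a.size
    if n == 0:
        raise ValueError("empty streams")
    # joint histogram over the observed alphabets
    a_vals, a_inv = np.unique(stream_a, return_inverse=True)
    b_vals, b_inv = np.unique(stream_b, return_inverse=True)
    joint = np.zeros((a_vals.size, b_vals.size))
    np.add.at(joint, (a_inv, b_inv), 1.0)
    p_ab = joint / n
    p_a = p_ab.sum(axis=1, keepdims=True)
    p_b = p_ab.sum(axis=0, keepdims=True)
    nz = p_ab > 0
    mi = float(np.sum(p_ab[nz] * np.log2(p_ab[nz] / (p_a @ p_b)[nz])))
    return max(mi, 0.0)


def noise_threshold(
    stream_a: np.ndarray,
    stream_b: np.ndarray,
    n_shuffles: int = 100,
    quantile: float = 0.95,
    seed: Optional[int] = None,
) -> float:
    """Shuffle-null noise level for the SSI between two streams.

    One stream is circularly shifted by random offsets (>= 1 frame),
    destroying cross-correlation but preserving each stream's marginal
    distribution and autocorrelation; the given quantile of the null SSI
    distribution is returned. Zero-entropy streams have threshold 0.
    """
    if n_shuffles < 10:
        raise ValueError("need at least 10 shuffles")
    stream_a = np.asarray(stream_a)
    stream_b = np.asarray(stream_b)
    if stream_entropy_bits(stream_a) == 0.0 or stream_entropy_bits(stream_b) == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    n = stream_b.size
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shift = int(rng.integers(1, n))
        null[i] = ssi_bits(stream_a, np.roll(stream_b, shift))
    return float(np.quantile(null, quantile))


def excess_ssi_from_streams(
    stream_a: np.ndarray,
    stream_b: np.ndarray,
    n_shuffles: int = 100,
    quantile: float = 0.95,
    seed: Optional[int] = None,
) -> SSIResult:
    ssi = ssi_bits(stream_a, stream_b)
    thr = noise_threshold(stream_a, stream_b, n_shuffles=n_shuffles,
                          quantile=quantile, seed=seed)
    return SSIResult(
        ssi=ssi,
        noise_threshold=thr,
        exssi=max(ssi - thr, 0.0),
        n_frames=stream_a.size + 1,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def excess_ssi(
    tracks_or_replicas,
    site_a: BindingSiteDef,
    site_b: BindingSiteDef,
    dt_ps: float = 20.0,
    n_shuffles: int = 100,
    quantile: float = 0.95,
    seed: Optional[int] = None,
) -> SSIResult:
    """Full pipeline: occupancy -> transitions -> SSI minus noise threshold.

    Accepts a single :class:`IonTracks` or a sequence of replicas; with
    several replicas the per-replica exSSI values are aggregated into a
    mean +/- SE (SE is undefined, and left None, for a single replica).
    """
    if isinstance(tracks_or_replicas, IonTracks):
        replicas = [tracks_or_replicas]
    else:
        replicas = list(tracks_or_replicas)
    results = []
    for i, tr in enumerate(replicas):
        occ_a = build_occupancy(tr, site_a, dt_ps=dt_ps)
        occ_b = build_occupancy(tr, site_b, dt_ps=dt_ps)
        sa = transition_stream(occ_a)
        sb = transition_stream(occ_b)
        rep_seed = None if seed is None else seed + i
        results.append(
            excess_ssi_from_streams(sa, sb, n_shuffles=n_shuffles,
                                    quantile=quantile, seed=rep_seed)
        )
    ex = np.array([r.exssi for r in results])
    pooled = results[0]
    pooled.per_replica = results if len(results) > 1 else []
    pooled.mean_exssi = float(ex.mean())
    pooled.se_exssi = (
        float(ex.std(ddof=1) / np.sqrt(len(ex))) if len(ex) > 1 else None
    )
    if len(results) > 1:
        pooled = SSIResult(
            ssi=float(np.mean([r.ssi for r in results])),
            noise_threshold=float(np.mean([r.noise_threshold for r in results])),
            exssi=float(ex.mean()),
            n_frames=int(sum(r.n_frames for r in results)),
            n_shuffles=n_shuffles,
            seed=seed,
            per_replica=results,
            mean_exssi=float(ex.mean()),
            se_exssi=float(ex.std(ddof=1) / np.sqrt(len(ex))),
        )
    return pooled
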