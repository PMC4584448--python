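"""Channel-to-source reduction by ICA with restart aggregation.

The recordings are reduced to a variance-chosen number of statistically
independent source signals.  FastICA (negentropy fixed-point) is run from
multiple random initializations; components are pooled across restarts and
clustered on absolute source-series correlation (average linkage), and each
cluster's centrotype is returned with a stability index (mean within-cluster
similarity).  Artifactual components — extreme-valued (kurtosis outliers) or
with abnormal spectra — are screened out before causality analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA

from .preprocessing import ARTIFACT_BANDS, _band_log_power, _robust_z
from .types import TrialRecording

__all__ = ["ICModel", "choose_order_by_variance", "decompose", "screen_components"]


@dataclass
class ICModel:
    """Fitted ICA model over a trial-segmented recording.

    unmixing : (m, n_channels) — maps centered channel data to sources
    mixing   : (n_channels, m) — pseudoinverse of unmixing
    sources  : (n_trials, m, n_samples)
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray
    channel_means: np.ndarray
    variance_explained: float
    stability: np.ndarray
    fs: float
    kept: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def kept_sources(self) -> np.ndarray:
        return self.sources[:, self.kept, :]

    def kept_mixing(self) -> np.ndarray:
        return self.mixing[:, self.kept]


def choose_order_by_variance(eigenvalues: np.ndarray, fraction: float = 0.90) -> int:
    """Smallest m whose leading eigenvalues reach ``fraction`` of total
    variance.  Eigenvalues must be nonnegative and sorted descending."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(ev < -1e-12 * max(ev.max(), 1.0)):
        raise ValueError("eigenvalues must be nonnegative")
    if np.any(np.diff(ev) > 1e-12 * max(ev.max(), 1.0)):
        raise ValueError("eigenvalues must be sorted descending")
    cum = np.cumsum(ev) / ev.sum()
    if fraction >= 1.0:
        return int(np.sum(ev > 0))
    return int(np.searchsorted(cum, fraction) + 1)


def _cluster_components(
    all_sources: np.ndarray, m: int
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Cluster pooled restart components on |corr| of their source series.

    Returns (centrotype indices, stability per cluster, cluster ids).
    """
    c = np.abs(np.corrcoef(all_sources))
    np.fill_diagonal(c, 1.0)
    dist = np.clip(1.0 - c, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    ids = fcluster(z, t=m, criterion="maxclust")
    centrotypes, stability = [], []
    for cl in range(1, m + 1):
        members = np.flatnonzero(ids == cl)
        sub = c[np.ix_(members, members)]
        centrotypes.append(int(members[np.argmax(sub.sum(axis=1))]))
        if members.size > 1:
            off = sub[~np.eye(members.size, dtype=bool)]
            stability.append(float(off.mean()))
        else:
            stability.append(0.0)
    return centrotypes, np.asarray(stability), ids


def decompose(
    rec: TrialRecording,
    m: int | None = None,
    variance_fraction: float = 0.90,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
) -> ICModel:
    """Fit ICA on the trial-concatenated data (C+ and C− trials combined,
    one common basis) with restart aggregation.

    Components from all restarts are clustered on absolute correlation and
    each cluster's centrotype kept; the per-component stability index is
    the mean within-cluster similarity.  Component sign is fixed so the
    largest-magnitude channel weight is positive; source series are scaled
    to unit variance.
    """
    if restarts < 2:
        raise ValueError("need >= 2 restarts for the stability index")
    x = rec.data.transpose(1, 0, 2).reshape(rec.n_channels, -1)
    means = x.mean(axis=1)
    xc = x - means[:, None]
    if m is None:
        ev = np.linalg.eigvalsh(np.cov(xc))[::-1]
        m = choose_order_by_variance(np.clip(ev, 0, None), variance_fraction)
    if m > rec.n_channels:
        raise ValueError("order m cannot exceed channel count")

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(restarts)
    comps = []
    n_ok = 0
    for r in range(restarts):
        rs = np.random.default_rng(child[r])
        try:
            ica = FastICA(
                n_components=m,
                whiten="unit-variance",
                max_iter=max_iter,
                random_state=int(rs.integers(2**31)),
            )
            ica.fit(xc.T)
            comps.append(ica.components_)
            n_ok += 1
        except Exception:  # non-convergent restart
            continue
    if n_ok == 0:
        raise RuntimeError("FastICA failed to converge in every restart")
    w_all = np.vstack(comps)  # (restarts*m, n_channels)
    s_all = w_all @ xc
    centro, stability, _ = _cluster_components(s_all, m)
    w = w_all[centro]

    # unit-variance sources, positive largest channel weight
    s = w @ xc
    w = w / s.std(axis=1, keepdims=True)
    peak = np.argmax(np.abs(w), axis=1)
    sign = np.sign(w[np.arange(m), peak])
    w = w * sign[:, None]

    mixing = np.linalg.pinv(w)
    sources = np.einsum(
        "mc,tcn->tmn", w, rec.data - means[None, :, None]
    )
    # variance explained by the retained subspace
    recon = np.einsum("cm,tmn->tcn", mixing, sources)
    tot = ((rec.data - means[None, :, None]) ** 2).sum()
    var_exp = float(1.0 - ((rec.data - means[None, :, None] - recon) ** 2).sum() / tot)

    return ICModel(
        unmixing=w,
        mixing=mixing,
        sources=sources,
        channel_means=means,
        variance_explained=var_exp,
        stability=stability,
        fs=rec.fs,
        kept=list(range(m)),
    )


def screen_components(
    model: ICModel,
    kurtosis_z: float = 15.0,
    spectrum_z: float = 20.0,
) -> tuple[list[int], dict]:
    """Discard artifactual components.

    A component is removed if (a) the kurtosis of its concatenated source
    series is more than ``kurtosis_z`` robust z-units above the across-IC
    median, or (b) its band-averaged log spectral power is more than
    ``spectrum_z`` robust z-units out in any screening band.  Returns
    (kept index list, report) and records it on the model.
    """
    m = model.n_components
    flat = model.sources.transpose(1, 0, 2).reshape(m, -1)
    kurt = stats.kurtosis(flat, axis=1)

    # robust z with absolute scale floors: with few components the MAD can
    # collapse to ~0 and any genuine diversity would explode the z-score
    def _floored_z(x, floor):
        med = np.median(x, axis=0, keepdims=True)
        scale = np.maximum(1.4826 * np.median(np.abs(x - med), axis=0, keepdims=True), floor)
        return (x - med) / scale

    kz = _floored_z(kurt[:, None], floor=1.0)[:, 0]
    blp = _band_log_power(flat[:, None, :], model.fs)[:, 0, :]  # (m, bands)
    bz = _floored_z(blp, floor=0.25)  # 0.25 log10 units = 2.5 dB

    report = {}
    kept = []
    for i in range(m):
        reasons = []
        if kz[i] > kurtosis_z:
            reasons.append(f"kurtosis z={kz[i]:.1f}")
        bad = np.flatnonzero(np.abs(bz[i]) > spectrum_z)
        for b in bad:
            reasons.append(f"band {ARTIFACT_BANDS[b]} Hz z={bz[i, b]:.1f}")
        if reasons:
            report[i] = "; ".join(reasons)
        else:
            kept.append(i)
    if not kept:
        raise ValueError("all components screened out")
    model.kept = kept
    return kept, {"removed": report, "n_kept": len(kept)}
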