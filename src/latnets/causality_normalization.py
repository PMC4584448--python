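"""Event-related causality (ERC) and ternary ΔERC contrast maps.

ERC expresses dDTF in decibels relative to a coupling-free baseline:
ERC(t, f) = 10·log₁₀(dDTF(t, f) / median_{t ⊂ baseline} dDTF(t, f)).

ΔERC contrasts two trial types cell-by-cell over (connection, window,
frequency): a trial bootstrap yields the difference distribution, a
two-sided p-value per cell is corrected by Benjamini–Hochberg across all
cells of the comparison, and surviving cells are coded +1/−1 by the sign of
the observed difference (0 otherwise).  Nine ordered trial-type pairings —
context contrasts under each response, and response contrasts under each
context — are each evaluated in the C+ and C− conditions (18 comparisons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .spectral_causality import WindowEnsembleStats

__all__ = [
    "ComparisonSpec",
    "DeltaERC",
    "baseline_median",
    "erc",
    "erc_from_stats",
    "delta_erc",
    "build_comparisons",
    "COMPARISON_FAMILIES",
]

logger = logging.getLogger(__name__)

#: The nine ordered trial-type pairings, grouped by family.
COMPARISON_FAMILIES = {
    "context-Rf": (("ChRf", "CmRf"), ("CmRf", "CwRf"), ("CwRf", "ChRf")),
    "context-Rn": (("ChRn", "CmRn"), ("CmRn", "CwRn"), ("CwRn", "ChRn")),
    "response": (("ChRf", "ChRn"), ("CmRf", "CmRn"), ("CwRf", "CwRn")),
}


@dataclass(frozen=True)
class ComparisonSpec:
    """One ordered ERC contrast: minuend − subtrahend within a condition."""

    minuend: str
    subtrahend: str
    family: str
    condition: str

    @property
    def key(self) -> str:
        return f"{self.minuend}-{self.subtrahend}:{self.condition}"


def build_comparisons() -> list[ComparisonSpec]:
    """The 18 comparison specs: 9 ordered pairings × {C+, C−}.

    Ordering is condition-major (all C+ first), families in the order
    context-Rf, context-Rn, response.
    """
    specs = []
    for condition in ("Cplus", "Cminus"):
        for family, pairs in COMPARISON_FAMILIES.items():
            for a, b in pairs:
                specs.append(ComparisonSpec(a, b, family, condition))
    return specs


@dataclass
class DeltaERC:
    """Ternary significant-difference map for one comparison.

    signs: (n_windows, n_freqs, k, k) in {−1, 0, +1}, zero diagonal.
    """

    spec: ComparisonSpec
    signs: np.ndarray
    observed_diff: Optional[np.ndarray]
    p_values: Optional[np.ndarray]
    alpha_fdr: float

    def nonzero_fraction(self) -> float:
        k = self.signs.shape[2]
        off = ~np.eye(k, dtype=bool)
        return float((self.signs[:, :, off] != 0).mean())


def baseline_median(values: np.ndarray, baseline_windows: np.ndarray) -> np.ndarray:
    """Median over baseline windows, per (frequency, sink, source).

    values: (n_windows, n_freqs, k, k) → (n_freqs, k, k)
    """
    bw = np.asarray(baseline_windows, dtype=int)
    if bw.size == 0:
        raise ValueError("need at least one baseline window")
    if bw.min() < 0 or bw.max() >= values.shape[0]:
        raise ValueError("baseline windows outside the window grid")
    return np.median(values[bw], axis=0)


def erc(values: np.ndarray, medians: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """10·log₁₀(value / baseline median), elementwise, in dB.

    Medians at or below zero are floored at ``eps`` (with a warning) so the
    ratio stays defined; cells where value equals its median map to 0 dB.
    """
    med = np.asarray(medians, dtype=float)
    if np.any(med <= 0):
        # identically-zero cells (e.g. self-connections) floor silently;
        # a zero median under nonzero values deserves a warning
        informative = (med <= 0) & (np.max(values, axis=0) > 0)
        if informative.any():
            logger.warning(
                "flooring %d nonpositive baseline medians at %g",
                int(informative.sum()),
                eps,
            )
        med = np.where(med <= 0, eps, med)
    vals = np.where(values <= 0, eps, values)
    return 10.0 * np.log10(vals / med[None])


def erc_from_stats(
    stats: WindowEnsembleStats,
    baseline_windows: np.ndarray,
    freqs: np.ndarray,
    fs: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """dDTF → ERC for one trial-type ensemble (optionally reweighted)."""
    d = stats.causality(freqs, fs, weights)["ddtf"]
    med = baseline_median(d, baseline_windows)
    return erc(d, med)


def delta_erc(
    stats_a: WindowEnsembleStats,
    stats_b: WindowEnsembleStats,
    spec: ComparisonSpec,
    baseline_windows: np.ndarray,
    freqs: np.ndarray,
    fs: float,
    alpha_fdr: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
    method: str = "normal",
    min_trials: int = 20,
) -> DeltaERC:
    """Ternary significant-difference map between two trial-type ensembles.

    Each bootstrap replicate resamples trials within each type, refits the
    windowed VARs from the precomputed sufficient statistics, and recomputes
    the ERC difference.  ``method='normal'`` converts the observed difference
    and the bootstrap SE into a two-sided normal-tail p-value (granular
    enough for step-up FDR over thousands of cells); ``method='percentile'``
    uses the bootstrap percentile p-value directly.  Benjamini–Hochberg runs
    across every off-diagonal (connection, window, frequency) cell of the
    comparison.
    """
    if stats_a.n_trials < min_trials or stats_b.n_trials < min_trials:
        raise ValueError(
            f"comparison {spec.key}: need >= {min_trials} trials per type "
            f"(got {stats_a.n_trials}, {stats_b.n_trials})"
        )
    rng = np.random.default_rng(seed)
    erc_a = erc_from_stats(stats_a, baseline_windows, freqs, fs)
    erc_b = erc_from_stats(stats_b, baseline_windows, freqs, fs)
    observed = erc_a - erc_b

    def _boot_ercs(stats):
        n = stats.n_trials
        w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)
        d = stats.ddtf_batch(freqs, fs, w)
        med = np.median(d[:, baseline_windows], axis=1)
        med = np.where(med <= 0, 1e-12, med)
        d = np.where(d <= 0, 1e-12, d)
        return 10.0 * np.log10(d / med[:, None])

    boots = _boot_ercs(stats_a) - _boot_ercs(stats_b)

    if method == "normal":
        se = boots.std(axis=0, ddof=1)
        z = np.divide(
            observed, se, out=np.zeros_like(observed), where=se > 1e-12
        )
        p = 2.0 * sstats.norm.sf(np.abs(z))
    elif method == "percentile":
        n_le = (boots <= 0).sum(axis=0)
        n_ge = (boots >= 0).sum(axis=0)
        p = 2.0 * (np.minimum(n_le, n_ge) + 1) / (n_boot + 1)
        p = np.clip(p, 0.0, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    k = observed.shape[2]
    off = ~np.eye(k, dtype=bool)
    flat_p = p[:, :, off].ravel()
    reject, *_ = multipletests(flat_p, alpha=alpha_fdr, method="fdr_bh")
    signs = np.zeros(observed.shape, dtype=np.int8)
    rej_mask = np.zeros(observed.shape, dtype=bool)
    rej_mask[:, :, off] = reject.reshape(p.shape[:2] + (k * (k - 1),))
    signs[rej_mask] = np.sign(observed[rej_mask]).astype(np.int8)
    return DeltaERC(
        spec=spec, signs=signs, observed_diff=observed, p_values=p, alpha_fdr=alpha_fdr
    )
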