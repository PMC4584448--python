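"""Shuffle-based inference on structure loadings.

Significance of the comparison-mode loadings is assessed by trial-label
shuffling: trial-type labels are permuted within each condition, the whole
dDTF → ERC → ΔERC → tensor chain is recomputed, and the comparison-mode
loadings are re-estimated by least squares with the time-frequency and
connection modes held fixed at their original values.  Observed loadings
falling outside the two-sided empirical α band of the shuffle null are
flagged.  Significant pairwise differences are then turned into per-trial-
type activation levels by an anchored least-squares reconstruction, and
inter-structure dependencies are the Pearson correlations of the loading
vectors within each comparison family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sstats

from .causality_normalization import ComparisonSpec, build_comparisons
from .tensor_factorization import ParafacModel, _khatri_rao
from .types import CONDITIONS, TRIAL_TYPES

__all__ = [
    "LoadingSignificance",
    "refit_mode0",
    "loading_significance",
    "reconstruct_activation",
    "interdependency",
]


@dataclass
class LoadingSignificance:
    """Observed mode-0 loadings (18 × R) with their shuffle-null summary
    and two-sided significance flags at level alpha."""

    observed: np.ndarray
    null_loadings: np.ndarray  # (n_shuffles, 18, R)
    significant: np.ndarray  # bool (18, R)
    alpha: float
    comparisons: list[ComparisonSpec]


def refit_mode0(tensor: np.ndarray, model: ParafacModel) -> np.ndarray:
    """Least-squares comparison-mode loadings with modes 1–2 fixed."""
    b, c = model.mode1, model.mode2
    z = _khatri_rao(b, c)
    gram = (b.T @ b) * (c.T @ c)
    t0 = tensor.reshape(tensor.shape[0], -1)
    return t0 @ z @ np.linalg.pinv(gram)


def loading_significance(
    tensor_builder: Callable[[np.random.Generator], np.ndarray],
    tensor: np.ndarray,
    model: ParafacModel,
    n_shuffles: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> LoadingSignificance:
    """Shuffle test on the comparison-mode loadings.

    ``tensor_builder(rng)`` must rebuild the ΔERC tensor after permuting
    trial-type labels within each condition.  For each shuffle, mode-0
    loadings are re-estimated against the fixed modes 1–2; an observed
    loading outside the empirical [α/2, 1−α/2] band of its null is flagged.
    """
    if n_shuffles < 2.0 / alpha - 1:
        warnings.warn(
            f"{n_shuffles} shuffles cannot resolve two-sided alpha={alpha}; "
            f"the achievable floor is {2.0 / (n_shuffles + 1):.3f}"
        )
    rng = np.random.default_rng(seed)
    observed = refit_mode0(tensor, model)
    null = np.empty((n_shuffles,) + observed.shape)
    for s in range(n_shuffles):
        null[s] = refit_mode0(tensor_builder(rng), model)
    # rank-based two-sided permutation p-value (the interpolated-quantile
    # variant is anti-conservative at 50 shuffles)
    n_ge = (null >= observed[None]).sum(axis=0)
    n_le = (null <= observed[None]).sum(axis=0)
    p = 2.0 * (np.minimum(n_ge, n_le) + 1) / (n_shuffles + 1)
    significant = p <= alpha
    return LoadingSignificance(
        observed=observed,
        null_loadings=null,
        significant=significant,
        alpha=alpha,
        comparisons=build_comparisons(),
    )


def reconstruct_activation(sig: LoadingSignificance) -> dict[str, np.ndarray]:
    """Per-condition activation levels of the six trial types per structure.

    For each structure and condition, solves least squares for the six
    levels from {level(minuend) − level(subtrahend) = loading} over the
    significant comparisons only (minimum-norm solution, hence mean-zero
    anchored over the involved types).  Returns {condition: (6, R)} in
    canonical trial-type order; all zeros when nothing is significant.
    """
    r = sig.observed.shape[1]
    tt_index = {t: i for i, t in enumerate(TRIAL_TYPES)}
    out = {}
    for cond in CONDITIONS:
        levels = np.zeros((len(TRIAL_TYPES), r))
        for struct in range(r):
            rows, rhs = [], []
            for ci, spec in enumerate(sig.comparisons):
                if spec.condition != cond or not sig.significant[ci, struct]:
                    continue
                row = np.zeros(len(TRIAL_TYPES))
                row[tt_index[spec.minuend]] = 1.0
                row[tt_index[spec.subtrahend]] = -1.0
                rows.append(row)
                rhs.append(sig.observed[ci, struct])
            if rows:
                sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
                levels[:, struct] = sol
        out[cond] = levels
    return out


def interdependency(model: ParafacModel) -> dict[str, dict[str, np.ndarray]]:
    """Inter-structure correlations of the comparison loadings per family.

    For each family (context under Rf, context under Rn, response) the six
    loadings (3 comparisons × 2 conditions) of each structure are
    correlated between structures (Pearson, n = 6) with two-sided p-values
    for the no-correlation null.  Zero-variance vectors yield NaN and are
    flagged.
    """
    if model.rank < 2:
        raise ValueError("interdependency needs at least two structures")
    specs = build_comparisons()
    out = {}
    for family in ("context-Rf", "context-Rn", "response"):
        idx = [i for i, sp in enumerate(specs) if sp.family == family]
        vecs = model.mode0[idx, :]  # (6, R)
        r = model.rank
        corr = np.eye(r)
        pval = np.zeros((r, r))
        degenerate = np.zeros((r, r), dtype=bool)
        for i in range(r):
            for j in range(r):
                if i == j:
                    continue
                if np.std(vecs[:, i]) < 1e-300 or np.std(vecs[:, j]) < 1e-300:
                    corr[i, j], pval[i, j] = np.nan, np.nan
                    degenerate[i, j] = True
                else:
                    corr[i, j], pval[i, j] = sstats.pearsonr(vecs[:, i], vecs[:, j])
        out[family] = {"correlation": corr, "p_values": pval, "degenerate": degenerate}
    return out
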