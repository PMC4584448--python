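"""ΔERC tensor assembly and constrained PARAFAC with core consistency.

The ternary significant-difference maps from all comparisons, subjects and
connections are pooled into one 3-way tensor

    [comparison-condition (18)] × [time-frequency] × [connection-subject]

and decomposed into R rank-1 latent network structures by alternating least
squares with no constraint on the comparison mode and nonnegativity on the
time-frequency and connection modes.  The appropriate R is chosen with the
core-consistency diagnostic (CORCONDIA): the least-squares Tucker core
implied by the fitted loadings is compared with the ideal superdiagonal
core, and a sharp drop in consistency marks overfactoring.

Initialization follows the classical pair: a direct trilinear (GRAM-style
generalized rank annihilation on two random slab aggregates) start, and
random orthogonalized restarts with the best-fit solution retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.optimize import linear_sum_assignment

from .causality_normalization import ComparisonSpec, DeltaERC, build_comparisons

__all__ = [
    "TensorAxes",
    "ParafacModel",
    "assemble",
    "parafac",
    "corcondia",
    "scan_components",
    "congruence",
    "match_columns",
]


# ---------------------------------------------------------------------------
# tensor assembly


@dataclass
class TensorAxes:
    """Axis registries for the ΔERC tensor.

    mode-0: the 18 comparison specs (condition-major order);
    mode-1: time-frequency, flat index = window·n_freqs + bin;
    mode-2: connection-subject, flat blocks per subject in given order,
            within a subject ordered pairs (source a → sink b), a ≠ b,
            row-major over (a, b).
    """

    comparisons: list[ComparisonSpec]
    n_windows: int
    n_freqs: int
    subjects: list[str]
    ics_per_subject: dict[str, list[int]]
    window_centers_s: Optional[np.ndarray] = None
    freqs_hz: Optional[np.ndarray] = None

    def tf_index(self, window: int, freq_bin: int) -> int:
        return window * self.n_freqs + freq_bin

    def tf_label(self, flat: int) -> tuple[int, int]:
        return divmod(flat, self.n_freqs)[0], flat % self.n_freqs

    def connection_labels(self) -> list[tuple[str, int, int]]:
        """(subject, source IC, sink IC) for every mode-2 index."""
        out = []
        for s in self.subjects:
            ics = self.ics_per_subject[s]
            for a in ics:
                for b in ics:
                    if a != b:
                        out.append((s, a, b))
        return out

    def connection_index(self, subject: str, source: int, sink: int) -> int:
        off = 0
        for s in self.subjects:
            k = len(self.ics_per_subject[s])
            if s == subject:
                ics = self.ics_per_subject[s]
                a = ics.index(source)
                b = ics.index(sink)
                pos = a * (k - 1) + (b if b < a else b - 1)
                return off + pos
            off += k * (k - 1)
        raise KeyError(subject)

    def subject_slices(self) -> dict[str, slice]:
        out, off = {}, 0
        for s in self.subjects:
            k = len(self.ics_per_subject[s])
            out[s] = slice(off, off + k * (k - 1))
            off += k * (k - 1)
        return out


def assemble(
    delta_maps: dict[str, dict[str, DeltaERC]],
    subjects: Optional[Sequence[str]] = None,
    ics_per_subject: Optional[dict[str, list[int]]] = None,
    dtype=np.float64,
) -> tuple[np.ndarray, TensorAxes]:
    """Pool per-subject ΔERC maps into the 3-way ternary tensor.

    ``delta_maps[subject][spec.key]`` must hold a :class:`DeltaERC` for all
    18 comparisons with common window/frequency grids.  Missing entries
    raise with the full gap list.
    """
    specs = build_comparisons()
    if subjects is None:
        subjects = sorted(delta_maps)
    gaps = [
        f"{s}:{sp.key}"
        for s in subjects
        for sp in specs
        if sp.key not in delta_maps.get(s, {})
    ]
    if gaps:
        raise ValueError("missing comparisons: " + ", ".join(gaps))

    first = delta_maps[subjects[0]][specs[0].key].signs
    n_win, n_freq = first.shape[:2]
    if ics_per_subject is None:
        ics_per_subject = {
            s: list(range(delta_maps[s][specs[0].key].signs.shape[2])) for s in subjects
        }
    blocks = []
    for s in subjects:
        k = delta_maps[s][specs[0].key].signs.shape[2]
        sub = np.empty((len(specs), n_win * n_freq, k * (k - 1)), dtype=np.int8)
        for ci, sp in enumerate(specs):
            signs = delta_maps[s][sp.key].signs  # (w, f, sink, source)
            if signs.shape[:2] != (n_win, n_freq):
                raise ValueError(f"grid mismatch for {s}:{sp.key}")
            conn = 0
            for a in range(k):
                for b in range(k):
                    if a == b:
                        continue
                    sub[ci, :, conn] = signs[:, :, b, a].ravel()
                    conn += 1
        blocks.append(sub)
    tensor = np.concatenate(blocks, axis=2).astype(dtype, copy=False)
    axes = TensorAxes(
        comparisons=specs,
        n_windows=n_win,
        n_freqs=n_freq,
        subjects=list(subjects),
        ics_per_subject=ics_per_subject,
    )
    return tensor, axes


# ---------------------------------------------------------------------------
# PARAFAC


@dataclass
class ParafacModel:
    """Fitted R-structure PARAFAC model.

    mode0 (signed, carries all scale) × mode1, mode2 (nonnegative,
    unit-norm columns).
    """

    mode0: np.ndarray
    mode1: np.ndarray
    mode2: np.ndarray
    fit_percent: float
    core_consistency: Optional[float] = None
    init: str = "random"
    seed: int = 0
    n_iter: int = 0
    converged: bool = True

    @property
    def rank(self) -> int:
        return self.mode0.shape[1]

    def factors(self) -> list[np.ndarray]:
        return [self.mode0, self.mode1, self.mode2]

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.mode0, self.mode1, self.mode2)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker: rows indexed (i_a · n_b + i_b)."""
    r = a.shape[1]
    return np.einsum("ir,jr->ijr", a, b).reshape(-1, r)


def _nnls_rows(gram: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Row-wise nonnegative solve of min ‖X Gᵀ-ish‖ via the normal equations.

    Solves, for each row i, min_{x ≥ 0} xᵀ G x − 2 tᵢᵀ x with G = ZᵀZ and
    tᵢ = Zᵀ yᵢ, through the Cholesky reformulation ‖Lᵀx − L⁻¹tᵢ‖².
    """
    r = gram.shape[0]
    jitter = 1e-12 * max(np.trace(gram) / r, 1.0)
    for _ in range(8):
        try:
            chol = np.linalg.cholesky(gram + jitter * np.eye(r))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:
        raise np.linalg.LinAlgError("gram matrix not positive definite")
    rhs = np.linalg.solve(chol, target.T)  # (r, n_rows)
    out = np.empty_like(target)
    at = chol.T
    for i in range(target.shape[0]):
        out[i], _ = nnls(at, rhs[:, i])
    return out


def _fit_fraction(norm_t2, factors, mttkrp0) -> float:
    """1 − ‖T − T̂‖²/‖T‖² using cached mode-0 MTTKRP."""
    a, b, c = factors
    gram = (a.T @ a) * (b.T @ b) * (c.T @ c)
    norm_hat2 = float(gram.sum())
    inner = float((mttkrp0 * a).sum())
    resid2 = max(norm_t2 - 2 * inner + norm_hat2, 0.0)
    return 1.0 - resid2 / norm_t2


def _als(
    tensor: np.ndarray,
    factors: list[np.ndarray],
    tol: float,
    max_iter: int,
) -> tuple[list[np.ndarray], float, int, bool]:
    d0, d1, d2 = tensor.shape
    t0 = tensor.reshape(d0, d1 * d2)
    t1 = tensor.transpose(1, 0, 2).reshape(d1, d0 * d2)
    t2 = tensor.transpose(2, 0, 1).reshape(d2, d0 * d1)
    norm_t2 = float((tensor**2).sum())
    if norm_t2 == 0:
        return factors, 1.0, 0, True
    a, b, c = factors
    prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        # mode-0: unconstrained
        z = _khatri_rao(b, c)
        gram = (b.T @ b) * (c.T @ c)
        a = t0 @ z @ np.linalg.pinv(gram)
        # mode-1: nonnegative
        z = _khatri_rao(a, c)
        gram = (a.T @ a) * (c.T @ c)
        b = _nnls_rows(gram, t1 @ z)
        # mode-2: nonnegative
        z = _khatri_rao(a, b)
        gram = (a.T @ a) * (b.T @ b)
        c = _nnls_rows(gram, t2 @ z)
        # guard collapsed columns
        for mat, nonneg in ((b, True), (c, True)):
            dead = np.flatnonzero(np.linalg.norm(mat, axis=0) < 1e-14)
            if dead.size:
                mat[:, dead] = 1e-6
        mttkrp0 = t0 @ _khatri_rao(b, c)
        frac = _fit_fraction(norm_t2, (a, b, c), mttkrp0)
        if abs(frac - prev) < tol:
            converged = True
            prev = frac
            break
        prev = frac
    # final exact mode-0 solve against the converged modes 1-2, so the
    # returned loadings are the least-squares fixed point of the fit
    z = _khatri_rao(b, c)
    gram = (b.T @ b) * (c.T @ c)
    a = t0 @ z @ np.linalg.pinv(gram)
    prev = _fit_fraction(norm_t2, (a, b, c), t0 @ z)
    return [a, b, c], prev, it, converged


def _normalize(factors: list[np.ndarray]) -> list[np.ndarray]:
    """Unit-norm columns on modes 1–2; all scale absorbed into mode 0."""
    a, b, c = factors
    nb = np.linalg.norm(b, axis=0)
    nc = np.linalg.norm(c, axis=0)
    nb = np.where(nb < 1e-300, 1.0, nb)
    nc = np.where(nc < 1e-300, 1.0, nc)
    return [a * (nb * nc), b / nb, c / nc]


def _random_orthogonal_init(
    shape: tuple[int, int, int], rank: int, rng: np.random.Generator
) -> list[np.ndarray]:
    factors = []
    for mode, d in enumerate(shape):
        m = rng.standard_normal((d, max(rank, 1)))
        if d >= rank:
            m, _ = np.linalg.qr(m)
            m = m[:, :rank]
        if mode > 0:
            m = np.abs(m)
        factors.append(m)
    return factors


def _dtld_init(
    tensor: np.ndarray, rank: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Direct-trilinear start: generalized rank annihilation on two random
    aggregates of the mode-0 slabs."""
    d0, d1, d2 = tensor.shape
    w1 = rng.standard_normal(d0)
    w2 = rng.standard_normal(d0)
    s1 = np.einsum("i,ijk->jk", w1, tensor)
    s2 = np.einsum("i,ijk->jk", w2, tensor)
    u, _, vt = np.linalg.svd(s1 + s2, full_matrices=False)
    u = u[:, :rank]
    v = vt[:rank].T
    g1 = u.T @ s1 @ v
    g2 = u.T @ s2 @ v
    ridge = 1e-10 * np.eye(rank)
    evals, evecs = np.linalg.eig(np.linalg.solve(g2 + ridge, g1))
    b = np.real(u @ g2 @ evecs)  # mode-1 factor up to scale
    if not np.all(np.isfinite(b)):
        raise np.linalg.LinAlgError("DTLD produced non-finite factors")
    # sign-fix then clip for the nonnegative mode; mode-2 and mode-0 follow
    # from one least-squares sweep inside ALS
    sign = np.sign(b.sum(axis=0))
    sign[sign == 0] = 1.0
    b = np.clip(b * sign, 0.0, None)
    b = b + 1e-6
    c = np.abs(rng.standard_normal((d2, rank)))
    a = rng.standard_normal((d0, rank))
    # one mode-2/mode-0 refinement pass from the DTLD mode-1 factor
    return [a, b, c]


def parafac(
    tensor: np.ndarray,
    rank: int,
    tol: float = 1e-6,
    init: str = "random",
    n_restarts: int = 100,
    seed: int = 0,
    max_iter: int = 2000,
    pilot_iter: int = 60,
    compute_corcondia: bool = False,
) -> ParafacModel:
    """Constrained PARAFAC by ALS.

    init='random': ``n_restarts`` random-orthogonal starts are run as short
    pilots, the best-fit iterate is refined to ``tol``; init='dtld' runs a
    single direct-trilinear start to full tolerance.  Modes 1–2 are solved
    under nonnegativity (active-set NNLS per row); mode 0 is unconstrained
    and absorbs all scale.
    """
    tensor = np.asarray(tensor, dtype=float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(tensor.shape):
        raise ValueError("rank exceeds the smallest tensor dimension")
    rng = np.random.default_rng(seed)
    if init == "dtld":
        try:
            factors = _dtld_init(tensor, rank, rng)
        except np.linalg.LinAlgError:
            warnings.warn("DTLD initialization failed; falling back to random")
            factors = _random_orthogonal_init(tensor.shape, rank, rng)
        factors, frac, n_iter, converged = _als(tensor, factors, tol, max_iter)
    elif init == "random":
        best = None
        for r in range(max(n_restarts, 1)):
            f0 = _random_orthogonal_init(tensor.shape, rank, rng)
            f, frac, _, _ = _als(tensor, f0, max(tol, 1e-5), pilot_iter)
            if best is None or frac > best[1]:
                best = (f, frac)
        factors, frac, n_iter, converged = _als(tensor, best[0], tol, max_iter)
    else:
        raise ValueError(f"unknown init {init!r}")
    if not converged:
        warnings.warn(f"PARAFAC did not converge in {max_iter} iterations")
    factors = _normalize(factors)
    model = ParafacModel(
        mode0=factors[0],
        mode1=factors[1],
        mode2=factors[2],
        fit_percent=100.0 * frac,
        init=init,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
    )
    if compute_corcondia:
        try:
            model.core_consistency = corcondia(model, tensor)
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"core consistency unavailable: {exc}")
            model.core_consistency = np.nan
    return model


def corcondia(model: ParafacModel, tensor: np.ndarray) -> float:
    """Core-consistency diagnostic (%).

    Computes the least-squares Tucker core G for the fitted loadings and
    scores 100·(1 − Σ(g − t)²/Σt²) against the superdiagonal indicator t.
    """
    a, b, c = model.factors()
    r = model.rank
    for name, m in (("mode0", a), ("mode1", b), ("mode2", c)):
        if np.linalg.matrix_rank(m) < r:
            raise np.linalg.LinAlgError(f"rank-deficient {name} loading matrix")
    pa, pb, pc = (np.linalg.pinv(m) for m in (a, b, c))
    core = np.einsum("ri,ijk->rjk", pa, np.asarray(tensor, float))
    core = np.einsum("sj,rjk->rsk", pb, core)
    core = np.einsum("tk,rsk->rst", pc, core)
    ideal = np.zeros((r, r, r))
    ideal[np.arange(r), np.arange(r), np.arange(r)] = 1.0
    return float(100.0 * (1.0 - ((core - ideal) ** 2).sum() / r))


def scan_components(
    tensor: np.ndarray,
    r_max: int,
    threshold: float = 80.0,
    seed: int = 0,
    n_restarts: int = 20,
    tol: float = 1e-6,
    pilot_iter: int = 40,
) -> dict:
    """Core-consistency scan over R = 1…r_max for both init methods.

    Selected R = the largest R whose best-fit consistency is ≥ threshold
    while the consistency at R+1 falls below it (R = r_max qualifies on the
    first clause alone).  If no R qualifies the maximum-consistency R is
    returned flagged.
    """
    if r_max < 2:
        raise ValueError("r_max must be >= 2")
    curves = {"dtld": [], "random": []}
    best_models = []
    for r in range(1, r_max + 1):
        models = []
        for init in ("dtld", "random"):
            m = parafac(
                tensor,
                r,
                tol=tol,
                init=init,
                n_restarts=n_restarts,
                seed=seed + r,
                pilot_iter=pilot_iter,
                compute_corcondia=True,
            )
            curves[init].append(m.core_consistency)
            models.append(m)
        best_models.append(max(models, key=lambda m: m.fit_percent))
    cons = np.array([m.core_consistency for m in best_models])
    # selection treats consistency as [0, 100]; an unavailable value counts 0
    clamped = np.clip(np.nan_to_num(cons, nan=0.0), 0.0, None)
    candidates = [
        r
        for r in range(1, r_max + 1)
        if clamped[r - 1] >= threshold and (r == r_max or clamped[r] < threshold)
    ]
    if candidates:
        selected, flagged = max(candidates), False
    else:
        selected, flagged = int(np.argmax(clamped)) + 1, True
    return {
        "selected_r": selected,
        "flagged": flagged,
        "consistency": cons,
        "curves": {k: np.array(v) for k, v in curves.items()},
        "models": best_models,
    }


# ---------------------------------------------------------------------------
# factor matching utilities


def congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Congruence (cosine) coefficients between columns of a and b."""
    an = a / np.linalg.norm(a, axis=0, keepdims=True)
    bn = b / np.linalg.norm(b, axis=0, keepdims=True)
    return an.T @ bn


def match_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one column assignment maximizing |congruence|.

    Returns (permutation such that b[:, perm] matches a, matched scores).
    """
    c = np.abs(congruence(a, b))
    rows, cols = linear_sum_assignment(-c)
    return cols, c[rows, cols]
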