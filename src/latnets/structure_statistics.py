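"""Graph-level statistics of the latent network structures.

Each structure's connection-mode loadings are reshaped, per subject, into a
weighted directed graph over the retained source components.  From these
graphs the module computes causal density (out-strength + in-strength),
causal outflow (out-strength − in-strength), channel-space projections via
the mixing weights, maximum flow between cortical areas, top-quantile
connection overlap, temporal/spectral profiles, and cross-model structure
matching by domain-wise Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.optimize import linear_sum_assignment

from .tensor_factorization import ParafacModel, TensorAxes

__all__ = [
    "StructureGraph",
    "StructureProfile",
    "AREA_NAMES",
    "loadings_to_graphs",
    "node_strengths",
    "project_to_channels",
    "area_max_flow",
    "top_shared_connections",
    "undirected_pathways",
    "profiles",
    "compare_structures",
]

#: Canonical cortical area labels for the area-level flow summary.
AREA_NAMES = ("V", "P", "PF", "mPF", "M", "aT", "pT")


@dataclass
class StructureGraph:
    """Weighted digraph over kept source components for one structure and
    subject; ``weights[a, b]`` = loading of connection a → b (zero diagonal,
    nonnegative)."""

    weights: np.ndarray
    subject: str
    structure: int
    ics: list[int]

    @property
    def k(self) -> int:
        return self.weights.shape[0]


@dataclass
class StructureProfile:
    """Per-structure temporal (per-window) and spectral (per-bin) profiles,
    both nonnegative by the mode-1 constraint."""

    temporal: np.ndarray
    spectral: np.ndarray
    structure: int


def loadings_to_graphs(
    model: ParafacModel, axes: TensorAxes
) -> dict[int, dict[str, StructureGraph]]:
    """Block-partition each connection-mode column by subject and reshape
    to (source, sink) weight matrices."""
    total = sum(len(v) * (len(v) - 1) for v in axes.ics_per_subject.values())
    if model.mode2.shape[0] != total:
        raise ValueError(
            f"mode-2 length {model.mode2.shape[0]} does not match registry ({total})"
        )
    out: dict[int, dict[str, StructureGraph]] = {}
    slices = axes.subject_slices()
    for r in range(model.rank):
        out[r] = {}
        for s in axes.subjects:
            ics = axes.ics_per_subject[s]
            k = len(ics)
            block = model.mode2[slices[s], r]
            # row-major (source a, sink b), a ≠ b — inverse of assemble()
            w = np.zeros((k, k))
            w[~np.eye(k, dtype=bool)] = block

            out[r][s] = StructureGraph(weights=w, subject=s, structure=r, ics=list(ics))
    return out


def node_strengths(g: StructureGraph) -> dict[str, np.ndarray]:
    """Causal density (out+in strength) and outflow (out−in) per node."""
    out_s = g.weights.sum(axis=1)
    in_s = g.weights.sum(axis=0)
    return {
        "out_strength": out_s,
        "in_strength": in_s,
        "density": out_s + in_s,
        "outflow": out_s - in_s,
        "total_weight": float(g.weights.sum()),
    }


def project_to_channels(values: np.ndarray, mixing: np.ndarray) -> np.ndarray:
    """Spatially weight per-IC values onto channels.

    channel value = Σ_ic |W_ic,ch| / max_ch |W_ic,ch| · value_ic, i.e. each
    IC's channel-weight profile is normalized to peak 1; linear in values.
    """
    w = np.abs(np.asarray(mixing, dtype=float))  # (n_channels, n_ics)
    peak = w.max(axis=0)
    if np.any(peak <= 0):
        raise ValueError("all-zero mixing weights for some IC")
    return (w / peak) @ np.asarray(values, dtype=float)


def area_max_flow(
    g: StructureGraph, areas: dict[int, str], area_names=AREA_NAMES
) -> tuple[np.ndarray, dict]:
    """(n_areas × n_areas) maximum single-link flow between areas.

    Entry (A, B) = max weight over edges with source IC in A and sink IC in
    B; the diagonal is excluded (zero).  Empty areas give zero rows/columns
    and are flagged.
    """
    populated = {a for a in areas.values()}
    if len(populated) < 2:
        raise ValueError("need at least two populated areas")
    n = len(area_names)
    idx = {a: i for i, a in enumerate(area_names)}
    out = np.zeros((n, n))
    for ai, src in enumerate(g.ics):
        for bi, snk in enumerate(g.ics):
            if ai == bi:
                continue
            a_area = areas.get(src)
            b_area = areas.get(snk)
            if a_area is None or b_area is None or a_area == b_area:
                continue
            i, j = idx[a_area], idx[b_area]
            out[i, j] = max(out[i, j], g.weights[ai, bi])
    flags = {"empty_areas": [a for a in area_names if a not in populated]}
    return out, flags


def _top_edges(g: StructureGraph, q: float) -> set[tuple[int, int]]:
    w = g.weights
    pos = w[w > 0]
    if pos.size == 0:
        raise ValueError("graph has no positive weights")
    cut = np.quantile(pos, 1.0 - q)
    return {tuple(e) for e in np.argwhere(w > cut)}


def top_shared_connections(ga: StructureGraph, gb: StructureGraph, q: float = 0.10) -> float:
    """Fraction of A's top-q connections also in B's top-q set.

    Top set = edges with weight strictly above the (1−q) quantile of the
    positive weights.  Asymmetric by construction (denominator is |top A|).
    """
    if ga.k != gb.k:
        raise ValueError("graphs must share a node set")
    ta = _top_edges(ga, q)
    tb = _top_edges(gb, q)
    if not ta:
        raise ValueError("empty top set for the first graph")
    return len(ta & tb) / len(ta)


def undirected_pathways(
    graphs: list[StructureGraph], qs=(0.01, 0.05, 0.10, 0.25)
) -> dict[float, dict[str, set]]:
    """Shared undirected top-q pathways across structures.

    An undirected edge {a, b} is present for a graph if either direction is
    in its top-q set.  Returns, per q, the intersection across all graphs
    and the union over graphs.
    """
    if len(graphs) < 2:
        raise ValueError("need at least two graphs")
    out = {}
    for q in qs:
        und_sets = []
        for g in graphs:
            try:
                top = _top_edges(g, q)
            except ValueError:
                top = set()
            und_sets.append({frozenset(e) for e in top})
        inter = set.intersection(*und_sets) if und_sets else set()
        union = set.union(*und_sets) if und_sets else set()
        out[q] = {"intersection": inter, "union": union}
    return out


def profiles(model: ParafacModel, axes: TensorAxes) -> list[StructureProfile]:
    """Temporal profile = per-window sum over bins of the time-frequency
    loading; spectral profile = per-bin mean over windows."""
    out = []
    for r in range(model.rank):
        tf = model.mode1[:, r].reshape(axes.n_windows, axes.n_freqs)
        out.append(
            StructureProfile(
                temporal=tf.sum(axis=1), spectral=tf.mean(axis=0), structure=r
            )
        )
    return out


def _outflow_vector(model: ParafacModel, axes: TensorAxes) -> np.ndarray:
    """Causal outflow per IC concatenated across subjects: (Σ k_s, R)."""
    graphs = loadings_to_graphs(model, axes)
    cols = []
    for r in range(model.rank):
        vec = np.concatenate(
            [node_strengths(graphs[r][s])["outflow"] for s in axes.subjects]
        )
        cols.append(vec)
    return np.column_stack(cols)


def compare_structures(
    model_a: ParafacModel,
    axes_a: TensorAxes,
    model_b: ParafacModel,
    axes_b: TensorAxes,
    alpha: float = 0.05,
    rho_high: float = 0.8,
) -> dict:
    """Match structures across two fits by domain-wise Pearson correlation.

    Domains: comparison loadings (mode 0), temporal profile, spectral
    profile, and the concatenated causal-outflow vector.  The one-to-one
    assignment maximizes the summed correlation across domains; flags mark
    significant (p < alpha) and high (ρ > rho_high) diagonal correlations
    after reordering.
    """
    if model_a.mode0.shape[0] != model_b.mode0.shape[0]:
        raise ValueError("comparison-mode dimension mismatch")
    if (axes_a.n_windows, axes_a.n_freqs) != (axes_b.n_windows, axes_b.n_freqs):
        raise ValueError("time-frequency grid mismatch")
    prof_a = profiles(model_a, axes_a)
    prof_b = profiles(model_b, axes_b)
    domains = {
        "comparison": (model_a.mode0, model_b.mode0),
        "temporal": (
            np.column_stack([p.temporal for p in prof_a]),
            np.column_stack([p.temporal for p in prof_b]),
        ),
        "spectral": (
            np.column_stack([p.spectral for p in prof_a]),
            np.column_stack([p.spectral for p in prof_b]),
        ),
    }
    try:
        domains["outflow"] = (
            _outflow_vector(model_a, axes_a),
            _outflow_vector(model_b, axes_b),
        )
    except ValueError:
        pass  # incompatible connection registries: outflow domain skipped

    ra, rb = model_a.rank, model_b.rank
    corr = {}
    pval = {}
    for name, (ma, mb) in domains.items():
        c = np.zeros((ra, rb))
        p = np.ones((ra, rb))
        for i in range(ra):
            for j in range(rb):
                if np.std(ma[:, i]) < 1e-300 or np.std(mb[:, j]) < 1e-300:
                    c[i, j], p[i, j] = np.nan, np.nan
                else:
                    c[i, j], p[i, j] = sstats.pearsonr(ma[:, i], mb[:, j])
        corr[name] = c
        pval[name] = p
    total = sum(np.nan_to_num(c) for c in corr.values())
    rows, cols = linear_sum_assignment(-total)
    diag = {name: corr[name][rows, cols] for name in corr}
    flags = {
        name: {
            "significant": pval[name][rows, cols] < alpha,
            "high": diag[name] > rho_high,
        }
        for name in corr
    }
    return {
        "correlation": corr,
        "p_values": pval,
        "assignment": cols,
        "diagonal": diag,
        "flags": flags,
    }
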