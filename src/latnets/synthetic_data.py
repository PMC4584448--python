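"""Synthetic ground-truth generator for the full analysis pipeline.

Latent sources evolve as a time-varying vector autoregression.  Each source
is a damped AR(2) resonator (resonance at a chosen band center, bandwidth
set by the pole radius), and condition-dependent directed couplings between
sources switch on in defined task periods for defined trial types.  Channels
are a linear mixture of the sources plus observation noise.  Per-trial gaze
traces with a controllable on-screen fraction drive the C+/C− screening, and
a configurable fraction of trials carries a broadband artifact burst.

The default schedule plants five distinct directed structures:

1. context-graded β coupling (s0→s1, 20 Hz) during Context — strength
   ordered Ch > Cm > Cw;
2. Rf-only high-γ coupling (s2→s3, 85 Hz) during Response;
3. generalized-context β coupling (s4→s5, 18 Hz) during Context for the
   social contexts {Ch, Cm};
4. its Rf-gated re-activation (s4→s5, 18 Hz) during Response;
5. a reversed-direction α/low-β coupling (s1→s0, 11 Hz) during Response,
   gated on C+ ∧ Rf.

All condition-dependent couplings act only on C+ trials (perceived context),
so C+ vs C− contrasts are informative as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (
    CONDITIONS,
    CONTEXTS,
    RESPONSES,
    TRIAL_TYPES,
    ScenarioLabel,
    TaskTimeline,
    TrialRecording,
)

__all__ = [
    "CouplingEntry",
    "PlantedStructure",
    "CouplingSchedule",
    "GroundTruth",
    "build_schedule",
    "default_effect_spec",
    "make_ground_truth",
    "generate_gaze",
    "simulate_trials",
    "simulate_dataset",
    "var_coefficients",
    "companion_spectral_radius",
]


@dataclass(frozen=True)
class CouplingEntry:
    """One scheduled directed coupling: a lag-1 AR coefficient from
    ``source`` to ``sink`` active during ``interval`` (seconds,
    trial-relative) for trials matching the context/response/condition sets."""

    source: int
    sink: int
    band_hz: float
    bandwidth_hz: float
    strength: float
    interval: tuple[float, float]
    contexts: frozenset = frozenset(CONTEXTS)
    responses: frozenset = frozenset(RESPONSES)
    conditions: frozenset = frozenset(CONDITIONS)

    def active_for(self, label: ScenarioLabel, condition: str) -> bool:
        return (
            label.context in self.contexts
            and label.response in self.responses
            and condition in self.conditions
        )


@dataclass(frozen=True)
class PlantedStructure:
    """Ground-truth bookkeeping for one planted structure (used by
    recovery tests, never by the analysis)."""

    name: str
    source: int
    sink: int
    band_hz: float
    interval: tuple[float, float]
    contexts: frozenset
    responses: frozenset
    conditions: frozenset


@dataclass
class CouplingSchedule:
    """A stability-checked set of coupling entries over ``n_sources``
    resonator sources."""

    n_sources: int
    fs: float
    trial_len: float
    entries: list[CouplingEntry]
    resonance_hz: np.ndarray
    resonance_bw_hz: np.ndarray
    structures: list[PlantedStructure] = field(default_factory=list)

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    def innovation_scales(self) -> np.ndarray:
        """Per-source innovation SDs that equalize the stationary variance
        of the uncoupled resonators at 1 (analytic AR(2) variance)."""
        out = np.empty(self.n_sources)
        for j in range(self.n_sources):
            a1, a2 = _resonator_ar2(
                self.resonance_hz[j], self.resonance_bw_hz[j], self.fs
            )
            v = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
            out[j] = 1.0 / np.sqrt(v)
        return out


@dataclass
class GroundTruth:
    """Mixing matrix and schedule behind one synthetic subject."""

    mixing: np.ndarray  # (n_channels, n_sources)
    schedule: CouplingSchedule
    seed: int
    noise_sd: float = 0.5

    def __post_init__(self):
        if np.linalg.matrix_rank(self.mixing) < self.mixing.shape[1]:
            raise ValueError("mixing matrix must have full column rank")
        if self.schedule.n_structures < 0:
            raise ValueError("planted structure count must be >= 0")


def _resonator_ar2(f0: float, bw: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients with poles r·e^{±iθ}: resonance at f0 Hz,
    half-power bandwidth ≈ bw Hz via r = exp(−π·bw/fs)."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * f0 / fs
    return 2 * r * np.cos(theta), -(r**2)


def _baseline_coefficients(schedule: "CouplingSchedule") -> tuple[np.ndarray, np.ndarray]:
    """Diagonal resonator coefficient matrices (no couplings)."""
    k = schedule.n_sources
    a1 = np.zeros((k, k))
    a2 = np.zeros((k, k))
    for j in range(k):
        c1, c2 = _resonator_ar2(
            schedule.resonance_hz[j], schedule.resonance_bw_hz[j], schedule.fs
        )
        a1[j, j] = c1
        a2[j, j] = c2
    return a1, a2


def var_coefficients(
    schedule: CouplingSchedule,
    label: ScenarioLabel,
    condition: str,
    t_seconds: float,
) -> list[np.ndarray]:
    """Assembled VAR coefficient matrices [A1, A2] at one time point for
    one trial type.  A1/A2 carry the diagonal resonator terms; active
    couplings add to the off-diagonal of A1."""
    a1, a2 = _baseline_coefficients(schedule)
    a1 = a1.copy()
    for e in schedule.entries:
        if e.active_for(label, condition) and e.interval[0] <= t_seconds < e.interval[1]:
            a1[e.sink, e.source] += e.strength
    return [a1, a2]


def companion_spectral_radius(coeffs: Sequence[np.ndarray]) -> float:
    """Spectral radius of the VAR companion matrix (stability iff < 1)."""
    k = coeffs[0].shape[0]
    p = len(coeffs)
    comp = np.zeros((k * p, k * p))
    comp[:k] = np.hstack(coeffs)
    if p > 1:
        comp[k:, : k * (p - 1)] = np.eye(k * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def default_effect_spec() -> list[dict]:
    """The five default planted structures as a declarative effect spec."""
    ctx_interval = (2.5, 4.0)
    resp_interval = (4.0, 7.0)
    return [
        dict(
            name="context-graded-beta",
            source=0,
            sink=1,
            band_hz=20.0,
            interval=ctx_interval,
            strengths={"Ch": 0.30, "Cm": 0.20, "Cw": 0.10},
            responses=("Rf", "Rn"),
            conditions=("Cplus",),
        ),
        dict(
            name="rf-high-gamma",
            source=2,
            sink=3,
            band_hz=85.0,
            interval=resp_interval,
            strengths={"Ch": 0.28, "Cm": 0.28, "Cw": 0.28},
            responses=("Rf",),
            conditions=("Cplus",),
        ),
        dict(
            name="generalized-context-beta",
            source=4,
            sink=5,
            band_hz=18.0,
            interval=ctx_interval,
            strengths={"Ch": 0.28, "Cm": 0.28},
            responses=("Rf", "Rn"),
            conditions=("Cplus",),
        ),
        dict(
            name="reactivation-beta",
            source=4,
            sink=5,
            band_hz=18.0,
            interval=resp_interval,
            strengths={"Ch": 0.28, "Cm": 0.28},
            responses=("Rf",),
            conditions=("Cplus",),
        ),
        dict(
            name="reversed-alpha",
            source=1,
            sink=0,
            band_hz=11.0,
            interval=resp_interval,
            strengths={"Ch": 0.28, "Cm": 0.28, "Cw": 0.28},
            responses=("Rf",),
            conditions=("Cplus",),
        ),
    ]


#: Default source resonance centers (Hz).  Drivers sit at the bands their
#: planted couplings transmit; receivers get neutral placements.
DEFAULT_RESONANCE_HZ = (20.0, 11.0, 85.0, 55.0, 18.0, 30.0)


def build_schedule(
    effects: Optional[list[dict]] = None,
    n_sources: int = 6,
    fs: float = 250.0,
    trial_len: float = 8.0,
    resonance_hz: Optional[Sequence[float]] = None,
    resonance_bw_hz: float | Sequence[float] = 6.0,
    timeline: Optional[TaskTimeline] = None,
) -> CouplingSchedule:
    """Build and stability-check a coupling schedule.

    ``effects=None`` uses the default five-structure spec; ``effects=[]``
    yields baseline-only dynamics.  Raises ValueError with a stability
    report if any assembled per-window VAR has companion spectral
    radius ≥ 1.
    """
    if effects is None:
        effects = default_effect_spec()
    timeline = timeline or TaskTimeline()
    if resonance_hz is None:
        resonance_hz = DEFAULT_RESONANCE_HZ[:n_sources]
        if len(resonance_hz) < n_sources:
            extra = np.linspace(8, 0.4 * fs, n_sources - len(resonance_hz))
            resonance_hz = tuple(resonance_hz) + tuple(extra)
    resonance_hz = np.asarray(resonance_hz, dtype=float)
    bw = np.broadcast_to(np.asarray(resonance_bw_hz, dtype=float), (n_sources,)).copy()
    nyq = fs / 2
    if np.any(resonance_hz <= 0) or np.any(resonance_hz >= nyq):
        raise ValueError("resonance frequencies must lie in (0, Nyquist)")

    entries: list[CouplingEntry] = []
    structures: list[PlantedStructure] = []
    for eff in effects:
        if eff["band_hz"] <= 0 or eff["band_hz"] >= nyq:
            raise ValueError(f"band {eff['band_hz']} Hz outside (0, Nyquist)")
        t0, t1 = eff["interval"]
        if not (0 <= t0 < t1 <= trial_len):
            raise ValueError(f"interval {eff['interval']} outside trial")
        if eff["source"] == eff["sink"]:
            raise ValueError("self-couplings are not allowed")
        responses = frozenset(eff.get("responses", RESPONSES))
        conditions = frozenset(eff.get("conditions", CONDITIONS))
        for ctx, s in eff["strengths"].items():
            entries.append(
                CouplingEntry(
                    source=eff["source"],
                    sink=eff["sink"],
                    band_hz=eff["band_hz"],
                    bandwidth_hz=eff.get("bandwidth_hz", 6.0),
                    strength=float(s),
                    interval=(float(t0), float(t1)),
                    contexts=frozenset({ctx}),
                    responses=responses,
                    conditions=conditions,
                )
            )
        structures.append(
            PlantedStructure(
                name=eff["name"],
                source=eff["source"],
                sink=eff["sink"],
                band_hz=eff["band_hz"],
                interval=(float(t0), float(t1)),
                contexts=frozenset(eff["strengths"].keys()),
                responses=responses,
                conditions=conditions,
            )
        )

    schedule = CouplingSchedule(
        n_sources=n_sources,
        fs=fs,
        trial_len=trial_len,
        entries=entries,
        resonance_hz=resonance_hz,
        resonance_bw_hz=bw,
        structures=structures,
    )

    # stability: check every (trial type, condition) at each interval edge
    breakpoints = sorted({0.0} | {t for e in entries for t in e.interval})
    unstable = []
    for tt in TRIAL_TYPES:
        label = ScenarioLabel(tt[:2], tt[2:])
        for cond in CONDITIONS:
            for t in breakpoints:
                rho = companion_spectral_radius(var_coefficients(schedule, label, cond, t))
                if rho >= 1.0:
                    unstable.append((tt, cond, t, rho))
    if unstable:
        lines = ", ".join(f"{tt}/{c} at {t:.2f}s ρ={r:.3f}" for tt, c, t, r in unstable[:5])
        raise ValueError(f"unstable schedule: {lines}")
    return schedule


def make_ground_truth(
    n_channels: int,
    schedule: CouplingSchedule,
    seed: int,
    noise_sd: float = 0.5,
) -> GroundTruth:
    """Random well-conditioned mixing (channels × sources)."""
    k = schedule.n_sources
    if n_channels < k:
        raise ValueError("channel count must be >= source count (mixing not injective)")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, k)))
    scales = rng.uniform(0.7, 1.3, size=k)
    return GroundTruth(mixing=q * scales, schedule=schedule, seed=seed, noise_sd=noise_sd)


def generate_gaze(
    fractions: Sequence[float],
    duration: float,
    screening_window: tuple[float, float],
    seed: int,
    gaze_fs: float = 30.0,
    screen_halfwidth_deg: float = 20.0,
) -> np.ndarray:
    """30 Hz 2-D gaze traces whose realized on-screen fraction inside the
    screening window matches each target within one sample.

    Returns (n_trials, n_samples, 2) in degrees; off-screen excursions sit
    outside ±screen_halfwidth_deg.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * gaze_fs))
    w0 = int(round(screening_window[0] * gaze_fs))
    w1 = int(round(screening_window[1] * gaze_fs))
    n_win = w1 - w0
    out = rng.uniform(-0.5, 0.5, size=(len(fractions), n_samp, 2)) * screen_halfwidth_deg
    for i, f in enumerate(fractions):
        n_on = int(round(f * n_win))
        off_idx = w0 + rng.permutation(n_win)[n_on:]
        out[i, off_idx, :] = np.sign(rng.standard_normal((len(off_idx), 2))) * (
            screen_halfwidth_deg * 1.4
        )
    return out


def _simulate_group(
    schedule: CouplingSchedule,
    label: ScenarioLabel,
    condition: str,
    n_trials: int,
    n_samples: int,
    rng: np.random.Generator,
    burn_in: int = 250,
) -> np.ndarray:
    """Simulate all trials of one (trial type, condition) group at once."""
    k = schedule.n_sources
    fs = schedule.fs
    x = np.zeros((n_trials, k, n_samples + burn_in))
    noise = rng.standard_normal((n_trials, k, n_samples + burn_in))
    noise *= schedule.innovation_scales()[None, :, None]
    # coefficient matrices per distinct active-coupling set (burn-in runs
    # pre-trial baseline dynamics at negative trial time)
    base_a1, base_a2 = _baseline_coefficients(schedule)
    coeff_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    coeff_at = []
    t_sec = (np.arange(n_samples + burn_in) - burn_in) / fs
    for t in t_sec:
        key = tuple(
            e.active_for(label, condition) and e.interval[0] <= t < e.interval[1]
            for e in schedule.entries
        )
        if key not in coeff_cache:
            a1 = base_a1.copy()
            for e, on in zip(schedule.entries, key):
                if on:
                    a1[e.sink, e.source] += e.strength
            coeff_cache[key] = (a1, base_a2)
        coeff_at.append(coeff_cache[key])
    for t in range(2, n_samples + burn_in):
        a1, a2 = coeff_at[t]
        x[:, :, t] = (
            x[:, :, t - 1] @ a1.T + x[:, :, t - 2] @ a2.T + noise[:, :, t]
        )
    return x[:, :, burn_in:]


def simulate_trials(
    schedule: CouplingSchedule,
    truth: GroundTruth,
    n_trials_per_type: int,
    seed: int,
    timeline: Optional[TaskTimeline] = None,
    p_cplus: float = 0.5,
    artifact_fraction: float = 0.05,
    artifact_gain: float = 5.0,
    gain_jitter: float = 0.25,
    subject: str = "S1",
    return_truth_info: bool = False,
):
    """Simulate a full trial-labelled recording for one subject.

    Trials are generated for all six scenario types.  Each trial is assigned
    a target condition (C+ with probability ``p_cplus``); the gaze trace is
    constructed to realize it, and downstream screening re-derives the
    condition from gaze alone.  ``artifact_fraction`` of trials receive a
    0.5 s broadband burst at ``artifact_gain``× the channel SD.
    ``gain_jitter`` applies a lognormal per-trial amplitude factor
    (exp N(0, jitter)) to the whole source vector, emulating trial-to-trial
    cortical power fluctuation; as a common scale it leaves the VAR
    causality structure untouched.

    Identical seeds give bit-identical output.
    """
    if n_trials_per_type < 2:
        raise ValueError("need at least 2 trials per type")
    timeline = timeline or TaskTimeline()
    rng = np.random.default_rng(seed)
    fs = schedule.fs
    n_samples = int(round(schedule.trial_len * fs))
    n_ch = truth.mixing.shape[0]

    labels: list[ScenarioLabel] = []
    intended_cond: list[str] = []
    for tt in TRIAL_TYPES:
        for _ in range(n_trials_per_type):
            labels.append(ScenarioLabel(tt[:2], tt[2:]))
            intended_cond.append("Cplus" if rng.random() < p_cplus else "Cminus")
    n_trials = len(labels)

    sources = np.zeros((n_trials, schedule.n_sources, n_samples))
    for tt in TRIAL_TYPES:
        for cond in CONDITIONS:
            idx = [
                i
                for i, (lab, c) in enumerate(zip(labels, intended_cond))
                if lab.trial_type == tt and c == cond
            ]
            if not idx:
                continue
            grp = _simulate_group(
                schedule, labels[idx[0]], cond, len(idx), n_samples, rng
            )
            sources[idx] = grp

    if gain_jitter > 0:
        gains = np.exp(gain_jitter * rng.standard_normal(n_trials))
        sources = sources * gains[:, None, None]

    data = np.einsum("cs,tsn->tcn", truth.mixing, sources)
    data += truth.noise_sd * rng.standard_normal(data.shape)

    # artifact bursts
    n_art = int(round(artifact_fraction * n_trials))
    art_idx = rng.permutation(n_trials)[:n_art]
    burst_len = int(round(0.5 * fs))
    ch_sd = data.std(axis=(0, 2))
    for i in art_idx:
        start = rng.integers(0, n_samples - burst_len)
        data[i, :, start : start + burst_len] += (
            artifact_gain * ch_sd[:, None] * rng.standard_normal((n_ch, burst_len))
        )

    # gaze realizing the intended condition through strict >80% screening
    frac_targets = np.where(np.array(intended_cond) == "Cplus", 0.97, 0.5)
    win = (timeline.context_start, timeline.context_start + 0.5)
    gaze = generate_gaze(
        frac_targets, schedule.trial_len, win, seed=int(rng.integers(2**31))
    )

    rec = TrialRecording(
        data=data,
        fs=fs,
        labels=labels,
        timeline=timeline,
        gaze=gaze,
        subject=subject,
    )
    if return_truth_info:
        return rec, {
            "intended_condition": intended_cond,
            "artifact_trials": sorted(int(i) for i in art_idx),
            "sources": sources,
        }
    return rec


def simulate_dataset(
    n_subjects: int = 3,
    n_channels: int = 12,
    n_sources: int = 6,
    n_trials_per_type: int = 120,
    fs: float = 250.0,
    trial_len: float = 8.0,
    seed: int = 0,
    effects: Optional[list[dict]] = None,
    **kwargs,
) -> tuple[list[TrialRecording], list[GroundTruth]]:
    """Multi-subject convenience wrapper around :func:`simulate_trials`."""
    schedule = build_schedule(effects=effects, n_sources=n_sources, fs=fs, trial_len=trial_len)
    recs, truths = [], []
    for s in range(n_subjects):
        truth = make_ground_truth(n_channels, schedule, seed=seed * 1000 + s)
        rec = simulate_trials(
            schedule,
            truth,
            n_trials_per_type,
            seed=seed * 1000 + 500 + s,
            subject=f"S{s + 1}",
            **kwargs,
        )
        recs.append(rec)
        truths.append(truth)
    return recs, truths
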