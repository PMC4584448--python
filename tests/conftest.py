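"""Shared fixtures: small synthetic datasets and pipeline runs.

Everything is generated programmatically at collection time; the heavier
end-to-end pipeline products are session-scoped so several tests can share
one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from latnets import synthetic_data as sd
from latnets import workflow_io as w
from latnets.types import TaskTimeline, TrialRecording, ScenarioLabel


@pytest.fixture(scope="session")
def default_schedule():
    return sd.build_schedule()


@pytest.fixture(scope="session")
def small_recording(default_schedule):
    """One subject, 8 channels, 6 sources, 8 trials/type — fast unit-test
    sized recording with gaze and artifacts."""
    truth = sd.make_ground_truth(8, default_schedule, seed=11)
    rec, info = sd.simulate_trials(
        default_schedule, truth, n_trials_per_type=8, seed=11, return_truth_info=True
    )
    return rec, truth, info


def make_tiny_config(seed: int) -> w.PipelineConfig:
    """The desk-scale end-to-end configuration used by integration tests."""
    return w.PipelineConfig.from_dict(
        {
            "seed": seed,
            "simulate": {
                "n_subjects": 1,
                "n_channels": 8,
                "n_sources": 6,
                "n_trials_per_type": 48,
            },
            "causality": {"step_ms": 500, "n_freqs": 10, "p": 4, "f_max": 110},
            "erc": {"n_boot": 200, "min_trials": 12},
            "infer": {"n_shuffles": 40, "shuffle_n_boot": 60},
        }
    )


@pytest.fixture(scope="session")
def tiny_pipeline_products():
    """Full chain on the tiny config, seed 1: subject data, tensor, PARAFAC
    model, significance — shared by the integration-level tests."""
    from latnets import structure_inference as si
    from latnets import tensor_factorization as tf

    seed = 1
    cfg = make_tiny_config(seed)
    recs, truths = sd.simulate_dataset(
        n_subjects=2,
        n_channels=8,
        n_sources=6,
        n_trials_per_type=72,
        seed=seed,
    )
    subjects = []
    reports = []
    for i, rec in enumerate(recs):
        subj, report = w.prepare_subject(rec, cfg, seed=seed + 17 * i)
        subjects.append(subj)
        reports.append(report)
    builder = w.DeltaTensorBuilder(subjects, cfg.erc, seed=seed, shuffle_n_boot=60)
    tensor = builder.build()
    axes = builder.axes
    model = tf.parafac(tensor, 5, n_restarts=20, seed=seed, compute_corcondia=True)
    sig = si.loading_significance(
        lambda rng: builder.build(rng), tensor, model, n_shuffles=40, seed=seed + 999
    )
    return {
        "cfg": cfg,
        "recordings": recs,
        "truths": truths,
        "subjects": subjects,
        "reports": reports,
        "builder": builder,
        "tensor": tensor,
        "axes": axes,
        "model": model,
        "significance": sig,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_labelled_recording(
    n_trials=12, n_channels=3, n_samples=400, fs=100.0, seed=0, gaze=False
) -> TrialRecording:
    """Plain noise recording with cycling labels (no planted structure)."""
    rng = np.random.default_rng(seed)
    labels = []
    types = ["Ch", "Cm", "Cw"]
    for i in range(n_trials):
        labels.append(ScenarioLabel(types[i % 3], "Rf" if i % 2 else "Rn"))
    g = None
    if gaze:
        g = rng.uniform(-10, 10, size=(n_trials, int(n_samples / fs * 30), 2))
    return TrialRecording(
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        fs=fs,
        labels=labels,
        timeline=TaskTimeline(
            waiting=1.0, context=1.0, response=1.0, baseline=(0.1, 0.9)
        )
        if n_samples / fs < 7
        else TaskTimeline(),
        gaze=g,
        subject="T1",
    )
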