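"""End-to-end orchestration: simulate -> preprocess -> decompose -> label ->
train -> evaluate.

This is the library-level counterpart of the CLI's ``run-all``: every stage
is a plain function over the other modules so the pipeline is scriptable
and each intermediate is inspectable. All randomness flows from one master
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import (ClassifierSpec, TrainConfig, build_conv_bilstm,
                          build_conv_lstm, gnb_baseline, knn_baseline,
                          knn_scores, predict, train_model)
from .dataset import (SplitConfig, WindowedSample, as_arrays,
                      make_splits, windows_from_decomposition)
from .emd import EEMDConfig, IMFDecomposition, eemd
from .evaluation import MetricsReport, aggregate_repeats, confusion_metrics
from .features import feature_matrix
from .preprocess import preprocess
from .synth import ActivityProfile, SyntheticRecording, generate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 20
    activities: tuple[str, ...] = ("resting", "outstretching", "wing",
                                   "drinking")
    body_parts: tuple[str, ...] = ("lower_arm",)
    axes: tuple[str, ...] = ("roll",)
    eemd: EEMDConfig = field(default_factory=EEMDConfig)
    tremor_imf_indices: tuple[int, ...] = (1, 2)
    split: SplitConfig = field(default_factory=SplitConfig)
    spec: ClassifierSpec = field(default_factory=ClassifierSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0


def decompose_recording(rec: SyntheticRecording,
                        eemd_cfg: EEMDConfig) -> IMFDecomposition:
    """Preprocess the mixed channel and run EEMD on it."""
    clean = preprocess(rec.mixed)
    cfg = EEMDConfig(emd=eemd_cfg.emd, n_ensembles=eemd_cfg.n_ensembles,
                     noise_std_ratio=eemd_cfg.noise_std_ratio,
                     seed=eemd_cfg.seed + rec.seed % (2 ** 20))
    return eemd(clean.values, cfg)


def build_cohort_windows(cfg: PipelineConfig
                         ) -> tuple[list[WindowedSample],
                                    list[SyntheticRecording],
                                    list[IMFDecomposition]]:
    """Simulate the cohort, decompose every channel, window and label."""
    profiles = [ActivityProfile.default(a) for a in cfg.activities]
    recordings, _ = generate_cohort(cfg.n_subjects, profiles, cfg.seed,
                                    body_parts=cfg.body_parts, axes=cfg.axes)
    samples: list[WindowedSample] = []
    decomps: list[IMFDecomposition] = []
    for rec_id, rec in enumerate(recordings):
        dec = decompose_recording(rec, cfg.eemd)
        decomps.append(dec)
        samples.extend(windows_from_decomposition(
            dec, recording_id=rec_id,
            tremor_imf_indices=frozenset(cfg.tremor_imf_indices),
            subject=rec.mixed.meta.get("subject", -1),
            activity=rec.profile.name))
    return samples, recordings, decomps


def _window_scale(X_train: np.ndarray) -> float:
    """Global scale applied to network inputs: the training windows' overall
    std. One constant for the whole dataset (per-window scaling would
    destroy the amplitude cue separating tremor from voluntary modes)."""
    sd = float(X_train.std())
    return sd if sd > 0 else 1.0


def train_and_evaluate(samples: list[WindowedSample],
                       cfg: PipelineConfig,
                       models: tuple[str, ...] = ("conv_bilstm",),
                       fs: float = 100.0,
                       ) -> dict[str, list[MetricsReport]]:
    """Run the re-training protocol for the requested models.

    Returns one MetricsReport per split repeat per model. Feature-based
    baselines (knn, gnb) share feature computation per repeat.
    """
    splits = make_splits(samples, cfg.split)
    reports: dict[str, list[MetricsReport]] = {m: [] for m in models}
    need_features = any(m in ("knn", "gnb") for m in models)
    for rep, (train_s, test_s) in enumerate(splits):
        X_tr, y_tr = as_arrays(train_s)
        X_te, y_te = as_arrays(test_s)
        if need_features:
            F_tr = feature_matrix(train_s, fs)
            F_te = feature_matrix(test_s, fs)
        for name in models:
            if name in ("conv_bilstm", "conv_lstm"):
                build = (build_conv_bilstm if name == "conv_bilstm"
                         else build_conv_lstm)
                model = build(cfg.spec, seed=cfg.train.seed + rep)
                scale = _window_scale(X_tr)
                train_model(model, X_tr / scale, y_tr,
                            TrainConfig(learning_rate=cfg.train.learning_rate,
                                        epochs=cfg.train.epochs,
                                        batch_size=cfg.train.batch_size,
                                        seed=cfg.train.seed + rep))
                scores, y_hat = predict(model, X_te / scale,
                                        cfg.train.decision_threshold)
            elif name == "knn":
                y_hat = knn_baseline(F_tr, y_tr, F_te)
                scores = knn_scores(F_tr, y_tr, F_te)
            elif name == "gnb":
                y_hat, scores = gnb_baseline(F_tr, y_tr, F_te,
                                             return_proba=True)
            else:
                raise ValueError(f"unknown model {name!r}")
            reports[name].append(confusion_metrics(y_te, y_hat, scores))
    return reports


def run_all(cfg: PipelineConfig,
            models: tuple[str, ...] = ("conv_bilstm", "knn", "gnb"),
            ) -> dict:
    """Full pipeline; returns a JSON-serializable summary."""
    samples, recordings, decomps = build_cohort_windows(cfg)
    reports = train_and_evaluate(samples, cfg, models=models)
    summary = {
        "n_recordings": len(recordings),
        "n_windows": len(samples),
        "positive_fraction": float(np.mean([s.label for s in samples])),
        "models": {},
    }
    for name, reps in reports.items():
        summary["models"][name] = {
            "per_repeat": [r.as_dict() for r in reps],
            "aggregate": (aggregate_repeats(reps) if len(reps) >= 2
                          else None),
        }
    return summary
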