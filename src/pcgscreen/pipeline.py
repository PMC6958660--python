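"""End-to-end runner: synthesize -> segment -> frame -> cross-validate.

One master seed fans out to per-stage seed streams (synthesis, emission
training, CV splitting, model training) via ``numpy.random.SeedSequence``,
so each stage is independently reproducible and running the stages by hand
with the same derived seeds gives the identical report.
"""

from __future__ import annotations

import numpy as np

from . import evaluation, models, segmentation, synth
from .framing import build_dataset
from .io import PipelineConfig
from .preprocess import resample


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    names = ("synth", "emissions", "cv", "train")
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))}


def train_default_emissions(config: PipelineConfig, seed: int,
                            n_per_class: int = 2) -> segmentation.EmissionModel:
    """Fit HSMM emissions on a small synthetic set with known state paths."""
    base = synth.SynthConfig(n_cycles=max(8, config.n_cycles // 2),
                             snr_db=config.snr_db, rng_seed=seed)
    recs = synth.generate_dataset({c: n_per_class for c in ("normal", "HFpEF", "HFrEF")},
                                  base)
    feats, paths = [], []
    for rec in recs:
        work = resample(rec, config.target_rate_hz)
        f = segmentation.extract_envelope_features(work, config.feature_rate_hz)
        feats.append(f)
        paths.append(segmentation.state_path_at_feature_rate(
            work, config.feature_rate_hz, f.n_ticks))
    return segmentation.fit_emissions(feats, paths)


def run_end_to_end(config: PipelineConfig) -> evaluation.CvReport:
    """Full pipeline on synthetic data, returning the cross-validation report."""
    seeds = derive_stage_seeds(config.seed)
    base = synth.SynthConfig(n_cycles=config.n_cycles, snr_db=config.snr_db,
                             rng_seed=seeds["synth"])
    recordings = synth.generate_dataset(
        {c: config.recordings_per_class for c in ("normal", "HFpEF", "HFrEF")}, base)

    emissions = None
    if not config.use_true_onsets:
        emissions = train_default_emissions(config, seeds["emissions"])
    dataset = build_dataset(recordings, config, emissions)

    plan = evaluation.make_cv_plan(
        dataset.y(), k=config.cv_folds, seed=seeds["cv"],
        stratified=config.stratified, grouping=config.grouping,
        groups=dataset.groups() if config.grouping == "recording" else None,
        val_fraction=config.validation_fraction_of_train)
    tc = models.TrainConfig(learning_rate=config.learning_rate,
                            l2_lambda=config.l2_lambda,
                            batch_size=config.batch_size, epochs=config.epochs,
                            n_layers=config.n_layers, units=config.units,
                            rng_seed=seeds["train"], chunk_size=config.chunk_size)
    report = evaluation.evaluate_model(config.model_name, dataset, plan, tc)
    report.manifest["stage_seeds"] = seeds
    report.manifest["master_seed"] = config.seed
    report.manifest["frame_length_s"] = config.frame_length_s
    report.manifest["n_frames"] = len(dataset)
    report.manifest["class_counts"] = dataset.class_counts
    return report
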