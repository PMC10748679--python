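"""End-to-end runner tying synthesis, QC, extraction and validation together.

One master seed fans out to per-stage seeds through a counter-based
``SeedSequence`` scheme, so any stage can be re-run in isolation and the
whole bundle is deterministic given the configuration. The run log records
wall-clock timestamps and therefore sits outside the determinism guarantee,
which covers the result files.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as sio
from .audio import AudioSample, read_wav, write_wav
from .clinical import (
    assign_subgroups,
    association_matrix,
    bonferroni_threshold,
    cluster_association_matrix,
    ff_test,
    subgroup_sizes,
    train_basisvae,
)
from .clinical.basisvae import BasisVAEConfig
from .cohort import DEFAULT_MISSING, CohortSpec, simulate_cohort
from .analytical import biplot_data, scca_pmd, spearman_matrix
from .features import extract_features, extract_reference_features
from .preprocess import qc_gate
from .synth import DDKSpec, PassageSpec, VoiceSpec, synth_ddk, synth_passage, synth_vowel

STAGES = ("synth", "qc", "extract", "analytical", "clinical")


class RunConfig(BaseModel):
    """Schema-validated configuration for a full pipeline run."""

    out_dir: str
    master_seed: int = 0
    tasks: list = Field(default_factory=lambda: ["phonation", "ddk", "passage"])
    n_recordings: int = Field(default=6, ge=2)
    cohort_n: int = Field(default=122, ge=20)
    cohort_effect_size: float = Field(default=1.0, ge=0.0)
    snr_threshold_db: float = 30.0
    scca_penalty_frac: float = Field(default=0.6, gt=0.0, le=1.0)
    vae_epochs: int = Field(default=2000, ge=10)
    vae_max_clusters: int = Field(default=3, ge=1)
    ff_n_perm: int = Field(default=1000, ge=100)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def stage_seed(master_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation from the master seed."""
    return int(
        np.random.SeedSequence([master_seed, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31)
    )


class RunLog:
    """Append-only line-delimited JSON log of pipeline stages."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.write_text("")

    def record(self, stage: str, **info) -> None:
        entry = {"stage": stage, "timestamp": time.time(), **info}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _planted_grid(n: int, seed: int):
    """Per-recording planted voice/DDK parameters spanning a mild range."""
    rng = np.random.default_rng(seed)
    jitter = np.linspace(0.3, 2.5, n)
    shimmer = np.linspace(1.0, 8.0, n)
    hnr = np.linspace(25.0, 12.0, n)
    rate = np.linspace(5.5, 3.0, n)
    ctv = np.linspace(0.005, 0.04, n)
    return jitter, shimmer, hnr, rate, ctv, rng


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a manifest of produced artifact paths.

    Any stage failure leaves earlier outputs in place and re-raises; the CLI
    converts that into a nonzero exit status.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "run_log.jsonl")
    manifest: dict = {}

    # --- synth ---
    seed = stage_seed(config.master_seed, "synth")
    log.record("synth", seed=seed, n_recordings=config.n_recordings)
    audio_dir = out / "audio"
    audio_dir.mkdir(exist_ok=True)
    jitter, shimmer, hnr, rate, ctv, grid_rng = _planted_grid(config.n_recordings, seed)

    def with_lead(audio):
        """Prepend 0.5 s of room tone so QC has a noise region to estimate."""
        lead = grid_rng.normal(0.0, 1e-3, int(0.5 * audio.fs_hz))
        return AudioSample(
            np.clip(np.concatenate([lead, audio.samples]), -1, 1),
            audio.fs_hz,
            audio.bit_depth,
            audio.task,
        )

    recordings = []  # (rec_id, task, path, transcript_meta)
    for i in range(config.n_recordings):
        if "phonation" in config.tasks:
            audio, _ = synth_vowel(
                VoiceSpec(
                    f0_hz=110.0 + 15.0 * i,
                    duration_s=2.5,
                    jitter_pct=jitter[i],
                    shimmer_pct=shimmer[i],
                    hnr_db=hnr[i],
                    seed=seed + i,
                )
            )
            path = audio_dir / f"rec{i:02d}_phonation.wav"
            write_wav(path, with_lead(audio))
            recordings.append((f"rec{i:02d}", "phonation", path, None))
        if "ddk" in config.tasks:
            audio, side = synth_ddk(
                DDKSpec(rate_syll_per_s=rate[i], ctv_s=ctv[i], n_syll=18, seed=seed + i)
            )
            path = audio_dir / f"rec{i:02d}_ddk.wav"
            write_wav(path, with_lead(audio))
            meta = {"n_words": int(side.syllable_onsets_s.size)}
            recordings.append((f"rec{i:02d}", "ddk", path, meta))
        if "passage" in config.tasks:
            audio, _, meta = synth_passage(
                PassageSpec(
                    speech_segment_durations_s=(3.0, 2.5, 3.5),
                    pause_durations_s=(0.3 + 0.05 * i, 0.9),
                    n_words=99,
                    seed=seed + i,
                )
            )
            path = audio_dir / f"rec{i:02d}_passage.wav"
            write_wav(path, with_lead(audio))
            recordings.append((f"rec{i:02d}", "passage", path, meta))
    missing = {
        k: int(round(v * config.cohort_n / 122))
        for k, v in DEFAULT_MISSING.items()
    }
    feats_cohort, clin = simulate_cohort(
        CohortSpec(
            n=config.cohort_n,
            effect_size=config.cohort_effect_size,
            missing_counts=missing,
            seed=seed,
        )
    )
    sio.write_feature_table(feats_cohort, out / "cohort_features.csv")
    sio.write_clinical_table(clin, out / "cohort_clinical.csv")
    manifest["cohort_features"] = str(out / "cohort_features.csv")
    manifest["cohort_clinical"] = str(out / "cohort_clinical.csv")

    # --- qc ---
    seed = stage_seed(config.master_seed, "qc")
    qc_results = {}
    kept = []
    for rec_id, task, path, meta in recordings:
        audio = read_wav(path, task=task)
        report = qc_gate(audio)
        qc_results[f"{rec_id}_{task}"] = dataclasses.asdict(report)
        if report.passed or report.snr_db > config.snr_threshold_db:
            kept.append((rec_id, task, path, meta))
        else:
            log.record("qc", excluded=f"{rec_id}_{task}", snr_db=report.snr_db)
    sio.write_json(qc_results, out / "qc_reports.json")
    manifest["qc_reports"] = str(out / "qc_reports.json")
    log.record("qc", seed=seed, n_kept=len(kept), n_total=len(recordings))

    # --- extract ---
    seed = stage_seed(config.master_seed, "extract")
    log.record("extract", seed=seed)
    tables = {}
    for task in config.tasks:
        rows_auto, rows_ref, ids = [], [], []
        for rec_id, rec_task, path, meta in kept:
            if rec_task != task:
                continue
            audio = read_wav(path, task=task)
            rows_auto.append(extract_features(audio, task, meta))
            rows_ref.append(extract_reference_features(audio, task, meta))
            ids.append(rec_id)
        if not ids:
            continue
        auto = pd.DataFrame(rows_auto, index=ids)
        ref = pd.DataFrame(rows_ref, index=ids)
        sio.write_feature_table(auto, out / f"features_{task}_automated.csv")
        sio.write_feature_table(ref, out / f"features_{task}_reference.csv")
        tables[task] = (auto, ref)
        manifest[f"features_{task}"] = str(out / f"features_{task}_automated.csv")

    # --- analytical validation ---
    seed = stage_seed(config.master_seed, "analytical")
    log.record("analytical", seed=seed)
    analytical = {}
    for task, (auto, ref) in tables.items():
        report = spearman_matrix(ref, auto)
        entry = {"n_cells": report.n_cells, "counts": report.counts}
        report.rho.to_csv(out / f"spearman_{task}.csv")
        if auto.shape[0] >= 4:
            scca = scca_pmd(ref, auto, seed=seed)
            entry["canonical_corrs"] = scca.canonical_corrs.tolist()
            biplot_data(scca).to_csv(out / f"biplot_{task}.csv", index=False)
        analytical[task] = entry
    sio.write_json(analytical, out / "analytical_report.json")
    manifest["analytical_report"] = str(out / "analytical_report.json")

    # --- clinical validation ---
    seed = stage_seed(config.master_seed, "clinical")
    log.record("clinical", seed=seed, n_participants=int(clin.shape[0]))
    groups = assign_subgroups(clin)
    vae_cfg = BasisVAEConfig(epochs=config.vae_epochs, max_clusters=config.vae_max_clusters)
    outputs = train_basisvae(
        feats_cohort, max_clusters=config.vae_max_clusters, seed=seed, config=vae_cfg
    )
    outputs.embeddings.to_csv(out / "embeddings.csv")
    outputs.cluster_probs.to_csv(out / "feature_clusters.csv")
    n_tests = groups.shape[1] * len(config.tasks)
    threshold = bonferroni_threshold(0.05, n_tests)
    ff_results = {}
    emb = outputs.embeddings.to_numpy()
    for k, measure in enumerate(groups.columns):
        lab = groups[measure]
        cats = [c for c in lab.dropna().unique()]
        if len(cats) != 2:
            continue
        a = emb[(lab == cats[0]).to_numpy()]
        b = emb[(lab == cats[1]).to_numpy()]
        if a.shape[0] < 3 or b.shape[0] < 3:
            continue
        res = ff_test(a, b, n_perm=config.ff_n_perm, seed=seed + k)
        ff_results[measure] = {
            "distance": res.distance,
            "p_value": res.p_value,
            "significant": res.p_value < threshold,
            "n_more": int(min(a.shape[0], b.shape[0])),
            "n_less": int(max(a.shape[0], b.shape[0])),
        }
    assoc = association_matrix(outputs.predictions, groups)
    clustered = cluster_association_matrix(assoc)
    assoc.values.to_csv(out / "association_matrix.csv")
    clustered.display.to_csv(out / "association_display.csv")
    sio.write_json(
        {
            "bonferroni_threshold": threshold,
            "ff_tests": ff_results,
            "n_clusters_effective": outputs.n_clusters_effective,
            "subgroup_sizes": subgroup_sizes(groups).to_dict(),
            "row_order": clustered.row_order,
            "col_order": clustered.col_order,
        },
        out / "clinical_report.json",
    )
    manifest["clinical_report"] = str(out / "clinical_report.json")
    log.record("done")
    return manifest
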