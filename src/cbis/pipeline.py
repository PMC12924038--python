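"""End-to-end pipeline orchestration: simulate → qc → features → fit →
recommend → evaluate, with config-driven seeding and a run manifest.

A :class:`RunConfig` is a single YAML/JSON document; one global seed is
fanned out deterministically to per-stage seeds, so a persisted config
reproduces a run's deterministic artifacts bit-for-bit.  Every stage writes
its artifacts under the run directory and records a checksum in the
manifest; recommendation audits (Q values, rules fired, confidence verdicts)
are logged as the accountability surface of the human-in-the-loop design.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .diary import write_diary
from .features import (
    adherence_bands,
    build_feature_vector,
    feature_matrix,
    leakage_band,
    prune_collinear,
    stratified_split,
)
from .preprocessing import run_qc
from .prepost import PrePostRecord, build_report
from .rl import (
    BehavioralState,
    PolicyConfig,
    QTable,
    default_safety_rules,
    confidence_gate,
    fit_offline,
    select_action,
    write_transition_log,
)
from .simulator import (
    GreedyPolicy,
    RandomPolicy,
    SimConfig,
    generate_cohort,
    generate_latents,
    rollout,
)

__all__ = ["RunConfig", "run_pipeline", "load_config", "PipelineError"]


class PipelineError(Exception):
    """Typed stage failure; the manifest records the partial run."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "cbis_run"
    version_tag: str = __version__
    # stage configs
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    qc: dict = field(default_factory=lambda: {"iqr_multiplier": 1.5, "window": 60.0})
    rl: dict = field(default_factory=lambda: {
        "alpha": 0.1, "gamma": 0.9, "epsilon": 0.1,
        "tolerance": 1e-4, "sweeps": 500})
    rollout: dict = field(default_factory=lambda: {"horizon": 30, "behavior_seeds": 2})
    eval_window: int = 5
    n_diary_files: int = 3    # example diaries written in both dialects

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise PipelineError("config document must be a mapping")
    return RunConfig.from_dict(doc)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic fan-out of the global seed (each child < 2^31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full closed loop; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": config.version_tag, "seed": config.seed,
        "stages": {}, "artifacts": {}}
    seeds = _stage_seeds(config.seed)

    def _record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {"seconds": round(_time.monotonic() - t0, 3),
                                     **info}

    def _save(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _checksum(path)}

    try:
        # ---- simulate ---------------------------------------------------
        t0 = _time.monotonic()
        sim_cfg = SimConfig(**{"seed": seeds[0], **config.sim})
        diaries = generate_cohort(sim_cfg)
        for i, diary in enumerate(diaries[: config.n_diary_files]):
            for ext in ("csv", "json"):
                p = out / f"diary_{diary.profile.patient_id}.{ext}"
                write_diary(diary, p)
                _save(f"diary_{i}_{ext}", p)
        _record("simulate", t0, n_patients=len(diaries))

        # ---- qc ---------------------------------------------------------
        t0 = _time.monotonic()
        retained = []
        reports = []
        for diary in diaries:
            clean, report, _, _ = run_qc(diary, **config.qc)
            reports.append(report.to_dict())
            if not report.excluded and clean.admitted():
                retained.append((clean, report))
        qc_path = out / "qc_reports.json"
        qc_path.write_text(json.dumps(reports, indent=1))
        _save("qc_reports", qc_path)
        _record("qc", t0, n_retained=len(retained), n_total=len(diaries))
        if not retained:
            raise PipelineError("qc stage retained no patients")

        # ---- features ---------------------------------------------------
        t0 = _time.monotonic()
        vectors = [build_feature_vector(d, r) for d, r in retained]
        matrix = feature_matrix(vectors)
        feat_path = out / "features.tsv"
        matrix.to_csv(feat_path, sep="\t", index_label="patient_id")
        _save("features", feat_path)
        kept, dropped = prune_collinear(matrix)
        leak_rates = {d.profile.patient_id: len(d.leaks) / max(d.span_days, 1)
                      for d, _ in retained}
        adh = adherence_bands({d.profile.patient_id:
                               matrix.loc[d.profile.patient_id, "completion_record_rate"]
                               for d, _ in retained})
        strata = {pid: f"{leakage_band(lr)}|{adh[pid]}"
                  for pid, lr in leak_rates.items()}
        split = stratified_split(list(strata), strata, seed=seeds[1])
        _record("features", t0, n_features_kept=len(kept),
                n_features_dropped=len(dropped),
                split_sizes={p: len(split.ids(p)) for p in
                             ("train", "validation", "test")})

        # ---- transition collection + offline fit ------------------------
        t0 = _time.monotonic()
        latents = generate_latents(sim_cfg)
        horizon = int(config.rollout["horizon"])
        transitions = []
        for k in range(int(config.rollout["behavior_seeds"])):
            res = rollout(RandomPolicy(), latents, horizon, config=sim_cfg,
                          seed=seeds[2] + k)
            transitions.extend(res.transition_rows())
        log_path = out / "transitions.tsv"
        write_transition_log(log_path, transitions)
        _save("transitions", log_path)
        q0 = QTable(alpha=config.rl["alpha"], gamma=config.rl["gamma"])
        fit = fit_offline(q0, [t for _, _, t in transitions],
                          sweeps=config.rl["sweeps"],
                          tolerance=config.rl["tolerance"], seed=seeds[3])
        q_path = out / "qtable.json"
        q_path.write_text(json.dumps(fit.qtable.to_json_dict()))
        _save("qtable", q_path)
        _record("fit", t0, converged=fit.converged, n_sweeps=fit.n_sweeps,
                n_transitions=len(transitions))

        # ---- recommend (audited) ----------------------------------------
        t0 = _time.monotonic()
        rules = default_safety_rules()
        policy = PolicyConfig(epsilon=config.rl["epsilon"], seed=seeds[4])
        rng = np.random.default_rng(seeds[4])
        audits = []
        example_states = sorted({int(s) for s in
                                 np.asarray([t.state_id for _, _, t in
                                             transitions[:200]])})[:10]
        for sid in example_states:
            state = BehavioralState.from_id(sid)
            action, audit = select_action(fit.qtable, state, policy,
                                          constraints=rules, rng=rng)
            verdict, score = confidence_gate(fit.qtable, state, action)
            audits.append({
                "state_id": sid,
                "action": {"pfmt_delta": action.pfmt_delta,
                           "void_interval_delta": action.void_interval_delta,
                           "fluid_plan_adjust": action.fluid_plan_adjust,
                           "maintain": action.maintain},
                "q_values": {str(k): v for k, v in audit.q_values.items()},
                "rules_fired": list(audit.rules_fired),
                "explored": audit.explored,
                "confidence": {"verdict": verdict, "score": score},
            })
        rec_path = out / "recommendations.json"
        rec_path.write_text(json.dumps(audits, indent=1))
        _save("recommendations", rec_path)
        _record("recommend", t0, n_examples=len(audits))

        # ---- evaluate (pre/post on a learned-policy rollout) -------------
        t0 = _time.monotonic()
        w = config.eval_window
        eval_horizon = max(horizon, 2 * w)
        res = rollout(GreedyPolicy(fit.qtable, epsilon=0.0), latents,
                      eval_horizon, config=sim_cfg, seed=seeds[5])
        records = []
        for i, pid in enumerate(res.patient_ids):
            for name, traj in (("incontinence_episodes", res.leaks),
                               ("adherence", res.adherence),
                               ("iciq_ui_sf_score", res.iciq)):
                records.append(PrePostRecord(
                    patient_id=pid, variable=name,
                    pre_window=tuple(traj[i, :w]),
                    post_window=tuple(traj[i, -w:])))
        report = build_report(records)
        rep_path = out / "prepost_report.tsv"
        report.to_csv(rep_path, sep="\t", index=False)
        _save("prepost_report", rep_path)
        _record("evaluate", t0, n_variables=report.shape[0])

    except PipelineError:
        manifest["status"] = "failed"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
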