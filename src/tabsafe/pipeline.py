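"""Orchestration of the synthesis workflow with reproducible manifests.

The release workflow runs prepare → generate → postprocess → evaluate →
privacy → rank as composable stages.  Every run writes a manifest
recording the config hash, seeds, per-stage output digests and
timestamps, so any released synthetic table is traceable to the exact
inputs and settings that produced it; reruns with the same seeds yield
identical digests.  A quality gate compares declared report fields
against configured thresholds and a failing gate never yields a released
artifact directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .corrdst import copula_baseline_sample, refine_synthetic
from .evaluate import similarity_report
from .postprocess import compile_rules, rejection_sample
from .preprocess import EncodedMatrix, fit_transform, inverse_transform
from .privacy import privacy_report
from .schema import (
    StudyConfig,
    config_to_dict,
    save_report,
    validate_table,
    write_table,
)

__all__ = ["run_pipeline", "quality_gate", "GateError"]

STAGES = ("preprocess", "synthesize", "postprocess", "evaluate", "privacy")


class GateError(KeyError):
    """A gate threshold references a report field that does not exist."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: StudyConfig) -> str:
    doc = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


def run_pipeline(
    cohort: pd.DataFrame,
    config: StudyConfig,
    outdir: str | Path,
    n_synth: Optional[int] = None,
    seed: Optional[int] = None,
    stages: Sequence[str] = STAGES,
    use_refinement: bool = False,
    refine_steps: int = 100,
    key_features: Optional[Sequence[str]] = None,
    sensitive_columns: Optional[Sequence[str]] = None,
    gate_thresholds: Optional[dict[str, dict[str, float]]] = None,
) -> dict[str, Any]:
    """Run the staged workflow on a cohort; returns the manifest.

    Stage outputs are pure functions of (cohort, config, seed): reports
    land in ``outdir`` as JSON, tables as delimited text, and the
    manifest lists a sha256 digest per artifact.  On a hard stage
    failure the manifest records the failing stage and the error is
    re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    n_synth = n_synth if n_synth is not None else len(cohort)
    manifest: dict[str, Any] = {
        "tool_version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": list(stages),
        "artifacts": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _digest(path)
        }

    state: dict[str, Any] = {}
    try:
        for stage in stages:
            if stage == "preprocess":
                encoded, tf = fit_transform(cohort, config)
                state["encoded"], state["transform"] = encoded, tf
                p = outdir / "transform.json"
                with open(p, "w") as fh:
                    json.dump(tf.to_dict(), fh, indent=2, sort_keys=True)
                record("transform", p)
            elif stage == "synthesize":
                enc = state["encoded"]
                raw = copula_baseline_sample(enc.to_numpy(), n_synth, seed)
                if use_refinement:
                    raw = refine_synthetic(
                        raw, enc.to_numpy(), config.loss_weights,
                        steps=refine_steps, seed=seed,
                    )
                synth_enc = EncodedMatrix(
                    data=pd.DataFrame(raw, columns=enc.data.columns),
                    provenance=dict(enc.provenance),
                )
                state["synth_encoded"] = synth_enc
                state["synth"] = inverse_transform(
                    synth_enc, state["transform"], config
                )
            elif stage == "postprocess":
                rules = compile_rules(config.constraint_rules, config)
                if rules:
                    synth, log = rejection_sample(
                        _regenerator(state, config, seed),
                        rules,
                        n_target=n_synth,
                        seed=seed,
                    )
                    state["synth"] = synth
                    p = outdir / "rejection.json"
                    save_report(log.to_dict(), p)
                    record("rejection_log", p)
                p = outdir / "synthetic.csv"
                write_table(state["synth"], p, config)
                record("synthetic_table", p)
            elif stage == "evaluate":
                rep = similarity_report(
                    cohort,
                    state["synth"],
                    config,
                    state["encoded"].to_numpy(),
                    _encode_synth(state, config),
                )
                rep["validation"] = validate_table(state["synth"], config)
                state["evaluate_report"] = rep
                p = outdir / "evaluate.json"
                save_report(rep, p)
                record("evaluate_report", p)
            elif stage == "privacy":
                keys = list(key_features or _default_keys(config))
                sens = list(
                    sensitive_columns
                    or [c.name for c in config.columns if c.sensitive]
                )
                rep = privacy_report(
                    cohort,
                    state["synth"],
                    state["encoded"].to_numpy(),
                    _encode_synth(state, config),
                    key_features=keys,
                    sensitive_columns=sens,
                    match_configs=config.match_configs,
                    seed=seed,
                )
                state["privacy_report"] = rep
                p = outdir / "privacy.json"
                save_report(rep, p)
                record("privacy_report", p)
            else:
                raise ValueError(f"unknown stage {stage!r}")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        save_report(manifest, outdir / "manifest.json")
        raise

    if gate_thresholds is not None:
        gate = quality_gate(
            {
                "evaluate": state.get("evaluate_report", {}),
                "privacy": state.get("privacy_report", {}),
            },
            gate_thresholds,
        )
        manifest["gate"] = gate
        if gate["passed"]:
            (outdir / "released").mkdir(exist_ok=True)
            released = outdir / "released" / "synthetic.csv"
            write_table(state["synth"], released, config)
            record("released_table", released)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    save_report(manifest, outdir / "manifest.json")
    return manifest


def _regenerator(
    state: dict[str, Any], config: StudyConfig, seed: int
) -> Callable[[int, int], pd.DataFrame]:
    enc = state["encoded"]

    def generate(n: int, batch_seed: int) -> pd.DataFrame:
        raw = copula_baseline_sample(enc.to_numpy(), n, batch_seed)
        m = EncodedMatrix(
            data=pd.DataFrame(raw, columns=enc.data.columns),
            provenance=dict(enc.provenance),
        )
        return inverse_transform(m, state["transform"], config)

    return generate


def _encode_synth(state: dict[str, Any], config: StudyConfig) -> np.ndarray:
    # re-encode through the transform fitted on real for comparable geometry
    if "synth_encoded_final" not in state:
        state["synth_encoded_final"] = _reencode(state, config)
    return state["synth_encoded_final"]


def _reencode(state: dict[str, Any], config: StudyConfig) -> np.ndarray:
    """Encode the final synthetic cohort with the transform fitted on real."""
    from .preprocess import (
        PLACEHOLDER,
        encode_dates,
        quantile_transform,
    )

    tf = state["transform"]
    synth = state["synth"]
    cols = []
    for spec in config.columns:
        if spec.role == "identifier":
            continue
        name = spec.name
        if spec.role in ("continuous", "date"):
            st = tf.numeric[name]
            if spec.role == "date":
                x = encode_dates(synth[name], tf.reference_date)
            else:
                x = synth[name].astype(float)
            missing = x.isna().to_numpy()
            imputed = x.fillna(st.median).to_numpy(float)
            cols.append(
                quantile_transform(
                    imputed, st.grid_values, st.grid_levels, tf.output_distribution
                )
            )
            if st.has_flag:
                cols.append(missing.astype(float))
        else:
            levels = tf.categorical[name].levels
            col = synth[name].astype(object).where(~synth[name].isna(), PLACEHOLDER)
            for level in levels:
                cols.append((col == level).to_numpy(float))
    return np.column_stack(cols)


def quality_gate(
    reports: dict[str, dict[str, Any]], thresholds: dict[str, dict[str, float]]
) -> dict[str, Any]:
    """Boolean gate over declared report fields.

    ``thresholds`` maps "report.field" → {"min": τ} and/or {"max": τ}.
    Returns pass/fail with a reason per failing criterion; an empty
    threshold set passes but is flagged unconstrained, and human-review
    fields are surfaced, never auto-passed.
    """
    reasons: list[str] = []
    checked = 0
    for dotted, bounds in thresholds.items():
        report_name, _, fieldpath = dotted.partition(".")
        node: Any = reports.get(report_name)
        if node is None:
            raise GateError(f"unknown report {report_name!r}")
        for part in fieldpath.split("."):
            if not isinstance(node, dict) or part not in node:
                raise GateError(f"unknown report field {dotted!r}")
            node = node[part]
        value = float(node)
        checked += 1
        if "min" in bounds and value < bounds["min"]:
            reasons.append(f"{dotted}={value:.4g} below min {bounds['min']}")
        if "max" in bounds and value > bounds["max"]:
            reasons.append(f"{dotted}={value:.4g} above max {bounds['max']}")
    return {
        "passed": not reasons,
        "reasons": reasons,
        "unconstrained": checked == 0,
        "needs_human_review": checked == 0,
    }


def _default_keys(config: StudyConfig) -> list[str]:
    keys = [c.name for c in config.by_role("continuous", "date")]
    return keys[:4] if keys else [c.name for c in config.columns[:2]]
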