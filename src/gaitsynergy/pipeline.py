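"""End-to-end orchestration: simulate -> preprocess -> extract -> compare.

:func:`analyze_cohort` is the in-memory pipeline used by tests and
reproduction scripts; :func:`run_pipeline` wraps it with config
validation, file output, and a run manifest, and is what the ``synergy
run`` command calls. All randomness derives from the single seed in the
config, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
import tempfile
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .compare import GroupComparisonReport, compare_groups
from .datatypes import GaitCycleMatrix
from .extract import (
    SynergySelectionCurve,
    nnmf_decompose,
    select_num_synergies,
)
from .preprocess import PreprocessParams, preprocess
from .simulate import Cohort, CohortSpec, generate_cohort

__all__ = [
    "RunConfig",
    "SubjectResult",
    "CohortAnalysis",
    "validate_config",
    "analyze_cohort",
    "run_pipeline",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated parameter set for one pipeline run."""

    seed: int = 1
    # simulation
    n_subjects: int = 10
    n_cycles_per_subject: int = 3
    noise_sigma: float = 0.1
    weight_perturbations: Mapping[tuple[str, str, int], float] = field(
        default_factory=dict
    )
    # preprocessing
    band_low_hz: float = 10.0
    band_high_hz: float = 500.0
    filter_order: int = 4
    envelope_cutoff_hz: float = 6.0
    n_points: int = 101
    # extraction
    threshold: float = 0.9
    k_max: int = 5
    n_restarts: int = 20
    max_iter: int = 2000
    tol: float = 1e-6
    # comparison
    alpha: float = 0.05
    holm_correction: bool = False
    nonparametric: bool = False

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            band_low_hz=self.band_low_hz,
            band_high_hz=self.band_high_hz,
            filter_order=self.filter_order,
            envelope_cutoff_hz=self.envelope_cutoff_hz,
            n_points=self.n_points,
        )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        perts = d.pop("weight_perturbations", {})
        if isinstance(perts, list):  # YAML-friendly list-of-maps form
            perts = {
                (p["group"], p["muscle"], int(p["synergy"])): float(p["factor"])
                for p in perts
            }
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(weight_perturbations=perts, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["weight_perturbations"] = [
            {"group": g, "muscle": m, "synergy": s, "factor": f}
            for (g, m, s), f in self.weight_perturbations.items()
        ]
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Return human-readable violations; empty list means valid."""
    v: list[str] = []
    if config.n_subjects < 2:
        v.append(f"n_subjects must be >= 2 per group, got {config.n_subjects}")
    if config.n_cycles_per_subject < 1:
        v.append("n_cycles_per_subject must be >= 1")
    if config.noise_sigma < 0:
        v.append("noise_sigma must be >= 0")
    if not 0 < config.band_low_hz < config.band_high_hz:
        v.append(
            f"band edges must satisfy 0 < low < high, got "
            f"({config.band_low_hz}, {config.band_high_hz})"
        )
    if config.filter_order < 1:
        v.append("filter_order must be >= 1")
    if config.envelope_cutoff_hz <= 0:
        v.append("envelope_cutoff_hz must be positive")
    if config.n_points < 2:
        v.append("n_points must be >= 2")
    if not 0 < config.threshold < 1:
        v.append(f"threshold must lie in (0, 1), got {config.threshold}")
    if config.k_max < 1:
        v.append("k_max must be >= 1")
    if config.n_restarts < 1:
        v.append("n_restarts must be >= 1")
    if config.max_iter < 1:
        v.append("max_iter must be >= 1")
    if config.tol <= 0:
        v.append("tol must be positive")
    if not 0 < config.alpha < 1:
        v.append(f"alpha must lie in (0, 1), got {config.alpha}")
    for (g, m, s), f in config.weight_perturbations.items():
        if f <= 0:
            v.append(f"perturbation factor for ({g}, {m}, {s}) must be > 0")
    return v


@dataclass(frozen=True)
class SubjectResult:
    """One subject's pipeline outputs."""

    group: str
    subject_index: int
    matrix: GaitCycleMatrix
    curve: SynergySelectionCurve
    decomposition_at_common_k: Any  # SynergyDecomposition
    refitted: bool


@dataclass(frozen=True)
class CohortAnalysis:
    """Everything the pipeline computes for a two-group cohort."""

    config: RunConfig
    subjects: Mapping[str, tuple[SubjectResult, ...]]
    modal_k: Mapping[str, int]
    k_common: int
    report: GroupComparisonReport
    warnings_seen: tuple[str, ...]


def _modal(values: Sequence[int]) -> int:
    counts = Counter(values)
    top = max(counts.values())
    return min(k for k, c in counts.items() if c == top)


def analyze_cohort(
    cohort: Cohort, config: RunConfig
) -> CohortAnalysis:
    """Run preprocessing, extraction, selection, and comparison in memory.

    Each subject is preprocessed and gets a per-subject synergy-count
    selection; the comparison then runs at the modal selected k pooled
    over all subjects (subjects whose own selection differs are refitted
    at that k and flagged). Per-subject global VAF for every k up to the
    common k feeds the VAF-by-k group test.
    """
    params = config.preprocess_params()
    caught: list[str] = []
    results: dict[str, list[SubjectResult]] = {}
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for group, subjects in cohort.groups.items():
            group_res = []
            for sub in subjects:
                mat = preprocess(sub.recording, sub.events, params)
                curve = select_num_synergies(
                    mat,
                    threshold=config.threshold,
                    k_max=config.k_max,
                    seed=config.seed + 1000 * sub.subject_index
                    + (0 if group == "A" else 500),
                    n_restarts=config.n_restarts,
                    max_iter=config.max_iter,
                    tol=config.tol,
                )
                group_res.append(
                    SubjectResult(group, sub.subject_index, mat, curve, None,
                                  False)
                )
            results[group] = group_res
        caught.extend(str(w.message) for w in wlist)

    modal_k = {g: _modal([r.curve.k_selected for r in rs])
               for g, rs in results.items()}
    k_common = _modal(
        [r.curve.k_selected for rs in results.values() for r in rs]
    )

    final: dict[str, tuple[SubjectResult, ...]] = {}
    vafs: dict[str, dict[int, list[float]]] = {}
    for group, rs in results.items():
        out = []
        gv: dict[int, list[float]] = {k: [] for k in range(1, k_common + 1)}
        for r in rs:
            per_k = {d.k: d for d in r.curve.per_k}
            refitted = r.curve.k_selected != k_common
            # make sure every k up to the common k has a fit for Table-2
            # style VAF comparison
            for k in range(1, k_common + 1):
                if k not in per_k:
                    per_k[k] = nnmf_decompose(
                        r.matrix, k,
                        seed=config.seed + 1000 * r.subject_index
                        + (0 if group == "A" else 500),
                        n_restarts=config.n_restarts,
                        max_iter=config.max_iter, tol=config.tol,
                    )
                gv[k].append(per_k[k].vaf_total)
            out.append(SubjectResult(
                group, r.subject_index, r.matrix, r.curve,
                per_k[k_common], refitted,
            ))
        final[group] = tuple(out)
        vafs[group] = gv

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        report = compare_groups(
            [r.decomposition_at_common_k for r in final["A"]],
            [r.decomposition_at_common_k for r in final["B"]],
            muscles=cohort.model.channel_labels,
            vafs_a=vafs["A"], vafs_b=vafs["B"],
            alpha=config.alpha,
            correction="holm" if config.holm_correction else None,
            nonparametric=config.nonparametric,
        )
    caught.extend(str(w.message) for w in wlist)

    return CohortAnalysis(
        config=config,
        subjects=final,
        modal_k=modal_k,
        k_common=k_common,
        report=report,
        warnings_seen=tuple(caught),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _report_tables(report: GroupComparisonReport, out: Path) -> None:
    import pandas as pd

    k = report.correlation_matrix.shape[0]
    corr = pd.DataFrame(
        report.correlation_matrix,
        index=[f"A_synergy_{i + 1}" for i in range(k)],
        columns=[f"B_synergy_{j + 1}" for j in range(k)],
    )
    # matched (diagonal) pair of each A synergy after alignment
    corr["matched_with"] = [f"B_synergy_{i + 1}" for i in range(k)]
    corr.to_csv(out / "correlation_matrix.csv")

    rows = []
    for t in report.vaf_tests:
        rows.append({
            "k": t.k, "mean_A": t.mean_a, "sd_A": t.sd_a,
            "mean_B": t.mean_b, "sd_B": t.sd_b,
            "t": t.t, "p": t.p, "significant": t.significant,
        })
    pd.DataFrame(rows).to_csv(out / "vaf_by_k.csv", index=False)

    rows = []
    for t in report.weight_tests:
        rows.append({
            "synergy": t.synergy + 1, "muscle": t.muscle,
            "mean_A": t.mean_a, "sd_A": t.sd_a,
            "mean_B": t.mean_b, "sd_B": t.sd_b,
            "t": t.t, "p": t.p, "p_holm": t.p_corrected,
            "significant": t.significant, "missing": t.missing,
        })
    pd.DataFrame(rows).to_csv(out / "weight_tests.csv", index=False)

    payload = {
        "alpha": report.alpha,
        "k": k,
        "correlation_matrix": report.correlation_matrix.tolist(),
        "similarity_class": report.similarity_class.tolist(),
        "matched_pairs": list(report.matched_pairs),
        "notes": list(report.notes),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort, analyze it, and write all outputs atomically.

    Outputs land in ``out_dir`` only on success (written to a temp
    sibling directory first, then renamed). Returns the output path.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))

    from . import io as gio
    from .simulate import default_walking_model

    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".synergy-run-", dir=out_dir.parent))
    try:
        model = default_walking_model(seed=config.seed,
                                      noise_sigma=config.noise_sigma)
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            n_cycles_per_subject=config.n_cycles_per_subject,
            weight_perturbations=config.weight_perturbations,
        )
        cohort = generate_cohort(model, spec)
        analysis = analyze_cohort(cohort, config)

        gio.write_ground_truth_json(tmp / "ground_truth.json", model)
        for group, subs in cohort.groups.items():
            gdir = tmp / f"group_{group}"
            gdir.mkdir()
            for sub in subs:
                base = f"subject_{sub.subject_index:02d}"
                gio.write_recording_csv(gdir / f"{base}_emg.csv", sub.recording)
                gio.write_events_csv(gdir / f"{base}_events.csv", sub.events)
        for group, subs in analysis.subjects.items():
            gdir = tmp / f"group_{group}"
            for r in subs:
                base = f"subject_{r.subject_index:02d}"
                gio.write_matrix_csv(gdir / f"{base}_matrix.csv", r.matrix)
                gio.write_decomposition(
                    gdir, r.decomposition_at_common_k, base,
                    cohort.model.channel_labels,
                )
        _report_tables(analysis.report, tmp)

        manifest = {
            "version": __version__,
            "config": config.to_jsonable(),
            "modal_k": dict(analysis.modal_k),
            "k_common": analysis.k_common,
            "warnings": list(analysis.warnings_seen),
            "checksums": {
                str(p.relative_to(tmp)): _sha256(p)
                for p in sorted(tmp.rglob("*")) if p.is_file()
            },
        }
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=1))

        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(tmp, out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return out_dir
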