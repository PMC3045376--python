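"""File formats, run configuration, and the end-to-end pipeline.

Formats are deliberately plain so round-trips are bit-exact: events and
tables are tab-separated UTF-8 with LF endings and dot decimals; path
models and reports are JSON.  A pipeline run is a pure function of
(RunConfig, seed): the manifest records the config hash and all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .glm import build_design_matrix, fit_glm, group_contrast_correlation, median_split_compare
from .group import (
    compare_paths,
    confirmatory_fit_cohort,
    count_shared_paths,
    path_label,
    stepwise_regress,
)
from .ppi import build_ppi_regressors, fit_ppi, group_ppi_test
from .sem import (
    ConditionSeries,
    PathModel,
    exploratory_search,
    extract_condition_blocks,
)
from .synthetic import (
    CATEGORIES,
    DEFAULT_DESIGN,
    Paradigm,
    ROITimeSeries,
    Segment,
    default_generating_model,
    make_paradigm,
    simulate_cohort,
)

__all__ = [
    "RunConfig",
    "read_events",
    "write_events",
    "read_timeseries",
    "write_timeseries",
    "read_cov",
    "write_cov",
    "read_model",
    "write_model",
    "run_pipeline",
]

log = logging.getLogger("effconn")


# --------------------------------------------------------------------------
# Events (BIDS-style TSV)
# --------------------------------------------------------------------------


def read_events(path, tr: float = 2.0, tail: float = 16.0) -> Paradigm:
    """Read a BIDS-style events TSV (onset, duration, trial_type) as a Paradigm."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    required = ["onset", "duration", "trial_type"]
    for col in required:
        if col not in header:
            raise ValueError(f"{path}: missing column {col!r}")
    idx = {c: header.index(c) for c in required}
    segments = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            onset = float(fields[idx["onset"]])
            duration = float(fields[idx["duration"]])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
        trial_type = fields[idx["trial_type"]]
        if trial_type not in CATEGORIES:
            raise ValueError(
                f"{path}:{lineno}: unknown trial_type {trial_type!r}"
            )
        segments.append(Segment(onset=onset, duration=duration, category=trial_type))
    if not segments:
        raise ValueError(f"{path}: no event rows")
    last_end = max(s.onset + s.duration for s in segments)
    n_scans = int(np.ceil((last_end + tail) / tr))
    try:
        return Paradigm(segments=tuple(segments), tr=tr, n_scans=n_scans)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_events(paradigm: Paradigm, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("onset\tduration\ttrial_type\n")
        for seg in paradigm.segments:
            fh.write(f"{seg.onset!r}\t{seg.duration!r}\t{seg.category}\n")


# --------------------------------------------------------------------------
# Time series, covariance, model
# --------------------------------------------------------------------------


def write_timeseries(ts: ROITimeSeries, path) -> None:
    ts.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_timeseries(path, tr: float = 2.0) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no samples")
    return ROITimeSeries(data=df.astype(float), tr=tr)


def write_cov(S: pd.DataFrame, path) -> None:
    S.to_csv(path, sep="\t", lineterminator="\n")


def read_cov(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError(
            f"{path}: row labels {list(df.index)} != column labels {list(df.columns)}"
        )
    M = df.to_numpy(dtype=float)
    if np.max(np.abs(M - M.T)) > 1e-10:
        raise ValueError(f"{path}: covariance asymmetry exceeds 1e-10")
    df.iloc[:, :] = (M + M.T) / 2.0
    return df


def write_model(model: PathModel, path) -> None:
    payload = {"nodes": list(model.nodes), "edges": [list(e) for e in model.edges]}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model(path) -> PathModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    nodes = tuple(payload["nodes"])
    edges = []
    for e in payload.get("edges", []):
        src, tgt = e
        if src not in nodes or tgt not in nodes:
            raise ValueError(f"{path}: edge references unknown node {src!r}->{tgt!r}")
        edges.append((src, tgt))
    return PathModel(nodes=nodes, edges=tuple(edges))


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run depends on."""

    design_counts: dict = field(default_factory=lambda: dict(DEFAULT_DESIGN))
    segment_duration: float = 15.0
    tr: float = 2.0
    n_subjects: int = 17
    seed: int = 0
    rois: tuple = ()  # empty -> the generating model's nodes
    conditions: tuple = ("neutral", "care", "justice")
    contrasts: dict = field(
        default_factory=lambda: {
            "care_gt_neutral": {"care": 1.0, "neutral": -1.0},
            "justice_gt_neutral": {"justice": 1.0, "neutral": -1.0},
        }
    )
    ppi_seed_roi: str = "pSTS"
    block_shift: float = 6.0
    drop_head: int = 2
    drop_tail: int = 1
    sem_max_edges: int | None = None
    sem_require_df_nonneg: bool = True
    sem_rank_by: str = "aic"
    sem_restarts: int = 3
    stepwise_p_in: float = 0.05
    stepwise_p_out: float = 0.10
    alpha: float = 0.05
    out_dir: str = "effconn_out"

    def validate(self) -> None:
        from .sem import _RANKABLE

        if self.sem_rank_by not in _RANKABLE:
            raise ValueError(f"unknown rank criterion {self.sem_rank_by!r}")
        if not 0 < self.stepwise_p_in < 1 or not 0 < self.stepwise_p_out < 1:
            raise ValueError("stepwise thresholds must lie in (0, 1)")
        if self.tr <= 0 or self.segment_duration <= 0:
            raise ValueError("tr and segment_duration must be positive")
        if self.n_subjects < 3:
            raise ValueError("pipeline needs at least 3 subjects")
        for cat in self.design_counts:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown design category {cat!r}")

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["rois"] = list(self.rois)
        payload["conditions"] = list(self.conditions)
        return json.dumps(payload, sort_keys=True, indent=2)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _stage_seeds(seed: int, names) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return dict(zip(names, children, strict=True))


def run_pipeline(config: RunConfig, model=None, out_dir=None) -> dict:
    """Simulate a cohort and run GLM, PPI, SEM search, comparisons, stepwise.

    Writes every report plus a manifest into ``out_dir`` and returns the
    result bundle as a dict.  Deterministic under ``config.seed``.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seed = _stage_seeds(
        config.seed, ["paradigm", "cohort", "sem", "confirmatory"]
    )

    if model is None:
        model = default_generating_model()
    rois = tuple(config.rois) if config.rois else tuple(model.nodes)

    log.info("stage paradigm: building %d-segment design", sum(config.design_counts.values()))
    paradigm = make_paradigm(
        config.design_counts,
        config.segment_duration,
        config.tr,
        seed=stage_seed["paradigm"].generate_state(1)[0] % (2**31),
    )
    write_events(paradigm, out / "events.tsv")

    log.info("stage simulate: %d subjects", config.n_subjects)
    cohort = simulate_cohort(
        model, paradigm, config.n_subjects,
        seed=stage_seed["cohort"].generate_state(1)[0] % (2**31),
    )
    scores = np.array([rec.score for rec in cohort])
    manifest_files = ["events.tsv"]
    for rec in cohort:
        fname = f"{rec.subject_id}_timeseries.tsv"
        write_timeseries(rec.timeseries, out / fname)
        manifest_files.append(fname)
    cohort_manifest = [
        {"subject_id": rec.subject_id, "score": rec.score,
         "timeseries": f"{rec.subject_id}_timeseries.tsv"}
        for rec in cohort
    ]

    # ---- GLM ----
    log.info("stage glm: %d contrasts", len(config.contrasts))
    design = build_design_matrix(paradigm)
    glm_rows = []
    for rec in cohort:
        for roi in rois:
            fit = fit_glm(rec.timeseries.data[roi], design, config.contrasts)
            for cname in config.contrasts:
                glm_rows.append(
                    {
                        "subject": rec.subject_id,
                        "roi": roi,
                        "contrast": cname,
                        "value": fit.contrast_values[cname],
                        "t": fit.contrast_t[cname],
                    }
                )
    glm_table = pd.DataFrame(glm_rows)
    glm_table.to_csv(out / "glm_contrasts.tsv", sep="\t", index=False, lineterminator="\n")
    manifest_files.append("glm_contrasts.tsv")

    behaviour = {}
    key_contrast = "justice_gt_neutral" if "justice_gt_neutral" in config.contrasts else None
    if key_contrast:
        vals = glm_table.query(
            "contrast == @key_contrast and roi == @config.ppi_seed_roi"
        ).sort_values("subject")["value"].to_numpy()
        r, r2, p = group_contrast_correlation(vals, scores)
        split = median_split_compare(scores, vals)
        behaviour = {
            "contrast": key_contrast,
            "roi": config.ppi_seed_roi,
            "r": r,
            "r2": r2,
            "p": p,
            "median_score": split.median,
            "score_mean_high": split.score_mean_high,
            "score_sd_high": split.score_sd_high,
            "score_mean_low": split.score_mean_low,
            "score_sd_low": split.score_sd_low,
            "split_t": split.t,
            "split_p": split.p,
        }
        _write_json(behaviour, out / "behaviour_correlation.json")
        manifest_files.append("behaviour_correlation.json")

    # ---- PPI ----
    log.info("stage ppi: seed %s", config.ppi_seed_roi)
    ppi_rows = []
    moral_contrasts = [c for c in ("care", "justice") if config.design_counts.get(c)]
    per_subject_betas: dict[tuple[str, str], list[float]] = {}
    for rec in cohort:
        seed_series = rec.timeseries.data[config.ppi_seed_roi].to_numpy()
        for cond in moral_contrasts:
            regs = build_ppi_regressors(
                seed_series, paradigm, (cond, "neutral"), mode="multiply"
            )
            for roi in rois:
                if roi == config.ppi_seed_roi:
                    continue
                res = fit_ppi(
                    rec.timeseries.data[roi], regs, confounds=design,
                    seed_label=config.ppi_seed_roi, target_label=roi,
                )
                ppi_rows.append(
                    {
                        "subject": rec.subject_id,
                        "seed": res.seed,
                        "target": res.target,
                        "contrast": res.contrast,
                        "beta": res.beta,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                    }
                )
                per_subject_betas.setdefault((cond, roi), []).append(res.beta)
    ppi_table = pd.DataFrame(ppi_rows)
    ppi_table.to_csv(out / "ppi_results.tsv", sep="\t", index=False, lineterminator="\n")
    manifest_files.append("ppi_results.tsv")

    ppi_group = []
    if len(moral_contrasts) == 2:
        for roi in rois:
            if roi == config.ppi_seed_roi:
                continue
            t, p, df = group_ppi_test(
                per_subject_betas[("care", roi)], per_subject_betas[("justice", roi)]
            )
            ppi_group.append(
                {"seed": config.ppi_seed_roi, "target": roi,
                 "comparison": "care_vs_justice", "t": t, "p": p, "df": df}
            )
        pd.DataFrame(ppi_group).to_csv(
            out / "ppi_group_tests.tsv", sep="\t", index=False, lineterminator="\n"
        )
        manifest_files.append("ppi_group_tests.tsv")

    # ---- condition covariances and exploratory SEM ----
    log.info("stage sem: exploratory search per condition")
    pooled: dict[str, ConditionSeries] = {}
    per_subject_cs: dict[str, dict[str, ConditionSeries]] = {c: {} for c in config.conditions}
    for cond in config.conditions:
        pieces = []
        for rec in cohort:
            cs = extract_condition_blocks(
                rec.timeseries, paradigm, cond,
                shift=config.block_shift,
                drop_head=config.drop_head,
                drop_tail=config.drop_tail,
            )
            per_subject_cs[cond][rec.subject_id] = cs
            pieces.append(cs.samples - cs.samples.mean(axis=0))
        samples = pd.concat(pieces, axis=0, ignore_index=True)
        pooled[cond] = ConditionSeries(condition=cond, samples=samples)
        write_cov(pooled[cond].S, out / f"cov_{cond}.tsv")
        manifest_files.append(f"cov_{cond}.tsv")

    best_models: dict[str, PathModel] = {}
    search_summary = {}
    sem_children = stage_seed["sem"].spawn(len(config.conditions))
    for cond, child in zip(config.conditions, sem_children, strict=True):
        result = exploratory_search(
            pooled[cond].S,
            pooled[cond].n_samples,
            rois,
            max_edges=config.sem_max_edges,
            require_df_nonneg=config.sem_require_df_nonneg,
            rank_by=config.sem_rank_by,
            seed=child.generate_state(1)[0] % (2**31),
            restarts=config.sem_restarts,
        )
        best = result.best
        best_models[cond] = best.model
        write_model(best.model, out / f"model_{cond}.json")
        manifest_files.append(f"model_{cond}.json")
        search_summary[cond] = {
            "n_models_fit": len(result.ranked) + len(result.failures),
            "n_converged": len(result.ranked),
            "best_edges": [list(e) for e in best.model.edges],
            "best_indices": {k: _jsonable(v) for k, v in best.indices.items()},
            "spectral_radius": best.spectral_radius,
            "recursive": best.recursive,
        }
    _write_json(search_summary, out / "sem_search.json")
    manifest_files.append("sem_search.json")

    # ---- per-subject confirmatory fits ----
    log.info("stage confirmatory: per-subject fits of group models")
    conf_children = stage_seed["confirmatory"].spawn(len(config.conditions))
    coeffs_by_cond, diags = {}, {}
    for cond, child in zip(config.conditions, conf_children, strict=True):
        coeffs, diag = confirmatory_fit_cohort(
            per_subject_cs[cond], best_models[cond],
            seed=child.generate_state(1)[0] % (2**31),
        )
        coeffs_by_cond[cond] = coeffs
        diags[cond] = diag
        coeffs.to_csv(out / f"confirmatory_{cond}.tsv", sep="\t", lineterminator="\n")
        manifest_files.append(f"confirmatory_{cond}.tsv")

    # ---- pathwise comparison: care vs justice ----
    comparisons = []
    if "care" in best_models and "justice" in best_models:
        n_shared, shared = count_shared_paths(best_models)
        union_paths = sorted(
            set(best_models["care"].edges) | set(best_models["justice"].edges)
        )
        common = coeffs_by_cond["care"].index.intersection(
            coeffs_by_cond["justice"].index
        )
        if len(common) >= 3:
            comps = compare_paths(
                coeffs_by_cond["care"].loc[common],
                coeffs_by_cond["justice"].loc[common],
                union_paths,
                alpha=config.alpha,
                n_comparisons=max(n_shared, 1),
                conditions=("care", "justice"),
            )
            comparisons = [
                {
                    "path": path_label(*c.path),
                    "beta_care": c.beta_a,
                    "beta_justice": c.beta_b,
                    "t": c.t,
                    "p": c.p,
                    "threshold": c.threshold,
                    "significant": c.significant,
                    "comparable": c.comparable,
                }
                for c in comps
            ]
            pd.DataFrame(comparisons).to_csv(
                out / "path_comparisons.tsv", sep="\t", index=False, lineterminator="\n"
            )
            manifest_files.append("path_comparisons.tsv")

    # ---- stepwise regression on the justice-model coefficients ----
    stepwise_report = {}
    if "justice" in coeffs_by_cond and len(coeffs_by_cond["justice"]) >= 5:
        coeffs = coeffs_by_cond["justice"]
        score_map = {rec.subject_id: rec.score for rec in cohort}
        y = np.array([score_map[s] for s in coeffs.index])
        sw = stepwise_regress(
            coeffs, y, p_in=config.stepwise_p_in, p_out=config.stepwise_p_out
        )
        stepwise_report = {
            "steps": sw.steps,
            "selected": sw.selected,
            "r2_by_step": sw.r2_by_step,
            "coefficients": {k: float(v) for k, v in sw.coefficients.items()},
            "intercept": sw.intercept,
        }
        _write_json(stepwise_report, out / "stepwise.json")
        manifest_files.append("stepwise.json")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "files": sorted(manifest_files),
        "cohort": cohort_manifest,
    }
    _write_json(manifest, out / "manifest.json")

    return {
        "paradigm": paradigm,
        "cohort": cohort,
        "glm": glm_table,
        "behaviour": behaviour,
        "ppi": ppi_table,
        "ppi_group": ppi_group,
        "pooled_covariances": pooled,
        "best_models": best_models,
        "search_summary": search_summary,
        "confirmatory": coeffs_by_cond,
        "confirmatory_diagnostics": diags,
        "comparisons": comparisons,
        "stepwise": stepwise_report,
        "manifest": manifest,
    }


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v


def _write_json(payload, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
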