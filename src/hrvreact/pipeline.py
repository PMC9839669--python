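"""End-to-end driver: simulate -> extract -> HRV -> model -> cluster -> report.

Every random draw flows from one master seed; a rerun with the same
configuration reproduces all outputs byte-identically.  Each stage's
outputs are written as delimited text and recorded, with SHA-256
digests, in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as clu
from . import io as hio
from . import metrics, models
from .extract import ExtractionConfig, extract_rr
from .schedule import PHASE_LABELS, build_default_schedule
from .simulate import Cohort, SimulationConfig, generate_cohort

log = logging.getLogger(__name__)

OUTCOMES = ("hr_bpm", "rr_mean_s", "rmssd_s", "sdnn_s")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    mode: str = "synthetic"  # or "real"
    use_truth_rr: bool = False  # bypass extraction, model generator truth
    cluster_mode: str = "paper"
    cluster_seed: int = 0
    cluster_n_init: int = 100
    run_clustering: bool = True
    signal_dir: str | None = None  # real mode
    subject_table: str | None = None  # real mode

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        ext = ExtractionConfig(**raw.pop("extraction", {}))
        return cls(simulation=sim, extraction=ext, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    stage_versions: dict
    file_digests: dict
    warnings: list

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _subjects_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for s in cohort.subjects:
        row = {
            "subject_id": s.id,
            "group": s.group,
            "true_cluster": s.true_cluster if s.true_cluster else "",
            "age": s.age,
            "bmi": s.bmi,
            "smoker": int(s.smoker),
            "lpa_score": "" if s.lpa_score is None else s.lpa_score,
            "physically_active": (
                "" if s.physically_active is None else int(s.physically_active)
            ),
            "fiq_total": "" if s.fiq_total is None else s.fiq_total,
            "pcs": "" if s.pcs is None else s.pcs,
            "pss": s.pss,
            "stai_a": s.stai_a,
            "stai_b": s.stai_b,
        }
        for item in range(1, 11):
            v = (s.fiq_items or {}).get(item)
            row[f"fiq_item_{item}"] = "" if v is None else v
        for j, lab in enumerate(
            ("start", "r1", "s1", "r2", "s2", "r3")
        ):
            row[f"nrs_pain_{lab}"] = int(s.nrs_pain[j])
            row[f"nrs_stress_{lab}"] = int(s.nrs_stress[j])
        rows.append(row)
    return pd.DataFrame(rows)


def _summaries_frame(summaries, cohort: Cohort) -> pd.DataFrame:
    groups = {s.id: s.group for s in cohort.subjects}
    rows = []
    for s in summaries:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": groups.get(s.subject_id, ""),
                "window": s.window,
                "hr_bpm": "" if s.hr_bpm is None else s.hr_bpm,
                "rr_mean_s": "" if s.rr_mean_s is None else s.rr_mean_s,
                "rmssd_s": "" if s.rmssd_s is None else s.rmssd_s,
                "sdnn_s": "" if s.sdnn_s is None else s.sdnn_s,
                "n_beats": s.n_beats,
            }
        )
    return pd.DataFrame(rows)


def build_nrs_long_table(subjects, group_attr: str = "group") -> dict:
    """Long tables for the NRS pain and stress ratings.

    The five post-phase ratings are the time levels (relax1 reference);
    the pre-protocol rating is the baseline covariate.
    """
    out = {}
    for kind in ("pain", "stress"):
        rows = []
        for s in subjects:
            ratings = s.nrs_pain if kind == "pain" else s.nrs_stress
            if ratings is None:
                continue
            for j, phase in enumerate(PHASE_LABELS, start=1):
                rows.append(
                    {
                        "subject_id": s.id,
                        "group": getattr(s, group_attr),
                        "time": phase,
                        "value": float(ratings[j]),
                        "baseline": float(ratings[0]),
                    }
                )
        out[kind] = pd.DataFrame(rows)
    return out


def _coef_frame(fit: models.GLSFit) -> pd.DataFrame:
    df = fit.params.copy()
    df["rho"] = fit.rho
    df["n_obs"] = fit.n_obs
    return df


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    seed: int | None = None,
) -> RunManifest:
    """Execute all stages on simulated (or supplied) data.

    Writes the subject table, per-window HRV summaries, model coefficient
    tables, cluster assignments and characterisation, a plain-text
    report, and a manifest with SHA-256 digests of every output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(
            config,
            simulation=dataclasses.replace(config.simulation, master_seed=seed),
        )
    caught: list[str] = []

    if config.mode == "real":
        if not config.subject_table or not config.signal_dir:
            raise PipelineError(
                "config", "real-data mode requires signal_dir and subject_table"
            )
        raise PipelineError(
            "config",
            "real-data mode: load signals with hrvreact.io.read_signal and "
            "run the stages directly; the turnkey driver covers synthetic mode",
        )

    # --- simulate -----------------------------------------------------
    try:
        schedule = build_default_schedule()
        cohort = generate_cohort(config.simulation, schedule)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    hio.write_table(_subjects_frame(cohort), out / "subjects.tsv")
    hio.write_table(
        _summaries_frame(cohort.truth_summaries, cohort), out / "hrv_truth.tsv"
    )

    # --- extract + hrv ------------------------------------------------
    try:
        if config.use_truth_rr:
            summaries = cohort.truth_summaries
        else:
            summaries = []
            for s in cohort.subjects:
                wave = cohort.recording(s.id)
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    rr, _ = extract_rr(wave, config.extraction)
                caught += [str(w.message) for w in wlist]
                summaries.extend(metrics.phase_summaries(rr, schedule, s.id))
    except Exception as exc:
        raise PipelineError("extract", str(exc)) from exc
    hrv_df = _summaries_frame(summaries, cohort)
    hio.write_table(hrv_df, out / "hrv_summaries.tsv")

    # --- group models -------------------------------------------------
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            comparisons = models.baseline_comparisons(cohort.subjects, summaries)
        caught += [str(w.message) for w in wlist]
        comp_df = pd.DataFrame(
            [
                {
                    "method": r.method,
                    "variable": r.detail.get("variable", ""),
                    "statistic": r.statistic,
                    "p": r.p,
                }
                for r in comparisons
            ]
        )
        hio.write_table(comp_df, out / "baseline_comparisons.tsv")
        fits_un, fits_adj = {}, {}
        for outcome in OUTCOMES:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                long = models.build_long_table(summaries, cohort.subjects, outcome)
            caught += [str(w.message) for w in wlist]
            fits_un[outcome] = models.fit_gls(long)
            adj = long.dropna(subset=["bmi", "smoker", "physically_active"]).copy()
            adj["smoker"] = adj["smoker"].astype(float)
            adj["physically_active"] = adj["physically_active"].astype(float)
            # constant covariates (e.g. no smokers in a tiny cohort) are
            # inestimable; drop them rather than fail the stage
            covs = tuple(
                c for c in ("bmi", "smoker", "physically_active")
                if adj[c].nunique() > 1
            )
            fits_adj[outcome] = models.fit_gls(adj, covariates=covs)
            hio.write_table(
                _coef_frame(fits_un[outcome]), out / f"gls_unadjusted_{outcome}.tsv"
            )
            hio.write_table(
                _coef_frame(fits_adj[outcome]), out / f"gls_adjusted_{outcome}.tsv"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("model", str(exc)) from exc

    # --- clustering ---------------------------------------------------
    report_sections: dict = {
        "comparisons": comp_df,
        "fits_unadjusted": fits_un,
        "fits_adjusted": fits_adj,
        "hrv": hrv_df,
    }
    if config.run_clustering:
        try:
            fm_ids, deltas_hr, deltas_rr, base_hr = [], [], [], []
            by_subject: dict[str, list] = {}
            for s in summaries:
                by_subject.setdefault(s.subject_id, []).append(s)
            for s in cohort.subjects:
                if s.group != "FM":
                    continue
                rec = metrics.reactivity(by_subject.get(s.id, []))
                if not rec.complete:
                    caught.append(f"{s.id}: {rec.reason_missing}")
                    continue
                base = [
                    x for x in by_subject[s.id] if x.window == "baseline"
                ][0]
                fm_ids.append(s.id)
                deltas_hr.append(rec.delta_hr_bpm)
                deltas_rr.append(rec.delta_rr_mean_s)
                base_hr.append(base.hr_bpm)
            react = pd.DataFrame(
                {
                    "subject_id": fm_ids,
                    "delta_hr_bpm": deltas_hr,
                    "delta_rr_mean_s": deltas_rr,
                    "baseline_hr_bpm": base_hr,
                }
            )
            hio.write_table(react, out / "reactivity.tsv")
            configs = clu.enumerate_feasible_configs(
                len(fm_ids),
                mode=config.cluster_mode,
                seed=config.cluster_seed,
                n_init=config.cluster_n_init,
            )
            results = clu.run_configs(react, configs)
            best = clu.select_clustering(results)
            best = clu.relabel_by_baseline_hr(
                best, react["baseline_hr_bpm"].to_numpy(float)
            )
            assign_df = pd.DataFrame(
                {"subject_id": fm_ids, "cluster": best.assignments}
            )
            hio.write_table(assign_df, out / "cluster_assignments.tsv")
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                creport = clu.characterize_clusters(
                    cohort.subjects, best, fm_ids, summaries=summaries
                )
            caught += [str(w.message) for w in wlist]
            hio.write_table(
                creport.questionnaire_tests, out / "cluster_questionnaires.tsv"
            )
            for outcome, fit in creport.trajectory_fits.items():
                hio.write_table(
                    _coef_frame(fit), out / f"gls_cluster_{outcome}.tsv"
                )
            report_sections["clustering"] = {
                "selected": best,
                "configs": [
                    (r.config.variables, r.config.k, r.wss) for r in results
                ],
                "report": creport,
            }
        except Exception as exc:
            raise PipelineError("cluster", str(exc)) from exc

    # --- report + manifest --------------------------------------------
    text = render_report(report_sections)
    (out / "report.txt").write_text(text)
    digests = {
        p.name: _digest(p) for p in sorted(out.glob("*")) if p.is_file()
        and p.name != "manifest.json"
    }
    from . import __version__

    manifest = RunManifest(
        config=config.to_dict(),
        master_seed=config.simulation.master_seed,
        stage_versions={stage: __version__ for stage in
                        ("simulate", "extract", "hrv", "model", "cluster")},
        file_digests=digests,
        warnings=sorted(set(caught)),
    )
    manifest.write(out / "manifest.json")
    return manifest


def _fmt(x) -> str:
    if x == "" or x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{float(x):.3g}"


def render_report(sections: dict) -> str:
    """Plain-text report mirroring the study's table shapes."""
    lines: list[str] = ["HRV stress-reactivity report", "=" * 60, ""]
    hrv = sections.get("hrv")
    if hrv is not None and not hrv.empty:
        lines.append("Per-window HRV by group (mean (SD); median [min, max])")
        df = hrv.replace("", np.nan)
        for metric in OUTCOMES:
            lines.append(f"  {metric}:")
            vals = df.dropna(subset=[metric])
            vals[metric] = vals[metric].astype(float)
            for window in ("baseline", *PHASE_LABELS):
                sub = vals[vals["window"] == window]
                cells = []
                for g in sorted(sub["group"].unique(), reverse=True):
                    x = sub[sub[metric].notna() & (sub["group"] == g)][metric]
                    if len(x) == 0:
                        cells.append(f"{g}: NA")
                        continue
                    cells.append(
                        f"{g}: {_fmt(x.mean())} ({_fmt(x.std(ddof=1))}); "
                        f"{_fmt(x.median())} [{_fmt(x.min())}, {_fmt(x.max())}]"
                    )
                lines.append(f"    {window:<9s} " + " | ".join(cells))
        lines.append("")
    else:
        lines.append("Per-window HRV: unavailable")
    for key, title in (
        ("fits_unadjusted", "GLS group x time + baseline (unadjusted)"),
        ("fits_adjusted", "GLS adjusted for BMI, smoking, physical activity"),
    ):
        fits = sections.get(key)
        if not fits:
            lines.append(f"{title}: unavailable")
            continue
        lines.append(title)
        for outcome, fit in fits.items():
            lines.append(f"  {outcome} (rho={_fmt(fit.rho)}, n={fit.n_obs}):")
            for _, row in fit.params.iterrows():
                lines.append(
                    f"    {row['term']:<28s} {_fmt(row['estimate']):>10s} "
                    f"[{_fmt(row['ci_low'])}, {_fmt(row['ci_high'])}] "
                    f"p={_fmt(row['p'])}"
                )
        lines.append("")
    cl = sections.get("clustering")
    if cl:
        best = cl["selected"]
        lines.append("Clustering (minimum within-cluster sum of squares)")
        for vars_, k, wss in cl["configs"]:
            lines.append(f"  candidate d={len(vars_)} k={k} "
                         f"({','.join(vars_)}): WSS={_fmt(wss)}")
        lines.append(
            f"  selected: {','.join(best.config.variables)}, k={best.config.k}, "
            f"sizes={best.sizes}, WSS={_fmt(best.wss)}"
        )
        rep = cl["report"]
        if rep.excluded_items:
            lines.append(f"  excluded questionnaire items: {rep.excluded_items}")
        if not rep.questionnaire_tests.empty:
            anova = rep.questionnaire_tests
            anova = anova[anova["method"] == "anova"]
            for _, row in anova.iterrows():
                lines.append(
                    f"  ANOVA {row['variable']:<14s} F={_fmt(row['statistic'])} "
                    f"p={_fmt(row['p'])}"
                )
        lines.append("")
    else:
        lines.append("Clustering: skipped")
    return "\n".join(lines) + "\n"
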