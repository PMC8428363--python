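"""End-to-end orchestration: slides -> tiles -> tumor tiles -> detections ->
scores -> patient markers -> statistics, plus cohort-assembly exclusions.

The pipeline is deterministic for a fixed configuration and seed: every
stochastic stage (bootstraps, backend training) is seeded from the run
seed, and re-running the same configuration reproduces the output bundle
bit-identically.

Slide accounting: every input slide appears exactly once in the per-slide
output with a status — ``scored`` (defined PTEN score), ``undefined`` (no
tumor cells found), or ``failed`` (the stage raised). Staining-failure
slides are *not* withheld: automatic scoring applies no staining QC, so a
no-antibody slide simply scores what it sees (typically 0 or undefined).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import scoring, survival
from .detector import OracleCellDetector
from .synthetic import GroundTruth
from .tiling import TileLabel, label_tiles, partition

__all__ = ["ExclusionRule", "STANDARD_EXCLUSION_RULES", "apply_exclusions",
           "SlideRecord", "RunConfig", "run_pipeline", "write_results"]


# ---------------------------------------------------------------------------
# cohort exclusions


@dataclass(frozen=True)
class ExclusionRule:
    """A named exclusion reading a boolean flag column of the cohort roster."""

    rule_id: str
    column: str

    def applies(self, row: pd.Series) -> bool:
        return bool(row.get(self.column, False))


_STANDARD_IDS = ("missing_consent", "short_followup", "no_tumor_material",
                 "preoperative_therapy", "postoperative_death",
                 "lost_followup")

STANDARD_EXCLUSION_RULES = {rid: ExclusionRule(rid, rid)
                            for rid in _STANDARD_IDS}


def apply_exclusions(roster: pd.DataFrame,
                     rules: Sequence[ExclusionRule | str] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort roster into eligible patients and an exclusion report.

    ``rules`` may mix ExclusionRule objects and standard rule ids. A patient
    is eligible iff no rule applies; the report counts triggers per rule (a
    patient with several flags is excluded once but counted under each
    rule). Returns ``(eligible, report)``.
    """
    if rules is None:
        rules = [r for r in STANDARD_EXCLUSION_RULES.values()
                 if r.column in roster.columns]
    resolved = []
    for r in rules:
        if isinstance(r, str):
            if r not in STANDARD_EXCLUSION_RULES:
                raise ValueError(f"unknown exclusion rule id {r!r}")
            r = STANDARD_EXCLUSION_RULES[r]
        resolved.append(r)
    triggered = {r.rule_id: 0 for r in resolved}
    excluded_mask = np.zeros(len(roster), dtype=bool)
    for i, (_, row) in enumerate(roster.iterrows()):
        for r in resolved:
            if r.applies(row):
                triggered[r.rule_id] += 1
                excluded_mask[i] = True
    eligible = roster.loc[~excluded_mask].reset_index(drop=True)
    report = pd.DataFrame({"rule": list(triggered), "n": list(triggered.values())})
    report.attrs["n_input"] = len(roster)
    report.attrs["n_excluded"] = int(excluded_mask.sum())
    report.attrs["n_eligible"] = len(eligible)
    return eligible, report


# ---------------------------------------------------------------------------
# pipeline configuration and run


@dataclass
class SlideRecord:
    """One slide entering the pipeline."""

    slide_id: str
    patient_id: str
    image: np.ndarray
    ground_truth: GroundTruth | None = None   # for oracle backends / labels
    annotations: list | None = None           # tumor polygons, if available


@dataclass
class RunConfig:
    """Pipeline run parameters; every seed consumed is derived from ``seed``."""

    detector_backend: str = "oracle"          # "oracle" or a fitted model
    cell_model: object | None = None          # fitted detector for "model"
    tumor_model: object | None = None         # fitted tile classifier or None
    tile_threshold: float = 0.5
    pten_threshold: float = 0.5
    n_bootstraps: int = 10_000
    seed: int = 0
    output_dir: str | Path | None = None


def _score_slide(record: SlideRecord, config: RunConfig) -> dict:
    tiles = partition(record.image, slide_id=record.slide_id)
    if record.annotations is not None:
        label_tiles(tiles, record.annotations)
    elif record.ground_truth is not None:
        label_tiles(tiles, record.ground_truth.tumor_polygons)

    if config.tumor_model is not None:
        probs = config.tumor_model.predict_proba(tiles)
        tumor_tiles = [t for t, p in zip(tiles, probs)
                       if p >= config.tile_threshold]
    else:
        tumor_tiles = [t for t in tiles if t.label == TileLabel.TUMOR]

    if config.detector_backend == "oracle":
        if record.ground_truth is None:
            raise ValueError(
                f"slide {record.slide_id}: oracle backend needs ground truth")
        model = OracleCellDetector(record.ground_truth)
    else:
        if config.cell_model is None:
            raise ValueError("model backend selected but cell_model is unset")
        model = config.cell_model

    detections = []
    for tile in tumor_tiles:
        detections.extend(model.detect(tile))
    ss = scoring.slide_pten_score(detections)
    return {
        "slide_id": record.slide_id,
        "patient_id": record.patient_id,
        "n_tiles": len(tiles),
        "n_tumor_tiles": len(tumor_tiles),
        "n_tumor_pos": ss.n_tumor_pos,
        "n_tumor_neg": ss.n_tumor_neg,
        "n_nontumor_pos": ss.n_nontumor_pos,
        "n_nontumor_neg": ss.n_nontumor_neg,
        "score": ss.score if ss.score is not None else np.nan,
        "status": "scored" if ss.score is not None else "undefined",
        "failure_mode": (record.ground_truth.failure_mode.value
                         if record.ground_truth is not None else "unknown"),
    }


def _patient_markers(slide_df: pd.DataFrame, cohort: pd.DataFrame | None,
                     config: RunConfig) -> pd.DataFrame:
    rows = []
    for pid, grp in slide_df.groupby("patient_id", sort=True):
        scores = [None if np.isnan(s) else float(s) for s in grp["score"]]
        score = scoring.patient_pten_score(scores)
        status = scoring.dichotomize_pten(score, config.pten_threshold)
        rows.append({"patient_id": pid,
                     "n_slides": len(grp),
                     "n_slides_scored": int(grp["status"].eq("scored").sum()),
                     "score": np.nan if score is None else score,
                     "pten_status": None if status is None else status.value})
    markers = pd.DataFrame(rows)
    if cohort is not None:
        keep = [c for c in ("patient_id", "ploidy", "capra_s", "manual_score",
                            "time", "event", "psa_years", "psa_values")
                if c in cohort.columns]
        markers = markers.merge(cohort[keep], on="patient_id", how="left")
    if "ploidy" in markers.columns:
        markers["ploidy_status"] = [
            None if s is None else s.value
            for s in (scoring.dichotomize_ploidy(c)
                      if isinstance(c, str) else None
                      for c in markers["ploidy"])]
        markers["combined"] = [
            None if c is None else c.value
            for c in (scoring.combined_marker(
                None if p is None else scoring.PtenStatus(p), pl)
                for p, pl in zip(markers["pten_status"], markers["ploidy"]))]
    if "capra_s" in markers.columns:
        integrated, groups = [], []
        for _, row in markers.iterrows():
            if pd.isna(row["capra_s"]):
                integrated.append(np.nan)
                groups.append(None)
                continue
            cap = scoring.capra_s_integrate(
                int(row["capra_s"]),
                None if row["pten_status"] is None
                else scoring.PtenStatus(row["pten_status"]),
                None if row.get("ploidy_status") is None
                else scoring.PloidyStatus(row["ploidy_status"]))
            integrated.append(cap.integrated)
            groups.append(cap.risk_group.value)
        markers["capra_s_integrated"] = integrated
        markers["risk_group"] = groups
    return markers


def _outcomes(markers: pd.DataFrame) -> pd.DataFrame | None:
    if {"psa_years", "psa_values"}.issubset(markers.columns):
        times, events = [], []
        for _, row in markers.iterrows():
            t = [float(x) for x in str(row["psa_years"]).split()]
            v = [float(x) for x in str(row["psa_values"]).split()]
            out = survival.derive_bcr(t, v)
            times.append(out.time)
            events.append(int(out.event))
        df = markers[["patient_id"]].copy()
        df["time"], df["event"] = times, events
        return df
    if {"time", "event"}.issubset(markers.columns):
        return markers[["patient_id", "time", "event"]].copy()
    return None


def _statistics(markers: pd.DataFrame, config: RunConfig) -> dict:
    stats: dict = {}
    outcomes = _outcomes(markers)
    if outcomes is None:
        return stats
    df = markers.drop(columns=[c for c in ("time", "event")
                               if c in markers.columns]
                      ).merge(outcomes, on="patient_id")
    df = df[df["pten_status"].notna()].copy()
    if len(df) < 10:
        return stats  # too few scored patients for meaningful inference
    df["pten_low"] = (df["pten_status"] == scoring.PtenStatus.LOW.value
                      ).astype(int)
    rng = np.random.default_rng(config.seed)
    B = config.n_bootstraps

    if df["pten_low"].nunique() == 2 and df["event"].sum() >= 2:
        chi2, p, _ = survival.logrank_test(df["time"], df["event"],
                                           df["pten_low"])
        cox = survival.cox_fit(df, "time", "event", ["pten_low"])
        conc = survival.harrell_cindex(
            df["time"], df["event"], df["pten_low"],
            n_bootstraps=B, seed=int(rng.integers(2 ** 31)))
        stats["pten"] = {
            "logrank_chi2": chi2, "logrank_p": p,
            "hr": float(cox.summary.loc[0, "hr"]),
            "hr_ci": [float(cox.summary.loc[0, "ci_low"]),
                      float(cox.summary.loc[0, "ci_high"])],
            "wald_p": float(cox.summary.loc[0, "p"]),
            "cindex": conc.cindex,
            "cindex_ci": [conc.ci_low, conc.ci_high],
        }
    if "combined" in df.columns and df["combined"].notna().all() \
            and df["combined"].nunique() > 1:
        cox = survival.cox_fit(
            df, "time", "event", ["combined"],
            categorical={"combined": scoring.CombinedMarker.BOTH_FAVORABLE.value})
        stats["combined"] = {
            r["covariate"]: {"hr": r["hr"], "hr_ci": [r["ci_low"], r["ci_high"]],
                             "p": r["p"]}
            for _, r in cox.summary.iterrows()}
        chi2, p, _ = survival.logrank_test(df["time"], df["event"],
                                           df["combined"])
        stats["combined"]["logrank_p"] = p
    if "manual_score" in df.columns and df["manual_score"].notna().all():
        manual_low = (df["manual_score"] < config.pten_threshold).astype(int)
        if manual_low.nunique() == 2:
            auc = survival.roc_auc(1 - manual_low, df["score"],
                                   n_bootstraps=B,
                                   seed=int(rng.integers(2 ** 31)))
            stats["auto_vs_manual"] = {
                "auc": auc.auc, "auc_ci": [auc.ci_low, auc.ci_high]}
        r, ci = survival.pearson_r(df["score"], df["manual_score"])
        stats.setdefault("auto_vs_manual", {})["pearson_r"] = r
        stats["auto_vs_manual"]["pearson_ci"] = list(ci)
    if "capra_s_integrated" in df.columns and df["capra_s"].notna().all():
        diff = survival.cindex_difference_test(
            df["time"], df["event"],
            df["capra_s_integrated"].astype(float),
            df["capra_s"].astype(float),
            n_bootstraps=B, seed=int(rng.integers(2 ** 31)))
        c_base = survival.concordance_index(df["time"], df["event"],
                                            df["capra_s"].astype(float))
        stats["capra_s"] = {
            "cindex_base": c_base,
            "cindex_integrated": c_base + diff.delta,
            "difference": diff.delta,
            "difference_ci": [diff.ci_low, diff.ci_high],
            "difference_p": diff.p,
        }
    return stats


def run_pipeline(slides: Sequence[SlideRecord],
                 cohort: pd.DataFrame | None = None,
                 config: RunConfig | None = None) -> dict:
    """Run the full scoring + statistics pipeline.

    Returns {"slide_scores": DataFrame, "patient_markers": DataFrame,
    "statistics": dict, "config": dict}; with ``config.output_dir`` set the
    bundle is also written to disk via :func:`write_results`.
    """
    config = config or RunConfig()
    slide_rows = []
    for rec in slides:
        try:
            slide_rows.append(_score_slide(rec, config))
        except Exception as err:  # stage-level failure stays accountable
            slide_rows.append({"slide_id": rec.slide_id,
                               "patient_id": rec.patient_id,
                               "status": "failed", "error": str(err),
                               "score": np.nan})
    slide_df = pd.DataFrame(slide_rows)
    markers = _patient_markers(slide_df, cohort, config)
    stats = _statistics(markers, config)
    cfg = {k: v for k, v in dataclasses.asdict(config).items()
           if k not in ("cell_model", "tumor_model")}
    cfg["output_dir"] = None if config.output_dir is None \
        else str(config.output_dir)
    results = {"slide_scores": slide_df, "patient_markers": markers,
               "statistics": stats, "config": cfg}
    if config.output_dir is not None:
        write_results(results, config.output_dir)
    return results


def write_results(results: dict, outdir: str | Path) -> dict:
    """Write the result bundle as CSV + JSON text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "slide_scores": outdir / "slide_scores.csv",
        "patient_markers": outdir / "patient_markers.csv",
        "statistics": outdir / "statistics.json",
        "run": outdir / "run.json",
    }
    results["slide_scores"].to_csv(paths["slide_scores"], index=False)
    results["patient_markers"].to_csv(paths["patient_markers"], index=False)
    paths["statistics"].write_text(
        json.dumps(results["statistics"], indent=1, sort_keys=True))
    paths["run"].write_text(json.dumps(results["config"], indent=1,
                                       sort_keys=True))
    return paths
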