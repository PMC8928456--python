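"""End-to-end orchestration: generate (or load) -> dosimetry -> match ->
significance -> constraint derivation -> RBE, with provenance and report
rendering.

Two entry points: :func:`run_pipeline` (full cohort with voxel samples) and
:func:`run_from_indices` (precomputed DVH index table), so the constraint /
RBE arithmetic is reproducible without any dose data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import DoseLETSampleSet, PatientRecord, generate_cohort
from .cohort_io import read_cohort, write_cohort
from .config import PipelineConfig, config_hash
from .dosimetry import index_table
from .inference_stats import index_significance_table
from .matching import balance_table, fit_propensity, greedy_match
from .rbe import Table3Result, rbe_with_ci

__all__ = ["RunReport", "run_pipeline", "run_from_indices", "incidence_summary", "table1_analog"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunReport:
    seed: int
    config_hash: str
    version: str
    cohort_summary: dict  # Table-1-analog
    incidence: dict
    balance: pd.DataFrame
    significance: pd.DataFrame  # Table-2-analog
    table3: Table3Result
    n_pairs: int


def incidence_summary(records: Sequence[PatientRecord]) -> dict:
    """Crude and site-restricted (oral cavity / oropharynx) necrosis
    incidence per modality, with numerators and denominators retained.
    Crude rates are rounded to 1 decimal place, site-restricted to 2."""
    out = {}
    for modality in ("photon", "proton"):
        sub = [r for r in records if r.modality == modality]
        events = sum(r.orn for r in sub)
        out[modality] = {
            "events": events,
            "n": len(sub),
            "percent": round(100.0 * events / len(sub), 1) if sub else None,
        }
        site = [r for r in sub if r.oropharynx_or_oral_cavity]
        site_events = sum(r.orn for r in site)
        out[f"{modality}_site_restricted"] = {
            "events": site_events,
            "n": len(site),
            "percent": round(100.0 * site_events / len(site), 2) if site else None,
        }
        if not sub or not site:
            out.setdefault("flags", []).append(f"zero denominator for {modality}")
    return out


def table1_analog(records: Sequence[PatientRecord]) -> dict:
    """Covariate counts and percentages (to 1 dp) overall and per modality."""
    groups = {
        "total": list(records),
        "photon": [r for r in records if r.modality == "photon"],
        "proton": [r for r in records if r.modality == "proton"],
    }

    def entry(sub, pred):
        count = sum(1 for r in sub if pred(r))
        return {
            "count": count,
            "percent": round(100.0 * count / len(sub), 1) if sub else None,
        }

    summary: dict = {}
    for gname, sub in groups.items():
        g: dict = {"n": len(sub)}
        g["female"] = entry(sub, lambda r: r.gender == "female")
        for stage in ("I", "II", "III", "IV", "X"):
            g[f"stage_{stage}"] = entry(sub, lambda r, s=stage: r.stage == s)
        for flag in (
            "chemo",
            "hypertension",
            "diabetes",
            "dental_extraction",
            "smoking_history",
            "current_smoker",
            "oropharynx_or_oral_cavity",
            "orn",
        ):
            g[flag] = entry(sub, lambda r, f=flag: bool(getattr(r, f)))
        ages = [r.age for r in sub]
        g["age_median"] = float(np.median(ages)) if ages else None
        summary[gname] = g
    return summary


def _write_csv(df: pd.DataFrame, path: Path, chash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=index)


def _table3_frame(t3: Table3Result, dose_levels) -> pd.DataFrame:
    rows = []
    for (modality, level), cv in t3.critical.items():
        rows.append(
            {
                "modality": modality,
                "dose_level": level,
                "critical_volume_cc": round(cv.critical_value, 2),
                "ci_low": round(cv.ci_low, 2),
                "ci_high": round(cv.ci_high, 2),
                "auc": round(cv.auc, 3),
                "auc_ci_low": round(cv.auc_ci[0], 3),
                "auc_ci_high": round(cv.auc_ci[1], 3),
                "tpr": round(cv.tpr_at, 3),
                "fpr": round(cv.fpr_at, 3),
            }
        )
    df_cv = pd.DataFrame(rows)
    rows = []
    for est in t3.estimates:
        rows.append(
            {
                "modality": "rbe",
                "dose_level": est.proton_nominal_dose,
                "equivalent_dose_gy": round(est.equivalent_constraint_dose, 2),
                "eq_ci_low": round(est.equivalent_dose_ci[0], 2),
                "eq_ci_high": round(est.equivalent_dose_ci[1], 2),
                "rbe": round(est.rbe, 3),
                "rbe_ci_low": round(est.ci_low, 3),
                "rbe_ci_high": round(est.ci_high, 3),
                "extrapolated": est.extrapolated,
            }
        )
    return pd.concat([df_cv, pd.DataFrame(rows)], ignore_index=True)


def _report_json(report: RunReport, t3: Table3Result) -> dict:
    return {
        "provenance": {
            "seed": report.seed,
            "config_hash": report.config_hash,
            "version": report.version,
        },
        "cohort_summary": report.cohort_summary,
        "incidence": report.incidence,
        "n_pairs": report.n_pairs,
        "significance": json.loads(report.significance.to_json(orient="index")),
        "balance": json.loads(report.balance.to_json(orient="index")),
        "critical_volumes": {
            f"{m}_v{l:g}": dataclasses.asdict(cv) for (m, l), cv in t3.critical.items()
        },
        "rbe_estimates": [dataclasses.asdict(e) for e in t3.estimates],
        "extrapolation_rate": {f"{k:g}": v for k, v in t3.extrapolation_rate.items()},
        "repair_rate": t3.repair_rate,
        "bootstrap_rejected": t3.n_rejected,
    }


def run_from_indices(
    indices: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Optional[Path] = None,
) -> Table3Result:
    """Indices-only entry point: constraint derivation + RBE from a
    precomputed DVH index table (columns modality, orn, v40...)."""
    spec = dataclasses.replace(config.bootstrap, seed=config.seed)
    t3 = rbe_with_ci(indices, config.dose_levels, spec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        chash = config_hash(config)
        _write_csv(_table3_frame(t3, config.dose_levels), out_dir / "table3.csv", chash, index=False)
    return t3


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    cohort_dir: Optional[Path] = None,
) -> RunReport:
    """Run the full analysis; writes all intermediate artifacts under
    ``out_dir`` and returns the rendered report.

    If ``cohort_dir`` is given the cohort is loaded from disk instead of
    generated. Deterministic for a given config and seed. On stage failure
    a FAILED marker naming the stage is written and the error re-raised.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    stage = "init"
    try:
        stage = "cohort"
        if cohort_dir is not None:
            records, samples = read_cohort(cohort_dir)
        else:
            records, samples = generate_cohort(
                config.covariates,
                config.confounding,
                config.dose_field,
                config.outcome,
                config.n_patients,
                config.seed,
            )
            write_cohort(records, samples, out_dir / "cohort")

        stage = "dosimetry"
        indices = index_table(records, samples)
        _write_csv(indices, out_dir / "indices.csv", chash, index=False)

        stage = "matching"
        prop = fit_propensity(records)
        matched = greedy_match(prop, records)
        pairs_df = pd.DataFrame(
            [
                {
                    "proton_id": p,
                    "photon_id": g,
                    "score_proton": prop.scores[p],
                    "score_photon": prop.scores[g],
                }
                for p, g in matched.pairs
            ]
        )
        _write_csv(pairs_df, out_dir / "pairs.csv", chash, index=False)
        balance = balance_table(records, matched.pairs)
        _write_csv(balance, out_dir / "balance.csv", chash)

        stage = "significance"
        matched_ids = {pid for pair in matched.pairs for pid in pair}
        matched_indices = indices[indices["patient_id"].isin(matched_ids)].reset_index(drop=True)
        significance = index_significance_table(matched_indices)
        _write_csv(significance, out_dir / "table2.csv", chash)

        stage = "rbe"
        spec = dataclasses.replace(config.bootstrap, seed=config.seed)
        t3 = rbe_with_ci(matched_indices, config.dose_levels, spec)
        _write_csv(_table3_frame(t3, config.dose_levels), out_dir / "table3.csv", chash, index=False)

        stage = "report"
        report = RunReport(
            seed=config.seed,
            config_hash=chash,
            version=__version__,
            cohort_summary=table1_analog(records),
            incidence=incidence_summary(records),
            balance=balance,
            significance=significance,
            table3=t3,
            n_pairs=len(matched.pairs),
        )
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_report_json(report, t3), fh, indent=2, sort_keys=True)
            fh.write("\n")

        if config.render_plots:
            stage = "plots"
            _render_plots(indices, t3, samples, records, out_dir)
        return report
    except BaseException as exc:
        (out_dir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(stage, exc) from exc


def _render_plots(indices, t3, samples, records, out_dir: Path) -> None:
    """Box plots (whiskers at half the IQR beyond the quartiles), tolerance
    curves, and a DLVH heatmap for the first proton patient."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .dosimetry import compute_dlvh, dlvh_contour

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    cols = ["v40", "v50", "v60", "v70", "v75"]
    for ax, modality, color in zip(axes, ("photon", "proton"), ("C0", "C3")):
        sub = indices[indices["modality"] == modality]
        data = [sub[c].to_numpy(float) for c in cols]
        whis = [
            (
                np.percentile(d, 25) - 0.5 * (np.percentile(d, 75) - np.percentile(d, 25)),
                np.percentile(d, 75) + 0.5 * (np.percentile(d, 75) - np.percentile(d, 25)),
            )
            for d in data
        ]
        bp = ax.boxplot(data, tick_labels=cols, whis=0.0, showfliers=False, patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(color)
        for i, (lo, hi) in enumerate(whis):
            ax.plot([i + 1, i + 1], [lo, hi], color="k", lw=0.8, zorder=0)
        ax.set_title(modality)
        ax.set_ylabel("volume (cc)")
    fig.tight_layout()
    fig.savefig(out_dir / "boxplots.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for modality, color in (("photon", "C0"), ("proton", "C3")):
        pts = sorted((l, cv.critical_value) for (m, l), cv in t3.critical.items() if m == modality)
        ax.plot([p[0] for p in pts], [p[1] for p in pts], "o-", color=color, label=modality)
    ax.set_xlabel("dose level (Gy[RBE])")
    ax.set_ylabel("critical volume (cc)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "tolerance_curves.png", dpi=120)
    plt.close(fig)

    proton_ids = {r.patient_id for r in records if r.modality == "proton"}
    proton_samples = next((s for s in samples if s.patient_id in proton_ids), None)
    if proton_samples is not None:
        surface = compute_dlvh(proton_samples)
        fig, ax = plt.subplots(figsize=(5.5, 4))
        mesh = ax.pcolormesh(
            surface.dose_grid, surface.let_grid, surface.volume_fraction.T, shading="auto"
        )
        fig.colorbar(mesh, ax=ax, label="volume fraction")
        for pct, color in ((5, "w"), (20, "orange"), (50, "r")):
            contour = dlvh_contour(surface, pct)
            if contour.points:
                ax.plot(*zip(*contour.points), color=color, lw=1.2, label=f"DL{pct}%")
        ax.set_xlabel("dose (Gy[RBE=1.1])")
        ax.set_ylabel("LET (keV/um)")
        ax.legend(loc="upper right")
        fig.tight_layout()
        fig.savefig(out_dir / "dlvh.png", dpi=120)
        plt.close(fig)
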