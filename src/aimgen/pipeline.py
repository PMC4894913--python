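"""End-to-end analysis: simulate/ingest -> decompose -> phi -> curves -> stats.

``analyze_cohort`` is the library entry point and returns every intermediate
product in memory; ``run_pipeline`` wraps it with file I/O, a run manifest,
and optional figures.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import curves as curves_mod
from . import io as io_mod
from . import phi as phi_mod
from . import stats as stats_mod
from .preprocess import cohort_series, plateau
from .simulate import CohortConfig, simulate_cohort

log = logging.getLogger("aimgen")

#: catch-probe location label per group; aim and aim_target share the 30 deg
#: probe (identical paradigms until the aftereffect) and are pooled for phi
CATCH_LOCATION = {
    "target": "0",
    "aim": "30",
    "aim_target": "30",
    "extreme_ccw": "60",
    "extreme_cw": "-90",
    "cursor": "-30",
    "hand": "45",
}


def phi_location_table(subject_phi: pd.DataFrame) -> pd.DataFrame:
    """Attach the catch-location factor to per-subject mean phi."""
    out = subject_phi.copy()
    out["catch_location"] = out["group_name"].map(CATCH_LOCATION)
    return out


def location_groups(subject_phi: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-location arrays of subject mean phi (locations as labels)."""
    table = phi_location_table(subject_phi)
    table = table[~table["mean_phi"].isna()]
    return {
        loc: sub["mean_phi"].to_numpy(dtype=float)
        for loc, sub in table.groupby("catch_location", sort=False)
    }


def plateau_summary(series_by_subject) -> pd.DataFrame:
    """Per-subject plateau (last 100 rotation trials) of reach, aim, implicit."""
    rows = []
    for sid, series in series_by_subject.items():
        rows.append(
            {
                "subject_id": sid,
                "group_name": series.group_name,
                "plateau_reach": plateau(series.reach_angle),
                "plateau_aim": plateau(series.aim_angle),
                "plateau_implicit": plateau(series.calculated_implicit),
            }
        )
    return pd.DataFrame(rows)


def catch_vs_aftereffect_table(series_by_subject) -> pd.DataFrame:
    """Long table for the mixed RM-ANOVA: plateau catch vs early aftereffect.

    Plateau catch is the mean of the last two catch trials; early aftereffect
    the mean of the first four aftereffect trials.
    """
    rows = []
    for sid, series in series_by_subject.items():
        if len(series.catch_magnitude) < 2 or len(series.aftereffect_magnitude) < 4:
            log.warning("subject %s lacks catch/aftereffect trials; dropped", sid)
            continue
        rows.append(
            {"subject": sid, "group": series.group_name, "time": "plateau_catch",
             "value": float(np.mean(series.catch_magnitude[-2:]))}
        )
        rows.append(
            {"subject": sid, "group": series.group_name, "time": "early_aftereffect",
             "value": float(np.mean(series.aftereffect_magnitude[:4]))}
        )
    return pd.DataFrame(rows)


def analyze_cohort(
    trials: pd.DataFrame,
    min_subjects: int = curves_mod.DEFAULT_MIN_SUBJECTS,
    cosine_period: float | None = None,
) -> dict:
    """Run the full analysis on a trial table; returns all products."""
    series = cohort_series(trials)
    log.info("preprocessed %d subjects", len(series))

    phi_records = phi_mod.phi_table(series)
    retained, retention = phi_mod.filter_phi(phi_records)
    subject_phi = phi_mod.subject_mean_phi(phi_records)
    log.info("phi: %d/%d retained", retention["retained"], retention["total"])

    results: list[stats_mod.StatResult] = []
    results.append(phi_mod.catch_number_anova(retained))

    by_location = location_groups(subject_phi)
    for loc, vals in by_location.items():
        if len(vals) >= 2:
            results.append(
                stats_mod.one_sample_t(vals, 1.0, effect=f"phi[{loc}] vs 1")
            )
    if len(by_location) >= 2:
        results.append(
            stats_mod.one_way_anova(by_location, effect="phi ~ catch_location")
        )
        if "30" in by_location:
            pairs = [("30", loc) for loc in by_location if loc != "30"]
            results.extend(stats_mod.fisher_lsd(by_location, pairs))

    # within-subject check in the target group: last catch vs first aftereffect
    target = [s for s in series.values() if s.group_name == "target"]
    if len(target) >= 2:
        last_catch = [s.catch_magnitude[-1] for s in target]
        first_after = [s.aftereffect_magnitude[0] for s in target]
        results.append(
            stats_mod.paired_t(last_catch, first_after,
                               effect="target: last catch vs first aftereffect")
        )

    mixed_table = catch_vs_aftereffect_table(series)
    mixed = {}
    if len(mixed_table) and mixed_table["group"].nunique() >= 2:
        mixed = stats_mod.mixed_rm_anova(mixed_table)
        results.extend(
            stats_mod.StatResult(f"catch_vs_aftereffect: {k}", r.statistic, r.df, r.p_value)
            for k, r in mixed.items()
        )

    subject_curves = [curves_mod.subject_curve(s) for s in series.values()]
    pooled = curves_mod.pool_curves(subject_curves, min_subjects=min_subjects)
    cosine = None
    folded = None
    folded_detail = None
    if len(pooled.offsets) >= 4:
        cosine = curves_mod.fit_cosine(pooled, period=cosine_period)
        folded, folded_detail = curves_mod.fold_and_correlate(pooled)
        results.append(folded)

    rotation = trials[trials["block_label"] == "rotation"]
    angle_fits = {}
    for label, col in (("cursor", "cursor_angle"), ("hand", "reach_angle")):
        angle_fits[label] = curves_mod.fit_angle_gaussian(
            rotation[col].to_numpy(dtype=float)
        )
    aim_angles = rotation["reported_landmark"].to_numpy(dtype=float, na_value=math.nan)
    angle_fits["aim"] = curves_mod.fit_angle_gaussian(aim_angles * -5.625)

    return {
        "series": series,
        "phi_records": phi_records,
        "phi_retained": retained,
        "retention": retention,
        "subject_phi": phi_location_table(subject_phi),
        "plateaus": plateau_summary(series),
        "mixed_table": mixed_table,
        "mixed_anova": mixed,
        "stat_results": results,
        "subject_curves": subject_curves,
        "pooled_curve": pooled,
        "cosine_fit": cosine,
        "folded_correlation": folded,
        "folded_detail": folded_detail,
        "angle_fits": angle_fits,
    }


def _stats_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "statistic": r.statistic,
                "df": "x".join(str(d) for d in r.df),
                "p_value": r.p_value,
                "alpha": stats_mod.ALPHA,
                "note": r.note,
            }
            for r in results
        ]
    )


def _curve_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {"offset_deg": curve.offsets, "mean_implicit": curve.means,
         "n_subjects": curve.n_subjects}
    )


def run_pipeline(
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir="aimgen_run",
    trials: pd.DataFrame | None = None,
    min_subjects: int = curves_mod.DEFAULT_MIN_SUBJECTS,
    cosine_period: float | None = None,
    figures: bool = False,
) -> dict:
    """Simulate (unless ``trials`` given), analyze, and write all artifacts.

    Deterministic under fixed (config, seed).  On failure, partially written
    outputs are removed.  Returns the manifest dict.
    """
    cfg = config or CohortConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        if trials is None:
            trials = simulate_cohort(cfg, seed=seed)
            log.info("simulated %d trials", len(trials))
        path = out / "trials.csv"
        io_mod.write_trial_table(trials, path)
        written["trials"] = path

        res = analyze_cohort(trials, min_subjects=min_subjects, cosine_period=cosine_period)

        res["phi_records"].to_csv(out / "phi.csv", index=False)
        written["phi"] = out / "phi.csv"
        res["subject_phi"].to_csv(out / "subject_phi.csv", index=False)
        written["subject_phi"] = out / "subject_phi.csv"
        res["plateaus"].to_csv(out / "plateaus.csv", index=False)
        written["plateaus"] = out / "plateaus.csv"
        _stats_frame(res["stat_results"]).to_csv(out / "stats.csv", index=False)
        written["stats"] = out / "stats.csv"
        _curve_frame(res["pooled_curve"]).to_csv(out / "pooled_curve.csv", index=False)
        written["pooled_curve"] = out / "pooled_curve.csv"

        report_lines = [
            f"aimgen run (seed={seed})",
            f"subjects: {len(res['series'])}",
            "phi retention: {retained}/{total} ({retained_fraction:.1%}), "
            "{undefined} undefined".format(**res["retention"]),
        ]
        if res["cosine_fit"] is not None:
            f = res["cosine_fit"]
            report_lines.append(
                f"cosine fit: center {f.center:.2f} deg, amplitude {f.amplitude:.2f} deg, "
                f"period {f.period:.0f} deg, R^2 {f.r_squared:.3f}"
            )
        if res["folded_correlation"] is not None:
            fc = res["folded_correlation"]
            report_lines.append(
                f"folded-angle correlation: r = {fc.statistic:.2f}, p = {fc.p_value:.4f}"
            )
        for label, fit in res["angle_fits"].items():
            report_lines.append(
                f"{label} angle distribution: mean {fit.center:.2f} deg, "
                f"SD {fit.width:.2f} deg, R^2 {fit.r_squared:.3f}"
            )
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        written["report"] = out / "report.txt"

        if figures:
            _write_figures(res, out)
            written["figures"] = out / "curves.png"

        manifest = io_mod.write_manifest(
            out / "manifest.json", config=cfg, seed=seed, artifacts=written
        )
        res["manifest"] = manifest
        return res
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise


def _write_figures(res: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    pooled = res["pooled_curve"]
    axes[0].plot(pooled.offsets, pooled.means, "o-", label="pooled curve")
    if res["cosine_fit"] is not None:
        f = res["cosine_fit"]
        grid = np.linspace(pooled.offsets.min(), pooled.offsets.max(), 200)
        axes[0].plot(
            grid,
            f.amplitude * np.cos(2 * np.pi * (grid - f.center) / f.period) + f.offset_term,
            label="cosine fit",
        )
    axes[0].set_xlabel("offset from modal aim (deg)")
    axes[0].set_ylabel("implicit (deg)")
    axes[0].legend()

    table = res["subject_phi"]
    means = table.groupby("catch_location")["mean_phi"].mean()
    axes[1].bar(means.index, means.values)
    axes[1].set_xlabel("catch location (deg)")
    axes[1].set_ylabel("mean phi")
    fig.tight_layout()
    fig.savefig(out / "curves.png", dpi=120)
    plt.close(fig)
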