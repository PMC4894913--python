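"""The phi catch-trial statistic: generalization as a proportion.

For catch trial *i*, ``phi_i`` is the catch-trial magnitude divided by the
mean calculated implicit over the four rotation trials immediately preceding
the probe.  ``phi = 1`` means the no-feedback probe fully expressed the
implicit learning inferred from the aim reports (complete generalization at
the probe direction); smaller values mean the learning did not carry to that
direction.  Values outside (-2.3, 2.3) are treated as outliers and dropped;
near-zero denominators (|bin mean| below an epsilon guard) make phi
undefined and the record is excluded with a logged reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import SubjectSeries
from .stats import StatResult, one_way_anova

PHI_OUTLIER_BOUND = 2.3
DENOMINATOR_EPS = 0.5  # degrees; |bin mean| below this makes phi undefined


@dataclass(frozen=True)
class PhiRecord:
    """One catch trial's phi value and its provenance."""

    subject_id: str
    group_name: str
    catch_index: int
    catch_magnitude: float
    implicit_bin_mean: float
    phi: float
    retained: bool
    reason: str = ""


def phi_for_catch(
    catch_magnitude: float,
    preceding_implicit,
    *,
    subject_id: str = "",
    group_name: str = "",
    catch_index: int = 0,
    eps: float = DENOMINATOR_EPS,
) -> PhiRecord:
    """Compute phi for one catch trial from its 4-trial pre-probe bin.

    ``preceding_implicit`` must hold exactly the four calculated-implicit
    values from the rotation trials immediately before the probe; NaNs
    (missing aim reports) are excluded from the bin mean.
    """
    bin_vals = np.asarray(preceding_implicit, dtype=float)
    if bin_vals.shape != (4,):
        raise ValueError(
            f"need exactly 4 preceding implicit trials, got {bin_vals.shape}"
        )
    good = bin_vals[~np.isnan(bin_vals)]
    if len(good) == 0:
        denom = math.nan
    else:
        denom = float(good.mean())
    if math.isnan(denom) or abs(denom) < eps:
        return PhiRecord(
            subject_id, group_name, catch_index, float(catch_magnitude),
            denom, math.nan, False, reason="denominator_near_zero",
        )
    phi = float(catch_magnitude) / denom
    retained = -PHI_OUTLIER_BOUND <= phi <= PHI_OUTLIER_BOUND
    return PhiRecord(
        subject_id, group_name, catch_index, float(catch_magnitude),
        denom, phi, retained, reason="" if retained else "outlier",
    )


def subject_phi_records(series: SubjectSeries) -> list[PhiRecord]:
    """Phi records for every catch probe of one subject."""
    records = []
    for i, (mag, anchor) in enumerate(
        zip(series.catch_magnitude, series.probe_trials), start=1
    ):
        if anchor < 4:
            raise ValueError(
                f"subject {series.subject_id}: probe after rotation trial "
                f"{anchor} has fewer than 4 preceding trials"
            )
        bin_vals = series.calculated_implicit[anchor - 4 : anchor]
        records.append(
            phi_for_catch(
                mag,
                bin_vals,
                subject_id=series.subject_id,
                group_name=series.group_name,
                catch_index=i,
            )
        )
    return records


def phi_table(series_by_subject: dict[str, SubjectSeries]) -> pd.DataFrame:
    """Cohort-wide phi table, one row per catch trial."""
    rows = []
    for series in series_by_subject.values():
        rows.extend(vars(r) for r in subject_phi_records(series))
    return pd.DataFrame(rows)


def filter_phi(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the +/-2.3 outlier rule (strict inequalities; boundary kept).

    Returns the retained rows and a retention report with counts.  Undefined
    phi values (near-zero denominators) are excluded and counted separately.
    """
    defined = records[~records["phi"].isna()]
    retained = defined[defined["phi"].abs() <= PHI_OUTLIER_BOUND]
    report = {
        "total": int(len(records)),
        "defined": int(len(defined)),
        "retained": int(len(retained)),
        "undefined": int(len(records) - len(defined)),
        "retained_fraction": len(retained) / len(records) if len(records) else math.nan,
    }
    return retained.reset_index(drop=True), report


def subject_mean_phi(records: pd.DataFrame) -> pd.DataFrame:
    """Mean retained phi per subject.

    Subjects with zero retained records are flagged (``n_retained == 0``,
    NaN mean) so group-level tests can drop them explicitly.
    """
    out = []
    for sid, sub in records.groupby("subject_id", sort=False):
        kept = sub[sub["retained"]]
        out.append(
            {
                "subject_id": sid,
                "group_name": sub["group_name"].iloc[0],
                "mean_phi": float(kept["phi"].mean()) if len(kept) else math.nan,
                "n_retained": int(len(kept)),
            }
        )
    return pd.DataFrame(out)


def catch_number_anova(retained: pd.DataFrame) -> StatResult:
    """One-way fixed-effects ANOVA on phi with catch-trial number as factor.

    Tests whether the proportion drifts across the seven probes; a flat
    profile justifies averaging phi within subject.
    """
    groups = {
        int(i): sub["phi"].to_numpy(dtype=float)
        for i, sub in retained.groupby("catch_index")
    }
    return one_way_anova(groups, effect="phi ~ catch_number")
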