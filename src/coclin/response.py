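"""Treatment-response tables and waterfall orderings.

Response of a lesion is quantified as the percent change of a chosen imaging
biomarker between the baseline (T0) and follow-up (T1) studies:
``RR = 100 * (followup - baseline) / baseline``; negative values indicate
shrinkage/decrease. A cohort's records, ordered from the smallest to the
greatest response, form the waterfall plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidInputError, UndefinedResponseError
from .features import LesionFeatures


@dataclass
class ResponseRecord:
    subject_id: str
    cohort: str                     # "patient" or "PDX"
    lesion_label: str
    feature_name: str
    baseline_value: float
    followup_value: float
    response_rate: float            # percent change from baseline
    baseline_date: str = ""
    followup_date: str = ""
    location: str = ""
    modality: str = "MR"


def response_rate(baseline: float, followup: float) -> float:
    """Percent change from baseline: 100 * (followup - baseline) / baseline."""
    if baseline == 0:
        raise UndefinedResponseError("response rate undefined for zero baseline")
    return 100.0 * (followup - baseline) / baseline


def build_response_table(
    features: Iterable[LesionFeatures],
    feature_name: str,
    baseline_tp: str = "T0",
    followup_tp: str = "T1",
    cohort: str = "patient",
) -> tuple[list[ResponseRecord], list[dict]]:
    """One ResponseRecord per subject x lesion present at both timepoints.

    Subject/lesion pairs missing either timepoint (or with a zero baseline,
    for which the rate is undefined) are returned in the exclusion list
    rather than silently dropped.
    """
    if feature_name not in LesionFeatures.FEATURE_NAMES:
        raise InvalidInputError(f"unknown feature {feature_name!r}")
    by_key: dict[tuple[str, str], dict[str, LesionFeatures]] = {}
    for f in features:
        by_key.setdefault((f.subject_id, f.lesion_label), {})[f.timepoint] = f

    records: list[ResponseRecord] = []
    exclusions: list[dict] = []
    for (subject, lesion), tps in sorted(by_key.items()):
        missing = [tp for tp in (baseline_tp, followup_tp) if tp not in tps]
        if missing:
            exclusions.append(
                {"subject_id": subject, "lesion_label": lesion,
                 "reason": f"missing timepoint(s): {', '.join(missing)}"}
            )
            continue
        t0, t1 = tps[baseline_tp], tps[followup_tp]
        base, follow = t0.value(feature_name), t1.value(feature_name)
        try:
            rr = response_rate(base, follow)
        except UndefinedResponseError:
            exclusions.append(
                {"subject_id": subject, "lesion_label": lesion,
                 "reason": "zero baseline value"}
            )
            continue
        records.append(
            ResponseRecord(
                subject_id=subject,
                cohort=cohort,
                lesion_label=lesion,
                feature_name=feature_name,
                baseline_value=base,
                followup_value=follow,
                response_rate=rr,
                baseline_date=t0.study_date,
                followup_date=t1.study_date,
                modality=t0.modality,
            )
        )
    return records, exclusions


def waterfall_order(records: Sequence[ResponseRecord]) -> list[ResponseRecord]:
    """Sort records ascending by response rate (ties by subject id).

    Patient and PDX cohorts are plotted side by side, so callers order each
    cohort's records independently.
    """
    names = {r.feature_name for r in records}
    if len(names) > 1:
        raise InvalidInputError(f"mixed feature names in waterfall input: {sorted(names)}")
    return sorted(records, key=lambda r: (r.response_rate, r.subject_id))


def response_table_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """Records as a DataFrame, one row per lesion, for CSV export."""
    cols = [
        "subject_id", "cohort", "lesion_label", "location", "feature_name",
        "baseline_date", "followup_date", "modality",
        "baseline_value", "followup_value", "response_rate",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
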