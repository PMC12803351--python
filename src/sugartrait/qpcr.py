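"""qPCR density dynamics: normalized delta-Ct fold changes and the
ratio t-test against no change.

Fold changes between a reference condition/timepoint and a sample are
computed directly from Ct values normalized to culture volume (in
vitro) or fecal weight (in vivo):

    dCt = (Ct_reference - Ct_sample) + log2(w_sample / w_reference)
    fold_change = 2 ** dCt

Lower Ct means more template, so a sample with fewer cycles than the
reference has expanded.  The weight term is applied exactly as given;
absolute copy numbers are never computed (only relative change within a
strain is meaningful without a standard curve).

Not-detected (ND) reactions propagate as a ``not_detected`` call rather
than being imputed; an optional censoring mode imputes them at the
terminal cycle for users who prefer a bounded estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXPANDED = "expanded"
NOT_EXPANDED = "not_expanded"
NOT_DETECTED = "not_detected"

CT_CEILING = 40.0  # total cycles run; used only in censoring-imputation mode


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement of one strain in one sample."""

    sample_id: str
    strain: str
    condition: str
    timepoint: float
    ct_value: Optional[float]  # None encodes ND (not detected)
    normalizer_value: float
    normalizer_kind: str = "volume"  # or "weight"

    def __post_init__(self) -> None:
        if self.ct_value is not None and not (0 < self.ct_value <= CT_CEILING):
            raise ValueError(f"ct_value {self.ct_value} outside (0, {CT_CEILING}]")
        if self.normalizer_value <= 0:
            raise ValueError("normalizer_value must be positive")

    @property
    def detected(self) -> bool:
        return self.ct_value is not None


@dataclass(frozen=True)
class FoldChangeResult:
    strain: str
    condition: str
    delta_ct: Optional[float]
    fold_change: Optional[float]
    growth_call: str
    ct_reference: Optional[float] = None
    ct_sample: Optional[float] = None
    normalizer_reference: Optional[float] = None
    normalizer_sample: Optional[float] = None


def fold_change_from_ct(
    reference: CtRecord,
    sample: CtRecord,
    impute_nd_at_ceiling: bool = False,
) -> FoldChangeResult:
    """Fold change of a strain from a reference record to a sample record.

    Both records must concern the same strain and carry the same kind of
    normalizer.  ND in either record yields a ``not_detected`` result
    unless ``impute_nd_at_ceiling`` replaces missing Cts with the
    terminal cycle number.
    """
    if reference.strain != sample.strain:
        raise ValueError(
            f"strain mismatch: {reference.strain!r} vs {sample.strain!r}"
        )
    if reference.normalizer_kind != sample.normalizer_kind:
        raise ValueError(
            "normalizer kinds differ: "
            f"{reference.normalizer_kind!r} vs {sample.normalizer_kind!r}"
        )
    ct_ref, ct_smp = reference.ct_value, sample.ct_value
    if impute_nd_at_ceiling:
        ct_ref = CT_CEILING if ct_ref is None else ct_ref
        ct_smp = CT_CEILING if ct_smp is None else ct_smp
    if ct_ref is None or ct_smp is None:
        return FoldChangeResult(
            strain=sample.strain,
            condition=sample.condition,
            delta_ct=None,
            fold_change=None,
            growth_call=NOT_DETECTED,
            ct_reference=reference.ct_value,
            ct_sample=sample.ct_value,
            normalizer_reference=reference.normalizer_value,
            normalizer_sample=sample.normalizer_value,
        )
    dct = (ct_ref - ct_smp) + math.log2(
        sample.normalizer_value / reference.normalizer_value
    )
    fc = 2.0**dct
    return FoldChangeResult(
        strain=sample.strain,
        condition=sample.condition,
        delta_ct=dct,
        fold_change=fc,
        growth_call=EXPANDED if fc > 1 else NOT_EXPANDED,
        ct_reference=ct_ref,
        ct_sample=ct_smp,
        normalizer_reference=reference.normalizer_value,
        normalizer_sample=sample.normalizer_value,
    )


def classify_growth(result: FoldChangeResult) -> str:
    """Growth call over the assay horizon: expansion means fold change
    strictly greater than 1; ND propagates."""
    if result.fold_change is None:
        return NOT_DETECTED
    return EXPANDED if result.fold_change > 1 else NOT_EXPANDED


def average_technical_replicates(records: Sequence[CtRecord]) -> CtRecord:
    """Collapse technical qPCR duplicates by averaging on the Ct scale.

    All records must share sample, strain, condition and timepoint.  An
    ND replicate makes the collapsed record ND (conservative).
    """
    if not records:
        raise ValueError("no records to average")
    first = records[0]
    for r in records[1:]:
        key = (r.sample_id, r.strain, r.condition, r.timepoint, r.normalizer_kind)
        if key != (
            first.sample_id,
            first.strain,
            first.condition,
            first.timepoint,
            first.normalizer_kind,
        ):
            raise ValueError("technical replicates must share all identifiers")
    if any(not r.detected for r in records):
        ct = None
    else:
        ct = float(np.mean([r.ct_value for r in records]))
    return CtRecord(
        sample_id=first.sample_id,
        strain=first.strain,
        condition=first.condition,
        timepoint=first.timepoint,
        ct_value=ct,
        normalizer_value=float(np.mean([r.normalizer_value for r in records])),
        normalizer_kind=first.normalizer_kind,
    )


def fold_changes_from_table(
    table: pd.DataFrame,
    reference_time: float = 0.0,
    horizon: float = 72.0,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Per-strain fold changes between two timepoints of a Ct table.

    Expects columns sample_id, strain, condition, timepoint_h, ct,
    normalizer_value, normalizer_kind; ``ct`` may contain the string
    "ND" or be empty for undetected reactions.  Technical replicates
    (identical identifying columns) are averaged on the Ct scale first.
    With ``per_replicate`` the sample_id is treated as a biological
    replicate label shared by the reference and sample wells, and one
    fold change is reported per (strain, condition, replicate).
    """
    req = {
        "sample_id",
        "strain",
        "condition",
        "timepoint_h",
        "ct",
        "normalizer_value",
        "normalizer_kind",
    }
    if missing := req - set(table.columns):
        raise ValueError(f"Ct table missing columns {sorted(missing)}")

    def to_record(rows: pd.DataFrame) -> CtRecord:
        recs = []
        for _, r in rows.iterrows():
            raw = r["ct"]
            nd = pd.isna(raw) or str(raw).strip().upper() == "ND"
            recs.append(
                CtRecord(
                    sample_id=str(r["sample_id"]),
                    strain=str(r["strain"]),
                    condition=str(r["condition"]),
                    timepoint=float(r["timepoint_h"]),
                    ct_value=None if nd else float(raw),
                    normalizer_value=float(r["normalizer_value"]),
                    normalizer_kind=str(r["normalizer_kind"]),
                )
            )
        return average_technical_replicates(recs)

    keys = ["strain", "condition"] + (["sample_id"] if per_replicate else [])
    out = []
    for key, sub in table.groupby(keys, sort=True):
        ref_rows = sub[sub["timepoint_h"] == reference_time]
        smp_rows = sub[sub["timepoint_h"] == horizon]
        if ref_rows.empty or smp_rows.empty:
            continue
        res = fold_change_from_ct(to_record(ref_rows), to_record(smp_rows))
        row = {
            "strain": key[0],
            "condition": key[1],
            "delta_ct": res.delta_ct,
            "fold_change": res.fold_change,
            "growth_call": res.growth_call,
        }
        if per_replicate:
            row["replicate"] = key[2]
        out.append(row)
    cols = ["strain", "condition"]
    cols += ["replicate"] if per_replicate else []
    cols += ["delta_ct", "fold_change", "growth_call"]
    return pd.DataFrame(out, columns=cols)


def ratio_t_test(fold_changes: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided one-sample ratio t-test of fold changes against 1.

    Performed on log2 fold changes against mean 0 (testing a ratio
    against 1 is a location test on the log scale).  Returns
    ``(t, df, p)``.  All fold changes must be positive and n >= 2.
    Degenerate zero-variance input returns p = 1 when the values all
    equal 1 exactly, else p = 0 with t signed infinity.
    """
    fc = np.asarray(fold_changes, dtype=float)
    if fc.ndim != 1 or len(fc) < 2:
        raise ValueError("need at least 2 fold changes")
    if np.any(fc <= 0):
        raise ValueError("fold changes must be positive")
    logs = np.log2(fc)
    df = len(logs) - 1
    if np.allclose(np.std(logs, ddof=1), 0.0):
        m = float(np.mean(logs))
        if m == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, m), df, 0.0
    t, p = stats.ttest_1samp(logs, popmean=0.0)
    return float(t), df, float(p)
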