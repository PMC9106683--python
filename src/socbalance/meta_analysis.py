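"""Effect-size meta-analysis of literature degradation gradients.

Published observations of SOC/SOM, N and bulk density along pasture
degradation gradients are harmonized into a common scheme: study-specific
degradation labels are regrouped onto the six-stage scale S0--S5 through an
explicit mapping table, SOM contents are converted to SOC (factor 2.0),
stocks are computed per 10-cm depth interval, and the per-study effect size

    ES [%] = 100 * (D - R) / R

compares each degraded value D with the study's own non-degraded reference
R.  Effects are aggregated as simple means +/- SE per variable, stage and
depth interval.

Inclusion criteria (applied record-wise with per-study reference checks):
(i) a degradation classification is given, (ii) SOC/N/BD data are present,
(iii) the study includes a non-degraded reference, (iv) sampling depth is
given, (v) only exact 10-cm depth intervals are admitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .profiles import DegradationStage
from .stocks import elemental_stock, som_to_soc

__all__ = [
    "LiteratureRecord",
    "EffectSize",
    "DEFAULT_STAGE_MAPPING",
    "apply_inclusion_criteria",
    "regroup_stage",
    "record_stock",
    "effect_size",
    "compute_effects",
    "aggregate_effects",
]

#: Default regrouping of free-text degradation labels onto S0--S5.  The
#: mapping is deliberately an explicit, user-editable table: regrouping of
#: verbal degradation descriptions is a judgment call that must be visible
#: and reproducible, never inferred from text at run time.
DEFAULT_STAGE_MAPPING: dict[str, DegradationStage] = {
    "s0": DegradationStage.S0,
    "non-degraded": DegradationStage.S0,
    "undegraded": DegradationStage.S0,
    "intact": DegradationStage.S0,
    "pristine": DegradationStage.S0,
    "healthy meadow": DegradationStage.S0,
    "s1": DegradationStage.S1,
    "very slightly degraded": DegradationStage.S1,
    "initial degradation": DegradationStage.S1,
    "crack formation": DegradationStage.S1,
    "s2": DegradationStage.S2,
    "slightly degraded": DegradationStage.S2,
    "lightly degraded": DegradationStage.S2,
    "light degradation": DegradationStage.S2,
    "s3": DegradationStage.S3,
    "moderately degraded": DegradationStage.S3,
    "moderate degradation": DegradationStage.S3,
    "s4": DegradationStage.S4,
    "heavily degraded": DegradationStage.S4,
    "heavy degradation": DegradationStage.S4,
    "s5": DegradationStage.S5,
    "severely degraded": DegradationStage.S5,
    "extremely degraded": DegradationStage.S5,
    "bare soil": DegradationStage.S5,
    "black soil": DegradationStage.S5,
}

#: depth-interval width (cm) admitted by inclusion criterion (v)
_INTERVAL_CM = 10.0


@dataclass
class LiteratureRecord:
    """One published observation: a stage x depth interval of one study."""

    study_id: str
    original_label: str
    depth_top: float | None
    depth_bottom: float | None
    carbon_kind: str | None = None  # "SOC" or "SOM" when carbon_content given
    carbon_content: float | None = None  # g per kg
    n_content: float | None = None  # g per kg
    bulk_density: float | None = None  # g cm^-3
    mapped_stage: DegradationStage | None = None
    region: str | None = None
    year: int | None = None

    def soc_g_kg(self, som_factor: float = 2.0) -> float | None:
        """SOC content with the SOM conversion applied when needed."""
        if self.carbon_content is None:
            return None
        if self.carbon_kind == "SOM":
            return som_to_soc(self.carbon_content, som_factor)
        return self.carbon_content


@dataclass
class EffectSize:
    """Percent change of one variable vs the within-study reference."""

    variable: str  # "SOC_stock", "N_stock" or "BD"
    stage: DegradationStage
    depth_top: float
    depth_bottom: float
    value: float  # %
    study_id: str
    basis: str = "stock"  # "stock" when BD-based, "content" otherwise


def regroup_stage(
    original_label: str, mapping: dict[str, DegradationStage] | None = None
) -> DegradationStage:
    """Map a study's verbal degradation label onto the S0--S5 scale.

    Matching is exact after case folding and whitespace stripping; an
    unmapped label raises (stages are never guessed from text).
    """
    mapping = DEFAULT_STAGE_MAPPING if mapping is None else mapping
    key = str(original_label).strip().casefold()
    folded = {str(k).strip().casefold(): v for k, v in mapping.items()}
    if key not in folded:
        raise DataError(f"unmapped degradation label: {original_label!r}")
    return folded[key]


def apply_inclusion_criteria(
    records: list[LiteratureRecord],
    mapping: dict[str, DegradationStage] | None = None,
) -> tuple[list[LiteratureRecord], list[tuple[LiteratureRecord, str]]]:
    """Filter literature records by the inclusion criteria.

    Returns ``(kept, rejected)`` where every rejection carries its reason.
    The reference-presence check (criterion iii) uses the stage mapping to
    recognize reference records; studies whose mapped stages never include
    S0 are rejected wholesale.
    """
    mapping = DEFAULT_STAGE_MAPPING if mapping is None else mapping
    folded = {str(k).strip().casefold(): v for k, v in mapping.items()}

    kept: list[LiteratureRecord] = []
    rejected: list[tuple[LiteratureRecord, str]] = []
    prelim: list[LiteratureRecord] = []

    for r in records:
        if not str(r.original_label).strip():
            rejected.append((r, "no degradation classification"))
            continue
        if r.carbon_content is None and r.n_content is None and r.bulk_density is None:
            rejected.append((r, "no SOC/N/BD data"))
            continue
        if r.depth_top is None or r.depth_bottom is None:
            rejected.append((r, "missing depth"))
            continue
        if not np.isclose(r.depth_bottom - r.depth_top, _INTERVAL_CM):
            rejected.append((r, "interval != 10 cm"))
            continue
        prelim.append(r)

    # criterion (iii): a non-degraded reference within the study
    by_study: dict[str, list[LiteratureRecord]] = {}
    for r in prelim:
        by_study.setdefault(r.study_id, []).append(r)
    for study, rs in by_study.items():
        stages = {
            folded.get(str(r.original_label).strip().casefold()) for r in rs
        }
        if DegradationStage.S0 in stages:
            kept.extend(rs)
        else:
            rejected.extend((r, "no reference") for r in rs)
    return kept, rejected


def record_stock(
    record: LiteratureRecord, element: str = "C", som_factor: float = 2.0
) -> float:
    """Elemental stock (kg ha^-1) of one record's depth interval."""
    if record.bulk_density is None:
        raise DataError(
            f"stock unavailable: record {record.study_id}/{record.original_label} "
            "lacks bulk density"
        )
    if record.depth_top is None or record.depth_bottom is None:
        raise DataError("stock unavailable: record lacks a depth interval")
    if element == "C":
        content = record.soc_g_kg(som_factor)
    elif element == "N":
        content = record.n_content
    else:
        raise DataError(f"unknown element {element!r}")
    if content is None:
        raise DataError(f"stock unavailable: record lacks {element} content")
    return elemental_stock(
        content, record.bulk_density, record.depth_bottom - record.depth_top
    )


def effect_size(degraded_value: float, reference_value: float) -> float:
    """Percent change of a degraded value D against the reference R.

    ES = 100 (D - R) / R; positive means an increase relative to the
    non-degraded reference.
    """
    if reference_value == 0:
        raise DataError("undefined effect size: reference value is 0")
    return 100.0 * (degraded_value - reference_value) / reference_value


def _pair_value(
    record: LiteratureRecord, variable: str, som_factor: float
) -> tuple[float, str] | None:
    """Value and basis of a record for one variable, or None if unavailable."""
    if variable == "BD":
        return (record.bulk_density, "direct") if record.bulk_density is not None else None
    element = "C" if variable == "SOC_stock" else "N"
    content = record.soc_g_kg(som_factor) if element == "C" else record.n_content
    if content is None:
        return None
    if record.bulk_density is not None:
        return record_stock(record, element, som_factor), "stock"
    return content, "content"


def compute_effects(
    records: list[LiteratureRecord],
    mapping: dict[str, DegradationStage] | None = None,
    som_factor: float = 2.0,
) -> list[EffectSize]:
    """Effect sizes of all degraded records against their study's reference.

    Records are regrouped via *mapping* (when ``mapped_stage`` is unset),
    then paired with the reference record of the same study and depth
    interval.  Effects are computed on stocks whenever BD is available on
    both sides, else on contents; the basis is recorded per effect.
    """
    for r in records:
        if r.mapped_stage is None:
            r.mapped_stage = regroup_stage(r.original_label, mapping)

    effects: list[EffectSize] = []
    by_study: dict[str, list[LiteratureRecord]] = {}
    for r in records:
        by_study.setdefault(r.study_id, []).append(r)

    for study, rs in by_study.items():
        refs = {
            (r.depth_top, r.depth_bottom): r
            for r in rs
            if r.mapped_stage is DegradationStage.S0
        }
        for r in rs:
            if r.mapped_stage is DegradationStage.S0:
                continue
            ref = refs.get((r.depth_top, r.depth_bottom))
            if ref is None:
                continue
            for variable in ("SOC_stock", "N_stock", "BD"):
                dv = _pair_value(r, variable, som_factor)
                rv = _pair_value(ref, variable, som_factor)
                if dv is None or rv is None:
                    continue
                # compare like with like: both stocks or both contents
                basis = dv[1] if dv[1] == rv[1] else "content"
                if basis == "content" and variable != "BD":
                    d = r.soc_g_kg(som_factor) if variable == "SOC_stock" else r.n_content
                    rr = (
                        ref.soc_g_kg(som_factor)
                        if variable == "SOC_stock"
                        else ref.n_content
                    )
                else:
                    d, rr = dv[0], rv[0]
                if rr == 0:
                    continue
                effects.append(
                    EffectSize(
                        variable=variable,
                        stage=r.mapped_stage,
                        depth_top=r.depth_top,
                        depth_bottom=r.depth_bottom,
                        value=effect_size(d, rr),
                        study_id=study,
                        basis=basis if variable != "BD" else "direct",
                    )
                )
    return effects


def aggregate_effects(effects: list[EffectSize]) -> pd.DataFrame:
    """Mean effect +/- SE and observation count per variable/stage/depth cell.

    All observations are weighted equally.  Cells with a single observation
    report SE as NaN.
    """
    if not effects:
        return pd.DataFrame(
            columns=["variable", "stage", "depth_top", "depth_bottom", "mean_pct", "se_pct", "n"]
        )
    frame = pd.DataFrame(
        {
            "variable": [e.variable for e in effects],
            "stage": [e.stage.name for e in effects],
            "depth_top": [e.depth_top for e in effects],
            "depth_bottom": [e.depth_bottom for e in effects],
            "value": [e.value for e in effects],
        }
    )
    grouped = (
        frame.groupby(["variable", "stage", "depth_top", "depth_bottom"])["value"]
        .agg(
            mean_pct="mean",
            se_pct=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            n="size",
        )
        .reset_index()
    )
    return grouped
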