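"""CSV readers/writers for profile tables, literature tables and results.

All tables are comma-separated, decimal-point, UTF-8; units are fixed by
the schema (cm for depths, g kg^-1 for contents, g cm^-3 for bulk density,
permil for delta-13C) and never guessed from the file.  Lines starting with
``#`` are metadata comments: every writer stamps the package version and
the active configuration into the header so each output is traceable to a
run.

Profile tables carry one row per horizon with required columns
``stage, replicate, horizon, top_cm, bottom_cm, soc_g_kg, bd_g_cm3,
crack_cm`` plus recognized optional columns; unknown columns are ignored
with a warning.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError, SchemaError
from .profiles import (
    DegradationStage,
    Horizon,
    SoilProfile,
    StageEnsemble,
    validate_profile,
)

__all__ = [
    "ProfileTableSchema",
    "RunConfig",
    "read_profiles",
    "read_literature",
    "write_results",
    "read_results",
    "profiles_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileTableSchema:
    """Column layout of a horizon-per-row soil profile table."""

    required: tuple[str, ...] = (
        "stage",
        "replicate",
        "horizon",
        "top_cm",
        "bottom_cm",
        "soc_g_kg",
        "bd_g_cm3",
        "crack_cm",
    )
    #: optional column -> Horizon attribute
    optional: tuple[tuple[str, str], ...] = (
        ("n_g_kg", "n_content"),
        ("d13c_permil", "delta13c"),
        ("vsc_frac", "vsc_content"),
        ("clay_pct", "clay"),
        ("root_mg_cm3", "root_density"),
    )


@dataclass
class RunConfig:
    """Run-wide configuration shared by all pipeline commands.

    depth_limit:
        Stock integration limit in cm (default 30).
    som_to_soc_factor:
        Divisor converting SOM to SOC content (default 2.0).
    vsc_recovery:
        Fraction of lignin C recovered as VSC phenols (default 0.38).
    lignin_depletion:
        Lignin delta-13C depletion vs bulk plant material, permil (4.3).
    stage_mapping:
        Optional label -> stage table for the meta-analysis (defaults to
        the built-in mapping when None).
    alpha:
        Significance level of the closure test (default 0.05).
    seed:
        Seed for all synthetic-data generation.
    """

    depth_limit: float = 30.0
    som_to_soc_factor: float = 2.0
    vsc_recovery: float = 0.38
    lignin_depletion: float = 4.3
    stage_mapping: dict[str, DegradationStage] | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_limit <= 0:
            raise ConfigError(f"depth_limit must be > 0, got {self.depth_limit}")
        if self.som_to_soc_factor <= 0 or self.vsc_recovery <= 0:
            raise ConfigError("conversion factors must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stage_mapping" in raw and raw["stage_mapping"] is not None:
            raw["stage_mapping"] = {
                str(k): DegradationStage.from_label(v)
                for k, v in raw["stage_mapping"].items()
            }
        return cls(**raw)

    def echo(self) -> str:
        """One-line summary stamped into output headers."""
        return (
            f"depth_limit={self.depth_limit} som_factor={self.som_to_soc_factor} "
            f"vsc_recovery={self.vsc_recovery} lignin_depletion={self.lignin_depletion} "
            f"alpha={self.alpha} seed={self.seed}"
        )


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"schema error in {path}: missing columns {missing}")


def read_profiles(
    path: str | Path, schema: ProfileTableSchema | None = None
) -> list[StageEnsemble]:
    """Read a horizon-per-row profile CSV into per-stage ensembles.

    Rows are grouped by (stage, replicate) and ordered by top depth; each
    assembled profile is validated and any invariant violation aborts with
    a message naming the profile.
    """
    schema = schema or ProfileTableSchema()
    try:
        frame = pd.read_csv(path, comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot read profile table {path}: {exc}") from exc
    _require_columns(frame, schema.required, path)

    known = set(schema.required) | {col for col, _ in schema.optional}
    ignored = [c for c in frame.columns if c not in known]
    if ignored:
        logger.warning("ignoring unrecognized columns %s in %s", ignored, path)

    dup = frame.duplicated(subset=["stage", "replicate", "horizon"])
    if dup.any():
        rows = frame.index[dup].tolist()
        raise DataError(
            f"data error in {path}: duplicate (stage, replicate, horizon) rows {rows}"
        )

    ensembles: dict[DegradationStage, list[SoilProfile]] = {}
    for (stage_label, replicate), group in frame.groupby(
        ["stage", "replicate"], sort=True
    ):
        stage = DegradationStage.from_label(stage_label)
        group = group.sort_values("top_cm")
        cracks = group["crack_cm"].unique()
        if len(cracks) > 1:
            raise DataError(
                f"data error in {path}: inconsistent crack_cm for "
                f"{stage_label}/{replicate}: {cracks.tolist()}"
            )
        horizons = []
        for _, row in group.iterrows():
            extras = {}
            for col, attr in schema.optional:
                if col in group.columns and pd.notna(row[col]):
                    extras[attr] = float(row[col])
            horizons.append(
                Horizon(
                    label=str(row["horizon"]),
                    top_depth=float(row["top_cm"]),
                    bottom_depth=float(row["bottom_cm"]),
                    soc_content=float(row["soc_g_kg"]),
                    bulk_density=float(row["bd_g_cm3"]),
                    **extras,
                )
            )
        profile = SoilProfile(
            stage=stage,
            replicate=str(replicate),
            crack_depth=float(cracks[0]),
            horizons=horizons,
        )
        violations = validate_profile(profile)
        if violations:
            raise DataError(
                f"data error in {path}, profile {stage_label}/{replicate}: "
                + "; ".join(violations)
            )
        ensembles.setdefault(stage, []).append(profile)

    return [
        StageEnsemble(stage=s, profiles=ensembles[s]) for s in sorted(ensembles)
    ]


def profiles_to_frame(ensembles: list[StageEnsemble]) -> pd.DataFrame:
    """Serialize ensembles back to the horizon-per-row table layout."""
    rows = []
    for ens in ensembles:
        for p in ens.profiles:
            for h in p.horizons:
                rows.append(
                    {
                        "stage": p.stage.name,
                        "replicate": p.replicate,
                        "horizon": h.label,
                        "top_cm": h.top_depth,
                        "bottom_cm": h.bottom_depth,
                        "soc_g_kg": h.soc_content,
                        "bd_g_cm3": h.bulk_density,
                        "crack_cm": p.crack_depth,
                        "n_g_kg": h.n_content,
                        "d13c_permil": h.delta13c,
                        "vsc_frac": h.vsc_content,
                        "clay_pct": h.clay,
                        "root_mg_cm3": h.root_density,
                    }
                )
    return pd.DataFrame(rows)


_LITERATURE_REQUIRED = ("study_id", "degradation_label")
_LITERATURE_NUMERIC = (
    "depth_top_cm",
    "depth_bottom_cm",
    "carbon_g_kg",
    "n_g_kg",
    "bd_g_cm3",
)


def read_literature(path: str | Path):
    """Read a literature-record CSV into :class:`LiteratureRecord` objects.

    Columns: ``study_id, degradation_label, depth_top_cm, depth_bottom_cm,
    carbon_kind, carbon_g_kg, n_g_kg, bd_g_cm3`` (+ optional ``region``,
    ``year``).  Empty cells become None; unparseable numeric cells raise a
    data error naming the row.  Degradation labels are carried verbatim for
    later regrouping.
    """
    from .meta_analysis import LiteratureRecord

    try:
        frame = pd.read_csv(path, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot read literature table {path}: {exc}") from exc
    if frame.empty:
        return []
    _require_columns(frame, _LITERATURE_REQUIRED, path)

    def num(row_idx, row, col):
        if col not in frame.columns:
            return None
        cell = row[col]
        if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
            return None
        try:
            return float(cell)
        except ValueError:
            raise DataError(
                f"data error in {path} row {row_idx}: unparseable {col}={cell!r}"
            ) from None

    records = []
    for idx, row in frame.iterrows():
        kind = row.get("carbon_kind")
        kind = str(kind).strip().upper() if pd.notna(kind) and str(kind).strip() else None
        if kind not in (None, "SOC", "SOM"):
            raise DataError(f"data error in {path} row {idx}: carbon_kind {kind!r}")
        carbon = num(idx, row, "carbon_g_kg")
        if carbon is not None and kind is None:
            kind = "SOC"  # unflagged carbon defaults to SOC
        year = num(idx, row, "year")
        records.append(
            LiteratureRecord(
                study_id=str(row["study_id"]),
                original_label=str(row["degradation_label"]),
                depth_top=num(idx, row, "depth_top_cm"),
                depth_bottom=num(idx, row, "depth_bottom_cm"),
                carbon_kind=kind,
                carbon_content=carbon,
                n_content=num(idx, row, "n_g_kg"),
                bulk_density=num(idx, row, "bd_g_cm3"),
                region=str(row["region"]) if "region" in frame.columns and pd.notna(row.get("region")) else None,
                year=int(year) if year is not None else None,
            )
        )
    return records


def write_results(
    frame: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write a result table as commented-header CSV at fixed precision."""
    path = Path(path)
    lines = [f"# socbalance v{__version__}"]
    if config is not None:
        lines.append(f"# config: {config.echo()}")
    for key, value in (extra_meta or {}).items():
        lines.append(f"# {key}: {value}")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
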