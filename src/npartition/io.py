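"""CSV record schemas, configuration provenance and logging helpers.

One canonical cow-day schema per phase, versioned in a leading comment line
(``# npartition-phase1-v1``). Delimiter is a comma, decimal point ".",
encoding UTF-8. Reading validates the header against the schema and each
row against the record types; offending rows are reported with their cow
and day.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from . import __version__
from .config import (
    ASSUMED_CONSTANTS,
    IOConfig,
    PipelineConfig,
    PRINTED_CONSTANTS,
    config_to_dict,
)
from .errors import NPartitionError, SchemaError
from .types import (
    CowDayRecord,
    MilkRecord,
    NBalanceResult,
    PastureComposition,
    StallDayRecord,
    Treatment,
)

logger = logging.getLogger("npartition")

SCHEMA_VERSION = 1

_PASTURE_COLS = [
    "pasture_cp_pct", "pasture_ndf_pct", "pasture_adf_pct",
    "pasture_nsc_pct", "pasture_dmd_pct", "pasture_me_mj",
]
_MILK_COLS = ["milk_yield_kg", "milk_fat_pct", "milk_cp_pct", "milk_lactose_pct"]

PHASE1_COLUMNS = (
    ["cow_id", "day", "treatment", "urea_g"] + _MILK_COLS
    + ["bw_kg", "km_walked"] + _PASTURE_COLS
)
PHASE2_COLUMNS = (
    ["cow_id", "day", "treatment", "offered_kg_dm", "refused_kg_dm", "urea_g"]
    + _MILK_COLS
    + ["fecal_wet_kg", "fecal_dm_pct", "fecal_n_g_per_kg", "urine_volume_l"]
    + _PASTURE_COLS
)
BALANCE_COLUMNS = [
    "cow_id", "day", "dmi_kg", "n_intake_g", "fecal_n_g", "milk_n_g",
    "urine_n_est_g", "diet_cp_pct", "urine_n_conc_g_per_l", "flagged",
]

Phase = Literal["phase1", "phase2"]


def _schema_header(phase: str) -> str:
    return f"# npartition-{phase}-v{SCHEMA_VERSION}\n"


def _milk_dict(m: MilkRecord) -> dict:
    return {
        "milk_yield_kg": m.yield_kg, "milk_fat_pct": m.fat_pct,
        "milk_cp_pct": m.cp_pct, "milk_lactose_pct": m.lactose_pct,
    }


def _pasture_dict(p: PastureComposition) -> dict:
    return {
        "pasture_cp_pct": p.cp_pct, "pasture_ndf_pct": p.ndf_pct,
        "pasture_adf_pct": p.adf_pct, "pasture_nsc_pct": p.nsc_pct,
        "pasture_dmd_pct": p.dmd_pct, "pasture_me_mj": p.me,
    }


def records_to_frame(records: Sequence[CowDayRecord | StallDayRecord]) -> pd.DataFrame:
    """Flatten cow-day records into the canonical column order."""
    rows = []
    for r in records:
        if isinstance(r, CowDayRecord):
            rows.append(
                {
                    "cow_id": r.cow_id, "day": r.day, "treatment": r.treatment.value,
                    "urea_g": r.urea_g, **_milk_dict(r.milk),
                    "bw_kg": r.bw, "km_walked": r.km_walked, **_pasture_dict(r.pasture),
                }
            )
        else:
            rows.append(
                {
                    "cow_id": r.cow_id, "day": r.day, "treatment": r.treatment.value,
                    "offered_kg_dm": r.offered_kg_dm, "refused_kg_dm": r.refused_kg_dm,
                    "urea_g": r.urea_g, **_milk_dict(r.milk),
                    "fecal_wet_kg": r.fecal_wet_kg, "fecal_dm_pct": r.fecal_dm_pct,
                    "fecal_n_g_per_kg": r.fecal_n_g_per_kg,
                    "urine_volume_l": r.urine_volume_l, **_pasture_dict(r.pasture),
                }
            )
    cols = PHASE1_COLUMNS if rows and "bw_kg" in rows[0] else PHASE2_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def write_records(
    records: Sequence[CowDayRecord | StallDayRecord],
    path: str | Path,
    io: IOConfig = IOConfig(),
) -> Path:
    """Write cow-day records as a versioned CSV (byte-identical for equal
    inputs)."""
    if not records:
        raise SchemaError("refusing to write an empty record collection")
    phase = "phase1" if isinstance(records[0], CowDayRecord) else "phase2"
    df = records_to_frame(records)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_schema_header(phase))
        df.to_csv(
            fh, index=False, sep=io.delimiter,
            float_format=f"%.{io.decimals}f", lineterminator="\n",
        )
    logger.info("wrote %d %s records to %s", len(df), phase, path)
    return path


def _row_context(row: pd.Series, idx: int) -> str:
    return f"row {idx} (cow {row.get('cow_id', '?')}, day {row.get('day', '?')})"


def read_records(
    path: str | Path,
    schema: Phase,
    on_invalid: Literal["error", "drop"] = "error",
) -> list[CowDayRecord] | list[StallDayRecord]:
    """Read a versioned cow-day CSV back into typed, validated records.

    Unknown or missing columns raise :class:`SchemaError`. A row that fails
    validation (unparseable number, negative milk yield, refused > offered,
    ...) raises a schema error naming the cow and day, or — with
    ``on_invalid="drop"`` — is rejected with a logged reason.
    """
    path = Path(path)
    expected = PHASE1_COLUMNS if schema == "phase1" else PHASE2_COLUMNS
    df = pd.read_csv(path, comment="#", dtype=str)
    unknown = [c for c in df.columns if c not in expected]
    missing = [c for c in expected if c not in df.columns]
    if unknown or missing:
        raise SchemaError(
            f"{path}: columns do not match {schema} schema v{SCHEMA_VERSION}"
            + (f"; unknown: {unknown}" if unknown else "")
            + (f"; missing: {missing}" if missing else "")
        )
    if df.empty:
        warnings.warn(f"{path}: valid header but no records", stacklevel=2)
        logger.warning("%s: empty record file", path)
        return []

    records: list = []
    for idx, row in df.iterrows():
        try:
            rec = _parse_row(row, schema)
        except (NPartitionError, TypeError) as exc:
            msg = f"{_row_context(row, idx)}: {exc}"
            if on_invalid == "drop":
                logger.warning("rejected %s", msg)
                continue
            raise SchemaError(msg) from exc
        records.append(rec)
    return records


def _num(row: pd.Series, col: str) -> float:
    raw = row[col]
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        raise SchemaError(f"missing value in '{col}'")
    try:
        return float(raw)
    except ValueError as exc:
        raise SchemaError(f"unparseable number '{raw}' in '{col}'") from exc


def _parse_row(row: pd.Series, schema: Phase):
    milk = MilkRecord(
        yield_kg=_num(row, "milk_yield_kg"),
        fat_pct=_num(row, "milk_fat_pct"),
        cp_pct=_num(row, "milk_cp_pct"),
        lactose_pct=_num(row, "milk_lactose_pct"),
    )
    pasture = PastureComposition(
        cp_pct=_num(row, "pasture_cp_pct"),
        ndf_pct=_num(row, "pasture_ndf_pct"),
        adf_pct=_num(row, "pasture_adf_pct"),
        nsc_pct=_num(row, "pasture_nsc_pct"),
        dmd_pct=_num(row, "pasture_dmd_pct"),
        me=_num(row, "pasture_me_mj"),
    )
    common = dict(
        cow_id=str(row["cow_id"]),
        day=int(_num(row, "day")),
        treatment=Treatment(row["treatment"]),
        urea_g=_num(row, "urea_g"),
        milk=milk,
        pasture=pasture,
    )
    if schema == "phase1":
        return CowDayRecord(
            bw=_num(row, "bw_kg"), km_walked=_num(row, "km_walked"), **common
        )
    vol = row["urine_volume_l"]
    return StallDayRecord(
        offered_kg_dm=_num(row, "offered_kg_dm"),
        refused_kg_dm=_num(row, "refused_kg_dm"),
        fecal_wet_kg=_num(row, "fecal_wet_kg"),
        fecal_dm_pct=_num(row, "fecal_dm_pct"),
        fecal_n_g_per_kg=_num(row, "fecal_n_g_per_kg"),
        urine_volume_l=None if pd.isna(vol) or vol == "" else float(vol),
        **common,
    )


def write_balance(
    results: Iterable[NBalanceResult], path: str | Path, io: IOConfig = IOConfig()
) -> Path:
    """Write a balance table (columns mirror the partition parameters)."""
    rows = [dataclasses.asdict(r) for r in results]
    df = pd.DataFrame(rows, columns=BALANCE_COLUMNS)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# npartition-balance-v{SCHEMA_VERSION}\n")
        df.to_csv(
            fh, index=False, sep=io.delimiter,
            float_format=f"%.{io.decimals}f", lineterminator="\n",
        )
    return path


def provenance(config: PipelineConfig, seed: int) -> dict:
    """Reproducibility block emitted with every run: config hash, seed,
    software version, and which constants are printed values of the source
    analysis vs assumptions of this package."""
    cfg = config_to_dict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    return {
        "software": "npartition",
        "version": __version__,
        "seed": seed,
        "config_sha256": digest,
        "schema_version": SCHEMA_VERSION,
        "constants": {
            "printed": {k: v for k, v in sorted(PRINTED_CONSTANTS.items())},
            "assumed": {k: v for k, v in sorted(ASSUMED_CONSTANTS.items())},
        },
        "config": cfg,
    }
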