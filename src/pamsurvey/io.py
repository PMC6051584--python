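"""CSV / YAML round-trip I/O for every pipeline artefact.

All files are plain comma-separated UTF-8 with '.' decimals and NA for
missing cells; timestamps are ISO-8601 local clock times at minute
resolution.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .detection_distance import LevelProfile
from .occupancy import DesignRow, nights_required
from .scheduling import DetectionHistory
from .synthetic_data import BellowEvent, SiteConfig

__all__ = [
    "write_events_csv",
    "read_events_csv",
    "write_history_csv",
    "read_history_csv",
    "write_design_csv",
    "read_design_csv",
    "write_profile_csv",
    "read_profile_csv",
    "load_sites_yaml",
    "validate_table3_consistency",
]

_TS_FMT = "%Y-%m-%dT%H:%M"


def write_events_csv(events: Sequence[BellowEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("site_id,timestamp,sex\n")
        for e in events:
            fh.write(f"{e.site_id},{e.timestamp.strftime(_TS_FMT)},{e.sex}\n")


def read_events_csv(path: str | Path) -> list[BellowEvent]:
    df = pd.read_csv(path)
    return [
        BellowEvent(r.site_id, dt.datetime.strptime(r.timestamp, _TS_FMT), r.sex)
        for r in df.itertuples()
    ]


def write_history_csv(history: DetectionHistory, path: str | Path) -> None:
    """First column site_id, one ISO-date column per night; cells 0/1/NA."""
    cols = [n.isoformat() for n in history.nights]
    data = history.detected.astype(object)
    data[~history.valid] = "NA"
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "site_id", list(history.site_ids))
    df.to_csv(path, index=False)


def read_history_csv(path: str | Path) -> DetectionHistory:
    df = pd.read_csv(path, dtype={"site_id": str}, keep_default_na=False)
    nights = tuple(dt.date.fromisoformat(c) for c in df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy()
    valid = raw != "NA"
    detected = np.where(valid, raw, 0).astype(int)
    return DetectionHistory(tuple(df["site_id"]), nights, detected, valid)


def write_design_csv(rows: Sequence[DesignRow], path: str | Path) -> None:
    pd.DataFrame([dataclass_row(r) for r in rows]).to_csv(path, index=False, na_rep="NA")


def dataclass_row(r: DesignRow) -> dict:
    return {
        "season_stage": r.season_stage,
        "density_class": r.density_class,
        "schedule": r.schedule,
        "p_hat": r.p_hat,
        "se_p": r.se_p,
        "nights_80": r.nights_80,
        "nights_95": r.nights_95,
        "note": r.note,
    }


def read_design_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profile_csv(profile: LevelProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"distance_m": profile.distances, "level_db": profile.levels}
    ).to_csv(path, index=False)


def read_profile_csv(path: str | Path, ambient_db: float = 42.0) -> LevelProfile:
    df = pd.read_csv(path)
    return LevelProfile(
        distances=df["distance_m"].to_numpy(),
        levels=df["level_db"].to_numpy(),
        ambient_db=ambient_db,
    )


def load_sites_yaml(path: str | Path) -> list[SiteConfig]:
    """Sites from a YAML list of {site_id, density, base_rate, latitude, longitude}."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return [SiteConfig(**row) for row in raw]


def validate_table3_consistency(
    table: pd.DataFrame | str | Path,
    confidences: tuple[float, float] = (0.80, 0.95),
) -> pd.DataFrame:
    """Recompute nights-to-confidence from p_hat and report mismatching rows.

    ``table`` needs columns ``p_hat``, ``nights_80``, ``nights_95``.  Returns
    the subset of rows whose printed night counts disagree with
    ``nights_required``, with the recomputed values appended; an empty frame
    means the table is internally consistent.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    for col in ("p_hat", "nights_80", "nights_95"):
        if col not in df.columns:
            raise ValueError(f"table is missing required column {col!r}")
    lo_c, hi_c = sorted(confidences)
    recomputed_lo = [nights_required(p, lo_c) for p in df["p_hat"]]
    recomputed_hi = [nights_required(p, hi_c) for p in df["p_hat"]]
    out = df.copy()
    out["recomputed_80"] = recomputed_lo
    out["recomputed_95"] = recomputed_hi
    bad = (out["recomputed_80"] != out["nights_80"]) | (
        out["recomputed_95"] != out["nights_95"]
    )
    return out[bad].reset_index(drop=True)
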