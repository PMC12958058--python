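"""File readers/writers and configuration.

Canonical dialect is CSV with a header row; arbitrary source headers are
accommodated through a column-name mapping (from a ``key=value`` config
file or a dict). Every reader validates on load and reports the exact
1-based input line for each rejected row. Fitted models and diagram
grids serialize to a single self-describing JSON "model bundle" in which
every numeric field records its unit; reading the bundle back reproduces
all numbers to full precision.

Time is hours everywhere; a single constant (:data:`HOURS_PER_DAY`)
converts to days for display only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .datatypes import (validate_duration_table, validate_measurement_series,
                        validate_temperature_log)
from .exceptions import ConfigurationError, ValidationError
from .growth import IsomegalenGrid, IsomorphenTable, LarvalGrowthResults
from .pupal import PupalIndicatorResults
from .thermal import ThermalSummationResults

__all__ = [
    "HOURS_PER_DAY",
    "read_duration_table",
    "write_duration_table",
    "read_measurement_series",
    "write_measurement_series",
    "read_temperature_log",
    "write_temperature_log",
    "write_model_bundle",
    "read_model_bundle",
    "read_config",
]

logger = logging.getLogger("thermodev")

#: Display-only conversion constant; all computation stays in hours.
HOURS_PER_DAY = 24.0

BUNDLE_FORMAT = "thermodev-model-bundle"
BUNDLE_VERSION = 1


def _apply_colmap(df: pd.DataFrame, colmap: dict | None) -> pd.DataFrame:
    if not colmap:
        return df
    unknown = [src for src in colmap.values() if src not in df.columns]
    if unknown:
        raise ConfigurationError(
            f"column mapping names absent source column(s) {unknown}; "
            f"file has {list(df.columns)}")
    return df.rename(columns={src: dst for dst, src in colmap.items()})


def read_duration_table(path, colmap: dict | None = None) -> pd.DataFrame:
    """Read and validate a replicate-level stage-duration CSV.

    ``colmap`` maps canonical names (temperature, replicate, stage,
    duration) to the file's actual headers.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df = _apply_colmap(df, colmap)
    missing = [c for c in ("temperature", "replicate", "stage", "duration")
               if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; provide a "
            f"column mapping if the file uses different headers")
    return validate_duration_table(df, source=str(path))


def write_duration_table(table: pd.DataFrame, path) -> None:
    validate_duration_table(table).to_csv(path, index=False, float_format="%.17g")


def read_measurement_series(path, colmap: dict | None = None) -> pd.DataFrame:
    """Read and validate a measurement-series CSV (larval or pupal).

    Missing measurement cells must be empty fields, never 0.
    """
    path = Path(path)
    df = _apply_colmap(pd.read_csv(path, float_precision="round_trip"), colmap)
    return validate_measurement_series(df, source=str(path))


def write_measurement_series(series: pd.DataFrame, path) -> None:
    validate_measurement_series(series).to_csv(path, index=False, float_format="%.17g")


def read_temperature_log(path) -> pd.DataFrame:
    """Read a two-column (time, temperature) record.

    Accepts a header row or a bare two-column numeric file. Duplicate
    timestamps are collapsed by averaging (with a warning); decreasing
    timestamps and empty files are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df.columns) < 2:
        raise ValidationError(f"{path}: need two columns (time, temperature)")
    first = str(df.columns[0])
    try:  # headerless numeric file: first "header" row is data
        float(first)
        df = pd.read_csv(path, header=None, float_precision="round_trip")
    except ValueError:
        pass
    df = df.iloc[:, :2]
    df.columns = ["time", "temperature"]
    if len(df) == 0:
        raise ValidationError(f"{path}: temperature log is empty")
    return validate_temperature_log(df, source=str(path))


def write_temperature_log(log: pd.DataFrame, path) -> None:
    validate_temperature_log(log).to_csv(path, index=False, float_format="%.17g")


_BUNDLE_CODECS = {
    "thermal": ThermalSummationResults,
    "growth": LarvalGrowthResults,
    "pupal": PupalIndicatorResults,
    "isomegalen": IsomegalenGrid,
    "isomorphen": IsomorphenTable,
}


def write_model_bundle(path, *, thermal=(), growth=(), pupal=(),
                       isomegalen=(), isomorphen=()) -> None:
    """Serialize fitted models and grids to a self-describing JSON bundle.

    An empty bundle is valid. All floats survive a round trip at full
    precision (repr-level JSON encoding).
    """
    records = []
    for kind, objs in (("thermal", thermal), ("growth", growth),
                       ("pupal", pupal), ("isomegalen", isomegalen),
                       ("isomorphen", isomorphen)):
        for obj in objs:
            expected = _BUNDLE_CODECS[kind]
            if not isinstance(obj, expected):
                raise ValidationError(
                    f"bundle section {kind!r} expects {expected.__name__}, "
                    f"got {type(obj).__name__}")
            records.append({"kind": kind, "data": obj.to_dict()})
    doc = {
        "format": BUNDLE_FORMAT,
        "version": BUNDLE_VERSION,
        "units": {"time": "h", "temperature": "degC", "length": "mm",
                  "weight": "g", "K": "degC*h"},
        "records": records,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    logger.info("wrote model bundle with %d record(s) to %s", len(records), path)


def read_model_bundle(path) -> dict[str, list]:
    """Read a model bundle back into results objects, keyed by kind."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != BUNDLE_FORMAT:
        raise ValidationError(f"{path}: not a {BUNDLE_FORMAT} file")
    out: dict[str, list] = {k: [] for k in _BUNDLE_CODECS}
    for rec in doc["records"]:
        kind = rec["kind"]
        if kind not in _BUNDLE_CODECS:
            raise ValidationError(f"{path}: unknown record kind {kind!r}")
        out[kind].append(_BUNDLE_CODECS[kind].from_dict(rec["data"]))
    return out


def read_config(path) -> dict[str, str]:
    """Read a ``key=value`` configuration file.

    Blank lines and ``#`` comments are ignored. Keys of the form
    ``column.<canonical>`` define the column mapping; other recognised
    keys include ``alpha``, ``length_grid`` and tolerance settings —
    consumers interpret them.
    """
    cfg: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(
                f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def colmap_from_config(cfg: dict[str, str]) -> dict[str, str]:
    """Extract a canonical->source column mapping from config keys
    ``column.<canonical>=<source header>``."""
    return {k.split(".", 1)[1]: v for k, v in cfg.items()
            if k.startswith("column.")}
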