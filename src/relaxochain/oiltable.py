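"""Reading and writing oil-property tables and echo-train files.

Oil tables are TSV/CSV files with one row per oil (formula, name, chain
length, state, and whichever relaxation/viscosity columns are
available).  Two reference tables ship with the package:

``table1_oils.tsv``
    17 liquid oils with measured T2, R2, R2/eta and viscosity — the
    calibration panel.
``table2_samples.tsv``
    29 oils and fats (liquids and solids) with molecular weight and
    chain length — the sample-preparation inventory.

Echo trains are CSV files with columns ``time_ms, amplitude`` plus an
optional YAML sidecar carrying acquisition metadata.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import OilRecord
from .cpmg import AcquisitionMeta, EchoTrain

__all__ = [
    "read_oil_table",
    "load_table1",
    "load_table2",
    "read_echo_train",
    "write_echo_train",
    "read_ir_series",
    "write_ir_series",
    "OilTableError",
]

MANDATORY_COLUMNS = ("formula", "name", "chain_length", "status")
_NUMERIC_COLUMNS = ("chain_length", "mw_gmol", "t2_ms", "r2_per_s", "r2_over_eta", "viscosity_cp")
_NA_TOKENS = {"", "n/a", "na", "nan", "none", "-"}


class OilTableError(ValueError):
    """Schema or parse failure in an oil table."""


def _parse_number(raw, column: str, line: int):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in _NA_TOKENS:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise OilTableError(
            f"line {line}: column {column!r} has malformed numeric value {raw!r}"
        ) from exc


def read_oil_table(path) -> list[OilRecord]:
    """Parse a TSV/CSV oil table into typed records.

    Missing viscosity entries ("N/A") become absent values; solids are
    flagged through ``OilRecord.state``.

    Raises
    ------
    OilTableError
        Naming the missing mandatory columns, or the offending line for
        malformed numerics.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise OilTableError(f"{path}: empty file, no header found") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise OilTableError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )

    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after header
        values = {}
        for col in _NUMERIC_COLUMNS:
            if col in df.columns:
                values[col] = _parse_number(row[col], col, line)
        cl = values.pop("chain_length", None)
        if cl is None:
            raise OilTableError(f"line {line}: chain_length is required")
        records.append(
            OilRecord(
                formula=str(row["formula"]).strip(),
                name=str(row["name"]).strip(),
                chain_length=int(cl),
                state=str(row["status"]).strip(),
                purity=str(row["purity"]).strip() if "purity" in df.columns else None,
                **values,
            )
        )
    return records


def _bundled(name: str) -> Path:
    return Path(str(resources.files("relaxochain").joinpath("data", name)))


def load_table1() -> list[OilRecord]:
    """The bundled 17-oil calibration panel (all liquid, full relaxation data)."""
    return read_oil_table(_bundled("table1_oils.tsv"))


def load_table2() -> list[OilRecord]:
    """The bundled 29-sample oil/fat inventory (molecular weights, states)."""
    return read_oil_table(_bundled("table2_samples.tsv"))


def write_echo_train(train: EchoTrain, path, sidecar: bool = True) -> None:
    """Write a train as ``time_ms,amplitude`` CSV plus a YAML metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_ms": train.times_ms, "amplitude": train.amplitudes}).to_csv(
        path, index=False
    )
    if sidecar:
        meta = {
            "echo_time_ms": train.echo_time_ms,
            "frequency_mhz": train.meta.frequency_mhz,
            "n_scans": train.meta.n_scans,
            "sampling_khz": train.meta.sampling_khz,
            "tr_s": train.meta.tr_s,
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_echo_train(path) -> EchoTrain:
    """Read a ``time_ms,amplitude`` CSV (and YAML sidecar if present)."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_ms", "amplitude"):
        if col not in df.columns:
            raise OilTableError(f"{path}: echo-train file lacks column {col!r}")
    times = df["time_ms"].to_numpy(float)
    if times.size < 2:
        raise OilTableError(f"{path}: too few echoes")
    te = float(times[0])
    if not np.allclose(np.diff(times), te, rtol=1e-6):
        raise OilTableError(f"{path}: echo times are not uniform multiples of TE")
    meta = AcquisitionMeta()
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        raw = yaml.safe_load(sidecar.read_text()) or {}
        te = float(raw.get("echo_time_ms", te))
        meta = AcquisitionMeta(
            frequency_mhz=float(raw.get("frequency_mhz", meta.frequency_mhz)),
            n_scans=int(raw.get("n_scans", meta.n_scans)),
            sampling_khz=float(raw.get("sampling_khz", meta.sampling_khz)),
            tr_s=float(raw.get("tr_s", meta.tr_s)),
        )
    return EchoTrain(te, df["amplitude"].to_numpy(float), meta)


def write_ir_series(series, path) -> None:
    """Write an IR-CPMG series as long-format CSV.

    Columns: ``inversion_time_ms, time_ms, amplitude`` — one row per
    (recovery delay, echo) pair.
    """
    from .t1t2 import IRCPMGSeries  # local import to avoid a cycle

    assert isinstance(series, IRCPMGSeries)
    echo_times = series.echo_times_ms
    frames = []
    for tinv, train in zip(series.inversion_times_ms, series.trains):
        frames.append(
            pd.DataFrame(
                {
                    "inversion_time_ms": tinv,
                    "time_ms": echo_times,
                    "amplitude": train.amplitudes,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ir_series(path):
    """Read an IR-CPMG series from the long-format CSV written by
    :func:`write_ir_series`."""
    from .t1t2 import IRCPMGSeries

    df = pd.read_csv(path)
    for col in ("inversion_time_ms", "time_ms", "amplitude"):
        if col not in df.columns:
            raise OilTableError(f"{path}: series file lacks column {col!r}")
    trains = []
    tinvs = []
    for tinv, grp in df.groupby("inversion_time_ms", sort=True):
        grp = grp.sort_values("time_ms")
        te = float(grp["time_ms"].iloc[0])
        trains.append(EchoTrain(te, grp["amplitude"].to_numpy(float)))
        tinvs.append(float(tinv))
    return IRCPMGSeries(np.asarray(tinvs), tuple(trains))
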