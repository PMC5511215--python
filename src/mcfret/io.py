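"""Plain-text readers and writers for decays, survival curves and FCS data.

Decay histograms travel as 2-column TSV (time_ns, counts) with '#'-prefixed
``key: value`` metadata headers; FCS curves as (lag_s, G); z-scan series as
(z_nm, tau_ms, N).  Run configurations are YAML or JSON documents.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .fcs import FcsCurve, ZScanSeries
from .fretmc import DecayHistogram, SurvivalCurve

__all__ = [
    "read_decay",
    "write_decay",
    "write_survival",
    "read_fcs",
    "write_fcs",
    "read_zscan_series",
    "write_zscan_series",
    "load_config",
]


class FormatError(ValueError):
    """A malformed input file, with the offending line number in the message."""


def _parse_two_columns(path: Path, n_cols: int = 2):
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({err})") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows), meta


def read_decay(path: str | Path) -> DecayHistogram:
    """Read a TCSPC decay histogram from (time_ns, counts) TSV."""
    path = Path(path)
    arr, meta = _parse_two_columns(path)
    time, counts = arr[:, 0], arr[:, 1]
    neg = np.flatnonzero(counts < 0)
    if len(neg):
        raise FormatError(f"{path}: negative count in data row {neg[0] + 1}")
    if len(time) >= 2:
        widths = np.diff(time)
        if not np.allclose(widths, widths[0], rtol=1e-6, atol=1e-9):
            bad = int(np.argmax(np.abs(widths - widths[0]))) + 2
            raise FormatError(f"{path}: non-uniform bin width at data row {bad}")
    return DecayHistogram(time, counts, meta)


def _write_table(path: Path, columns, header_cols: str, meta: dict | None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            if isinstance(val, (str, int, float, bool)):
                fh.write(f"# {key}: {val}\n")
        fh.write(f"# {header_cols}\n")
        for row in zip(*columns):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def write_decay(path: str | Path, decay: DecayHistogram) -> None:
    _write_table(Path(path), (decay.time, decay.counts), "time_ns\tcounts", decay.meta)


def write_survival(path: str | Path, curve: SurvivalCurve) -> None:
    _write_table(Path(path), (curve.time, curve.values), "time_ns\tG", curve.meta)


def write_fcs(path: str | Path, curve: FcsCurve) -> None:
    _write_table(
        Path(path),
        (curve.lags, curve.g),
        "lag_s\tG",
        {"z_offset_nm": curve.z_offset, "duration_s": curve.duration},
    )


def read_fcs(path: str | Path) -> FcsCurve:
    arr, meta = _parse_two_columns(Path(path))
    return FcsCurve(
        arr[:, 0],
        arr[:, 1],
        z_offset=float(meta.get("z_offset_nm", 0.0)),
        duration=float(meta.get("duration_s", 60.0)),
    )


def write_zscan_series(path: str | Path, series: ZScanSeries) -> None:
    _write_table(
        Path(path),
        (series.z, series.tau_diff * 1e3, series.n_particles),
        "z_nm\ttau_ms\tN",
        {
            "wavelength_nm": series.wavelength,
            "refractive_index": series.refractive_index,
        },
    )


def read_zscan_series(path: str | Path) -> ZScanSeries:
    arr, meta = _parse_two_columns(Path(path), n_cols=3)
    return ZScanSeries(
        z=arr[:, 0],
        tau_diff=arr[:, 1] * 1e-3,
        n_particles=arr[:, 2],
        wavelength=float(meta.get("wavelength_nm", 470.0)),
        refractive_index=float(meta.get("refractive_index", 1.33)),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
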