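"""Readers and writers for the on-disk formats.

One dialect per format: multipage TIFF for FLIM stacks (pages = time bins)
with a JSON sidecar for acquisition metadata, single-page uint16 TIFF for
label masks, float32/uint8 TIFF pairs for calcium maps, CSV for all tabular
exchange (decays, traces, histograms, object and track tables) and JSON for
calibrations.  Lifetimes are expressed in picoseconds and concentrations in
nM in every external file; seconds are used internally.

Readers validate and reject malformed inputs rather than silently coercing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .calibration import HillCalibration, PhasorCalibration, SegmentHill
from .decay import AcquisitionParams, DecayHistogram, Phasor
from .exceptions import FormatError
from .quantify import CalciumMap, CellRecord, FlimStack, records_to_frame

__all__ = [
    "read_decay_csv",
    "write_decay_csv",
    "read_flim_stack",
    "write_flim_stack",
    "read_label_mask",
    "write_label_mask",
    "write_calcium_map",
    "read_calibration",
    "write_calibration",
    "read_trace_csv",
    "read_track_table",
    "write_cell_records",
    "write_titration_dir",
    "read_titration_dir",
]

CALIBRATION_SCHEMA = "phasorca/calibration-v1"


# ---------------------------------------------------------------------------
# Decay CSV
# ---------------------------------------------------------------------------


def write_decay_csv(decay: DecayHistogram, path: str | Path) -> None:
    """Write a decay as CSV with header `time_s,counts`."""
    pd.DataFrame(
        {"time_s": decay.params.bin_centers(), "counts": decay.counts}
    ).to_csv(path, index=False)


def read_decay_csv(
    path: str | Path, params: AcquisitionParams | None = None
) -> DecayHistogram:
    """Read a `time_s,counts` decay CSV.

    When `params` is omitted, bin width and count are inferred from the time
    column (the repetition rate keeps its 80 MHz default).
    """
    df = pd.read_csv(path)
    if not {"time_s", "counts"}.issubset(df.columns):
        raise FormatError(f"{path}: decay CSV requires columns time_s,counts")
    t = df["time_s"].to_numpy(dtype=float)
    if params is None:
        widths = np.diff(t)
        if t.size < 2 or not np.allclose(widths, widths[0], rtol=1e-6):
            raise FormatError(f"{path}: time bins are not uniform")
        params = AcquisitionParams(bin_width=float(widths[0]), n_bins=t.size)
    counts = df["counts"].to_numpy(dtype=float)
    if counts.size != params.n_bins:
        raise FormatError(
            f"{path}: {counts.size} rows but params.n_bins = {params.n_bins}"
        )
    return DecayHistogram(counts=counts, params=params)


# ---------------------------------------------------------------------------
# FLIM stacks (multipage TIFF + JSON sidecar)
# ---------------------------------------------------------------------------


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_flim_stack(
    stack: FlimStack, path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Write a FLIM stack as a multipage uint16 TIFF (one page per time bin)."""
    path = Path(path)
    voxels = stack.voxels
    if voxels.max() > np.iinfo(np.uint16).max:
        raise FormatError("voxel counts exceed uint16; rescale or split frames")
    tifffile.imwrite(path, voxels.transpose(2, 0, 1).astype(np.uint16))
    meta = {
        "laser_rep_rate_hz": stack.params.laser_rep_rate,
        "bin_width_ps": stack.params.bin_width * 1e12,
        "n_bins": stack.params.n_bins,
        "irf_width_ps": stack.params.irf_width * 1e12,
        "harmonic": stack.params.harmonic,
        "pixel_size_um": stack.pixel_size_um,
        "frame_index": stack.frame_index,
    }
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2))


def read_flim_stack(path: str | Path, sidecar: str | Path | None = None) -> FlimStack:
    """Read a multipage-TIFF FLIM stack and its JSON sidecar.

    The TIFF page count must equal the sidecar's n_bins; mismatches raise a
    FormatError naming both counts.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    n_bins = int(meta["n_bins"])
    if pages.shape[0] != n_bins:
        raise FormatError(
            f"{path}: TIFF has {pages.shape[0]} pages but sidecar declares "
            f"n_bins = {n_bins}"
        )
    params = AcquisitionParams(
        laser_rep_rate=float(meta["laser_rep_rate_hz"]),
        bin_width=float(meta["bin_width_ps"]) * 1e-12,
        n_bins=n_bins,
        irf_width=float(meta.get("irf_width_ps", 80.0)) * 1e-12,
        harmonic=int(meta.get("harmonic", 1)),
    )
    return FlimStack(
        voxels=pages.transpose(1, 2, 0),
        params=params,
        frame_index=int(meta.get("frame_index", 0)),
        pixel_size_um=meta.get("pixel_size_um"),
    )


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise FormatError(f"{path}: label mask must be a single-page 2-D image")
    return mask.astype(np.uint16)


def write_calcium_map(cmap: CalciumMap, path: str | Path) -> None:
    """Write concentration (float32 nM, NaN where absent) and status (uint8) TIFFs."""
    path = Path(path)
    tifffile.imwrite(path, cmap.ca_nM.astype(np.float32))
    tifffile.imwrite(
        path.with_name(path.stem + "_status" + path.suffix),
        cmap.status.astype(np.uint8),
    )


# ---------------------------------------------------------------------------
# Calibration JSON
# ---------------------------------------------------------------------------


def write_calibration(cal: PhasorCalibration, path: str | Path) -> None:
    doc = {
        "schema": CALIBRATION_SCHEMA,
        "kd_nM": cal.hill.kd,
        "hill_slope": cal.hill.hill_slope,
        "tau_free_ps": cal.hill.tau_free * 1e12,
        "tau_fret_ps": cal.hill.tau_fret * 1e12,
        "p_free": [cal.p_free.g, cal.p_free.s],
        "p_fret": [cal.p_fret.g, cal.p_fret.s],
        "brightness_ratio": cal.brightness_ratio,
        "segment_hill": (
            {"kd_nM": cal.segment_hill.kd, "hill_slope": cal.segment_hill.hill_slope}
            if cal.segment_hill
            else None
        ),
        "inversion_mode": cal.inversion_mode,
        "gate_radius": cal.gate_radius,
        "laser_rep_rate_hz": (
            cal.acquisition.laser_rep_rate if cal.acquisition else None
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_calibration(path: str | Path) -> PhasorCalibration:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != CALIBRATION_SCHEMA:
        raise FormatError(
            f"{path}: unknown calibration schema {doc.get('schema')!r}"
        )
    hill = HillCalibration(
        kd=doc["kd_nM"],
        hill_slope=doc["hill_slope"],
        tau_free=doc["tau_free_ps"] * 1e-12,
        tau_fret=doc["tau_fret_ps"] * 1e-12,
    )
    seg = doc.get("segment_hill")
    acq = None
    if doc.get("laser_rep_rate_hz"):
        acq = AcquisitionParams(laser_rep_rate=doc["laser_rep_rate_hz"])
    return PhasorCalibration(
        p_free=Phasor(*doc["p_free"]),
        p_fret=Phasor(*doc["p_fret"]),
        hill=hill,
        brightness_ratio=doc["brightness_ratio"],
        segment_hill=SegmentHill(seg["kd_nM"], seg["hill_slope"]) if seg else None,
        inversion_mode=doc.get("inversion_mode", "empirical"),
        gate_radius=doc.get("gate_radius", 0.3),
        acquisition=acq,
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def read_trace_csv(path: str | Path):
    """Read a `time_s,ch1,ch2[,event]` trace CSV into a RatioTrace."""
    from .traces import RatioTrace

    df = pd.read_csv(path)
    if not {"time_s", "ch1", "ch2"}.issubset(df.columns):
        raise FormatError(f"{path}: trace CSV requires columns time_s,ch1,ch2")
    events: tuple[float, ...] = ()
    if "event" in df.columns:
        events = tuple(df.loc[df["event"].fillna(0) > 0, "time_s"].astype(float))
    return RatioTrace(
        time_s=df["time_s"].to_numpy(float),
        ch1=df["ch1"].to_numpy(float),
        ch2=df["ch2"].to_numpy(float),
        events=events,
    )


def read_track_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"track_id", "frame_index", "label_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: track CSV requires columns {sorted(required)}")
    return df


def write_cell_records(records: Sequence[CellRecord], path: str | Path) -> None:
    df = records_to_frame(records)
    df["ca_nM"] = df["ca_nM"].map(lambda v: float(f"{v:.4g}") if np.isfinite(v) else v)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Titration directories
# ---------------------------------------------------------------------------


def write_titration_dir(titration, out_dir: str | Path) -> Path:
    """Write a titration set as decay CSVs plus a `manifest.csv` (`ca_nM,file`)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict[float, int] = {}
    for ca, decay in titration.decays:
        rep = counters.get(ca, 0)
        counters[ca] = rep + 1
        name = f"decay_ca{ca:g}nM_rep{rep}.csv"
        write_decay_csv(decay, out_dir / name)
        rows.append({"ca_nM": ca, "file": name})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_titration_dir(
    path: str | Path, params: AcquisitionParams | None = None
) -> list[tuple[float, DecayHistogram]]:
    """Read a titration directory via its manifest; returns (ca_nM, decay) pairs."""
    path = Path(path)
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"{path}: missing manifest.csv")
    df = pd.read_csv(manifest)
    if not {"ca_nM", "file"}.issubset(df.columns):
        raise FormatError(f"{manifest}: manifest requires columns ca_nM,file")
    return [
        (float(row.ca_nM), read_decay_csv(path / row.file, params=params))
        for row in df.itertuples()
    ]
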