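"""File formats: plain-text single scans and HDF5 scan-set containers.

Text scans are inspectable (header comment lines plus a tab-separated
radius x wavelength count table); full runs go to HDF5 with layout

    /scans/NNN            groups with time_s, speed_rpm, z_mm attrs and
                          radius, wavelength, counts datasets
    /instrument           attributes of the forward model
    /ground_truth         synthetic-only sidecar (species table, injected
                          noise, seed)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .instrument import InstrumentModel, Scan, ScanSet

__all__ = ["read_scan", "write_scan", "read_dataset", "write_dataset",
           "ScanParseError"]

_HEADER_KEYS = ("instrument", "laser_nm", "grating_lmm", "exposure_ms",
                "z_mm", "speed_rpm", "time_s", "temperature_C", "seed")


class ScanParseError(ValueError):
    """Malformed scan file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_scan(path, scan: Scan, *, header_extra: dict | None = None) -> None:
    """Write one scan as a tab-separated text table with a keyed header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# mweauc scan v1\n")
        meta = {
            "time_s": scan.time_s,
            "speed_rpm": scan.speed_rpm,
            "z_mm": scan.z_mm,
            "exposure_ms": scan.exposure_ms,
        }
        if header_extra:
            meta.update(header_extra)
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("radius_cm\t" + "\t".join(f"{w:.4f}"
                                           for w in scan.wavelength_nm) + "\n")
        for i, r in enumerate(scan.radius_cm):
            row = "\t".join(str(int(c)) for c in scan.counts[i])
            fh.write(f"{r:.6f}\t{row}\n")


def read_scan(path) -> Scan:
    """Read a text scan; malformed content raises with its line number."""
    path = Path(path)
    meta: dict = {}
    wavelengths = None
    radii: list[float] = []
    rows: list[list[int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if wavelengths is None:
                if parts[0] != "radius_cm":
                    raise ScanParseError(
                        "expected wavelength header row starting with "
                        "'radius_cm'", lineno)
                try:
                    wavelengths = np.asarray([float(p) for p in parts[1:]])
                except ValueError as exc:
                    raise ScanParseError(f"bad wavelength value: {exc}", lineno)
                continue
            if len(parts) != wavelengths.size + 1:
                raise ScanParseError(
                    f"expected {wavelengths.size + 1} columns, got "
                    f"{len(parts)}", lineno)
            try:
                r = float(parts[0])
                counts = [int(p) for p in parts[1:]]
            except ValueError as exc:
                raise ScanParseError(f"bad value: {exc}", lineno)
            if radii and r <= radii[-1]:
                raise ScanParseError(
                    f"radii must be strictly increasing ({r} after "
                    f"{radii[-1]})", lineno)
            if any(c < 0 or c > 65535 for c in counts):
                raise ScanParseError("counts outside [0, 65535]", lineno)
            radii.append(r)
            rows.append(counts)
    if wavelengths is None or not rows:
        raise ScanParseError("no data rows found", 0)
    return Scan(
        time_s=float(meta.get("time_s", 0.0)),
        speed_rpm=float(meta.get("speed_rpm", 0.0)),
        z_mm=float(meta.get("z_mm", 0.0)),
        radius_cm=np.asarray(radii),
        wavelength_nm=wavelengths,
        counts=np.asarray(rows, dtype=np.uint16),
        exposure_ms=float(meta.get("exposure_ms", 100.0)),
    )


# ---------------------------------------------------------------------------
# HDF5 datasets
# ---------------------------------------------------------------------------

def write_dataset(path, scanset: ScanSet) -> None:
    """Write a scan set (and its ground-truth sidecar, if any) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("scans")
        for k in range(scanset.n_scans):
            g = grp.create_group(f"{k:03d}")
            g.attrs["time_s"] = float(scanset.times_s[k])
            g.attrs["speed_rpm"] = float(scanset.speed_rpm)
            g.attrs["z_mm"] = 0.0
            g.create_dataset("radius", data=scanset.radius_cm)
            g.create_dataset("wavelength", data=scanset.wavelength_nm)
            g.create_dataset("counts", data=scanset.counts[k],
                             compression="gzip", compression_opts=4)
        inst = h5.create_group("instrument")
        if scanset.instrument is not None:
            for f in dataclasses.fields(scanset.instrument):
                val = getattr(scanset.instrument, f.name)
                if val is None:
                    continue
                inst.attrs[f.name] = val
        inst.attrs["exposure_ms"] = float(scanset.exposure_ms)
        if scanset.meniscus_cm is not None:
            inst.attrs["meniscus_cm"] = float(scanset.meniscus_cm)
        if scanset.bottom_cm is not None:
            inst.attrs["bottom_cm"] = float(scanset.bottom_cm)
        if scanset.ground_truth is not None:
            gt = h5.create_group("ground_truth")
            truth = dict(scanset.ground_truth)
            for key in ("ti_profile", "ri_offsets"):
                if key in truth:
                    gt.create_dataset(key, data=np.asarray(truth.pop(key)))
            gt.attrs["json"] = json.dumps(truth)


def read_dataset(path) -> ScanSet:
    """Read a scan-set container; missing required groups raise KeyError."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        if "scans" not in h5:
            raise KeyError("dataset is missing the required /scans group")
        if "instrument" not in h5:
            raise KeyError("dataset is missing the required /instrument group")
        keys = sorted(h5["scans"].keys())
        times = []
        counts = []
        radius = wavelength = None
        speed = 0.0
        for k in keys:
            g = h5["scans"][k]
            times.append(float(g.attrs["time_s"]))
            speed = float(g.attrs["speed_rpm"])
            radius = g["radius"][...]
            wavelength = g["wavelength"][...]
            counts.append(g["counts"][...])
        inst_attrs = dict(h5["instrument"].attrs)
        exposure = float(inst_attrs.pop("exposure_ms", 100.0))
        meniscus = inst_attrs.pop("meniscus_cm", None)
        bottom = inst_attrs.pop("bottom_cm", None)
        field_names = {f.name for f in dataclasses.fields(InstrumentModel)}
        kwargs = {}
        for key, val in inst_attrs.items():
            if key in field_names:
                if isinstance(val, np.ndarray):
                    val = tuple(val.tolist())
                elif isinstance(val, np.generic):
                    val = val.item()
                kwargs[key] = val
        if "grating_lmm" in kwargs:
            kwargs["grating_lmm"] = int(kwargs["grating_lmm"])
        if "sensor_pixels" in kwargs:
            kwargs["sensor_pixels"] = int(kwargs["sensor_pixels"])
        instrument = InstrumentModel(**kwargs) if kwargs else None
        ground_truth = None
        if "ground_truth" in h5:
            gt = h5["ground_truth"]
            ground_truth = json.loads(gt.attrs.get("json", "{}"))
            for key in ("ti_profile", "ri_offsets"):
                if key in gt:
                    ground_truth[key] = gt[key][...]
    return ScanSet(
        times_s=np.asarray(times),
        radius_cm=np.asarray(radius),
        wavelength_nm=np.asarray(wavelength),
        counts=np.asarray(counts, dtype=np.uint16),
        speed_rpm=speed,
        exposure_ms=exposure,
        instrument=instrument,
        ground_truth=ground_truth,
        meniscus_cm=None if meniscus is None else float(meniscus),
        bottom_cm=None if bottom is None else float(bottom),
    )
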