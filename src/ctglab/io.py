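"""Record and model I/O.

Two on-disk dialects are supported for CTG recordings:

* a CSV dialect with header ``time_s,fhr_bpm,uc_mmhg`` (UTF-8, '.' decimal);
* WFDB records (header + 16-bit signal file) with channels described as
  ``FHR`` and ``UC``, the layout used by the open intrapartum databases on
  PhysioNet.

In both, missing points are encoded in-band as values of exactly 0 or -1;
the readers translate them into boolean masks.  Fitted models are
serialized as a small versioned YAML tree with decimal text numbers so the
files are diffable and language-neutral.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, FormatError, SamplingError
from .types import (
    DEFAULT_SAMPLE_RATE,
    PHYSIOLOGICAL_FHR_RANGE,
    CaseMeta,
    CTGRecord,
    FittedModel,
)

CSV_COLUMNS = ("time_s", "fhr_bpm", "uc_mmhg")
MODEL_SCHEMA_VERSION = 1
_TIME_TOL_S = 1e-6


def missing_mask(values: np.ndarray, *, physiological_guard: bool = False) -> np.ndarray:
    """Mask of in-band missing samples: exactly 0 or -1, optionally plus
    FHR values outside the physiological range (30-250 bpm)."""
    mask = (values == 0.0) | (values == -1.0)
    if physiological_guard:
        lo, hi = PHYSIOLOGICAL_FHR_RANGE
        mask |= (values < lo) | (values > hi)
    return mask


def read_ctg_csv(
    path: str | Path,
    sample_rate: float | None = None,
    *,
    case_id: str | None = None,
    end_offset: float = 0.0,
    meta: CaseMeta | None = None,
    physiological_guard: bool = True,
) -> CTGRecord:
    """Read one recording from the package CSV dialect.

    The time column must be strictly increasing and uniformly spaced (to
    within 1 microsecond); when ``sample_rate`` is given it must agree with
    the time step.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    if tuple(df.columns[:3]) != CSV_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(CSV_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SamplingError(f"{path}: time column is not strictly increasing")
        if dt.max() - dt.min() > _TIME_TOL_S:
            raise SamplingError(f"{path}: non-uniform time step")
        rate = 1.0 / dt.mean()
    else:
        rate = sample_rate or DEFAULT_SAMPLE_RATE
    if sample_rate is not None and len(t) > 1:
        if abs(rate - sample_rate) > _TIME_TOL_S * sample_rate * rate:
            raise SamplingError(
                f"{path}: file sampled at {rate:g} Hz, expected {sample_rate:g} Hz"
            )
        rate = sample_rate
    fhr = df["fhr_bpm"].to_numpy(dtype=float)
    uc = df["uc_mmhg"].to_numpy(dtype=float)
    return CTGRecord(
        case_id=case_id or path.stem,
        fhr=fhr,
        uc=uc,
        sample_rate=rate,
        end_offset=end_offset,
        missing_fhr=missing_mask(fhr, physiological_guard=physiological_guard),
        missing_uc=missing_mask(uc),
        meta=meta or CaseMeta(),
    )


def write_ctg_csv(record: CTGRecord, path: str | Path) -> None:
    """Write a record in the package CSV dialect.

    Masked samples are written back as 0 so the file round-trips through
    :func:`read_ctg_csv` with identical masks.
    """
    fhr = record.fhr.copy()
    uc = record.uc.copy()
    fhr[record.missing_fhr] = 0.0
    uc[record.missing_uc] = 0.0
    df = pd.DataFrame(
        {"time_s": record.time_s, "fhr_bpm": fhr, "uc_mmhg": uc}
    )
    # full repr precision so unmasked samples round-trip exactly
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# WFDB (minimal): header `<name>.hea` + format-16 signal file.
# Header line 1: "<name> <nsig> <fs> <nsamp>"; one line per signal:
# "<file> <format> <gain>(<baseline>)/<units> <adcres> <adczero> <init> <cksum> <blksize> <description>"
# Sample value = (stored - baseline) / gain.
# --------------------------------------------------------------------------

def read_wfdb_record(
    path: str | Path,
    *,
    end_offset: float = 0.0,
    meta: CaseMeta | None = None,
    physiological_guard: bool = True,
) -> CTGRecord:
    """Read a two-channel WFDB record whose channels are described as
    ``FHR`` and ``UC`` (format 16, little-endian)."""
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"{hea}: header not found")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: malformed record line")
    name, nsig, fs, nsamp = head[0], int(head[1]), float(head[2]), int(head[3])
    sig_lines = lines[1 : 1 + nsig]
    if len(sig_lines) != nsig:
        raise FormatError(f"{hea}: expected {nsig} signal lines")

    channels: dict[str, np.ndarray] = {}
    specs = []
    for ln in sig_lines:
        parts = ln.split()
        if len(parts) < 3:
            raise FormatError(f"{hea}: malformed signal line: {ln!r}")
        fname, fmt = parts[0], parts[1]
        if fmt != "16":
            raise FormatError(f"{hea}: only format 16 is supported, got {fmt}")
        gain_spec = parts[2]
        if "/" in gain_spec:
            gain_spec = gain_spec.split("/", 1)[0]
        if "(" in gain_spec:
            g, b = gain_spec.split("(", 1)
            gain, base = float(g), float(b.rstrip(")"))
        else:
            gain, base = float(gain_spec), 0.0
        if gain == 0:
            gain = 200.0  # WFDB default ADC gain
        desc = parts[-1] if len(parts) > 3 else fname
        specs.append((fname, gain, base, desc))

    sig_files = {s[0] for s in specs}
    if len(sig_files) != 1:
        raise FormatError(f"{hea}: multi-file signals are not supported")
    dat = path.parent / specs[0][0]
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if raw.size % nsig:
        raise FormatError(f"{dat}: size not a multiple of channel count")
    raw = raw.reshape(-1, nsig)[:nsamp]
    for k, (_, gain, base, desc) in enumerate(specs):
        channels[desc.upper()] = (raw[:, k].astype(float) - base) / gain

    for ch in ("FHR", "UC"):
        if ch not in channels:
            raise FormatError(f"{path}: channel {ch!r} not found (have {sorted(channels)})")
    fhr, uc = channels["FHR"], channels["UC"]
    return CTGRecord(
        case_id=name,
        fhr=fhr,
        uc=uc,
        sample_rate=fs,
        end_offset=end_offset,
        missing_fhr=missing_mask(fhr, physiological_guard=physiological_guard),
        missing_uc=missing_mask(uc),
        meta=meta or CaseMeta(),
    )


def write_wfdb_record(record: CTGRecord, path: str | Path, *, gain: float = 100.0) -> None:
    """Write a two-channel format-16 WFDB record (used for fixtures and to
    round-trip against :func:`read_wfdb_record`)."""
    path = Path(path)
    n = len(record)
    fhr = record.fhr.copy()
    uc = record.uc.copy()
    fhr[record.missing_fhr] = 0.0
    uc[record.missing_uc] = 0.0
    data = np.empty((n, 2), dtype="<i2")
    data[:, 0] = np.round(fhr * gain).astype("<i2")
    data[:, 1] = np.round(uc * gain).astype("<i2")
    dat_name = path.name + ".dat"
    (path.parent / dat_name).write_bytes(data.tobytes())
    fs = record.sample_rate
    fs_str = f"{fs:g}"
    lines = [f"{path.name} 2 {fs_str} {n}"]
    for desc in ("FHR", "UC"):
        lines.append(f"{dat_name} 16 {gain:g}(0)/{'bpm' if desc == 'FHR' else 'mmHg'} 16 0 0 0 0 {desc}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Model serialization
# --------------------------------------------------------------------------

def save_stability_model(model, path: str | Path) -> None:
    """Serialize a baseline StabilityModel as versioned YAML text."""
    doc = {
        "schema": "ctglab-stability",
        "version": MODEL_SCHEMA_VERSION,
        "intercept": _num(model.intercept),
        "coef": [_num(c) for c in model.coef],
        "center": [_num(c) for c in model.center],
        "scale": [_num(c) for c in model.scale],
        "bands_bpm": [[float(lo), float(hi)] for lo, hi in model.bands_bpm],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_stability_model(path: str | Path):
    from .baseline import StabilityModel

    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("schema") != "ctglab-stability":
        raise FormatError(f"{path}: not a ctglab stability-model file")
    if doc.get("version") != MODEL_SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported schema version {doc.get('version')}")
    try:
        return StabilityModel(
            coef=np.array([float(x) for x in doc["coef"]]),
            intercept=float(doc["intercept"]),
            center=np.array([float(x) for x in doc["center"]]),
            scale=np.array([float(x) for x in doc["scale"]]),
            bands_bpm=tuple((float(lo), float(hi)) for lo, hi in doc["bands_bpm"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed stability-model file ({exc})") from exc


def _num(x: float) -> str:
    """Decimal text with 17 significant digits (round-trips IEEE doubles)."""
    return repr(float(x))


def save_model(model: FittedModel, path: str | Path) -> None:
    doc = {
        "schema": "ctglab-model",
        "version": MODEL_SCHEMA_VERSION,
        "outcome_threshold": _num(model.outcome_threshold),
        "beta0": _num(model.beta0),
        "features": [
            {
                "name": name,
                "beta": _num(model.beta[i]),
                "center": _num(model.center[i]),
                "scale": _num(model.scale[i]),
            }
            for i, name in enumerate(model.feature_names)
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> FittedModel:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: not valid YAML") from exc
    if not isinstance(doc, dict) or doc.get("schema") != "ctglab-model":
        raise FormatError(f"{path}: not a ctglab model file")
    if doc.get("version") != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: schema version {doc.get('version')} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    feats = doc.get("features")
    if not feats:
        raise FormatError(f"{path}: missing features block")
    try:
        names = tuple(f["name"] for f in feats)
        beta = np.array([float(f["beta"]) for f in feats])
        center = np.array([float(f["center"]) for f in feats])
        scale = np.array([float(f["scale"]) for f in feats])
        return FittedModel(
            feature_names=names,
            beta0=float(doc["beta0"]),
            beta=beta,
            center=center,
            scale=scale,
            outcome_threshold=float(doc["outcome_threshold"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model file ({exc})") from exc
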