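"""File formats: SNIRF-style HDF5 sessions, long CSV, PNG maps, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .protocol import SessionProtocol
from .simulate import ActivationProfile, ChannelGeometry, HbTimeSeries
from .tmap import TMap

__all__ = [
    "IntegrityError",
    "write_snirf",
    "read_snirf",
    "write_csv_long",
    "save_tmap_png",
    "load_tmap_png",
    "build_manifest",
    "verify_manifest",
]


class IntegrityError(RuntimeError):
    """A stored artifact does not match its recorded checksum."""


def _json_meta(series: HbTimeSeries) -> str:
    truth = None
    if series.truth is not None:
        t = series.truth
        truth = {
            "class_label": t.class_label,
            "active_channels": list(t.active_channels),
            "amplitude": t.amplitude,
            "jitter_sd": t.jitter_sd,
            "spread_amplitude": t.spread_amplitude,
            "spread_sigma": t.spread_sigma,
            "spread_center": list(t.spread_center),
            "spread_center_jitter_sd": t.spread_center_jitter_sd,
            "focal_delayed_fraction": t.focal_delayed_fraction,
            "channel_gain_sd": t.channel_gain_sd,
            "vaso_sd": t.vaso_sd,
            "vaso_band": list(t.vaso_band),
        }
    p = series.protocol
    return json.dumps({
        "protocol": {
            "pre_rest_s": p.pre_rest_s, "post_rest_s": p.post_rest_s,
            "n_trials": p.n_trials, "task_s": p.task_s,
            "rest_s": p.rest_s, "fs": p.fs,
        },
        "label": series.label, "subject": series.subject,
        "session": series.session, "truth": truth,
    })


def write_snirf(series: HbTimeSeries, path) -> None:
    """Store one session in an SNIRF-shaped HDF5 file.

    Layout follows the SNIRF convention (``/nirs/data1/dataTimeSeries``
    time x channel, ``/nirs/data1/time``, probe positions); the session
    context this package needs beyond that is kept as a JSON metadata
    tag.  Data are stored as float32.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=series.data.T.astype(np.float32))
        data.create_dataset("time", data=series.protocol.time().astype(np.float64))
        probe = nirs.create_group("probe")
        probe.create_dataset("detectorPos2D", data=series.geometry.xy.astype(np.float64))
        labels = np.array(series.geometry.channel_ids, dtype=h5py.string_dtype())
        probe.create_dataset("detectorLabels", data=labels)
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("dipmap", data=_json_meta(series))


def read_snirf(path) -> HbTimeSeries:
    with h5py.File(path, "r") as f:
        data = f["nirs/data1/dataTimeSeries"][()].T.astype(np.float64)
        xy = f["nirs/probe/detectorPos2D"][()]
        ids = tuple(s.decode() for s in f["nirs/probe/detectorLabels"][()])
        meta = json.loads(f["nirs/metaDataTags/dipmap"][()].decode())
    protocol = SessionProtocol(**meta["protocol"])
    geometry = ChannelGeometry(channel_ids=ids, xy=xy)
    truth = None
    if meta["truth"] is not None:
        t = dict(meta["truth"])
        t["active_channels"] = tuple(t["active_channels"])
        t["spread_center"] = tuple(t["spread_center"])
        if "vaso_band" in t:
            t["vaso_band"] = tuple(t["vaso_band"])
        truth = ActivationProfile(**t)
    return HbTimeSeries(
        data=data, fs=protocol.fs, protocol=protocol, geometry=geometry,
        truth=truth, label=meta["label"],
        subject=meta["subject"], session=meta["session"],
    )


def write_csv_long(sessions: list[HbTimeSeries], path) -> None:
    """Long-format CSV: subject, session, channel, sample_index, time_s, dHbO."""
    frames = []
    for s in sessions:
        t = s.protocol.time()
        n_ch, n = s.data.shape
        frames.append(pd.DataFrame({
            "subject": np.repeat(s.subject, n_ch * n),
            "session": np.repeat(s.session, n_ch * n),
            "channel": np.repeat(s.geometry.channel_ids, n),
            "sample_index": np.tile(np.arange(n), n_ch),
            "time_s": np.tile(t, n_ch),
            "dHbO": s.data.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_tmap_png(tmap: TMap, path) -> None:
    """8-bit RGB PNG plus a JSON sidecar with the map's provenance."""
    path = Path(path)
    arr = np.rint(np.clip(tmap.image, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")
    sidecar = {
        "label": tmap.label, "subject": tmap.subject, "trial": tmap.trial,
        "window_s": tmap.window_s,
        "channel_values": np.asarray(tmap.channel_values).tolist(),
        "t_raw": np.asarray(tmap.t_raw).tolist(),
        "p_raw": np.asarray(tmap.p_raw).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_tmap_png(path) -> TMap:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
    meta = json.loads(path.with_suffix(".json").read_text())
    return TMap(
        channel_values=np.array(meta["channel_values"]),
        t_raw=np.array(meta["t_raw"]), p_raw=np.array(meta["p_raw"]),
        image=arr, label=meta["label"], subject=meta["subject"],
        trial=meta["trial"], window_s=meta["window_s"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(paths: list, out_csv) -> pd.DataFrame:
    """Checksum manifest of artifact files."""
    rows = [{"path": str(Path(p).name), "sha256": _sha256(Path(p))} for p in paths]
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df


def verify_manifest(manifest_csv, base_dir=None) -> None:
    """Re-hash every file in a manifest; raise IntegrityError on mismatch."""
    manifest_csv = Path(manifest_csv)
    base = Path(base_dir) if base_dir else manifest_csv.parent
    df = pd.read_csv(manifest_csv)
    for _, row in df.iterrows():
        target = base / row["path"]
        if not target.exists():
            raise IntegrityError(f"missing artifact {target}")
        actual = _sha256(target)
        if actual != row["sha256"]:
            raise IntegrityError(
                f"checksum mismatch for {target}: manifest {row['sha256'][:12]}…, "
                f"file {actual[:12]}…"
            )
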