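"""Raw-recording interchange: flat binary + JSON sidecar, and SNIRF.

The native on-disk format for both modalities is a little-endian float32
array (``<base>.dat``, channel-major) with a JSON sidecar (``<base>.json``)
holding rate, shape, labels/geometry and per-channel quality metadata.
fNIRS recordings can additionally be exported to SNIRF (HDF5) for
interoperability with standard near-infrared tooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import montage
from .synthetic_participant import RawEEG, RawFNIRS


def write_raw_eeg(raw: RawEEG, base: str | Path) -> None:
    base = Path(base)
    raw.samples.astype("<f4").tofile(base.with_suffix(".dat"))
    sidecar = {
        "modality": "eeg",
        "rate": raw.rate,
        "shape": list(raw.samples.shape),
        "labels": raw.labels,
        "impedances_kohm": [float(x) for x in raw.impedances],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_raw_eeg(base: str | Path) -> RawEEG:
    base = Path(base)
    meta = json.loads(base.with_suffix(".json").read_text())
    if meta.get("modality") != "eeg":
        raise ValueError(f"{base}: sidecar is not an EEG recording")
    data = np.fromfile(base.with_suffix(".dat"), dtype="<f4").astype(
        np.float64).reshape(meta["shape"])
    return RawEEG(samples=data, rate=meta["rate"], labels=meta["labels"],
                  impedances=np.asarray(meta["impedances_kohm"]))


def write_raw_fnirs(raw: RawFNIRS, base: str | Path) -> None:
    base = Path(base)
    raw.intensities.astype("<f4").tofile(base.with_suffix(".dat"))
    sidecar = {
        "modality": "fnirs",
        "rate": raw.rate,
        "shape": list(raw.intensities.shape),
        "wavelengths_nm": list(raw.wavelengths),
        "channels": [asdict(c) for c in raw.channels],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_raw_fnirs(base: str | Path) -> RawFNIRS:
    base = Path(base)
    meta = json.loads(base.with_suffix(".json").read_text())
    if meta.get("modality") != "fnirs":
        raise ValueError(f"{base}: sidecar is not an fNIRS recording")
    data = np.fromfile(base.with_suffix(".dat"), dtype="<f4").astype(
        np.float64).reshape(meta["shape"])
    channels = [montage.FnirsChannel(
        name=c["name"], source=c["source"], detector=c["detector"],
        separation_mm=c["separation_mm"], is_short=c["is_short"],
        position=tuple(c["position"])) for c in meta["channels"]]
    return RawFNIRS(intensities=data, rate=meta["rate"], channels=channels,
                    wavelengths=tuple(meta["wavelengths_nm"]))


def write_snirf(raw: RawFNIRS, path: str | Path) -> None:
    """Minimal SNIRF v1.0 export (continuous-wave intensity data)."""
    import h5py

    n_ch = raw.n_channels
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="synthetic")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        data1 = nirs.create_group("data1")
        n = raw.intensities.shape[2]
        # SNIRF stores time x measurement columns; one column per
        # channel-wavelength pair.
        dts = raw.intensities.reshape(n_ch * 2, n).T
        data1.create_dataset("dataTimeSeries", data=dts)
        data1.create_dataset("time", data=np.arange(n) / raw.rate)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths))
        src = sorted({c.source for c in raw.channels})
        det = sorted({c.detector for c in raw.channels})
        probe.create_dataset("sourceLabels",
                             data=np.array(src, dtype=object),
                             dtype=h5py.string_dtype())
        probe.create_dataset("detectorLabels",
                             data=np.array(det, dtype=object),
                             dtype=h5py.string_dtype())
        pos = np.array([[c.position[0], c.position[1], 0.0]
                        for c in raw.channels])
        probe.create_dataset("sourcePos3D", data=pos)
        probe.create_dataset("detectorPos3D", data=pos)
        k = 1
        for c_idx, ch in enumerate(raw.channels):
            for w in (1, 2):
                ml = data1.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex",
                                  data=src.index(ch.source) + 1)
                ml.create_dataset("detectorIndex",
                                  data=det.index(ch.detector) + 1)
                ml.create_dataset("wavelengthIndex", data=w)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1


def read_snirf(path: str | Path,
               channels: list[montage.FnirsChannel] | None = None
               ) -> RawFNIRS:
    """Read a SNIRF file written by :func:`write_snirf`.

    Channel geometry (separations, short-channel flags) is not part of the
    minimal export; pass ``channels`` to restore it, else the default
    montage layout is assumed when the channel count matches.
    """
    import h5py

    with h5py.File(path, "r") as f:
        dts = np.asarray(f["nirs/data1/dataTimeSeries"])
        time = np.asarray(f["nirs/data1/time"])
        wl = tuple(float(x) for x in np.asarray(f["nirs/probe/wavelengths"]))
    n_ch = dts.shape[1] // 2
    rate = float(np.round(1.0 / np.median(np.diff(time)), 6))
    if channels is None:
        default = montage.fnirs_channels()
        if len(default) != n_ch:
            raise ValueError("channel geometry required for this layout")
        channels = default
    intens = dts.T.reshape(n_ch, 2, -1)
    return RawFNIRS(intensities=intens, rate=rate, channels=channels,
                    wavelengths=wl)
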