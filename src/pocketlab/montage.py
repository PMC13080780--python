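"""Channel inventory, ROI map and approximate sensor geometry.

The hybrid cap carries 32 EEG electrodes and 51 fNIRS channels (43 long
source-detector separations plus 8 short separations used as skin-signal
nuisance regressors). Channels are grouped into named regions of interest
(ROIs): nine for EEG (six lateral plus frontal/parietal/temporal midlines —
the midline ROIs are single electrodes) and six lateral ROIs for fNIRS.

The published ROI table's channel strings are partly malformed (run-together
tokens such as "AFP1AFF5F3F1", and "TPP8h" printed under both parietal
hemispheres). The tokenization below splits them on standard 10-20/10-5
electrode names and corrects the single obvious left/right typo (parietal
left receives TPP7h) so that no channel belongs to two ROIs. The temporal
midline ROI (Cz) is also referred to as "central midline" in the literature;
both labels resolve to the same ROI via ``ROI_ALIASES``.

Coordinates are approximate 2-D scalp projections (x: left -1 to right +1,
y: back -1 to front +1), sufficient for nearest-short-channel pairing and
for a plausible spatial weighting of the P300 field; they are not digitized
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# --- EEG -------------------------------------------------------------------

EEG_ROI_MAP: dict[str, list[str]] = {
    "frontal_left": ["AFP1", "AFF5", "F3", "F1"],
    "frontal_right": ["AFP2", "AFF6h", "F4", "F2"],
    "temporal_left": ["FTT7h", "TTP7h"],
    "temporal_right": ["FTT8h", "TTP8h"],
    "parietal_left": ["P1", "P7", "CPP5h", "TPP7h"],
    "parietal_right": ["P2", "P8", "CPP6h", "TPP8h"],
    "frontal_midline": ["Fz"],
    "parietal_midline": ["Pz"],
    "temporal_midline": ["Cz"],
}

ROI_ALIASES: dict[str, str] = {
    "central_midline": "temporal_midline",
}

# Electrodes not assigned to any analysis ROI (completing the 32-ch montage).
EEG_UNASSIGNED: list[str] = [
    "Fp1", "Fp2", "F7", "F8", "C3", "C4", "T7", "T8", "Oz",
]

EEG_CHANNELS: list[str] = (
    [ch for chans in EEG_ROI_MAP.values() for ch in chans] + EEG_UNASSIGNED
)

# Relative projection of the P300 scalp field onto each electrode. The
# component is maximal over the central/parietal midline (Cz, then Pz) and
# falls off toward frontal and temporal sites.
EEG_P300_WEIGHTS: dict[str, float] = {
    "Cz": 1.00, "Pz": 0.769, "Fz": 0.55,
    "P1": 0.60, "P2": 0.60, "CPP5h": 0.55, "CPP6h": 0.55,
    "TPP7h": 0.40, "TPP8h": 0.40, "P7": 0.30, "P8": 0.30,
    "C3": 0.55, "C4": 0.55, "F1": 0.40, "F2": 0.40,
    "F3": 0.30, "F4": 0.30, "AFF5": 0.20, "AFF6h": 0.20,
    "AFP1": 0.15, "AFP2": 0.15, "FTT7h": 0.20, "FTT8h": 0.20,
    "TTP7h": 0.25, "TTP8h": 0.25, "Fp1": 0.10, "Fp2": 0.10,
    "F7": 0.15, "F8": 0.15, "T7": 0.15, "T8": 0.15, "Oz": 0.30,
}

_POS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.30, 0.95), "Fp2": (0.30, 0.95), "FPZ": (0.00, 0.95),
    "FP1": (-0.30, 0.95), "FP2": (0.30, 0.95),
    "AFP1": (-0.15, 0.90), "AFP2": (0.15, 0.90),
    "AF3": (-0.35, 0.80), "AF4": (0.35, 0.80),
    "AF8": (0.70, 0.80), "AFz": (0.00, 0.80),
    "AFF5": (-0.50, 0.70), "AFF6h": (0.50, 0.70),
    "FF7": (-0.75, 0.65),
    "F7": (-0.80, 0.55), "F8": (0.80, 0.55),
    "F5": (-0.60, 0.55), "F6": (0.60, 0.55),
    "F3": (-0.40, 0.55), "F4": (0.40, 0.55),
    "F1": (-0.20, 0.55), "F2": (0.20, 0.55), "Fz": (0.00, 0.55),
    "FT7": (-0.85, 0.30), "FT8": (0.85, 0.30),
    "FTT7h": (-0.85, 0.15), "FTT8h": (0.85, 0.15),
    "T7": (-0.90, 0.00), "T8": (0.90, 0.00),
    "C5": (-0.70, 0.00), "C6": (0.70, 0.00),
    "C3": (-0.45, 0.00), "C4": (0.45, 0.00), "Cz": (0.00, 0.00),
    "TTP7h": (-0.85, -0.15), "TTP8h": (0.85, -0.15),
    "TP7": (-0.85, -0.30), "TP8": (0.85, -0.30),
    "CP3": (-0.40, -0.25), "CP4": (0.40, -0.25), "CP6": (0.70, -0.25),
    "CPP5h": (-0.55, -0.40), "CPP6h": (0.55, -0.40),
    "TPP7h": (-0.75, -0.45), "TPP8h": (0.75, -0.45),
    "P7": (-0.80, -0.55), "P8": (0.80, -0.55),
    "P5": (-0.60, -0.55), "P6": (0.60, -0.55),
    "P3": (-0.40, -0.55), "P4": (0.40, -0.55),
    "P1": (-0.20, -0.55), "P2": (0.20, -0.55), "Pz": (0.00, -0.55),
    "Oz": (0.00, -0.95),
}


def eeg_positions() -> dict[str, tuple[float, float]]:
    return {ch: _POS[ch] for ch in EEG_CHANNELS}


def resolve_roi(label: str) -> str:
    """Resolve an ROI label or alias to its canonical name."""
    return ROI_ALIASES.get(label, label)


# --- fNIRS -----------------------------------------------------------------

@dataclass(frozen=True)
class FnirsChannel:
    name: str            # "SOURCE-DETECTOR"
    source: str
    detector: str
    separation_mm: float
    is_short: bool
    position: tuple[float, float]   # geometric midpoint on the 2-D scalp map


FNIRS_ROI_MAP: dict[str, list[str]] = {
    "frontal_left": ["FPZ-FP1", "FPZ-AF3", "FF7-AF3", "F5-AF3",
                     "F5-F7", "AF3-AFz"],
    "frontal_right": ["FPZ-FP2", "FPZ-AF4", "AF8-FP2", "AF8-AF4",
                      "F6-AF4", "F6-F8", "AF4-AFz"],
    # Sides reproduced as printed in the source table (8-suffixed optodes
    # listed under "temporal left" and vice versa).
    "temporal_left": ["FT8-T8", "TP8-T8", "C6-T8"],
    "temporal_right": ["FT7-T7", "TP7-T7", "C5-T7"],
    "parietal_left": ["P5-P3", "P5-C5", "P3-CP3"],
    "parietal_right": ["P6-P4", "P6-CP6", "P4-CP4"],
}

_N_LONG = 43
_N_SHORT = 8
LONG_SEPARATION_MM = 30.0
SHORT_SEPARATION_MM = 8.0

# Short channels: one per scalp octant, co-located with a source optode.
_SHORT_POSITIONS: list[tuple[float, float]] = [
    (-0.30, 0.90), (0.30, 0.90),     # frontal
    (-0.80, 0.40), (0.80, 0.40),     # fronto-temporal
    (-0.85, -0.20), (0.85, -0.20),   # temporo-parietal
    (-0.45, -0.55), (0.45, -0.55),   # parietal
]


def _midpoint(a: str, b: str) -> tuple[float, float]:
    (x1, y1), (x2, y2) = _POS[a], _POS[b]
    return ((x1 + x2) / 2.0, (y1 + y2) / 2.0)


def fnirs_channels() -> list[FnirsChannel]:
    """Default 51-channel layout: 43 long + 8 short channels.

    The 25 ROI-assigned long channels take their positions from the optode
    map; the remaining 18 long channels (recorded but outside every analysis
    ROI) are spread over intermediate scalp positions.
    """
    chans: list[FnirsChannel] = []
    for roi_chans in FNIRS_ROI_MAP.values():
        for name in roi_chans:
            s, d = name.split("-")
            chans.append(FnirsChannel(name=name, source=s, detector=d,
                                      separation_mm=LONG_SEPARATION_MM,
                                      is_short=False,
                                      position=_midpoint(s, d)))
    n_extra = _N_LONG - len(chans)
    ang = np.linspace(0.0, 2 * np.pi, n_extra, endpoint=False)
    for i, a in enumerate(ang):
        pos = (0.55 * float(np.cos(a)), 0.55 * float(np.sin(a)))
        chans.append(FnirsChannel(name=f"X{i + 1:02d}-D{i + 1:02d}",
                                  source=f"X{i + 1:02d}",
                                  detector=f"D{i + 1:02d}",
                                  separation_mm=LONG_SEPARATION_MM,
                                  is_short=False, position=pos))
    for i, pos in enumerate(_SHORT_POSITIONS):
        chans.append(FnirsChannel(name=f"SC{i + 1}", source=f"SC{i + 1}",
                                  detector=f"SC{i + 1}d",
                                  separation_mm=SHORT_SEPARATION_MM,
                                  is_short=True, position=pos))
    assert len(chans) == _N_LONG + _N_SHORT
    return chans


def nearest_short_pairing(channels: list[FnirsChannel]) -> dict[str, str]:
    """Map each long channel name to the nearest short channel name."""
    shorts = [c for c in channels if c.is_short]
    if not shorts:
        return {}
    pairing = {}
    for c in channels:
        if c.is_short:
            continue
        d = [np.hypot(c.position[0] - s.position[0],
                      c.position[1] - s.position[1]) for s in shorts]
        pairing[c.name] = shorts[int(np.argmin(d))].name
    return pairing
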