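"""64-channel 10-10 montage (BioSemi ordering) and a centro-parietal gain map."""

from __future__ import annotations

import numpy as np

#: Standard BioSemi 64-electrode labels in cap order (two 32-channel banks).
BIOSEMI64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

# Relative P300 topography: strongest over centro-parietal midline sites,
# falling off frontally and laterally.  Used by the simulator to scale the
# response-locked template per channel.
_REGION_GAIN = {
    "CPz": 0.95, "Pz": 1.0, "POz": 0.7, "Cz": 0.85, "FCz": 0.5, "Fz": 0.3,
    "AFz": 0.15, "Fpz": 0.1, "Oz": 0.45, "Iz": 0.3,
}
_PREFIX_GAIN = [
    ("CP", 0.85), ("PO", 0.55), ("P", 0.75), ("FC", 0.4), ("AF", 0.12),
    ("Fp", 0.1), ("FT", 0.25), ("TP", 0.35), ("F", 0.25), ("C", 0.65),
    ("T", 0.25), ("O", 0.4), ("I", 0.3),
]


def _gain_for(name: str) -> float:
    if name in _REGION_GAIN:
        return _REGION_GAIN[name]
    for prefix, g in _PREFIX_GAIN:
        if name.startswith(prefix):
            # lateral sites (large digits) get a mild extra roll-off
            digits = "".join(ch for ch in name if ch.isdigit())
            rolloff = 1.0 if not digits else max(0.5, 1.0 - 0.06 * int(digits))
            return g * rolloff
    return 0.2


def centro_parietal_gains(channel_names: tuple[str, ...] = BIOSEMI64) -> np.ndarray:
    """Per-channel template gains, 1.0 at Pz, nonnegative everywhere."""
    return np.array([_gain_for(n) for n in channel_names])


#: Channels used in the reported ERP contrasts.
ERP_REPORT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "C3", "C4", "P5", "P6")

#: Channels where the simulated P300 is strongest (used in recovery checks).
CENTRO_PARIETAL = ("Pz", "CPz", "Cz", "P1", "P2", "CP1", "CP2")
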