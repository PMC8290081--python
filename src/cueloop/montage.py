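"""Standard channel layout, modeling-channel policy, and spatial adjacency.

The canonical recording layout has 64 channels: 60 scalp channels used for
decoding (including the mastoids M1/M2), the cerebellar pair CB1/CB2, and the
two ocular derivations VEOG/HEOG.  2-D positions are schematic head
coordinates (x: left-negative, y: anterior-positive) sufficient for
neighbour-graph construction; they are not digitized electrode positions.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SCALP_ROWS",
    "STANDARD_64",
    "MODEL60",
    "EOG_CHANNELS",
    "MASTOIDS",
    "positions_2d",
    "channel_kind",
    "montage_adjacency",
    "chain_adjacency",
]

# Anterior-to-posterior rows of the 10-20 layout: (labels, y coordinate).
SCALP_ROWS: list[tuple[list[str], float]] = [
    (["FP1", "FPZ", "FP2"], 0.95),
    (["AF3", "AF4"], 0.80),
    (["F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8"], 0.60),
    (["FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8"], 0.30),
    (["T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8"], 0.00),
    (["M1", "M2"], -0.10),
    (["TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8"], -0.30),
    (["P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8"], -0.60),
    (["PO7", "PO3", "POZ", "PO4", "PO8"], -0.80),
    (["O1", "OZ", "O2"], -0.95),
    (["CB1", "CB2"], -1.05),
]

EOG_CHANNELS = ["VEOG", "HEOG"]
MASTOIDS = ["M1", "M2"]

#: All 64 channels of the canonical recording, in acquisition order.
STANDARD_64: list[str] = [lab for row, _ in SCALP_ROWS for lab in row] + EOG_CHANNELS

#: The 60 channels used to build decoders: the standard set minus
#: CB1, CB2, HEOG and VEOG.
MODEL60: list[str] = [
    lab for lab in STANDARD_64 if lab not in {"CB1", "CB2", "VEOG", "HEOG"}
]

_X_SPREAD = {3: 0.35, 2: 0.30, 5: 0.30, 9: 0.22}


def _row_positions(labels: list[str], y: float) -> dict[str, tuple[float, float]]:
    n = len(labels)
    if labels == MASTOIDS:
        return {"M1": (-1.15, y), "M2": (1.15, y)}
    step = _X_SPREAD.get(n, 0.25)
    half = (n - 1) / 2.0
    return {lab: ((i - half) * step, y) for i, lab in enumerate(labels)}


def positions_2d(labels: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """Schematic 2-D position for each channel label (EOG placed off-scalp)."""
    pos: dict[str, tuple[float, float]] = {}
    for row, y in SCALP_ROWS:
        pos.update(_row_positions(row, y))
    pos["VEOG"] = (-0.55, 1.15)
    pos["HEOG"] = (0.55, 1.15)
    if labels is None:
        return pos
    missing = [l for l in labels if l.upper() not in pos]
    if missing:
        raise KeyError(f"no layout position for channel(s): {missing}")
    return {l: pos[l.upper()] for l in labels}


def channel_kind(label: str) -> str:
    """Classify a channel label as ``scalp``, ``mastoid`` or ``eog``."""
    u = label.upper()
    if u in {"VEOG", "HEOG", "VEOL", "VEOU", "HEOL", "HEOR", "EOG"}:
        return "eog"
    if u in {"M1", "M2", "A1", "A2", "TP9", "TP10"}:
        return "mastoid"
    return "scalp"


def montage_adjacency(labels: list[str], k: int = 4) -> np.ndarray:
    """Symmetric boolean neighbour matrix from k-nearest 2-D positions."""
    pos = positions_2d(labels)
    xy = np.array([pos[l] for l in labels], dtype=float)
    n = len(labels)
    adj = np.zeros((n, n), dtype=bool)
    if n == 1:
        return adj
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    kk = min(k, n - 1)
    nearest = np.argsort(d, axis=1)[:, :kk]
    for i in range(n):
        adj[i, nearest[i]] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    return adj


def chain_adjacency(n: int) -> np.ndarray:
    """Adjacency of a linear chain: channel i neighbours i-1 and i+1."""
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = True
    adj[idx + 1, idx] = True
    return adj
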