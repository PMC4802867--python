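"""Evaluation metrics: localization accuracy, overlap scores, center distances."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalReport",
    "localization_accuracy",
    "sensitivity",
    "specificity",
    "dice",
    "match_centers",
    "center_distances",
]


class UndefinedMetricError(ValueError):
    pass


def localization_accuracy(n_correct: int, n_detected: int) -> float:
    """Percentage of detections whose center lies inside the true disc."""
    if n_detected < 1:
        raise UndefinedMetricError("no detections: accuracy undefined")
    if n_correct > n_detected:
        raise ValueError("n_correct cannot exceed n_detected")
    return 100.0 * n_correct / n_detected


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def sensitivity(m_mask, a_mask) -> float:
    """|M intersect A| / |M| for reference mask M and automatic mask A."""
    m = _as_bool(m_mask)
    a = _as_bool(a_mask)
    nm = int(m.sum())
    if nm == 0:
        raise UndefinedMetricError("reference mask is empty")
    return int((m & a).sum()) / nm


def specificity(m_mask, a_mask, image_extent: int | None = None) -> float:
    """(|I| - |M union A|) / (|I| - |M|) over the image extent I."""
    m = _as_bool(m_mask)
    a = _as_bool(a_mask)
    n_i = int(image_extent) if image_extent is not None else m.size
    nm = int(m.sum())
    if n_i <= nm:
        raise UndefinedMetricError("reference mask covers the whole extent")
    nu = int((m | a).sum())
    return (n_i - nu) / (n_i - nm)


def dice(m_mask, a_mask) -> float:
    """Dice similarity index 2|M intersect A| / (|M| + |A|)."""
    m = _as_bool(m_mask)
    a = _as_bool(a_mask)
    denom = int(m.sum()) + int(a.sum())
    if denom == 0:
        raise UndefinedMetricError("both masks are empty")
    return 2.0 * int((m & a).sum()) / denom


def match_centers(detected, reference, gate_px: float = 30.0) -> tuple:
    """Greedy nearest-neighbor matching of detected to reference centers.

    Pairs are accepted in order of increasing distance, each center used at
    most once, distances above ``gate_px`` rejected.  Returns
    ``(pairs, unmatched_detected, unmatched_reference)`` where ``pairs`` is a
    list of ``(i_detected, j_reference, distance_px)``.
    """
    det = [np.asarray(c, dtype=float) for c in detected]
    ref = [np.asarray(c, dtype=float) for c in reference]
    cand = []
    for i, d in enumerate(det):
        for j, r in enumerate(ref):
            dist = float(np.hypot(*(d - r)))
            if dist <= gate_px:
                cand.append((dist, i, j))
    cand.sort()
    used_d: set = set()
    used_r: set = set()
    pairs = []
    for dist, i, j in cand:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((i, j, dist))
    un_d = [i for i in range(len(det)) if i not in used_d]
    un_r = [j for j in range(len(ref)) if j not in used_r]
    return pairs, un_d, un_r


@dataclass
class EvalReport:
    acc: float
    per_disc: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    n_detected: int = 0
    n_reference: int = 0
    unmatched_detected: int = 0
    unmatched_reference: int = 0


def center_distances(detected, reference, pixel_spacing: float | None = None,
                     gate_px: float = 30.0) -> dict:
    """Euclidean distance statistics between matched center pairs.

    Returns a dict with per-pair distances (px and mm when spacing given) and
    mean/std/median/max/min summaries; unmatched counts are reported, never
    silently dropped.
    """
    pairs, un_d, un_r = match_centers(detected, reference, gate_px=gate_px)
    d_px = np.array([p[2] for p in pairs], dtype=float)
    out = {
        "pairs": pairs,
        "distances_px": d_px.tolist(),
        "unmatched_detected": len(un_d),
        "unmatched_reference": len(un_r),
    }
    if pixel_spacing is not None:
        out["distances_mm"] = (d_px * pixel_spacing).tolist()
    if d_px.size:
        out["summary_px"] = {
            "mean": float(d_px.mean()),
            "std": float(d_px.std(ddof=0)),
            "median": float(np.median(d_px)),
            "max": float(d_px.max()),
            "min": float(d_px.min()),
        }
        if pixel_spacing is not None:
            d_mm = d_px * pixel_spacing
            out["summary_mm"] = {
                "mean": float(d_mm.mean()),
                "std": float(d_mm.std(ddof=0)),
                "median": float(np.median(d_mm)),
                "max": float(d_mm.max()),
                "min": float(d_mm.min()),
            }
    else:
        out["summary_px"] = {}
    return out
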