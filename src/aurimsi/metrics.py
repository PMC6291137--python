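"""Gold-layer quality metrics: TIC, fragmentation ratio, pixel selection.

These are the statistics used to compare sputter-coating conditions:
the total ion count over picked peaks with the gold-cluster peaks
excluded (they come from the layer, not the tissue, and would bias the
comparison), and the fragmentation ratio — the phosphatidylcholine
head-group fragment at m/z 184.07 divided by the summed peak intensity
in 500–1000 Da, a proxy for how soft the ionization is. "Intensity"
means peak height throughout; pass ``use_area=True`` for areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import MONOISOTOPIC_MASS
from .preprocess import Peak, PeakMatrix

__all__ = [
    "gold_exclusion_windows",
    "tic",
    "fragmentation_ratio",
    "top_k_pixels",
    "condition_metrics",
    "compare_conditions",
]


def gold_exclusion_windows(half_width: float = 0.2, n_max: int = 5) -> list[tuple[float, float]]:
    """(center, half-width) windows around the [Au_n]+ cluster masses."""
    au = MONOISOTOPIC_MASS["Au"]
    return [(n * au, half_width) for n in range(1, n_max + 1)]


def _value(p: Peak, use_area: bool) -> float:
    return p.area if use_area else p.height


def tic(
    peaks: Sequence[Peak],
    exclusion_windows: Iterable[tuple[float, float]] = (),
    use_area: bool = False,
) -> float:
    """Summed peak intensity, skipping peaks inside any exclusion window."""
    windows = list(exclusion_windows)
    total = 0.0
    for p in peaks:
        if any(abs(p.mz - c) <= hw for c, hw in windows):
            continue
        total += _value(p, use_area)
    return total


def fragmentation_ratio(
    peaks: Sequence[Peak],
    fragment_mz: float = 184.07,
    fragment_tol: float = 0.1,
    mz_range: tuple[float, float] = (500.0, 1000.0),
    use_area: bool = False,
) -> float:
    """Head-group fragment intensity over the 500–1000 Da summed intensity.

    The fragment is the most intense peak within ``fragment_mz ±
    fragment_tol``; the ratio is 0 when no such peak exists (soft
    ionization / no signal), and +inf when the fragment exists but the
    denominator is empty (degenerate spectrum).
    """
    frag = 0.0
    for p in peaks:
        if abs(p.mz - fragment_mz) <= fragment_tol:
            frag = max(frag, _value(p, use_area))
    if frag == 0.0:
        return 0.0
    denom = sum(
        _value(p, use_area) for p in peaks if mz_range[0] <= p.mz <= mz_range[1]
    )
    if denom == 0.0:
        import logging

        logging.getLogger(__name__).warning(
            "fragmentation ratio: fragment present but no peaks in %s Da", mz_range
        )
        return inf
    return frag / denom


def top_k_pixels(
    values: np.ndarray, coordinates: np.ndarray, k: int = 250
) -> np.ndarray:
    """Indices of the k pixels with the highest criterion value.

    Ties are broken by (row, col) order so the selection is
    deterministic; if fewer than k pixels exist, all are returned.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    values = np.asarray(values, float)
    coordinates = np.asarray(coordinates, int)
    if k >= values.size:
        return np.arange(values.size)
    order = np.lexsort((coordinates[:, 0], coordinates[:, 1], -values))
    return np.sort(order[:k])


def condition_metrics(
    matrix: PeakMatrix,
    label: str = "",
    k: int = 250,
    exclude_gold: bool = True,
    rank_gold_excluded: bool = True,
    use_area: bool = False,
) -> pd.DataFrame:
    """Per-pixel metrics table over the top-k pixels of one condition.

    With ``exclude_gold`` the gold-cluster peaks are removed from the
    peak list before *both* metrics — they come from the layer, not the
    tissue. Pixels are ranked by gold-excluded TIC by default
    (``rank_gold_excluded``).
    """
    windows = gold_exclusion_windows() if exclude_gold else []
    n = len(matrix.coordinates)
    tics = np.empty(n)
    tics_rank = np.empty(n)
    frags = np.empty(n)
    for i in range(n):
        plist = matrix.pixel_peaks(i)
        kept = [p for p in plist if all(abs(p.mz - c) > hw for c, hw in windows)]
        tics[i] = tic(kept, (), use_area)
        tics_rank[i] = tics[i] if rank_gold_excluded else tic(plist, (), use_area)
        frags[i] = fragmentation_ratio(kept, use_area=use_area)
    sel = top_k_pixels(tics_rank, matrix.coordinates, k)
    return pd.DataFrame(
        {
            "condition": label,
            "x": matrix.coordinates[sel, 0],
            "y": matrix.coordinates[sel, 1],
            "tic": tics[sel],
            "fragmentation_ratio": frags[sel],
        }
    )


def compare_conditions(
    conditions: Sequence[tuple[str, PeakMatrix]],
    k: int = 250,
    exclude_gold: bool = True,
    use_area: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-condition metric distributions + quartile summary.

    Returns ``(per_pixel, summary)``: the per-pixel table concatenated
    over conditions (suitable for boxplots) and per-condition medians
    and quartiles of both metrics. Output is sorted by condition label,
    so it does not depend on input order.
    """
    frames = [
        condition_metrics(m, label, k, exclude_gold, use_area=use_area)
        for label, m in conditions
    ]
    per_pixel = pd.concat(frames, ignore_index=True).sort_values(
        ["condition", "y", "x"], kind="stable", ignore_index=True
    )
    rows = []
    for label, grp in per_pixel.groupby("condition", sort=True):
        for metric in ("tic", "fragmentation_ratio"):
            q1, med, q3 = np.percentile(grp[metric], [25, 50, 75])
            rows.append(
                {"condition": label, "metric": metric, "q1": q1, "median": med, "q3": q3}
            )
    return per_pixel, pd.DataFrame(rows)
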