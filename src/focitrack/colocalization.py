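"""Two-channel focus colocalization in fixed cells.

Quantifies how often channel-B (RPA, resection marker) foci sit inside
channel-A (53BP1, break marker) foci: S-phase nuclei are selected by an
automatic threshold on a replication-label (EdU) channel, foci are segmented
per nucleus in both channels, the B-channel intensity is measured inside each
A-focus mask, and every B focus is assigned to the A focus containing its
center of mass, giving per-A-focus nested counts reduced to the categories
0 / 1 / >1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters

from .segmentation import Focus, measure_foci, segment_foci

__all__ = [
    "ColocalizationRecord",
    "ColocalizationSummary",
    "select_edu_positive",
    "segment_fixed_foci",
    "intensity_in_mask",
    "count_b_foci_per_a_focus",
    "colocalize",
]


@dataclass(frozen=True)
class ColocalizationRecord:
    """One channel-A focus with its nested channel-B content."""

    cell_id: int
    a_label: int
    mean_b_intensity: float
    n_b_foci: int


@dataclass
class ColocalizationSummary:
    """Pooled nested-count categories over a set of A foci."""

    records: list[ColocalizationRecord]

    @property
    def n_a_foci(self) -> int:
        return len(self.records)

    def category_fractions(self) -> dict[str, float]:
        """Fractions of A foci with 0, 1 or >1 nested B foci (sum to 1)."""
        n = len(self.records)
        if n == 0:
            return {"0": math.nan, "1": math.nan, ">1": math.nan}
        counts = np.array([r.n_b_foci for r in self.records])
        return {
            "0": float(np.mean(counts == 0)),
            "1": float(np.mean(counts == 1)),
            ">1": float(np.mean(counts > 1)),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": r.cell_id,
                    "a_label": r.a_label,
                    "mean_b_intensity": r.mean_b_intensity,
                    "n_b_foci": r.n_b_foci,
                }
                for r in self.records
            ],
            columns=["cell_id", "a_label", "mean_b_intensity", "n_b_foci"],
        )


def select_edu_positive(
    edu_image: np.ndarray,
    nucleus_labels: np.ndarray,
    fallback_cutoff: float | None = None,
) -> tuple[list[int], dict[int, float]]:
    """Select S-phase nuclei by automatic threshold on per-nucleus EdU means.

    Returns ``(selected_ids, per_nucleus_mean)``. With a single nucleus or
    indistinguishable means the automatic (Otsu) threshold is undefined; the
    configured ``fallback_cutoff`` is used instead, or — with a warning — all
    nuclei are retained when no cutoff is given.
    """
    edu_image = np.asarray(edu_image, dtype=float)
    ids = [int(i) for i in np.unique(nucleus_labels) if i > 0]
    if not ids:
        return [], {}
    means = {
        i: float(ndi.mean(edu_image, labels=nucleus_labels, index=i)) for i in ids
    }
    vals = np.array([means[i] for i in ids])
    # a spread small relative to the level means one population, not two:
    # Otsu would split it arbitrarily
    degenerate = len(ids) < 2 or np.ptp(vals) < 0.25 * abs(float(np.median(vals)))
    if degenerate:
        if fallback_cutoff is not None:
            return [i for i in ids if means[i] >= fallback_cutoff], means
        warnings.warn(
            "EdU auto-threshold undefined (single nucleus or indistinguishable "
            "means); retaining all nuclei"
        )
        return ids, means
    th = filters.threshold_otsu(vals)
    return [i for i in ids if means[i] > th], means


def segment_fixed_foci(
    channel: np.ndarray,
    nucleus_labels: np.ndarray,
    min_area: int = 4,
    guard_sds: float = 3.0,
    min_peak_distance: int = 2,
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Segment foci per nucleus by automatic threshold plus watershed.

    Each nucleus gets its own Otsu threshold over its pixels, floored at
    ``mean + guard_sds·SD`` of the nuclear intensity so that nuclei without
    foci (where Otsu would cut into background noise) yield no labels.
    Returns a label map global over the whole image.
    """
    channel = np.asarray(channel, dtype=float)
    nucleus_labels = np.asarray(nucleus_labels)
    out = np.zeros(channel.shape, dtype=np.int32)
    offset = 0
    slices = ndi.find_objects(nucleus_labels)
    for nid, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        # work on the nucleus bounding box (padded) to keep this O(nucleus)
        pad = 4
        sl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, channel.shape)
        )
        crop = channel[sl]
        mask = nucleus_labels[sl] == nid
        vals = crop[mask]
        if vals.size < 2 or np.ptp(vals) == 0:
            continue
        th = float(filters.threshold_otsu(vals))
        guard = float(vals.mean() + guard_sds * vals.std(ddof=1))
        th = max(th, guard)
        labels = segment_foci(
            crop,
            threshold=th,
            upper_threshold=np.inf,
            smoothing_sigma=smoothing_sigma,
            min_area=min_area,
            mask=mask,
            min_peak_distance=min_peak_distance,
        )
        hit = labels > 0
        out[sl][hit] = labels[hit] + offset
        offset = int(out.max())
    return out


def intensity_in_mask(a_focus_labels: np.ndarray, b_channel: np.ndarray) -> dict[int, float]:
    """Mean B-channel intensity inside each A-focus mask."""
    b_channel = np.asarray(b_channel, dtype=float)
    ids = [int(i) for i in np.unique(a_focus_labels) if i > 0]
    return {
        i: float(ndi.mean(b_channel, labels=a_focus_labels, index=i)) for i in ids
    }


def count_b_foci_per_a_focus(
    a_focus_labels: np.ndarray,
    b_foci: Sequence[Focus],
    pixel_size: float,
) -> tuple[dict[int, int], dict[str, float]]:
    """Assign each B focus to the A focus containing its center of mass.

    A B focus whose COM lies in no A mask stays unassigned. Returns
    ``(per_a_counts, category_fractions)`` where fractions over the
    categories {0, 1, >1} are relative to all A foci and sum to 1.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    a_ids = [int(i) for i in np.unique(a_focus_labels) if i > 0]
    counts = {i: 0 for i in a_ids}
    h, w = a_focus_labels.shape
    for bf in b_foci:
        col = int(round(bf.com[0] / pixel_size))
        row = int(round(bf.com[1] / pixel_size))
        if 0 <= row < h and 0 <= col < w:
            lab = int(a_focus_labels[row, col])
            if lab > 0:
                counts[lab] += 1
    n = len(a_ids)
    if n == 0:
        fractions = {"0": math.nan, "1": math.nan, ">1": math.nan}
    else:
        arr = np.array(list(counts.values()))
        fractions = {
            "0": float(np.mean(arr == 0)),
            "1": float(np.mean(arr == 1)),
            ">1": float(np.mean(arr > 1)),
        }
    return counts, fractions


def colocalize(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    nucleus_labels: np.ndarray,
    pixel_size: float,
    selected_nuclei: Sequence[int] | None = None,
    min_area: int = 4,
) -> ColocalizationSummary:
    """Full two-channel quantification over (optionally selected) nuclei.

    Segments A and B foci per nucleus, measures mean B intensity within each
    A mask and counts nested B foci per A focus by COM containment.
    """
    summary = ColocalizationSummary(records=[])
    nucleus_labels = np.asarray(nucleus_labels)
    if selected_nuclei is not None:
        nucleus_labels = np.where(
            np.isin(nucleus_labels, list(selected_nuclei)), nucleus_labels, 0
        )
    a_labels = segment_fixed_foci(channel_a, nucleus_labels, min_area=min_area)
    b_labels = segment_fixed_foci(channel_b, nucleus_labels, min_area=min_area)
    b_foci = measure_foci(b_labels, channel_b, pixel_size)
    b_means = intensity_in_mask(a_labels, channel_b)
    counts, _ = count_b_foci_per_a_focus(a_labels, b_foci, pixel_size)
    a_ids = sorted(counts)
    cells = (
        ndi.maximum(nucleus_labels, labels=a_labels, index=a_ids) if a_ids else []
    )
    for a_id, cell in zip(a_ids, cells):
        summary.records.append(
            ColocalizationRecord(
                cell_id=int(cell),
                a_label=a_id,
                mean_b_intensity=b_means[a_id],
                n_b_foci=counts[a_id],
            )
        )
    return summary
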