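"""Gap-free focus tracking by nearest-neighbor center-of-mass linking.

Foci in consecutive frames are linked when the Euclidean distance between
their centers of mass is below a cutoff (default 0.7 µm). Links are assigned
greedily by ascending distance so each focus continues at most one track;
additional candidates within range are recorded as split (one-to-many) or
merge (many-to-one) events. Tracks are maximal chains of links, are not
allowed to contain gaps, may start or end at any frame, and have duration

    duration = (number of linked foci - 1) * frame_interval

so a focus present in all 51 frames of a 20-min-interval acquisition yields a
1000-min track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .segmentation import Focus

__all__ = [
    "LinkSet",
    "FocusTrack",
    "DurationBins",
    "CountCorrelation",
    "link_frames",
    "build_tracks",
    "track_duration",
    "bin_tracks_by_duration",
    "foci_per_frame",
    "correlate_counts",
]


@dataclass
class LinkSet:
    """Links and split/merge events between one pair of consecutive frames.

    ``links`` holds ``(label_t, label_t1, distance_um)`` for the assigned
    one-to-one continuations; ``splits`` records ``(label_t, candidates_t1)``
    for foci with two or more in-range candidates in the next frame, and
    ``merges`` records ``(label_t1, candidates_t)`` symmetrically.
    """

    frame: int
    links: list[tuple[int, int, float]] = field(default_factory=list)
    splits: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    merges: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)


@dataclass
class FocusTrack:
    """An ordered, gap-free sequence of foci in consecutive frames."""

    track_id: int
    foci: list[Focus]
    frame_interval: float
    split_from: int | None = None
    merged_into: int | None = None

    @property
    def start_frame(self) -> int:
        return self.foci[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.foci[-1].frame_index

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    @property
    def duration(self) -> float:
        """Track duration in min: (n foci − 1) × frame interval."""
        return (len(self.foci) - 1) * self.frame_interval

    @property
    def positions(self) -> np.ndarray:
        """COM positions, shape (n_foci, 2), µm."""
        return np.array([f.com for f in self.foci], dtype=float)


def link_frames(
    foci_t: Sequence[Focus],
    foci_t1: Sequence[Focus],
    max_link_distance: float = 0.7,
    inclusive: bool = False,
    frame: int | None = None,
) -> LinkSet:
    """Link foci between two consecutive frames by COM distance.

    Candidate pairs are those closer than ``max_link_distance`` (strictly, by
    default; ``inclusive=True`` accepts equality). Assignment is greedy by
    ascending distance, ties broken by ascending ``(label_t, label_t1)``, so
    each focus joins at most one continuing link. A focus with two or more
    candidates in the next frame records a split event; two or more foci
    sharing one candidate record a merge event.
    """
    if max_link_distance <= 0:
        raise ValueError("max_link_distance must be positive")
    if frame is None:
        frame = foci_t[0].frame_index if foci_t else 0
    ls = LinkSet(frame=frame)
    if not foci_t or not foci_t1:
        return ls

    candidates: list[tuple[float, int, int]] = []
    for a in foci_t:
        for b in foci_t1:
            d = math.hypot(a.com[0] - b.com[0], a.com[1] - b.com[1])
            if d < max_link_distance or (inclusive and d == max_link_distance):
                candidates.append((d, a.label, b.label))

    cand_fwd: dict[int, list[int]] = {}
    cand_bwd: dict[int, list[int]] = {}
    for _, la, lb in candidates:
        cand_fwd.setdefault(la, []).append(lb)
        cand_bwd.setdefault(lb, []).append(la)

    used_t: set[int] = set()
    used_t1: set[int] = set()
    for d, la, lb in sorted(candidates):
        if la in used_t or lb in used_t1:
            continue
        used_t.add(la)
        used_t1.add(lb)
        ls.links.append((la, lb, d))

    ls.splits = [
        (la, tuple(sorted(lbs))) for la, lbs in sorted(cand_fwd.items()) if len(lbs) >= 2
    ]
    ls.merges = [
        (lb, tuple(sorted(las))) for lb, las in sorted(cand_bwd.items()) if len(las) >= 2
    ]
    return ls


def build_tracks(
    foci_by_frame: Mapping[int, Sequence[Focus]],
    link_sets: Sequence[LinkSet],
    frame_interval: float = 20.0,
) -> list[FocusTrack]:
    """Assemble maximal gap-free chains of links into tracks.

    Every focus belongs to exactly one track; unlinked foci form single-focus
    tracks of duration 0. Split continuations open new tracks annotated with
    their parent track, and tracks that vanish into a merge are annotated with
    the surviving track.
    """
    frames = sorted(foci_by_frame)
    if frames and frames != list(range(frames[0], frames[-1] + 1)):
        raise ValueError("foci_by_frame must cover consecutive frame indices")
    by_frame_links = {ls.frame: ls for ls in link_sets}
    for ls in link_sets:
        if ls.frame not in foci_by_frame or (ls.frame + 1) not in foci_by_frame:
            if ls.links or ls.splits or ls.merges:
                raise ValueError(f"link set for frame pair ({ls.frame}, {ls.frame + 1}) "
                                 "does not match the provided frames")

    next_map: dict[tuple[int, int], tuple[int, int]] = {}
    prev_map: dict[tuple[int, int], tuple[int, int]] = {}
    for ls in link_sets:
        for la, lb, _ in ls.links:
            next_map[(ls.frame, la)] = (ls.frame + 1, lb)
            prev_map[(ls.frame + 1, lb)] = (ls.frame, la)

    focus_index: dict[tuple[int, int], Focus] = {
        (t, f.label): f for t in frames for f in foci_by_frame[t]
    }

    tracks: list[FocusTrack] = []
    membership: dict[tuple[int, int], int] = {}
    for t in frames:
        for f in sorted(foci_by_frame[t], key=lambda f: f.label):
            key = (t, f.label)
            if key in prev_map:
                continue  # continuation, not a track start
            chain = [focus_index[key]]
            cur = key
            while cur in next_map:
                cur = next_map[cur]
                chain.append(focus_index[cur])
            tid = len(tracks)
            tracks.append(FocusTrack(track_id=tid, foci=chain, frame_interval=frame_interval))
            for focus in chain:
                membership[(focus.frame_index, focus.label)] = tid

    # annotate split/merge bookkeeping on the affected tracks
    for ls in link_sets:
        for la, cands in ls.splits:
            parent = membership.get((ls.frame, la))
            assigned = next_map.get((ls.frame, la))
            for lb in cands:
                child_key = (ls.frame + 1, lb)
                if child_key == assigned or parent is None:
                    continue
                child = membership.get(child_key)
                if child is not None and tracks[child].start_frame == ls.frame + 1:
                    tracks[child].split_from = parent
        for lb, cands in ls.merges:
            target = membership.get((ls.frame + 1, lb))
            assigned = prev_map.get((ls.frame + 1, lb))
            for la in cands:
                src_key = (ls.frame, la)
                if src_key == assigned or target is None:
                    continue
                src = membership.get(src_key)
                if src is not None and tracks[src].end_frame == ls.frame:
                    tracks[src].merged_into = target
    return tracks


def track_duration(track: FocusTrack | Sequence[Focus], frame_interval: float) -> float:
    """Duration in min: (number of linked foci − 1) × frame interval."""
    n = track.n_foci if isinstance(track, FocusTrack) else len(track)
    if n == 0:
        raise ValueError("empty track has no duration")
    return (n - 1) * frame_interval


@dataclass(frozen=True)
class DurationBins:
    """Disjoint closed duration groups (min) plus an overflow group.

    The default groups are 20–80, 100–160, 180–240, 260–320 and 340–400 min;
    durations above the last edge fall into the overflow group, and
    single-frame (duration 0) tracks are kept apart from the groups.
    """

    groups: tuple[tuple[float, float], ...] = (
        (20.0, 80.0),
        (100.0, 160.0),
        (180.0, 240.0),
        (260.0, 320.0),
        (340.0, 400.0),
    )

    def labels(self) -> list[str]:
        return [f"{int(lo)}-{int(hi)}" for lo, hi in self.groups] + ["overflow"]

    def assign(self, duration: float) -> str | None:
        """Group label for a duration; ``None`` for duration-0 tracks."""
        if duration < 0:
            raise ValueError("duration must be nonnegative")
        if duration == 0:
            return None
        his = [hi for _, hi in self.groups]
        idx = int(np.searchsorted(his, duration, side="left"))
        if idx >= len(self.groups):
            return "overflow"
        lo, hi = self.groups[idx]
        return f"{int(lo)}-{int(hi)}"


def bin_tracks_by_duration(
    tracks: Iterable[FocusTrack],
    bins: DurationBins | None = None,
) -> tuple[dict[str, list[FocusTrack]], list[FocusTrack]]:
    """Group tracks by duration; returns (groups, duration-zero tracks)."""
    bins = bins or DurationBins()
    groups: dict[str, list[FocusTrack]] = {lab: [] for lab in bins.labels()}
    zeros: list[FocusTrack] = []
    for tr in tracks:
        lab = bins.assign(tr.duration)
        if lab is None:
            zeros.append(tr)
        else:
            groups[lab].append(tr)
    return groups, zeros


def foci_per_frame(
    foci_by_nucleus: Mapping[int, Mapping[int, Sequence[Focus]]],
    n_frames: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw per-frame focus counts per nucleus, with a mean ± SEM summary.

    ``foci_by_nucleus[nucleus][frame]`` lists the segmented foci of one
    nucleus in one frame (tracking-independent). Returns ``(counts, summary)``
    where ``counts`` is frames × nuclei and ``summary`` has columns
    ``mean``/``sem``/``n_nuclei``.
    """
    if n_frames is None:
        n_frames = 1 + max(
            (t for per in foci_by_nucleus.values() for t in per), default=-1
        )
    frames = range(n_frames)
    counts = pd.DataFrame(
        {
            nid: [len(per.get(t, ())) for t in frames]
            for nid, per in sorted(foci_by_nucleus.items())
        },
        index=pd.Index(frames, name="frame"),
    )
    if counts.empty:
        summary = pd.DataFrame(columns=["mean", "sem", "n_nuclei"])
    else:
        summary = pd.DataFrame(
            {
                "mean": counts.mean(axis=1),
                "sem": counts.sem(axis=1, ddof=1) if counts.shape[1] > 1 else 0.0,
                "n_nuclei": counts.shape[1],
            }
        )
    return counts, summary


@dataclass(frozen=True)
class CountCorrelation:
    """Least-squares linear relation between two paired count series."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def correlate_counts(
    manual: Sequence[float], automated: Sequence[float]
) -> CountCorrelation:
    """Linear fit and R² between manual and automated focus counts.

    With zero variance in either input the correlation is undefined and the
    R² is reported as NaN.
    """
    x = np.asarray(manual, dtype=float)
    y = np.asarray(automated, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired counts")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CountCorrelation(math.nan, math.nan, math.nan, x.size)
    res = sstats.linregress(x, y)
    return CountCorrelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=x.size,
    )
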