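"""Single-cell tracking, reporter traces and infection-fate classification.

Cells are tracked through a label-mask sequence by greedy frame-to-frame
overlap matching (IoU).  For each track the mean mCherry intensity inside
the cell mask is extracted per frame and background-subtracted, giving a
reporter trace; expression onset is the first frame where the trace exceeds
a noise-scaled threshold persistently.  Each sufficiently long track is then
classified: *expressed_lysed* (reporter turned on and the cell disappeared
before the end of the movie — productive infection ending in lysis),
*outgrowth* (no reporter but sustained growth — a resistant infected cell),
*uninfected*, or *censored* when the evidence is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import BackgroundModel

__all__ = [
    "Track",
    "FluorescenceTrace",
    "track_cells",
    "trace_fluorescence",
    "detect_onset",
    "classify_fate",
    "fate_confusion",
]

MIN_TRACK_FRAMES = 5


@dataclass
class Track:
    """One tracked cell: per-frame labels over a contiguous frame range."""

    track_id: int
    start: int
    labels: list[int] = field(default_factory=list)  # label per frame from start
    fate: str | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.labels) - 1

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def label_at(self, frame: int) -> int | None:
        if self.start <= frame <= self.end:
            return self.labels[frame - self.start]
        return None


@dataclass
class FluorescenceTrace:
    track_id: int
    start: int
    values: np.ndarray            # background-subtracted mean per frame
    onset_frame: int | None = None


def _label_areas(mask: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(mask[mask > 0], return_counts=True)
    return dict(zip(ids.tolist(), counts.tolist()))


def _overlaps(prev: np.ndarray, curr: np.ndarray):
    """Pairwise overlap areas between labels of consecutive masks."""
    both = (prev > 0) & (curr > 0)
    if not both.any():
        return {}
    pairs = np.stack([prev[both], curr[both]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(uniq.T, counts)}


def track_cells(masks: list[np.ndarray], iou_min: float = 0.5) -> list[Track]:
    """Greedy frame-to-frame tracking of labelled cells.

    Candidate links between consecutive frames are ranked by IoU; each label
    is used at most once per frame, so at a division the parent identity
    follows the daughter with the larger overlap (higher IoU) and the other
    daughter starts a new track.  A label with no admissible link ends its
    track; unmatched labels in the new frame start tracks.
    """
    if len(masks) == 0:
        raise ValueError("empty mask sequence")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError("all masks must share one shape")
    tracks: list[Track] = []
    active: dict[int, Track] = {}     # current-frame label -> track
    for lab in _label_areas(masks[0]):
        tr = Track(track_id=len(tracks) + 1, start=0, labels=[lab])
        tracks.append(tr)
        active[lab] = tr
    for f in range(1, len(masks)):
        prev, curr = masks[f - 1], masks[f]
        areas_p = _label_areas(prev)
        areas_c = _label_areas(curr)
        cand = []
        for (a, b), inter in _overlaps(prev, curr).items():
            iou = inter / (areas_p[a] + areas_c[b] - inter)
            if iou >= iou_min:
                cand.append((iou, a, b))
        cand.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_prev: set[int] = set()
        used_curr: set[int] = set()
        new_active: dict[int, Track] = {}
        for iou, a, b in cand:
            if a in used_prev or b in used_curr or a not in active:
                continue
            used_prev.add(a)
            used_curr.add(b)
            tr = active[a]
            tr.labels.append(b)
            new_active[b] = tr
        for lab in areas_c:
            if lab not in used_curr:
                tr = Track(track_id=len(tracks) + 1, start=f, labels=[lab])
                tracks.append(tr)
                new_active[lab] = tr
        active = new_active
    return tracks


def trace_fluorescence(frames: list[np.ndarray], masks: list[np.ndarray],
                       tracks: list[Track],
                       backgrounds: list[BackgroundModel] | list[float],
                       ) -> list[FluorescenceTrace]:
    """Background-subtracted mean reporter intensity per frame per track."""
    if len(frames) != len(masks):
        raise ValueError("frames and masks must align")
    bg_means = [b.mean if isinstance(b, BackgroundModel) else float(b)
                for b in backgrounds]
    traces = []
    for tr in tracks:
        vals = []
        for f in range(tr.start, tr.end + 1):
            lab = tr.label_at(f)
            sel = masks[f] == lab
            if not sel.any():
                raise ValueError(f"track {tr.track_id}: label {lab} missing "
                                 f"in frame {f}")
            vals.append(float(frames[f][sel].mean()) - bg_means[f])
        traces.append(FluorescenceTrace(track_id=tr.track_id, start=tr.start,
                                        values=np.asarray(vals)))
    return traces


def population_curves(traces: list[FluorescenceTrace], n_frames: int,
                      groups: dict[int, str] | None = None) -> pd.DataFrame:
    """Across-cell mean and sample SD of traces per frame (optionally grouped)."""
    rows = []
    def _accumulate(label, sel):
        for f in range(n_frames):
            vals = [t.values[f - t.start] for t in sel
                    if t.start <= f < t.start + t.values.size]
            if vals:
                v = np.asarray(vals)
                rows.append({"group": label, "frame": f, "mean": v.mean(),
                             "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                             "n": v.size})
    if groups is None:
        _accumulate("all", traces)
    else:
        for g in sorted(set(groups.values())):
            _accumulate(g, [t for t in traces if groups.get(t.track_id) == g])
    return pd.DataFrame(rows, columns=["group", "frame", "mean", "sd", "n"])


def detect_onset(trace: np.ndarray | FluorescenceTrace, threshold: float,
                 persistence: int = 2) -> int | None:
    """First frame index where the trace exceeds ``threshold`` persistently.

    Requires ``persistence`` consecutive above-threshold frames; the index
    is relative to the trace start.  Returns None when expression never
    turns on.
    """
    vals = trace.values if isinstance(trace, FluorescenceTrace) else np.asarray(trace, float)
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if vals.size < persistence:
        raise ValueError("trace shorter than the persistence window")
    above = vals > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def classify_fate(track: Track, onset: int | None, area_start: float,
                  area_end: float, n_frames_total: int,
                  infected: bool | None = None,
                  min_frames: int = MIN_TRACK_FRAMES) -> str:
    """Infection-fate label for one track.

    ``infected`` is an optional ground-truth (or external) flag used to
    separate resistant outgrowth from plain uninfected growth; without it
    the call falls back on growth alone.
    """
    if track.n_frames < min_frames:
        return "censored"
    ends_early = track.end < n_frames_total - 1
    grew = area_end >= 2.0 * area_start
    if onset is not None and ends_early:
        return "expressed_lysed"
    if onset is None:
        if infected is True:
            return "outgrowth" if grew else "censored"
        if infected is False:
            return "uninfected"
        return "outgrowth" if grew else "uninfected"
    return "censored"


def fate_confusion(true_fates: dict[int, str], called_fates: dict[int, str]
                   ) -> pd.DataFrame:
    """Confusion matrix of ground-truth vs called fates over shared ids."""
    ids = sorted(set(true_fates) & set(called_fates))
    truth = pd.Categorical([true_fates[i] for i in ids])
    call = pd.Categorical([called_fates[i] for i in ids])
    return pd.crosstab(pd.Series(truth, name="truth"),
                       pd.Series(call, name="called"), dropna=False)
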