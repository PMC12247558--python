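"""Time-series preparation: volume selection, reordering, hemodynamic lag.

Naturalistic-viewing runs interleave the stimuli of interest (trick
volumes) with mock lead-ins, fixations and rating periods, in a
pseudo-randomised order that differs between subjects. Before intersubject
correlation the series are concatenated: volumes of no interest are
dropped, the remaining trick volumes are re-grouped into a canonical
stimulus order shared by all subjects, and the whole selection is shifted
forward by an integer number of repetition times (TRs) to account for the
hemodynamic delay. The lag itself can be chosen by intersubject pattern
correlation (ISPC): time-point-wise spatial correlation of masked voxel
patterns, averaged over time and subject pairs, maximised over candidate
lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import LabeledTimeSeries

__all__ = [
    "ConcatenationPlan",
    "build_plan",
    "apply_plan",
    "select_lag",
    "group_gm_mask",
    "events_to_labels",
    "read_labeled_series",
]


@dataclass(frozen=True)
class ConcatenationPlan:
    """Per-subject source indices realising a canonical concatenation."""

    canonical_order: tuple  # stimulus ids, canonical order
    lag_tr: int
    retained_index: dict  # subject_id -> np.ndarray of source t indices

    @property
    def n_volumes(self) -> int:
        return len(next(iter(self.retained_index.values())))


def _trick_indices(labels: pd.DataFrame) -> dict:
    """Map stimulus id -> array of trick-volume time indices."""
    is_trick = labels["volume_class"] == "trick"
    out = {}
    for sid, grp in labels[is_trick].groupby("stimulus_id"):
        out[sid] = grp.index.to_numpy()
    return out


def build_plan(
    labels_by_subject: dict,
    canonical_order=None,
    lag_tr: int = 0,
) -> ConcatenationPlan:
    """Build the concatenation plan from per-subject volume labels.

    Retains trick-class volumes only, shifted forward by ``lag_tr`` (the
    ``lag`` volumes following each trick window stand in for its first
    ``lag``, capturing the delayed response), grouped by stimulus in
    ``canonical_order`` (default: sorted stimulus ids). Errors if the
    per-stimulus trick-volume counts differ across subjects or the shift
    runs past the end of an acquisition.
    """
    if lag_tr < 0:
        raise ValueError("lag_tr must be non-negative")
    per_subject = {sid: _trick_indices(lab) for sid, lab in labels_by_subject.items()}
    subjects = list(per_subject)
    stim_sets = [set(d) for d in per_subject.values()]
    if any(s != stim_sets[0] for s in stim_sets):
        raise ValueError("subjects saw different stimulus sets")
    if canonical_order is None:
        canonical_order = tuple(sorted(stim_sets[0]))
    counts = {stim: len(per_subject[subjects[0]][stim]) for stim in canonical_order}
    retained = {}
    for sid, tricks in per_subject.items():
        n_vol = len(labels_by_subject[sid])
        idx = []
        for stim in canonical_order:
            t = tricks[stim]
            if len(t) != counts[stim]:
                raise ValueError(
                    f"trick volume count mismatch for stimulus {stim!r}: "
                    f"{len(t)} in subject {sid!r} vs {counts[stim]}"
                )
            shifted = t + lag_tr
            if shifted[-1] >= n_vol:
                raise ValueError(
                    f"lag {lag_tr} pushes stimulus {stim!r} past the end of "
                    f"subject {sid!r}'s acquisition"
                )
            idx.append(shifted)
        retained[sid] = np.concatenate(idx)
    lengths = {len(v) for v in retained.values()}
    assert len(lengths) == 1
    return ConcatenationPlan(tuple(canonical_order), int(lag_tr), retained)


def apply_plan(series: LabeledTimeSeries, plan: ConcatenationPlan) -> np.ndarray:
    """Concatenate one subject's series per the plan (copy, no interpolation)."""
    if series.subject_id not in plan.retained_index:
        raise KeyError(f"plan has no entry for subject {series.subject_id!r}")
    idx = plan.retained_index[series.subject_id]
    if idx.max() >= series.n_volumes:
        raise IndexError("plan index out of range for this series")
    return series.data[..., idx]


def select_lag(
    series_list: list[LabeledTimeSeries],
    mask: np.ndarray,
    candidate_lags=range(0, 7),
    canonical_order=None,
):
    """Choose the hemodynamic lag by intersubject pattern correlation.

    For each candidate lag the series are concatenated and, at every time
    point, the spatial Pearson correlation of masked voxel patterns is
    computed for every subject pair; the score is the average over time and
    pairs. Returns ``(best_lag, table)`` with the full lag -> score table.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 subjects")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels = {s.subject_id: s.labels for s in series_list}
    scores = {}
    for lag in candidate_lags:
        plan = build_plan(labels, canonical_order, lag_tr=int(lag))
        X = np.stack([apply_plan(s, plan)[mask, :] for s in series_list])  # (N, V, T)
        X = X - X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        np.divide(X, sd, out=X, where=sd > 0)
        V = mask.sum()
        N = len(series_list)
        # mean over pairs of corr_t = sum_v x_i x_j / V, then mean over t
        total = np.einsum("ivt,jvt->ij", X, X) / (V * X.shape[2])
        iu = np.triu_indices(N, k=1)
        scores[int(lag)] = float(total[iu].mean())
    table = pd.DataFrame(
        {"lag_tr": list(scores), "ispc": list(scores.values())}
    ).sort_values("lag_tr", ignore_index=True)
    best = int(table.loc[table["ispc"].idxmax(), "lag_tr"])
    return best, table


def group_gm_mask(subject_masks: list[np.ndarray], threshold: float = 0.5) -> np.ndarray:
    """Group grey-matter mask: voxel included iff GM in >= ``threshold`` of subjects."""
    masks = [np.asarray(m, dtype=float) for m in subject_masks]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("subject masks must share one grid")
    return np.mean(masks, axis=0) >= threshold


def events_to_labels(events: pd.DataFrame, n_volumes: int, tr_seconds: float) -> pd.DataFrame:
    """Expand a BIDS-style events table to per-volume labels.

    Onsets and durations (seconds) must be TR-aligned. Volumes not covered
    by any event are labelled ``rest``.
    """
    stim = np.full(n_volumes, -1, dtype=object)
    klass = np.full(n_volumes, "rest", dtype=object)
    for _, row in events.iterrows():
        on = row["onset"] / tr_seconds
        dur = row["duration"] / tr_seconds
        if abs(on - round(on)) > 1e-6 or abs(dur - round(dur)) > 1e-6:
            raise ValueError(f"event not TR-aligned: onset={row['onset']} duration={row['duration']}")
        a, b = int(round(on)), int(round(on + dur))
        klass[a:b] = row["trial_type"]
        sid = row.get("stimulus_id", "n/a")
        if isinstance(sid, str) and sid not in ("n/a", ""):
            stim[a:b] = int(sid.split("-")[-1]) - 1
        elif not isinstance(sid, str) and not pd.isna(sid):
            stim[a:b] = int(sid)
    return pd.DataFrame(
        {"stimulus_id": stim.astype(int), "volume_class": klass, "censor": 0}
    )


def read_labeled_series(nifti_path, events_path, subject_id: str, group: str) -> LabeledTimeSeries:
    """Load a 4D NIfTI plus its events TSV into a labelled series."""
    import nibabel as nib

    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    events = pd.read_csv(events_path, sep="\t")
    labels = events_to_labels(events, data.shape[-1], tr)
    return LabeledTimeSeries(
        data=data, tr_seconds=tr, labels=labels, subject_id=subject_id, group=group
    )
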