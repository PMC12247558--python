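"""Synthetic behavioural and fMRI data with known ground truth.

Two generators mirror the study design they are meant to exercise: 36 video
stimuli shown to N subjects in pseudo-randomised per-subject orders, a
between-subject incentive manipulation with two equal groups, 1-7 curiosity
ratings, recognition (with 1-6 confidence) and cued-recall outcomes drawn
from a logistic mixed model; and, for the imaging arm, per-subject 4D time
series composed of a stimulus-locked signal shared across subjects, a
subject-idiosyncratic component, and white noise, assembled in each
subject's presentation order with the shared component delayed by an
integer hemodynamic lag.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BehaviourSimConfig",
    "FmriSimConfig",
    "LabeledTimeSeries",
    "generate_behaviour",
    "generate_fmri",
    "default_trick_volumes",
    "write_labeled_series",
    "write_trial_table",
]

#: volume classes used in per-volume labels
VOLUME_CLASSES = ("mock", "trick", "fixation", "rating", "rest")

# default confidence distributions over 1..6, conditional on correctness;
# chosen to give a monotone confidence-accuracy association
_CONF_CORRECT = (0.02, 0.05, 0.08, 0.15, 0.30, 0.40)
_CONF_INCORRECT = (0.25, 0.25, 0.20, 0.15, 0.10, 0.05)


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class BehaviourSimConfig:
    """Generative settings for the behavioural trial tables.

    The logistic model for a binary memory outcome of subject *i* on
    stimulus *j* is

        logit P(y_ij = 1) = intercept + (beta_curiosity + s_i) * c_ij
                            + beta_incentive * g_i
                            + beta_interaction * c_ij * g_i + u_i + v_j

    with ``c_ij`` the subject-mean-centred curiosity rating, ``g_i`` the
    effect-coded group (-1 control, +1 incentive), ``u_i ~ N(0,
    sd_subject_intercept^2)``, ``v_j ~ N(0, sd_stimulus_intercept^2)`` and
    ``s_i ~ N(0, sd_curiosity_slope^2)``. Defaults reproduce the scale of
    the behavioural effects the pipeline is designed around (log-odds per
    rating unit ~0.08, incentive ~0.15, no interaction).
    """

    n_subjects: int = 50
    n_stimuli: int = 36
    beta_curiosity: float = 0.084
    beta_incentive: float = 0.155
    beta_interaction: float = 0.0
    intercept: float = 0.2
    intercept_recall: float = -0.6
    sd_subject_intercept: float = 1.0
    sd_stimulus_intercept: float = 0.8
    sd_curiosity_slope: float = 0.2
    # latent rating model: 4 + stimulus appeal + subject bias + noise,
    # rounded and clipped into 1..7
    sd_stimulus_appeal: float = 0.8
    sd_subject_rating_bias: float = 0.7
    sd_rating_noise: float = 1.2
    confidence_model: dict = field(
        default_factory=lambda: {1: _CONF_CORRECT, 0: _CONF_INCORRECT}
    )
    seed: int = 0

    def validate(self) -> None:
        sds = (
            self.sd_subject_intercept,
            self.sd_stimulus_intercept,
            self.sd_curiosity_slope,
            self.sd_stimulus_appeal,
            self.sd_subject_rating_bias,
            self.sd_rating_noise,
        )
        if any(s < 0 for s in sds):
            raise ConfigurationError("random-effect SDs must be non-negative")
        if self.n_subjects % 2:
            raise ConfigurationError("n_subjects must be even (two equal groups)")
        if self.n_subjects < 2 or self.n_stimuli < 1:
            raise ConfigurationError("need at least 2 subjects and 1 stimulus")
        for key in (0, 1):
            p = np.asarray(self.confidence_model[key], dtype=float)
            if p.shape != (6,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ConfigurationError(
                    "confidence_model must map correctness to a distribution over 1..6"
                )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def generate_behaviour(cfg: BehaviourSimConfig) -> pd.DataFrame:
    """Draw one trial table: one row per subject x stimulus.

    Returns a DataFrame with columns ``subject_id, stimulus_id,
    presentation_index, curiosity_raw, curiosity_centred,
    recognition_correct, confidence, recall_correct, incentive_code`` plus
    the ground-truth per-subject curiosity slope in ``true_subject_slope``
    (constant within subject; handy for recovery tests).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    S, M = cfg.n_subjects, cfg.n_stimuli

    group = np.where(np.arange(S) % 2 == 0, -1, 1)  # interleaved, balanced
    appeal = rng.normal(0.0, cfg.sd_stimulus_appeal, M)
    rating_bias = rng.normal(0.0, cfg.sd_subject_rating_bias, S)
    u = rng.normal(0.0, cfg.sd_subject_intercept, S)
    v = rng.normal(0.0, cfg.sd_stimulus_intercept, M)
    slope_dev = rng.normal(0.0, cfg.sd_curiosity_slope, S)

    latent = (
        4.0
        + rating_bias[:, None]
        + appeal[None, :]
        + rng.normal(0.0, cfg.sd_rating_noise, (S, M))
    )
    rating = np.clip(np.rint(latent), 1, 7).astype(int)
    centred = rating - rating.mean(axis=1, keepdims=True)

    def _draw(intercept: float) -> np.ndarray:
        eta = (
            intercept
            + (cfg.beta_curiosity + slope_dev[:, None]) * centred
            + cfg.beta_incentive * group[:, None]
            + cfg.beta_interaction * centred * group[:, None]
            + u[:, None]
            + v[None, :]
        )
        return (rng.random((S, M)) < _sigmoid(eta)).astype(int)

    recog = _draw(cfg.intercept)
    recall = _draw(cfg.intercept_recall)

    p_conf = np.array(
        [cfg.confidence_model[0], cfg.confidence_model[1]], dtype=float
    )
    cum = p_conf.cumsum(axis=1)
    confidence = 1 + (rng.random((S, M))[..., None] >= cum[recog]).sum(axis=-1)

    orders = np.array([rng.permutation(M) for _ in range(S)])
    pres_index = np.empty((S, M), dtype=int)
    for i in range(S):
        pres_index[i, orders[i]] = np.arange(1, M + 1)

    sub_idx = np.repeat(np.arange(S), M)
    stim_idx = np.tile(np.arange(M), S)
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in sub_idx],
            "stimulus_id": [f"stim-{j + 1:02d}" for j in stim_idx],
            "presentation_index": pres_index.ravel(),
            "curiosity_raw": rating.ravel(),
            "curiosity_centred": centred.ravel(),
            "recognition_correct": recog.ravel(),
            "confidence": confidence.ravel().astype(int),
            "recall_correct": recall.ravel(),
            "incentive_code": group[sub_idx],
            "true_subject_slope": (cfg.beta_curiosity + slope_dev)[sub_idx],
        }
    )
    return table


# ---------------------------------------------------------------------------
# fMRI simulator
# ---------------------------------------------------------------------------


def default_trick_volumes(n_stimuli: int) -> np.ndarray:
    """Per-stimulus trick volume counts, alternating 16/17.

    At 36 stimuli this sums to 594 retained volumes, the concatenated
    length the pipeline's defaults are sized for (videos of ~32-38 s at a
    2 s repetition time).
    """
    return np.where(np.arange(n_stimuli) % 2 == 0, 16, 17).astype(int)


@dataclass(frozen=True)
class FmriSimConfig:
    """Generative settings for the multi-subject labelled 4D series.

    Per voxel and time point, subject *i*'s signal inside a (lag-shifted)
    trick window of stimulus *j* is ``shared_j(t) + a_i * idio_i(t) +
    noise``; outside trick windows only idiosyncratic signal and noise are
    present. With ``a_i = 1`` the expected pairwise ISC is the variance
    ratio ``sd_shared^2 / (sd_shared^2 + sd_idiosyncratic^2 +
    sd_noise^2)``.

    ``annak_scores`` (per-subject scalars) modulate the idiosyncratic
    amplitude: with ``annak_direction='negative'`` high scorers get *more*
    idiosyncratic signal (low scorers are alike), with ``'positive'`` the
    mapping is inverted (high scorers are alike).
    """

    n_subjects: int = 10
    n_stimuli: int = 36
    volumes_per_stimulus: int | Sequence[int] | None = None
    mock_volumes: int = 3
    fixation_volumes: int = 3
    rating_volumes: int = 6
    voxel_grid: tuple[int, int, int] = (12, 12, 12)
    tr_seconds: float = 2.0
    sd_shared: float = 1.0
    sd_idiosyncratic: float = 1.0
    sd_noise: float = 1.0
    true_lag_tr: int = 4
    annak_scores: Sequence[float] | None = None
    annak_direction: str = "negative"
    trial_orders: Sequence[Sequence[int]] | None = None
    seed: int = 0

    def trick_volume_counts(self) -> np.ndarray:
        if self.volumes_per_stimulus is None:
            return default_trick_volumes(self.n_stimuli)
        v = np.atleast_1d(np.asarray(self.volumes_per_stimulus, dtype=int))
        if v.size == 1:
            v = np.full(self.n_stimuli, int(v[0]))
        if v.shape != (self.n_stimuli,) or (v < 1).any():
            raise ConfigurationError("volumes_per_stimulus must be positive, one per stimulus")
        return v

    def validate(self) -> None:
        if min(self.sd_shared, self.sd_idiosyncratic, self.sd_noise) < 0:
            raise ConfigurationError("signal SDs must be non-negative")
        if self.true_lag_tr < 0:
            raise ConfigurationError("true_lag_tr must be non-negative")
        if self.true_lag_tr > self.fixation_volumes + self.rating_volumes:
            raise ConfigurationError(
                "true_lag_tr exceeds the post-trick window; the delayed response "
                "would spill into the next trial"
            )
        if self.annak_direction not in ("negative", "positive"):
            raise ConfigurationError("annak_direction must be 'negative' or 'positive'")
        if self.annak_scores is not None and len(self.annak_scores) != self.n_subjects:
            raise ConfigurationError("annak_scores must have one value per subject")
        self.trick_volume_counts()
        if self.trial_orders is not None:
            if len(self.trial_orders) != self.n_subjects:
                raise ConfigurationError("trial_orders must have one order per subject")
            ref = np.arange(self.n_stimuli)
            for order in self.trial_orders:
                if not np.array_equal(np.sort(np.asarray(order)), ref):
                    raise ConfigurationError(
                        "each trial order must be a permutation of 0..n_stimuli-1"
                    )


@dataclass
class LabeledTimeSeries:
    """One subject's 4D series plus per-volume labels.

    ``labels`` has one row per volume with columns ``stimulus_id``
    (canonical 0-based stimulus index or -1 for unlabelled volumes),
    ``volume_class`` and ``censor``.
    """

    data: np.ndarray  # (x, y, z, t)
    tr_seconds: float
    labels: pd.DataFrame
    subject_id: str
    group: str  # control | incentive

    def __post_init__(self) -> None:
        if self.data.shape[-1] != len(self.labels):
            raise ValueError("labels length must equal the series' t extent")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def _idio_scale(cfg: FmriSimConfig) -> np.ndarray:
    if cfg.annak_scores is None:
        return np.ones(cfg.n_subjects)
    s = np.asarray(cfg.annak_scores, dtype=float)
    rng = s.max() - s.min()
    norm = np.zeros_like(s) if rng == 0 else (s - s.min()) / rng
    return norm if cfg.annak_direction == "negative" else 1.0 - norm


def generate_fmri(cfg: FmriSimConfig) -> list[LabeledTimeSeries]:
    """Simulate one labelled 4D series per subject.

    Trial layout per stimulus: ``mock_volumes`` mock volumes, the
    stimulus's trick volumes, then fixation and rating volumes. The shared
    stimulus-locked component is written ``true_lag_tr`` volumes after
    trick onset; idiosyncratic signal and noise cover the whole session.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    S, M = cfg.n_subjects, cfg.n_stimuli
    n_vox = int(np.prod(cfg.voxel_grid))
    trick = cfg.trick_volume_counts()
    trial_len = cfg.mock_volumes + trick + cfg.fixation_volumes + cfg.rating_volumes
    total = int(trial_len.sum())

    if cfg.trial_orders is None:
        orders = [rng.permutation(M) for _ in range(S)]
    else:
        orders = [np.asarray(o, dtype=int) for o in cfg.trial_orders]

    # shared stimulus-locked signal: one (n_vox, n_trick_j) block per stimulus
    shared = [rng.normal(0.0, cfg.sd_shared, (n_vox, int(k))) for k in trick]
    scale = _idio_scale(cfg)

    out: list[LabeledTimeSeries] = []
    for i in range(S):
        data = rng.normal(0.0, cfg.sd_noise, (n_vox, total))
        if cfg.sd_idiosyncratic > 0 and scale[i] > 0:
            data += scale[i] * rng.normal(0.0, cfg.sd_idiosyncratic, (n_vox, total))
        stim_id = np.full(total, -1, dtype=int)
        vol_class = np.empty(total, dtype=object)
        t = 0
        for j in orders[i]:
            k = int(trick[j])
            stim_id[t : t + cfg.mock_volumes + k] = j
            vol_class[t : t + cfg.mock_volumes] = "mock"
            t += cfg.mock_volumes
            vol_class[t : t + k] = "trick"
            start = t + cfg.true_lag_tr
            data[:, start : start + k] += shared[j]
            t += k
            vol_class[t : t + cfg.fixation_volumes] = "fixation"
            t += cfg.fixation_volumes
            vol_class[t : t + cfg.rating_volumes] = "rating"
            t += cfg.rating_volumes
        labels = pd.DataFrame(
            {
                "stimulus_id": stim_id,
                "volume_class": vol_class,
                "censor": np.zeros(total, dtype=int),
            }
        )
        out.append(
            LabeledTimeSeries(
                data=data.reshape(*cfg.voxel_grid, total).astype(np.float32),
                tr_seconds=cfg.tr_seconds,
                labels=labels,
                subject_id=f"sub-{i + 1:03d}",
                group="control" if i % 2 == 0 else "incentive",
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers (NIfTI + BIDS-style events / TSV)
# ---------------------------------------------------------------------------


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_labeled_series(series: LabeledTimeSeries, nifti_path, events_path) -> None:
    """Write a 4D NIfTI plus a BIDS-style events TSV (onset/duration in s)."""
    import nibabel as nib

    img = nib.Nifti1Image(series.data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr_seconds))
    nib.save(img, str(nifti_path))

    lab = series.labels
    rows = []
    start = 0
    for _, grp in lab.groupby(
        (lab["volume_class"].ne(lab["volume_class"].shift())
         | lab["stimulus_id"].ne(lab["stimulus_id"].shift())).cumsum()
    ):
        start = grp.index[0]
        sid = int(grp["stimulus_id"].iloc[0])
        rows.append(
            {
                "onset": start * series.tr_seconds,
                "duration": len(grp) * series.tr_seconds,
                "trial_type": grp["volume_class"].iloc[0],
                "stimulus_id": f"stim-{sid + 1:02d}" if sid >= 0 else "n/a",
            }
        )
    pd.DataFrame(rows).to_csv(events_path, sep="\t", index=False, float_format="%.10g")


def replace(cfg, **changes):
    """dataclasses.replace that works for both simulator configs."""
    return dataclasses.replace(cfg, **changes)
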