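"""Per-subject feature extraction: the eight-channel sample-entropy vector.

The pipeline per channel is: weight normalization -> standardization ->
sample entropy (m=2, r=0.25 by default). Weight normalization cannot change
the entropy (standardization absorbs any affine rescaling) but is kept so
intermediate series remain physically interpretable.

When a subject carries several trials of the same channel (e.g. two walking
passes) two policies are available: ``"average"`` computes one entropy per
trial and averages, ``"concatenate"`` joins the raw trials into one series
before preprocessing. Synthetic cohorts have exactly one trial per channel,
where the two policies coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import CHANNELS, FEATURE_NAMES, FeatureVector, GrfRecording, Subject
from .entropy import normalize_by_weight, sample_entropy, standardize
from .exceptions import MissingChannelError, ParameterError, UndefinedEntropyError

MULTI_TRIAL_MODES = ("average", "concatenate")


def normalize_recording(rec: GrfRecording, weight_kg: float) -> GrfRecording:
    """Return a copy of ``rec`` with force expressed in body-weight units."""
    return GrfRecording(
        subject_id=rec.subject_id,
        activity=rec.activity,
        foot=rec.foot,
        axis=rec.axis,
        series=normalize_by_weight(rec.series, weight_kg),
    )


def standardize_recording(rec: GrfRecording) -> GrfRecording:
    """Return a copy of ``rec`` with the series z-scored (population SD)."""
    return GrfRecording(
        subject_id=rec.subject_id,
        activity=rec.activity,
        foot=rec.foot,
        axis=rec.axis,
        series=standardize(rec.series),
    )


def _series_entropy(series, weight_kg, m, r, weight_normalize):
    s = np.asarray(series, dtype=float)
    if weight_normalize:
        s = normalize_by_weight(s, weight_kg)
    return sample_entropy(standardize(s), m=m, r=r)


def channel_entropy(
    subject: Subject,
    channel_name: str,
    m: int = 2,
    r: float = 0.25,
    weight_normalize: bool = True,
    multi_trial: str = "average",
) -> float:
    """Sample entropy of one of a subject's channels.

    Raises :class:`MissingChannelError` if the channel is absent and
    :class:`UndefinedEntropyError` if no template pairs match.
    """
    if multi_trial not in MULTI_TRIAL_MODES:
        raise ParameterError(f"multi_trial must be one of {MULTI_TRIAL_MODES}")
    recs = subject.recordings_for(channel_name)
    if not recs:
        raise MissingChannelError(channel_name, subject.subject_id)
    if len(recs) == 1:
        value = _series_entropy(
            recs[0].series, subject.weight_kg, m, r, weight_normalize
        )
    elif multi_trial == "concatenate":
        joined = np.concatenate([rec.series for rec in recs])
        value = _series_entropy(joined, subject.weight_kg, m, r, weight_normalize)
    else:
        per_trial = [
            _series_entropy(rec.series, subject.weight_kg, m, r, weight_normalize)
            for rec in recs
        ]
        value = float(np.mean(per_trial))
    if np.isnan(value):
        raise UndefinedEntropyError(channel_name, subject.subject_id)
    return value


def extract_features(
    subject: Subject,
    m: int = 2,
    r: float = 0.25,
    weight_normalize: bool = True,
    multi_trial: str = "average",
) -> FeatureVector:
    """The eight-channel entropy vector of a subject, in canonical order."""
    values = [
        channel_entropy(subject, ch.name, m, r, weight_normalize, multi_trial)
        for ch in CHANNELS
    ]
    return FeatureVector(subject_id=subject.subject_id, values=np.array(values))


def extract_feature_table(
    subjects: list[Subject],
    m: int = 2,
    r: float = 0.25,
    weight_normalize: bool = True,
    multi_trial: str = "average",
) -> pd.DataFrame:
    """Feature matrix for a cohort: subject_id, group, eight entropy columns."""
    rows = []
    for subject in subjects:
        fv = extract_features(subject, m, r, weight_normalize, multi_trial)
        rows.append({"subject_id": subject.subject_id, "group": subject.group,
                     **fv.as_dict()})
    return pd.DataFrame(rows, columns=["subject_id", "group", *FEATURE_NAMES])


class SampleEntropyFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer mapping Subjects to the 8-entropy matrix.

    ``fit`` is stateless (kept for pipeline compatibility); ``transform``
    accepts a sequence of :class:`~fallgrf.data.Subject` and returns an
    ``(n, 8)`` array in canonical channel order.
    """

    def __init__(self, m: int = 2, r: float = 0.25,
                 weight_normalize: bool = True, multi_trial: str = "average"):
        self.m = m
        self.r = r
        self.weight_normalize = weight_normalize
        self.multi_trial = multi_trial

    def fit(self, X, y=None):
        self.n_features_in_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([
            extract_features(
                s, self.m, self.r, self.weight_normalize, self.multi_trial
            ).values
            for s in X
        ])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
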