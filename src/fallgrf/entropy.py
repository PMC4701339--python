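"""Sample entropy and the series preprocessing that precedes it.

Sample entropy (SampEn) of a series is ``-ln(A/B)``, where ``B`` counts ordered
pairs of distinct length-``m`` templates whose Chebyshev distance is within a
tolerance ``r``, and ``A`` counts the same pairs still within tolerance when the
templates are extended by one point. Self-matches are excluded, and both counts
use the same ``N - m`` templates so the ratio is a conditional probability.
Lower values mean a more regular signal.

Preprocessing follows the analysis pipeline for ground-reaction-force data:
forces are first expressed in body-weight units, then each series is
standardized to zero mean and unit variance (population SD, divisor ``N``)
before the entropy is computed, so ``r`` acts as a fraction of the series SD.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .exceptions import DegenerateSeriesError, ParameterError

#: Standard gravity used to convert kg body weight into Newtons.
GRAVITY = 9.81

#: Sentinel for "sample entropy undefined" (no matching templates).
UNDEFINED = float("nan")


def normalize_by_weight(series, weight_kg: float, g: float = GRAVITY) -> np.ndarray:
    """Express force samples in units of the subject's body weight.

    Divides by ``weight_kg * g`` so that a constant force equal to the body
    weight maps to 1.0. The entropy features are invariant to this affine
    rescaling (standardization follows), but the step is kept for interpretable
    intermediate output.
    """
    if weight_kg <= 0:
        raise ParameterError("weight_kg must be positive")
    return np.asarray(series, dtype=float) / (weight_kg * g)


def standardize(series) -> np.ndarray:
    """Z-score a series to zero mean and unit variance (population SD).

    Raises :class:`DegenerateSeriesError` for series shorter than two samples
    or with zero variance, which cannot be standardized.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ParameterError("series must be one-dimensional")
    if x.size < 2:
        raise DegenerateSeriesError("need at least 2 samples to standardize")
    sd = float(x.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError("cannot standardize a zero-variance series")
    return (x - x.mean()) / sd


def sample_entropy_counts(series, m: int = 2, r: float = 0.25) -> tuple[int, int]:
    """Template-match counts ``(A, B)`` underlying sample entropy.

    ``B`` counts ordered pairs ``(i, j)``, ``i != j``, of length-``m``
    templates with Chebyshev distance <= ``r``; ``A`` the same for length
    ``m + 1``. Both use templates starting at ``i = 0 .. N - m - 1``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ParameterError("series must be one-dimensional")
    if m < 1:
        raise ParameterError("embedding dimension m must be >= 1")
    if r <= 0:
        raise ParameterError("tolerance r must be positive")
    n = x.size
    if n < m + 2:
        raise ParameterError(f"series length {n} < m + 2 = {m + 2}")

    n_templates = n - m
    emb_m1 = sliding_window_view(x, m + 1)  # (n_templates, m + 1)
    emb_m = emb_m1[:, :m]

    dist_m = cdist(emb_m, emb_m, metric="chebyshev")
    # Extending each template by one point only adds one coordinate to the max.
    last = x[m:]
    dist_m1 = np.maximum(dist_m, np.abs(last[:, None] - last[None, :]))

    b = int(np.count_nonzero(dist_m <= r)) - n_templates  # drop self-matches
    a = int(np.count_nonzero(dist_m1 <= r)) - n_templates
    return a, b


def sample_entropy(series, m: int = 2, r: float = 0.25) -> float:
    """Sample entropy ``-ln(A/B)``; NaN when either count is zero.

    The series is expected to be standardized already (``r`` is then a fraction
    of its SD). Returns the :data:`UNDEFINED` sentinel (NaN) rather than
    infinity when no templates match at either length.
    """
    a, b = sample_entropy_counts(series, m=m, r=r)
    if a == 0 or b == 0:
        return UNDEFINED
    return -math.log(a / b)
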