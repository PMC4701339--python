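"""Synthetic two-group GRF cohorts with calibrated sample-entropy structure.

No public GRF dataset accompanies the fall-risk analysis this package
implements, so every downstream stage is exercised on synthetic cohorts whose
*entropy* structure emulates the reference cohort: per channel and group, the
sample-entropy distribution is steered toward a target mean and SD, with
fallers showing lower entropy on the discriminative channels.

The generative family is the MIX(p) process: a deterministic sinusoid whose
samples are independently replaced by uniform noise with probability ``p``.
Its sample entropy increases monotonically with ``p``, which makes it cheap to
calibrate: a seeded Monte-Carlo curve of mean SampEn versus ``p`` is inverted
by interpolation (or by bisection in :func:`calibrate_irregularity`). Only the
entropy structure is emulated — no gait cycles, heel strikes or force-plate
physics; see the methods note for what that implies about the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data import (
    CHANNELS,
    FEATURE_NAMES,
    GROUP_FALLER,
    GROUP_NONFALLER,
    GrfRecording,
    Subject,
)
from .entropy import GRAVITY, sample_entropy, standardize
from .exceptions import CalibrationError, ParameterError

#: Default per-channel entropy calibration targets (mean, SD) per group.
#: They encode the reference cohort's group statistics: fallers lower on every
#: channel, markedly so on the sit-to-stand vertical forces.
DEFAULT_ENTROPY_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    GROUP_FALLER: {
        "L_ML_F": (0.5586, 0.1389),
        "L_AP_F": (0.4496, 0.0915),
        "L_SI_F": (0.2574, 0.1655),
        "R_ML_F": (0.5700, 0.1172),
        "R_AP_F": (0.4661, 0.0986),
        "R_SI_F": (0.2996, 0.1485),
        "L_V_F": (0.0852, 0.0297),
        "R_V_F": (0.1003, 0.0402),
    },
    GROUP_NONFALLER: {
        "L_ML_F": (0.6246, 0.1858),
        "L_AP_F": (0.4835, 0.0421),
        "L_SI_F": (0.2819, 0.0690),
        "R_ML_F": (0.5826, 0.1963),
        "R_AP_F": (0.5116, 0.0574),
        "R_SI_F": (0.3187, 0.1144),
        "L_V_F": (0.1110, 0.0313),
        "R_V_F": (0.1339, 0.0340),
    },
}

#: Channels on which the groups are expected to differ (faller entropy lower).
DISCRIMINATIVE_CHANNELS = ("L_SI_F", "R_ML_F", "R_AP_F", "L_V_F", "R_V_F")

#: Channel pairs sharing a latent irregularity factor (positive correlation).
DEFAULT_CORRELATED_PAIRS = (("L_SI_F", "R_ML_F"), ("L_V_F", "R_V_F"))

#: Body-weight range (kg) of the emulated cohort.
WEIGHT_RANGE_KG = (40.0, 90.0)


@dataclass(frozen=True)
class MixProcessParams:
    """MIX(p) parameters: irregularity p, sinusoid period, noise amplitude."""

    p: float
    period: float = 8.0
    noise_amplitude: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ParameterError("irregularity p must lie in [0, 1]")
        if self.period <= 0:
            raise ParameterError("period must be positive")
        if self.noise_amplitude <= 0:
            raise ParameterError("noise amplitude must be positive")


def generate_mix_series(
    params: MixProcessParams, length: int, seed: int | np.random.Generator
) -> np.ndarray:
    """One MIX(p) realization: sinusoid samples noise-replaced w.p. ``p``.

    ``x_t = (1 - z_t) sin(2 pi t / period) + z_t e_t`` with ``z_t``
    Bernoulli(p) and ``e_t`` uniform on ``[-sqrt(3), sqrt(3)]`` times the
    amplitude (unit variance at amplitude 1). Deterministic for a fixed seed.
    """
    if not isinstance(params, MixProcessParams):
        params = MixProcessParams(*params)
    if length < 10:
        raise ParameterError("length must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(length)
    sinusoid = np.sin(2.0 * np.pi * t / params.period)
    z = rng.random(length) < params.p
    bound = np.sqrt(3.0) * params.noise_amplitude
    noise = rng.uniform(-bound, bound, size=length)
    return np.where(z, noise, sinusoid)


@dataclass(frozen=True)
class MixEntropyCurve:
    """Monotone map from irregularity p to mean SampEn at one series length."""

    p_grid: np.ndarray
    mean_entropy: np.ndarray
    length: int
    m: int
    r: float
    period: float
    noise_amplitude: float

    @property
    def achievable_range(self) -> tuple[float, float]:
        return float(self.mean_entropy[0]), float(self.mean_entropy[-1])

    def p_for_entropy(self, target: float) -> float:
        lo, hi = self.achievable_range
        if not (lo <= target <= hi):
            raise CalibrationError(
                f"target entropy {target:.4f} outside the achievable interval "
                f"[{lo:.4f}, {hi:.4f}] at length {self.length}"
            )
        return float(np.interp(target, self.mean_entropy, self.p_grid))


_CURVE_CACHE: dict[tuple, MixEntropyCurve] = {}


def mix_entropy_curve(
    length: int,
    m: int = 2,
    r: float = 0.25,
    period: float = 8.0,
    noise_amplitude: float = 1.0,
    n_grid: int = 17,
    n_reps: int = 12,
    seed: int = 0,
) -> MixEntropyCurve:
    """Monte-Carlo calibration curve: mean SampEn of standardized MIX(p).

    Evaluated on an even p grid with common random numbers across grid points
    and forced non-decreasing (cumulative max) so inversion is well posed.
    Cached per parameter set.
    """
    key = (length, m, r, period, noise_amplitude, n_grid, n_reps, int(seed))
    if key in _CURVE_CACHE:
        return _CURVE_CACHE[key]
    rep_seeds = np.random.SeedSequence(int(seed)).generate_state(n_reps)
    p_grid = np.linspace(0.0, 1.0, n_grid)
    means = np.empty(n_grid)
    for gi, p in enumerate(p_grid):
        params = MixProcessParams(p=float(p), period=period,
                                  noise_amplitude=noise_amplitude)
        vals = []
        for s in rep_seeds:
            series = generate_mix_series(params, length, int(s))
            vals.append(sample_entropy(standardize(series), m=m, r=r))
        vals = np.asarray(vals, dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise CalibrationError(
                f"sample entropy undefined for every realization at p={p:.2f}"
            )
        means[gi] = finite.mean()
    means = np.maximum.accumulate(means)
    means = means + 1e-12 * np.arange(n_grid)  # strictly increasing for interp
    curve = MixEntropyCurve(p_grid=p_grid, mean_entropy=means, length=length,
                            m=m, r=r, period=period,
                            noise_amplitude=noise_amplitude)
    _CURVE_CACHE[key] = curve
    return curve


def calibrate_irregularity(
    target_entropy: float,
    length: int = 1000,
    seed: int = 0,
    m: int = 2,
    r: float = 0.25,
    period: float = 8.0,
    noise_amplitude: float = 1.0,
    tol: float = 0.05,
    n_reps: int = 20,
    max_iter: int = 40,
) -> MixProcessParams:
    """Find p so mean SampEn of standardized MIX(p) hits a target within tol.

    Monotone bisection with common random numbers (the same ``n_reps`` seeds
    at every probed p, so the objective is a deterministic function of p).
    Raises :class:`CalibrationError`, naming the achievable interval, when the
    target cannot be reached at this length.
    """
    if target_entropy <= 0:
        raise ParameterError("target entropy must be positive")
    rep_seeds = np.random.SeedSequence(int(seed)).generate_state(n_reps)

    def realized_mean(p: float) -> float:
        params = MixProcessParams(p=p, period=period,
                                  noise_amplitude=noise_amplitude)
        vals = []
        for s in rep_seeds:
            series = generate_mix_series(params, length, int(s))
            vals.append(sample_entropy(standardize(series), m=m, r=r))
        vals = np.asarray(vals, dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise CalibrationError(f"entropy undefined at p={p:.3f}")
        return float(finite.mean())

    f_lo, f_hi = realized_mean(0.0), realized_mean(1.0)
    if not (min(f_lo, f_hi) <= target_entropy <= max(f_lo, f_hi)):
        raise CalibrationError(
            f"target entropy {target_entropy:.4f} outside the achievable "
            f"interval [{f_lo:.4f}, {f_hi:.4f}] at length {length}"
        )
    if abs(f_lo - target_entropy) <= tol:
        return MixProcessParams(p=0.0, period=period,
                                noise_amplitude=noise_amplitude)
    lo, hi = 0.0, 1.0
    mid = 0.5
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = realized_mean(mid)
        if abs(fm - target_entropy) <= tol:
            return MixProcessParams(p=mid, period=period,
                                    noise_amplitude=noise_amplitude)
        if fm < target_entropy:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach the target {target_entropy:.4f} within "
        f"{max_iter} iterations (last p={mid:.4f})"
    )


def _validate_targets(targets: Mapping) -> None:
    for group in (GROUP_FALLER, GROUP_NONFALLER):
        if group not in targets:
            raise ParameterError(f"entropy targets missing group {group!r}")
        for name in FEATURE_NAMES:
            if name not in targets[group]:
                raise ParameterError(
                    f"entropy targets missing channel {name!r} for {group!r}"
                )
            mean, sd = targets[group][name]
            if mean <= 0:
                raise ParameterError("entropy target means must be positive")
            if sd < 0:
                raise ParameterError("entropy target SDs must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one reproducible synthetic cohort."""

    n_fallers: int
    n_nonfallers: int
    seed: int = 0
    series_length: int = 1000
    entropy_targets: Mapping = field(
        default_factory=lambda: DEFAULT_ENTROPY_TARGETS
    )
    variability_scale: float = 1.0
    latent_correlation: float = 0.5
    correlated_pairs: tuple = DEFAULT_CORRELATED_PAIRS
    period: float = 8.0

    def __post_init__(self):
        if self.n_fallers < 1 or self.n_nonfallers < 1:
            raise ParameterError("each group needs at least one subject")
        if self.series_length <= 100:
            raise ParameterError("series_length must exceed 100")
        if not (0.0 <= self.latent_correlation < 1.0):
            raise ParameterError("latent correlation must lie in [0, 1)")
        if self.variability_scale < 0:
            raise ParameterError("variability scale must be >= 0")
        _validate_targets(self.entropy_targets)


def _latent_covariance(spec: CohortSpec) -> np.ndarray:
    cov = np.eye(len(FEATURE_NAMES))
    index = {name: i for i, name in enumerate(FEATURE_NAMES)}
    for a, b in spec.correlated_pairs:
        i, j = index[a], index[b]
        cov[i, j] = cov[j, i] = spec.latent_correlation
    return cov


def _force_series(channel, standardized_like, weight_kg):
    """Affine map of a unit-scale series into plausible force magnitudes (N)."""
    body = weight_kg * GRAVITY
    if channel.axis in ("SI", "V"):
        return body * (1.0 + 0.3 * standardized_like)
    return 0.15 * body * standardized_like


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate the synthetic cohort: fallers first, then non-fallers.

    Per group and channel, subject-level entropy targets are drawn from a
    latent Gaussian (with the configured cross-channel correlation), exactly
    re-standardized to the target mean/SD (removing sampling error of the
    draw), clipped to the achievable entropy range, and mapped to MIX
    irregularities through the calibration curve. Bit-reproducible from the
    spec seed.
    """
    ss = np.random.SeedSequence(int(spec.seed))
    curve_ss, faller_ss, nonfaller_ss = ss.spawn(3)
    curve = mix_entropy_curve(
        spec.series_length, period=spec.period,
        seed=int(curve_ss.generate_state(1)[0] % (2**31)),
    )
    lo, hi = curve.achievable_range
    margin = 1e-6
    cov = _latent_covariance(spec)

    subjects: list[Subject] = []
    groups = (
        (GROUP_FALLER, "F", spec.n_fallers, faller_ss),
        (GROUP_NONFALLER, "N", spec.n_nonfallers, nonfaller_ss),
    )
    for group, prefix, n, group_ss in groups:
        rng = np.random.default_rng(group_ss)
        z = rng.multivariate_normal(np.zeros(len(FEATURE_NAMES)), cov, size=n)
        if n >= 2:
            # exact moment match: realized target means/SDs equal the spec's
            z = (z - z.mean(axis=0)) / z.std(axis=0)
        else:
            z = np.zeros_like(z)
        targets = np.empty_like(z)
        for j, name in enumerate(FEATURE_NAMES):
            mean, sd = spec.entropy_targets[group][name]
            if mean < lo or mean > hi:
                raise CalibrationError(
                    f"target mean {mean:.4f} for {name} ({group}) outside the "
                    f"achievable interval [{lo:.4f}, {hi:.4f}]"
                )
            targets[:, j] = np.clip(
                mean + spec.variability_scale * sd * z[:, j],
                lo + margin, hi - margin,
            )
        weights = rng.uniform(*WEIGHT_RANGE_KG, size=n)
        subject_seeds = group_ss.spawn(n)
        for s in range(n):
            sid = f"{prefix}{s + 1:03d}"
            channel_seeds = subject_seeds[s].spawn(len(CHANNELS))
            recordings = []
            for j, channel in enumerate(CHANNELS):
                p = curve.p_for_entropy(float(targets[s, j]))
                params = MixProcessParams(p=p, period=spec.period)
                series = generate_mix_series(
                    params, spec.series_length,
                    np.random.default_rng(channel_seeds[j]),
                )
                recordings.append(GrfRecording(
                    subject_id=sid, activity=channel.activity,
                    foot=channel.foot, axis=channel.axis,
                    series=_force_series(channel, series, weights[s]),
                ))
            subjects.append(Subject(
                subject_id=sid, group=group,
                weight_kg=float(weights[s]), recordings=recordings,
            ))
    return subjects


def make_planted_targets(
    planted: tuple[str, ...],
    gap_sd: float = 2.0,
    baseline_mean: float = 0.40,
    sd: float = 0.05,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Targets with group separation planted only on the given channels.

    Non-fallers sit at the baseline mean everywhere; fallers are shifted down
    by ``gap_sd`` SDs on the planted channels only. Used for signal-recovery
    experiments where the informative feature set is known by construction.
    """
    unknown = [c for c in planted if c not in FEATURE_NAMES]
    if unknown:
        raise ParameterError(f"unknown channels: {unknown}")
    faller = {}
    nonfaller = {}
    for name in FEATURE_NAMES:
        shift = gap_sd * sd if name in planted else 0.0
        faller[name] = (baseline_mean - shift, sd)
        nonfaller[name] = (baseline_mean, sd)
    return {GROUP_FALLER: faller, GROUP_NONFALLER: nonfaller}
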