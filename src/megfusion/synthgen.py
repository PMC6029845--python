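"""Synthetic MEG epochs, fMRI pattern sets, and behavioral trials.

Every downstream stage (preprocessing, decoding, fusion, inference) is
exercised on data from this module, so its generative model mirrors the
statistical structure the analyses assume: condition-specific spatial
patterns modulated by smooth temporal envelopes, an additive categorical
(e.g. face-vs-object) pattern component, and i.i.d. Gaussian sensor noise.

The default spec reproduces the emulated study design: 24 conditions split
into two categories of 12, ~30 trials per condition, 306 sensors, a
-300..900 ms peri-stimulus window sampled at 1 kHz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import EpochedRecording
from .rsa_fusion import ConditionPatternSet

__all__ = [
    "Envelope",
    "SyntheticSpec",
    "GroundTruth",
    "generate_meg_subjects",
    "generate_fmri_patterns",
    "generate_behavior",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class Envelope:
    """Gaussian temporal bump, truncated to zero before its onset.

    Parameters are in ms: the bump rises from `onset_ms`, peaks at
    `peak_ms`, and has full width at half maximum `fwhm_ms`; `amplitude`
    scales the peak value.
    """

    onset_ms: float
    peak_ms: float
    fwhm_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm_ms <= 0:
            raise ValueError("envelope fwhm_ms must be positive")
        if self.amplitude < 0:
            raise ValueError("envelope amplitude must be non-negative")
        if not self.onset_ms < self.peak_ms:
            raise ValueError("envelope onset must precede its peak")

    @property
    def sigma_ms(self) -> float:
        return self.fwhm_ms / _FWHM_TO_SIGMA

    def evaluate(self, time_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(time_ms, dtype=np.float64)
        bump = self.amplitude * np.exp(
            -0.5 * ((t - self.peak_ms) / self.sigma_ms) ** 2
        )
        return np.where(t >= self.onset_ms, bump, 0.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic cohort.

    Defaults follow the emulated study design (24 conditions = 12 faces +
    12 objects, 30 trials each, 306 channels, -300..900 ms at 1 kHz).
    Envelope timing defaults place the identity (per-exemplar) component
    early and the categorical component later, as observed for visual
    object recognition. `noise_sd` is the per-sample Gaussian standard
    deviation on each channel; pattern vectors are unit-norm, so
    amplitude / noise_sd sets the single-trial SNR directly.
    """

    n_subjects: int = 17
    n_conditions: int = 24
    category_names: tuple[str, str] = ("face", "object")
    n_trials_per_condition: int = 30
    n_channels: int = 306
    time_start_ms: float = -300.0
    time_stop_ms: float = 900.0
    time_step_ms: float = 1.0
    identity_envelope: Envelope = field(
        default_factory=lambda: Envelope(
            onset_ms=40.0, peak_ms=100.0, fwhm_ms=100.0, amplitude=1.0
        )
    )
    category_envelope: Envelope = field(
        default_factory=lambda: Envelope(
            onset_ms=90.0, peak_ms=170.0, fwhm_ms=140.0, amplitude=0.6
        )
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_step_ms <= 0:
            raise ValueError("time_step_ms must be positive")
        if self.n_conditions % 2 != 0:
            raise ValueError(
                "n_conditions must be even for a two-category split"
            )
        if min(
            self.n_subjects,
            self.n_trials_per_condition,
            self.n_channels,
        ) < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        t0, t1 = self.time_start_ms, self.time_stop_ms
        for name, env in (
            ("identity", self.identity_envelope),
            ("category", self.category_envelope),
        ):
            if not (t0 <= env.peak_ms <= t1):
                raise ValueError(
                    f"{name} envelope peak {env.peak_ms} ms lies outside "
                    f"the time axis [{t0}, {t1}] ms"
                )

    @property
    def time_axis(self) -> np.ndarray:
        n = int(round((self.time_stop_ms - self.time_start_ms) / self.time_step_ms)) + 1
        return self.time_start_ms + self.time_step_ms * np.arange(n)

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / self.time_step_ms

    @property
    def category_of(self) -> np.ndarray:
        """Category index (0 or 1) per condition: first half / second half."""
        half = self.n_conditions // 2
        return (np.arange(self.n_conditions) >= half).astype(int)


@dataclass
class GroundTruth:
    """Realized generative parameters of one cohort, for oracle checks.

    Holds the per-subject pattern vectors and the envelopes, exposes the
    implied noiseless condition x condition x time dissimilarity geometry,
    and carries the true component latencies.
    """

    spec: SyntheticSpec
    condition_patterns: np.ndarray  # (n_subjects, C, n_channels)
    category_patterns: np.ndarray  # (n_subjects, 2, n_channels)

    @property
    def time_axis(self) -> np.ndarray:
        return self.spec.time_axis

    @property
    def true_identity_peak_ms(self) -> float:
        return self.spec.identity_envelope.peak_ms

    @property
    def true_category_peak_ms(self) -> float:
        return self.spec.category_envelope.peak_ms

    @property
    def true_identity_onset_ms(self) -> float:
        return self.spec.identity_envelope.onset_ms

    @property
    def true_category_onset_ms(self) -> float:
        return self.spec.category_envelope.onset_ms

    def noiseless_signals(self, subject: int) -> np.ndarray:
        """Noise-free signal per condition: (C, n_channels, n_times)."""
        spec = self.spec
        t = spec.time_axis
        a_id = spec.identity_envelope.evaluate(t)  # (T,)
        a_cat = spec.category_envelope.evaluate(t)
        pats = self.condition_patterns[subject]  # (C, ch)
        cats = self.category_patterns[subject][spec.category_of]  # (C, ch)
        return (
            pats[:, :, None] * a_id[None, None, :]
            + cats[:, :, None] * a_cat[None, None, :]
        )

    def dissimilarity_geometry(self, subject: int = 0) -> np.ndarray:
        """Euclidean distance between noiseless condition signals.

        Returns (C, C, n_times); symmetric, zero diagonal, non-negative.
        """
        sig = self.noiseless_signals(subject)  # (C, ch, T)
        diff = sig[:, None] - sig[None, :]  # (C, C, ch, T)
        return np.sqrt((diff**2).sum(axis=2))

    def mean_geometry(self) -> np.ndarray:
        """Dissimilarity geometry averaged over subjects."""
        n = self.spec.n_subjects
        return sum(
            self.dissimilarity_geometry(s) for s in range(n)
        ) / n


def _unit_rows(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    """Standard-Gaussian rows normalized to unit Euclidean norm."""
    x = rng.standard_normal((n, dim))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def generate_meg_subjects(
    spec: SyntheticSpec,
) -> tuple[list[EpochedRecording], GroundTruth]:
    """Simulate one cohort of epoched MEG-like recordings.

    Each trial of condition c for subject s is

        identity_env(t) * p_sc  +  category_env(t) * q_s,cat(c)  +  noise

    with p and q unit-norm Gaussian spatial patterns drawn once per
    subject and i.i.d. Gaussian sensor noise of SD `spec.noise_sd`.
    Identical spec (including seed) reproduces the cohort bit-exactly.
    """
    time_axis = spec.time_axis
    n_t = time_axis.size
    cat_of = spec.category_of
    a_id = spec.identity_envelope.evaluate(time_axis)
    a_cat = spec.category_envelope.evaluate(time_axis)

    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)

    cond_patterns = np.empty((spec.n_subjects, spec.n_conditions, spec.n_channels))
    cat_patterns = np.empty((spec.n_subjects, 2, spec.n_channels))
    subjects: list[EpochedRecording] = []
    labels = np.repeat(np.arange(spec.n_conditions), spec.n_trials_per_condition)

    # pre-stimulus period if the epoch has one, else the first sample
    t0 = spec.time_start_ms
    baseline = (t0, 0.0) if t0 < 0.0 else (t0, t0)
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        p = _unit_rows(rng, spec.n_conditions, spec.n_channels)
        q = _unit_rows(rng, 2, spec.n_channels)
        cond_patterns[s] = p
        cat_patterns[s] = q
        # (C, ch, T) noiseless template, repeated per trial
        template = (
            p[:, :, None] * a_id[None, None, :]
            + q[cat_of][:, :, None] * a_cat[None, None, :]
        )
        data = np.repeat(template, spec.n_trials_per_condition, axis=0)
        if spec.noise_sd > 0:
            data = data + rng.normal(
                0.0, spec.noise_sd, size=(labels.size, spec.n_channels, n_t)
            )
        subjects.append(
            EpochedRecording(
                data=data,
                labels=labels.copy(),
                time_axis=time_axis,
                sampling_rate=spec.sampling_rate,
                baseline_window=baseline,
                history=[f"synthgen(seed={spec.seed}, subject={s})"],
            )
        )

    truth = GroundTruth(
        spec=spec,
        condition_patterns=cond_patterns,
        category_patterns=cat_patterns,
    )
    return subjects, truth


def generate_fmri_patterns(
    geometry: np.ndarray,
    n_voxels: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    roi_id: str = "synthetic",
) -> ConditionPatternSet:
    """Voxel patterns whose correlation RDM reproduces a target geometry.

    `geometry` is a symmetric non-negative condition x condition
    dissimilarity matrix interpreted on the 1 - Pearson scale (0 =
    identical, 2 = anti-correlated); entries above 2 are rescaled onto
    [0, 2] (a monotone map, so rank-based fusion is unaffected). The
    implied correlation matrix C = 1 - geometry is embedded by classical
    scaling: C = V L V', patterns = V sqrt(L) Q with Q orthonormal rows
    orthogonal to the constant vector, which makes every pattern row
    exactly zero-mean so the sample Pearson RDM of the noiseless patterns
    equals the target. If C is not positive semi-definite the negative
    eigenvalues are clipped and the closest embeddable geometry is
    returned with a warning. Gaussian voxel noise of SD `noise_sd` is then
    added.
    """
    d = np.asarray(geometry, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("geometry must be a square matrix")
    if not np.allclose(d, d.T):
        raise ValueError("geometry must be symmetric")
    if (d < 0).any():
        raise ValueError("geometry must be non-negative")
    n_cond = d.shape[0]
    if n_voxels < n_cond + 1:
        raise ValueError(
            f"n_voxels must exceed n_conditions (got {n_voxels} <= {n_cond})"
        )
    dmax = d.max()
    if dmax > 2.0:
        d = d * (2.0 / dmax)

    corr = 1.0 - d
    np.fill_diagonal(corr, 1.0)
    evals, evecs = np.linalg.eigh(corr)
    if evals.min() < -1e-10 * max(1.0, evals.max()):
        warnings.warn(
            "target geometry is not embeddable as a correlation structure; "
            "returning the closest PSD approximation",
            stacklevel=2,
        )
    evals = np.clip(evals, 0.0, None)
    factor = evecs * np.sqrt(evals)  # (C, C) rows span the geometry

    rng = np.random.default_rng(seed)
    # orthonormal voxel basis orthogonal to the constant vector, so each
    # noiseless pattern row has exactly zero mean across voxels
    basis = rng.standard_normal((n_voxels, n_cond + 1))
    basis[:, 0] = 1.0
    qmat, _ = np.linalg.qr(basis)
    voxel_basis = qmat[:, 1 : n_cond + 1].T  # (C, V), rows orthonormal

    responses = factor @ voxel_basis
    if noise_sd > 0:
        responses = responses + rng.normal(0.0, noise_sd, size=responses.shape)
    return ConditionPatternSet(
        responses=responses,
        roi_id=roi_id,
        condition_ids=np.arange(n_cond),
    )


def generate_behavior(
    target_dprime: float,
    criterion: float,
    n_signal: int,
    n_noise: int,
    seed: int = 0,
    condition_speed: str = "",
) -> pd.DataFrame:
    """Simulate yes/no detection trials under the equal-variance Gaussian model.

    Hit and false-alarm probabilities are P(hit) = Phi(d'/2 - c) and
    P(fa) = Phi(-d'/2 - c) for sensitivity d' and criterion c, so the d'
    recovered from the generated trials converges to `target_dprime` as
    the trial counts grow. Returns one row per trial with columns
    trial, signal_present, response_present, condition_speed.
    """
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("n_signal and n_noise must be positive")
    p_hit = norm.cdf(target_dprime / 2.0 - criterion)
    p_fa = norm.cdf(-target_dprime / 2.0 - criterion)
    rng = np.random.default_rng(seed)
    signal = np.concatenate(
        [np.ones(n_signal, dtype=bool), np.zeros(n_noise, dtype=bool)]
    )
    p_yes = np.where(signal, p_hit, p_fa)
    response = rng.random(signal.size) < p_yes
    return pd.DataFrame(
        {
            "trial": np.arange(signal.size),
            "signal_present": signal,
            "response_present": response,
            "condition_speed": condition_speed,
        }
    )
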