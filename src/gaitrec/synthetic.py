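"""Synthetic longitudinal gait cohorts with planted recovery archetypes.

The generator emulates the structure of a post-stroke follow-up study:
31 hemiplegic patients assessed at 2, 3, 4, 6, 8, 10, 12 and 24 weeks
post-onset, six sagittal kinematic channels per assessment time-normalized
to 100 points per gait cycle, and week-level missingness following the
study's observed profile (59 of 248 patient-weeks missing, ~24%).

Each patient belongs to a recovery archetype.  Week ``w``'s trajectory is

    normative(t) + A_c * exp(-r * (w - w_0)) * g(t) + noise,

i.e. a pathological deviation waveform ``g`` (a smooth periodic bump)
scaled per channel by the archetype's baseline amplitude ``A_c`` and
decaying exponentially toward the normative cycle at the archetype's
per-week rate ``r``.  Velocity channels carry the analytic derivative of
the angle-channel deviation so the channel semantics stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import (
    DEFAULT_CHANNELS,
    DEFAULT_WEEKS,
    ChannelLayout,
    CohortTensor,
    PatientSeries,
)

# Fixed low-order Fourier description of normative sagittal cycles
# (flexion/dorsiflexion positive, degrees).  Each entry: mean and a list of
# (harmonic k, amplitude, phase in cycle fraction); the curve is
# mean + sum_k amp * cos(2*pi*k*(u - phase)).  Chosen to match textbook
# shapes qualitatively: hip flexes once early and extends mid-late stance,
# knee shows a small stance-flexion wave and a dominant swing peak, ankle
# peaks in dorsiflexion during terminal stance then plantarflexes.
_NORMATIVE_FOURIER = {
    "hip_angle": (3.0, [(1, 16.0, 0.04), (2, 1.2, 0.45)]),
    "knee_angle": (28.0, [(1, 18.0, 0.72), (2, 14.0, 0.10)]),
    "ankle_angle": (-1.0, [(1, 7.0, 0.42), (2, 7.0, 0.50)]),
}

# Table-2-style distribution: {number of missing weeks: number of patients}
DEFAULT_MISSINGNESS_PROFILE = {0: 7, 1: 6, 2: 5, 3: 9, 4: 4}


def generate_normative_cycle(channel: str, points: int = 100) -> np.ndarray:
    """Deterministic normative gait cycle for one channel.

    Angle channels are fixed low-order Fourier curves (degrees); velocity
    channels are the analytic per-sample derivative of the matching angle
    channel (degrees per sample, i.e. per %cycle at 100 points).
    """
    if points < 4:
        raise ValueError("points must be >= 4")
    if channel.endswith("_velocity"):
        base = channel.replace("_velocity", "_angle")
        if base not in _NORMATIVE_FOURIER:
            raise KeyError(f"unknown channel {channel!r}")
        u = np.arange(points) / points
        _, harmonics = _NORMATIVE_FOURIER[base]
        out = np.zeros(points)
        for k, amp, phase in harmonics:
            out += -amp * (2 * np.pi * k / points) * np.sin(2 * np.pi * k * (u - phase))
        return out
    if channel not in _NORMATIVE_FOURIER:
        raise KeyError(f"unknown channel {channel!r}")
    mean, harmonics = _NORMATIVE_FOURIER[channel]
    u = np.arange(points) / points
    out = np.full(points, mean, dtype=float)
    for k, amp, phase in harmonics:
        out += amp * np.cos(2 * np.pi * k * (u - phase))
    return out


@dataclass(frozen=True)
class RecoveryArchetype:
    """One planted recovery pattern.

    baseline_deviation maps channel name -> initial deviation amplitude
    (degrees for angle channels; velocity channels inherit the analytic
    derivative of the angle bump scaled by their own amplitude entry).
    shape_params = (phase in cycle fraction, width in cycle fraction) of the
    periodic deviation bump.
    """

    archetype_id: str
    baseline_deviation: dict[str, float]
    recovery_rate: float
    shape_params: tuple[float, float] = (0.3, 0.1)

    def __post_init__(self):
        if self.recovery_rate < 0:
            raise ValueError("recovery_rate must be >= 0")
        if not all(np.isfinite(list(self.baseline_deviation.values()))):
            raise ValueError("baseline_deviation must be finite")


def deviation_waveform(
    shape_params: tuple[float, float], points: int, derivative: bool = False
) -> np.ndarray:
    """Smooth periodic bump (von Mises shape) or its per-sample derivative.

    exp(kappa*(cos(2*pi*(u-phase)) - 1)) with kappa = 1/(2*pi*width)^2, so
    for small widths the bump is approximately Gaussian with sd ``width``
    (in cycle fraction).  Peak value 1 at u = phase.
    """
    phase, width = shape_params
    if width <= 0:
        raise ValueError("width must be > 0")
    kappa = 1.0 / (2 * np.pi * width) ** 2
    u = np.arange(points) / points
    theta = 2 * np.pi * (u - phase)
    g = np.exp(kappa * (np.cos(theta) - 1.0))
    if derivative:
        return g * (-kappa * np.sin(theta)) * (2 * np.pi / points)
    return g


def default_archetypes(k: int = 3) -> list[RecoveryArchetype]:
    """Deterministic bank of well-separated recovery archetypes.

    Archetypes differ in bump phase (spread over the cycle), deviation
    amplitude/sign per joint, and recovery rate (slow 0.05/week to fast
    0.50/week), giving cluster-structured longitudinal dynamics.
    """
    if k < 1:
        raise ValueError("need at least one archetype")
    archetypes = []
    for j in range(k):
        phase = 0.05 + 0.9 * j / max(k, 1)
        sign = 1.0 if j % 2 == 0 else -1.0
        amp = 12.0 + 10.0 * (j % 3)
        rate = 0.05 + 0.45 * j / max(k - 1, 1)
        dev = {
            "hip_angle": sign * amp,
            "knee_angle": -sign * (amp + 4.0),
            "ankle_angle": sign * 0.6 * amp,
            "hip_velocity": sign * amp,
            "knee_velocity": -sign * (amp + 4.0),
            "ankle_velocity": sign * 0.6 * amp,
        }
        archetypes.append(
            RecoveryArchetype(
                archetype_id=f"arch{j}",
                baseline_deviation=dev,
                recovery_rate=rate,
                shape_params=(phase, 0.08 + 0.02 * (j % 2)),
            )
        )
    return archetypes


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort."""

    n_patients: int = 31
    weeks: tuple[int, ...] = DEFAULT_WEEKS
    archetypes: list[RecoveryArchetype] = field(default_factory=default_archetypes)
    archetype_proportions: tuple[float, ...] | None = None
    noise_sd: float = 2.0
    missingness_profile: dict[int, int] | None = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS_PROFILE)
    )
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.weeks:
            raise ValueError("weeks must be non-empty")
        if self.archetype_proportions is None:
            k = len(self.archetypes)
            self.archetype_proportions = tuple([1.0 / k] * k)
        if len(self.archetype_proportions) != len(self.archetypes):
            raise ValueError("one proportion per archetype required")
        if abs(sum(self.archetype_proportions) - 1.0) > 1e-9:
            raise ValueError("archetype_proportions must sum to 1")
        if self.missingness_profile is not None:
            if sum(self.missingness_profile.values()) != self.n_patients:
                raise ValueError("missingness profile counts must sum to n_patients")


def _archetype_deviation(
    archetype: RecoveryArchetype, layout: ChannelLayout
) -> np.ndarray:
    """Per-channel deviation template, concatenated to total_length."""
    p = layout.points_per_cycle
    parts = []
    for ch in layout.channels:
        amp = archetype.baseline_deviation.get(ch, 0.0)
        g = deviation_waveform(
            archetype.shape_params, p, derivative=ch.endswith("_velocity")
        )
        parts.append(amp * g)
    return np.concatenate(parts)


def normative_vector(layout: ChannelLayout) -> np.ndarray:
    """All channels' normative cycles concatenated to total_length."""
    return np.concatenate(
        [generate_normative_cycle(ch, layout.points_per_cycle) for ch in layout.channels]
    )


def generate_patient(
    archetype: RecoveryArchetype, spec: CohortSpec, patient_seed: int,
    patient_id: str | None = None,
) -> PatientSeries:
    """Simulate one fully observed patient (missingness applied separately)."""
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(patient_seed)
    norm = normative_vector(spec.layout)
    dev = _archetype_deviation(archetype, spec.layout)
    w0 = spec.weeks[0]
    rows = []
    for w in spec.weeks:
        decay = np.exp(-archetype.recovery_rate * (w - w0))
        noise = rng.normal(0.0, spec.noise_sd, size=norm.shape) if spec.noise_sd > 0 else 0.0
        rows.append(norm + decay * dev + noise)
    return PatientSeries(
        patient_id=patient_id or f"P{patient_seed}",
        values=np.stack(rows),
        week_mask=np.ones(len(spec.weeks), dtype=int),
        archetype_id=archetype.archetype_id,
    )


def apply_missingness(
    patients: list[PatientSeries],
    profile: dict[int, int],
    seed: int,
) -> list[PatientSeries]:
    """Zero week-masks according to a {missing-week-count: n-patients} profile.

    The first assessment week is always kept observed (every study patient
    has an anchor assessment), so at most len(weeks)-1 weeks can go missing.
    Values are left untouched; only masks change.
    """
    n = len(patients)
    if sum(profile.values()) != n:
        raise ValueError("profile counts must sum to the number of patients")
    n_weeks = patients[0].values.shape[0]
    if any(k > n_weeks - 1 for k in profile):
        raise ValueError("profile demands more missing weeks than available")
    rng = np.random.default_rng(seed)
    counts = [c for c, m in sorted(profile.items()) for _ in range(m)]
    order = rng.permutation(n)
    out = []
    assigned = np.empty(n, dtype=int)
    assigned[order] = counts
    for patient, n_missing in zip(patients, assigned):
        mask = np.ones(n_weeks, dtype=int)
        if n_missing > 0:
            missing = rng.choice(np.arange(1, n_weeks), size=n_missing, replace=False)
            mask[missing] = 0
        out.append(
            PatientSeries(
                patient.patient_id, patient.values.copy(), mask, patient.archetype_id
            )
        )
    return out


def generate_cohort(spec: CohortSpec) -> CohortTensor:
    """Simulate a full cohort tensor, deterministic given ``spec.seed``.

    Archetype membership uses exact largest-remainder counts from
    ``archetype_proportions`` shuffled by the seed, so the planted cluster
    sizes are reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_patients, len(spec.archetypes)
    raw = np.array(spec.archetype_proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        frac_order = np.argsort(-(raw - counts))
        counts[frac_order[:remainder]] += 1
    membership = np.repeat(np.arange(k), counts)
    membership = membership[rng.permutation(n)]
    patients = []
    seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        patients.append(
            generate_patient(
                spec.archetypes[membership[i]], spec, int(seeds[i]),
                patient_id=f"P{i:03d}",
            )
        )
    if spec.missingness_profile:
        patients = apply_missingness(
            patients, spec.missingness_profile, seed=int(rng.integers(0, 2**31 - 1))
        )
    cohort = CohortTensor.from_patients(patients, spec.weeks, spec.layout)
    cohort.provenance = ["real"] * n
    return cohort


__all__ = [
    "generate_normative_cycle",
    "deviation_waveform",
    "normative_vector",
    "RecoveryArchetype",
    "default_archetypes",
    "CohortSpec",
    "generate_patient",
    "apply_missingness",
    "generate_cohort",
    "DEFAULT_MISSINGNESS_PROFILE",
]
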