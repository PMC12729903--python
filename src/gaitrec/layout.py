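"""Channel layout and in-memory containers for longitudinal gait cohorts.

A cohort is a stack of patients, each represented by one multivariate
time series: the follow-up weeks form the sequence axis (default 8
assessments at 2, 3, 4, 6, 8, 10, 12 and 24 weeks post-onset) and the
feature axis concatenates six sagittal-plane channels (hip/knee/ankle
angle and angular velocity), each time-normalized to 100 points per gait
cycle, for 600 features per patient-week.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_CHANNELS = (
    "hip_angle",
    "knee_angle",
    "ankle_angle",
    "hip_velocity",
    "knee_velocity",
    "ankle_velocity",
)

DEFAULT_WEEKS = (2, 3, 4, 6, 8, 10, 12, 24)


@dataclass(frozen=True)
class ChannelLayout:
    """Ordering and sampling of the concatenated kinematic channels."""

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    points_per_cycle: int = 100

    def __post_init__(self):
        if self.points_per_cycle < 4:
            raise ValueError("points_per_cycle must be >= 4")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")

    @property
    def total_length(self) -> int:
        return len(self.channels) * self.points_per_cycle

    def channel_slice(self, channel: str) -> slice:
        if channel not in self.channels:
            raise KeyError(f"unknown channel {channel!r}")
        i = self.channels.index(channel)
        p = self.points_per_cycle
        return slice(i * p, (i + 1) * p)

    def to_dict(self) -> dict:
        return {"channels": list(self.channels), "points_per_cycle": self.points_per_cycle}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelLayout":
        return cls(tuple(d["channels"]), int(d["points_per_cycle"]))


@dataclass
class PatientSeries:
    """One patient's weekly trajectory matrix X with observation mask M.

    ``values`` is (n_weeks, total_length); ``week_mask`` is a binary vector
    marking which weekly assessments were actually recorded.  The mask is
    authoritative: rows with mask 0 must never be read as data (the array
    may still hold the simulated ground truth, which tests use as the
    held-out target for imputation).
    """

    patient_id: str
    values: np.ndarray
    week_mask: np.ndarray
    archetype_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.week_mask = np.asarray(self.week_mask)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_weeks, total_length)")
        if self.week_mask.shape != (self.values.shape[0],):
            raise ValueError("week_mask length must equal number of weeks")
        if not np.isin(self.week_mask, (0, 1)).all():
            raise ValueError("week_mask must be binary")
        if not np.isfinite(self.values[self.week_mask == 1]).all():
            raise ValueError("observed values must be finite")


@dataclass
class CohortTensor:
    """Stacked cohort: values (N, n_weeks, total_length), mask (N, n_weeks)."""

    values: np.ndarray
    mask: np.ndarray
    patient_ids: list[str]
    weeks: tuple[int, ...] = DEFAULT_WEEKS
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    archetype_ids: list[str] | None = None
    provenance: list[str] | None = None  # per-sample: "real" | "synthetic"
    week_provenance: np.ndarray | None = None  # per patient-week: "observed" | "imputed"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        n, w, d = self.values.shape
        if self.mask.shape != (n, w):
            raise ValueError("mask shape must be (N, n_weeks)")
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length mismatch")
        if len(self.weeks) != w:
            raise ValueError("weeks length mismatch")
        if d != self.layout.total_length:
            raise ValueError("feature dimension does not match layout")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_weeks(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return bool((self.mask == 1).all())

    def copy(self) -> "CohortTensor":
        return CohortTensor(
            self.values.copy(),
            self.mask.copy(),
            list(self.patient_ids),
            tuple(self.weeks),
            self.layout,
            None if self.archetype_ids is None else list(self.archetype_ids),
            None if self.provenance is None else list(self.provenance),
            None if self.week_provenance is None else self.week_provenance.copy(),
        )

    def to_patients(self) -> list[PatientSeries]:
        arch = self.archetype_ids or [None] * self.n_patients
        return [
            PatientSeries(pid, self.values[i], self.mask[i], arch[i])
            for i, pid in enumerate(self.patient_ids)
        ]

    @classmethod
    def from_patients(
        cls,
        patients: list[PatientSeries],
        weeks: tuple[int, ...] = DEFAULT_WEEKS,
        layout: ChannelLayout | None = None,
    ) -> "CohortTensor":
        layout = layout or ChannelLayout()
        return cls(
            np.stack([p.values for p in patients]),
            np.stack([p.week_mask for p in patients]),
            [p.patient_id for p in patients],
            weeks,
            layout,
            [p.archetype_id for p in patients],
        )


def masked_channel(cohort: CohortTensor, channel: str) -> np.ndarray:
    """View of one channel: (N, n_weeks, points_per_cycle)."""
    sl = cohort.layout.channel_slice(channel)
    return cohort.values[:, :, sl]


__all__ = [
    "ChannelLayout",
    "PatientSeries",
    "CohortTensor",
    "masked_channel",
    "DEFAULT_CHANNELS",
    "DEFAULT_WEEKS",
    "replace",
]
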