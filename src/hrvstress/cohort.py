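"""Synthetic RRI cohort generation.

Emulates a longitudinal stress/relaxation protocol: three diagnostic groups
(MDD, PD, HC), up to five laboratory visits per participant, and five
five-minute phases per visit (rest1, stress, rest2, relaxation, rest3).
Beat-to-beat intervals are generated from a two-oscillator model

    RR(t) = base + A_LF sin(2 pi f_LF t + phi_LF)
                 + A_HF sin(2 pi f_HF t + phi_HF) + eps,

whose parameters map one-to-one onto the spectral and variability features
analysed downstream: the LF oscillator (~0.095 Hz) and HF oscillator
(~0.25 Hz) control the band powers, the white noise eps controls entropy,
and the base interval controls mean RRI.  The stress phase perturbs the
participant's parameters (base and HF amplitude down, LF amplitude up) by
group-specific reactivity fractions; a per-visit random offset shared by all
five phases models day-to-day baseline drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, SimulationError

GROUPS: tuple[str, ...] = ("MDD", "PD", "HC")
PHASES: tuple[str, ...] = ("rest1", "stress", "rest2", "relaxation", "rest3")

__all__ = [
    "GROUPS",
    "PHASES",
    "CohortConfig",
    "GroupEffect",
    "Reactivity",
    "RRISeries",
    "ParticipantState",
    "generate_cohort",
    "simulate_phase_rri",
    "apply_missingness",
    "subsample_sessions",
    "session_keys",
]


@dataclass(frozen=True)
class GroupEffect:
    """Group-level shift of the baseline interval and oscillation amplitudes.

    ``rri_offset_ms`` is added to the population base RRI; ``amp_scale``
    multiplies both LF and HF amplitudes (patients < 1 emulates globally
    reduced HRV in the clinical groups).
    """

    rri_offset_ms: float = 0.0
    amp_scale: float = 1.0


@dataclass(frozen=True)
class Reactivity:
    """Fractional change applied during the stress phase.

    All fractions are signed and must lie in (-1, 1): ``rri_frac`` scales the
    base interval (negative = heart speeds up under stress), ``hf_frac``
    scales the HF amplitude (negative = vagal withdrawal), ``lf_frac`` scales
    the LF amplitude (positive = sympathetic dominance).
    """

    rri_frac: float = -0.08
    hf_frac: float = -0.35
    lf_frac: float = 0.30

    def validate(self) -> None:
        for name in ("rri_frac", "hf_frac", "lf_frac"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ConfigError(f"reactivity fraction {name}={v} outside (-1, 1)")


def _default_group_offsets() -> dict[str, GroupEffect]:
    # Patients show shorter RR intervals and globally lower HRV than HC.
    return {
        "MDD": GroupEffect(rri_offset_ms=-40.0, amp_scale=0.7),
        "PD": GroupEffect(rri_offset_ms=-60.0, amp_scale=0.7),
        "HC": GroupEffect(rri_offset_ms=0.0, amp_scale=1.0),
    }


def _default_reactivity() -> dict[str, Reactivity]:
    # Healthy controls react more strongly to the stressor than patients.
    return {
        "MDD": Reactivity(rri_frac=-0.04, hf_frac=-0.18, lf_frac=0.15),
        "PD": Reactivity(rri_frac=-0.04, hf_frac=-0.18, lf_frac=0.15),
        "HC": Reactivity(rri_frac=-0.08, hf_frac=-0.35, lf_frac=0.30),
    }


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults reproduce the study geometry: 41/47/59 participants (MDD/PD/HC),
    five visits of five 300-s phases, and a per-visit retention probability
    calibrated so that the expected number of retained sessions is ~650 of
    the 735 scheduled ones (visit 1 is always kept, so
    147 + 588 * 0.8554 ~= 650).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"MDD": 41, "PD": 47, "HC": 59}
    )
    n_visits: int = 5
    phase_duration_s: float = 300.0
    base_rri_ms: float = 850.0
    lf_amp_ms: float = 40.0
    hf_amp_ms: float = 25.0
    group_offsets: Mapping[str, GroupEffect] = field(default_factory=_default_group_offsets)
    reactivity: Mapping[str, Reactivity] = field(default_factory=_default_reactivity)
    subject_sd: float = 60.0
    reactivity_subject_sd: float = 0.20
    amp_subject_sd: float = 0.10
    visit_drift_sd: float = 20.0
    noise_sd_ms: float = 15.0
    f_lf: float = 0.095
    f_hf: float = 0.25
    freq_jitter_sd: float = 0.008
    retention_prob: float = 0.8554
    seed: int = 0

    def validate(self) -> None:
        for g in self.n_per_group:
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}; expected one of {GROUPS}")
        if any(int(n) < 0 for n in self.n_per_group.values()):
            raise ConfigError("group counts must be >= 0")
        if self.n_visits < 1:
            raise ConfigError("n_visits must be >= 1")
        if self.phase_duration_s <= 0:
            raise ConfigError("phase_duration_s must be > 0")
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ConfigError("retention_prob must lie in [0, 1]")
        if self.base_rri_ms <= 0:
            raise ConfigError("base_rri_ms must be > 0")
        for g, r in self.reactivity.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r} in reactivity")
            r.validate()


@dataclass(frozen=True)
class ParticipantState:
    """Latent parameters drawn once per participant and reused across visits."""

    participant_id: str
    group: str
    base_rri_ms: float
    lf_amp_ms: float
    hf_amp_ms: float
    reactivity_mult: float
    f_lf: float
    f_hf: float


@dataclass
class RRISeries:
    """One phase's beat-interval sequence with its session metadata."""

    participant_id: str
    group: str
    visit: int
    phase: str
    intervals_ms: np.ndarray

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)

    @property
    def n_beats(self) -> int:
        return int(self.intervals_ms.size)

    @property
    def duration_s(self) -> float:
        return float(self.intervals_ms.sum() / 1000.0)

    def key(self) -> tuple[str, int, str]:
        return (self.participant_id, self.visit, self.phase)


def simulate_phase_rri(
    state: ParticipantState,
    visit_drift_ms: float,
    phase: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> RRISeries:
    """Generate one phase's RR intervals for a participant/visit.

    Beats are laid down iteratively (t_{k+1} = t_k + RR(t_k)); generation
    stops at the first beat whose cumulative time exceeds the phase duration,
    so the series always spans the phase within one beat.
    """
    if phase not in PHASES:
        raise ConfigError(f"unknown phase {phase!r}; expected one of {PHASES}")
    base = state.base_rri_ms + visit_drift_ms
    a_lf = state.lf_amp_ms
    a_hf = state.hf_amp_ms
    if phase == "stress":
        react = config.reactivity[state.group]
        m = state.reactivity_mult
        base = base * (1.0 + react.rri_frac * m)
        a_hf = max(0.0, a_hf * (1.0 + react.hf_frac * m))
        a_lf = max(0.0, a_lf * (1.0 + react.lf_frac * m))
    if base <= 0:
        raise SimulationError(
            f"non-positive base RR interval ({base:.1f} ms) for "
            f"participant={state.participant_id} phase={phase}"
        )
    phi_lf = rng.uniform(0.0, 2.0 * math.pi)
    phi_hf = rng.uniform(0.0, 2.0 * math.pi)
    duration = config.phase_duration_s
    # Draw noise in blocks; the beat count is not known in advance.
    est = max(16, int(duration * 1000.0 / base * 1.5))
    noise = rng.normal(0.0, config.noise_sd_ms, size=est) if config.noise_sd_ms > 0 else None
    intervals: list[float] = []
    t = 0.0
    k = 0
    w_lf = 2.0 * math.pi * state.f_lf
    w_hf = 2.0 * math.pi * state.f_hf
    while t <= duration:
        rr = base + a_lf * math.sin(w_lf * t + phi_lf) + a_hf * math.sin(w_hf * t + phi_hf)
        if noise is not None:
            if k >= noise.size:
                noise = np.concatenate([noise, rng.normal(0.0, config.noise_sd_ms, size=est)])
            rr += noise[k]
        if rr <= 0:
            raise SimulationError(
                f"non-positive RR interval at t={t:.1f}s for "
                f"participant={state.participant_id} phase={phase} "
                f"(base={base:.1f}, A_LF={a_lf:.1f}, A_HF={a_hf:.1f}, "
                f"noise_sd={config.noise_sd_ms:.1f})"
            )
        intervals.append(rr)
        t += rr / 1000.0
        k += 1
    return RRISeries(state.participant_id, state.group, 0, phase, np.asarray(intervals))


def _draw_participant_state(
    pid: str, group: str, config: CohortConfig, rng: np.random.Generator
) -> ParticipantState:
    eff = config.group_offsets.get(group, GroupEffect())
    base = config.base_rri_ms + eff.rri_offset_ms + rng.normal(0.0, config.subject_sd)
    # independent LF/HF amplitude draws: resting sympathovagal balance
    # differs between people, not just overall HRV magnitude
    amp_lf = eff.amp_scale * max(0.2, rng.normal(1.0, config.amp_subject_sd))
    amp_hf = eff.amp_scale * max(0.2, rng.normal(1.0, config.amp_subject_sd))
    react_mult = max(0.1, rng.normal(1.0, config.reactivity_subject_sd))
    f_lf = config.f_lf + rng.normal(0.0, config.freq_jitter_sd)
    f_hf = config.f_hf + rng.normal(0.0, config.freq_jitter_sd)
    return ParticipantState(pid, group, base, config.lf_amp_ms * amp_lf,
                            config.hf_amp_ms * amp_hf, react_mult, f_lf, f_hf)


def generate_cohort(config: CohortConfig) -> list[RRISeries]:
    """Generate a full cohort of RRI series.

    Per-participant latent state (baseline, amplitudes, reactivity
    multiplier, oscillator frequencies) is drawn once and reused across
    visits; a per-visit drift offset is drawn once and shared by that visit's
    five phases.  Missingness is then applied with ``config.retention_prob``
    (visit 1 always retained).  Fully reproducible from ``config.seed``.
    """
    config.validate()
    series: list[RRISeries] = []
    p_index = 0
    for group in GROUPS:
        n = int(config.n_per_group.get(group, 0))
        for i in range(n):
            pid = f"{group}{i + 1:03d}"
            rng = np.random.default_rng([config.seed, p_index])
            state = _draw_participant_state(pid, group, config, rng)
            for visit in range(1, config.n_visits + 1):
                drift = rng.normal(0.0, config.visit_drift_sd)
                for phase in PHASES:
                    s = simulate_phase_rri(state, drift, phase, config, rng)
                    s.visit = visit
                    series.append(s)
            p_index += 1
    if config.retention_prob < 1.0:
        series = apply_missingness(series, config.retention_prob, seed=config.seed + 999_331)
    return series


def session_keys(cohort: Iterable[RRISeries]) -> list[tuple[str, int]]:
    """Sorted unique (participant, visit) pairs present in the cohort."""
    return sorted({(s.participant_id, s.visit) for s in cohort})


def apply_missingness(
    cohort: Sequence[RRISeries], retention_prob: float, seed: int
) -> list[RRISeries]:
    """Drop whole visits at random, keeping visit 1 for every participant.

    Each participant-visit beyond the first is retained independently with
    ``retention_prob``; all five phases of a dropped visit are removed
    together.
    """
    if not 0.0 <= retention_prob <= 1.0:
        raise ConfigError("retention_prob must lie in [0, 1]")
    if retention_prob >= 1.0:
        return list(cohort)
    rng = np.random.default_rng(seed)
    first_visit = {}
    for pid, visit in session_keys(cohort):
        first_visit.setdefault(pid, visit)
    keep: set[tuple[str, int]] = set()
    for pid, visit in session_keys(cohort):
        if visit == first_visit[pid] or rng.random() < retention_prob:
            keep.add((pid, visit))
    return [s for s in cohort if (s.participant_id, s.visit) in keep]


def subsample_sessions(
    cohort: Sequence[RRISeries], sessions_per_group: Mapping[str, int], seed: int
) -> list[RRISeries]:
    """Retain an exact number of (participant, visit) sessions per group.

    Used to reproduce a fixed retention pattern (e.g. 181/191/278 sessions
    for MDD/PD/HC).  Sessions are sampled uniformly without replacement;
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[tuple[str, int]]] = {g: [] for g in GROUPS}
    seen = set()
    for s in cohort:
        key = (s.participant_id, s.visit)
        if key not in seen:
            seen.add(key)
            by_group.setdefault(s.group, []).append(key)
    keep: set[tuple[str, int]] = set()
    for group, n_keep in sessions_per_group.items():
        sessions = sorted(by_group.get(group, []))
        if n_keep > len(sessions):
            raise ConfigError(
                f"requested {n_keep} sessions for group {group} "
                f"but only {len(sessions)} are available"
            )
        idx = rng.choice(len(sessions), size=int(n_keep), replace=False)
        keep.update(sessions[i] for i in idx)
    return [s for s in cohort if (s.participant_id, s.visit) in keep]
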