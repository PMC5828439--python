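"""Synthetic normal and neuropathic interference-pattern EMG.

Each subject's trace is a superposition of motor-unit action potential
(MUAP) trains: a multiphasic template per motor unit, convolved with a
renewal-process spike train, plus white Gaussian instrumentation noise.
Axonal neuropathy is modeled by its clinical mechanisms: loss of motor
units, reinnervation enlarging and prolonging the surviving units' MUAPs
(with occasional delayed satellite components), and a compensatory
increase in firing rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import DEFAULT_FS, EMGRecording


@dataclass(frozen=True)
class MotorUnitSpec:
    """Shape and firing statistics of one motor unit.

    amplitude: peak of the MUAP template (µV); duration_ms: template
    width; phases: number of alternating-sign lobes (2..8);
    firing_rate: mean discharge rate (Hz); isi_jitter_cv: coefficient of
    variation of the inter-spike intervals.
    """

    amplitude: float
    duration_ms: float
    phases: int
    firing_rate: float
    isi_jitter_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if not 2 <= self.phases <= 8:
            raise ValueError("phases must be in 2..8")
        if self.firing_rate <= 0:
            raise ValueError("firing_rate must be positive")
        if not 0 <= self.isi_jitter_cv < 1:
            raise ValueError("isi_jitter_cv must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated cohort.

    The healthy baseline is a pool of ``n_units_mean`` units per subject
    (Poisson-distributed across subjects) drawn from the base unit
    distributions below. For a neuropathic cohort, a fraction
    ``unit_loss_fraction`` of the pool is lost; survivors are scaled by
    ``reinnervation_gain`` in amplitude and duration, gain a delayed
    satellite component with probability ``satellite_prob``, and fire
    ``rate_compensation`` times faster. Between-subject spread is
    controlled by lognormal subject-level factors on amplitude and rate.
    """

    n_subjects: int = 40
    n_units_mean: int = 50
    neuropathic: bool = False
    unit_loss_fraction: float = 0.0
    reinnervation_gain: float = 1.0
    satellite_prob: float = 0.0
    rate_compensation: float = 1.0
    noise_sd: float = 5.0
    fs: float = DEFAULT_FS
    duration_s: float = 4.0
    seed: int = 0
    # base (healthy) motor-unit distributions
    amplitude_mean_uv: float = 50.0
    amplitude_cv: float = 0.45
    duration_ms_mean: float = 2.2
    duration_ms_cv: float = 0.25
    phases_min: int = 2
    phases_max: int = 5
    rate_mean_hz: float = 20.0
    rate_cv: float = 0.2
    isi_jitter_cv: float = 0.15
    # between-subject lognormal spread of global amplitude / unit count / rate
    subject_amp_sigma: float = 0.35
    subject_rate_sigma: float = 0.2
    # neuropathic disease-severity spectrum: each subject draws a severity
    # s ~ U(severity_range) that scales unit survival ((1-loss)^s),
    # reinnervation gain, rate compensation and satellite probability, so
    # the cohort spans mild to severe axonal loss
    severity_range: tuple[float, float] = (0.35, 1.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.fs > 0 and self.duration_s > 0):
            raise ValueError("fs and duration_s must be positive")
        if not 0 <= self.unit_loss_fraction < 1:
            raise ValueError("unit_loss_fraction must be in [0, 1)")
        if self.reinnervation_gain < 1:
            raise ValueError("reinnervation_gain must be >= 1")
        if not 0 <= self.satellite_prob <= 1:
            raise ValueError("satellite_prob must be in [0, 1]")
        if self.rate_compensation < 1:
            raise ValueError("rate_compensation must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def label(self) -> str:
        return "neuropathic" if self.neuropathic else "normal"


def default_normal_spec(**overrides) -> CohortSpec:
    """Calibrated healthy-control cohort (40 subjects, 4 s at 12.5 kHz)."""
    return CohortSpec(**overrides)


def default_neuropathic_spec(**overrides) -> CohortSpec:
    """Calibrated axonal-neuropathy cohort.

    Most of the motor-unit pool is lost; the surviving units are
    enlarged, prolonged and made polyphasic by reinnervation, most carry
    a satellite component, and firing rates are modestly increased.
    """
    params = dict(
        neuropathic=True,
        unit_loss_fraction=0.92,
        reinnervation_gain=2.0,
        satellite_prob=0.7,
        rate_compensation=1.10,
    )
    params.update(overrides)
    return CohortSpec(**params)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def muap_template(spec: MotorUnitSpec, fs: float) -> np.ndarray:
    """Multiphasic MUAP waveform (µV) sampled at ``fs``.

    Sum of ``phases`` alternating-sign Gaussian lobes spread over the
    template duration, mean-subtracted and rescaled so the absolute peak
    equals ``spec.amplitude``. Support length is ceil(fs * duration_ms / 1000).
    """
    n = int(np.ceil(fs * spec.duration_ms / 1000.0))
    if n < 4:
        raise ValueError(
            f"template of {n} samples is too short; need fs*duration_ms/1000 >= 4"
        )
    if spec.amplitude == 0:
        return np.zeros(n)
    t = np.linspace(0.0, 1.0, n)
    p = spec.phases
    centers = (np.arange(p) + 1.0) / (p + 1.0)
    sigma = 1.0 / (2.5 * (p + 1.0))
    w = np.zeros(n)
    for k, c in enumerate(centers):
        w += (-1.0) ** k * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    w -= w.mean()
    w *= spec.amplitude / np.max(np.abs(w))
    return w


def firing_train(
    rate: float,
    jitter_cv: float,
    duration_s: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Spike times (s) of a truncated-Gaussian renewal process.

    Inter-spike intervals are Gaussian with mean 1/rate and standard
    deviation jitter_cv/rate, floored at 0.2/rate; the first spike falls
    at a uniform fraction of one mean interval. Strictly increasing times
    in [0, duration_s); identical generator state gives identical trains.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    mean_isi = 1.0 / rate
    floor = 0.2 * mean_isi
    times: list[float] = []
    t = float(rng.uniform(0.0, mean_isi))
    while t < duration_s:
        times.append(t)
        isi = rng.normal(mean_isi, jitter_cv * mean_isi)
        t += max(isi, floor)
    return np.asarray(times)


def _draw_units(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[list[tuple[MotorUnitSpec, list[tuple[MotorUnitSpec, float]]]], float]:
    """Per-subject motor-unit pool.

    Returns ``(units, amp_factor)``: (unit, satellites) pairs — each
    satellite a (spec, delay_ms) tuple describing a short, sharp late
    component fired time-locked to the parent unit — plus the subject's
    global amplitude factor (electrode coupling / contraction level),
    which also scales the background-activity noise.
    """
    n_base = int(rng.poisson(spec.n_units_mean)) if spec.n_units_mean > 0 else 0
    if spec.n_units_mean > 0:
        n_base = max(n_base, 1)
    amp_factor = float(np.exp(rng.normal(0.0, spec.subject_amp_sigma)))
    rate_factor = float(np.exp(rng.normal(0.0, spec.subject_rate_sigma)))
    if n_base == 0:
        return [], amp_factor
    n_units = n_base
    severity = 1.0
    gain = spec.reinnervation_gain
    rate_comp = spec.rate_compensation
    sat_prob = spec.satellite_prob
    if spec.neuropathic:
        severity = float(rng.uniform(*spec.severity_range))
        survival = (1.0 - spec.unit_loss_fraction) ** severity
        n_units = int(round(n_base * survival))
        gain = 1.0 + (spec.reinnervation_gain - 1.0) * severity
        rate_comp = 1.0 + (spec.rate_compensation - 1.0) * severity
        # reinnervation complexity (satellites) is present from the mild
        # end of the spectrum on, unlike unit loss which tracks severity
        if n_units == 0:
            raise ValueError(
                "motor-unit pool empty after loss; unit_loss_fraction too high "
                f"for n_units_mean={spec.n_units_mean}"
            )
    units = []
    for _ in range(n_units):
        amp = spec.amplitude_mean_uv * amp_factor * float(
            np.exp(rng.normal(0.0, spec.amplitude_cv))
        )
        dur = spec.duration_ms_mean * max(
            float(rng.normal(1.0, spec.duration_ms_cv)), 0.3
        )
        phases = int(rng.integers(spec.phases_min, spec.phases_max + 1))
        rate = spec.rate_mean_hz * rate_factor * max(
            float(rng.normal(1.0, spec.rate_cv)), 0.3
        )
        if spec.neuropathic:
            # reinnervated units are larger, longer and polyphasic
            amp *= gain
            dur *= gain
            rate *= rate_comp
            phases = min(phases + int(round(2 * severity)), 8)
        unit = MotorUnitSpec(
            amplitude=amp,
            duration_ms=dur,
            phases=phases,
            firing_rate=rate,
            isi_jitter_cv=spec.isi_jitter_cv,
        )
        satellites: list[tuple[MotorUnitSpec, float]] = []
        if spec.neuropathic:
            # late components of immature sprouts: short and sharp, not
            # stretched like the reinnervated main complex
            for _ in range(int(rng.binomial(2, sat_prob))):
                sat = MotorUnitSpec(
                    amplitude=amp * float(rng.uniform(0.3, 0.6)),
                    duration_ms=float(rng.uniform(0.4, 0.9)),
                    phases=int(rng.integers(2, 4)),
                    firing_rate=rate,
                    isi_jitter_cv=spec.isi_jitter_cv,
                )
                satellites.append((sat, float(rng.uniform(5.0, 20.0))))
        units.append((unit, satellites))
    return units, amp_factor


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(subject_index,)))


def synthesize_recording(cohort: CohortSpec, subject_index: int) -> EMGRecording:
    """Simulate one subject's 4-second interference pattern.

    Deterministic in (cohort.seed, subject_index). Each unit's template
    is placed at its spike times and summed; white Gaussian noise is
    added last. The noise models background activity of distant motor
    units, so its SD is ``noise_sd`` scaled by the subject's amplitude
    factor rather than a fixed instrumentation floor.
    """
    rng = _subject_rng(cohort.seed, subject_index)
    n = int(round(cohort.fs * cohort.duration_s))
    signal = np.zeros(n)
    units, amp_factor = _draw_units(cohort, rng)
    for unit, satellites in units:
        template = muap_template(unit, cohort.fs)
        for sat_spec, delay_ms in satellites:
            delay = int(round(delay_ms * cohort.fs / 1000.0))
            sat = muap_template(sat_spec, cohort.fs)
            full = np.zeros(max(template.size, delay + sat.size))
            full[: template.size] += template
            full[delay : delay + sat.size] += sat
            template = full
        spikes = firing_train(unit.firing_rate, unit.isi_jitter_cv, cohort.duration_s, rng)
        idx = np.round(spikes * cohort.fs).astype(int)
        impulses = np.zeros(n)
        np.add.at(impulses, idx[idx < n], 1.0)
        signal += np.convolve(impulses, template)[:n]
    if cohort.noise_sd > 0:
        signal += rng.normal(0.0, cohort.noise_sd * amp_factor, size=n)
    prefix = "P" if cohort.neuropathic else "C"
    return EMGRecording(
        subject_id=f"{prefix}{subject_index:03d}",
        samples=signal,
        fs=cohort.fs,
        label=cohort.label,
    )


def generate_cohorts(normal: CohortSpec, neuropathic: CohortSpec) -> list[EMGRecording]:
    """Simulate both cohorts; one recording per subject, labels set.

    Per-subject randomness derives from each cohort's seed and the
    subject index, so regeneration with the same specs is bit-identical.
    """
    if normal.neuropathic or not neuropathic.neuropathic:
        raise ValueError("cohort specs must be (normal, neuropathic) in that order")
    recs = [synthesize_recording(normal, i) for i in range(normal.n_subjects)]
    recs += [synthesize_recording(neuropathic, i) for i in range(neuropathic.n_subjects)]
    return recs
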