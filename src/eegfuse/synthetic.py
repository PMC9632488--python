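"""Synthetic multichannel EEG with controllable class-separating spectral structure.

Clinical resting-state recordings (prefrontal Fp1/Fpz/Fp2 at 250 Hz) are
emulated by a simple generative model per channel:

    signal = alpha rhythm + 1/f^beta colored noise + white noise

* the alpha rhythm is a mixture of ``n_oscillators`` sinusoids with
  frequencies drawn uniformly inside ``alpha_band`` and random phases; its
  total RMS amplitude is ``alpha_amplitude[class]`` microvolts;
* the colored-noise spectral slope ``pink_exponent[class]`` emulates the
  broadband 1/f background of EEG;
* classes differ only through these per-class parameters, which lets the
  downstream pipeline be tested for recovery of a known, configurable
  spectral contrast (e.g. alpha-power differences between healthy controls
  and depressed subjects, or a monotone severity gradient in 4-class mode).

The generator makes no claim of physiological realism: no eye-blink or
muscle artifacts, no cross-channel connectivity, no non-stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from eegfuse.types import MultichannelRecord

_DEFAULT_CHANNELS = ["Fp1", "Fpz", "Fp2"]

#: oscillators summed to form the alpha rhythm of one channel
N_OSCILLATORS = 5


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    Per-class lists (``alpha_amplitude``, ``pink_exponent``) must have exactly
    ``n_classes`` entries; when left as ``None`` they default to a strong
    monotone alpha-power contrast (3.0 down to 0.5 uV RMS) with a shared
    1/f slope of 1.0 — a deliberately well-separated regime.

    Attributes
    ----------
    sampling_rate : float
        Hz; 250 matches 3-electrode prefrontal acquisition hardware.
    duration : float
        Seconds per record.
    n_channels : int
        Channel count; names default to Fp1/Fpz/Fp2 (then Ch4, Ch5, ...).
    n_classes : int
        2 (control vs depressed) or 4 (severity bands).
    alpha_amplitude : list[float]
        Per-class alpha-rhythm RMS amplitude, microvolts.
    alpha_band : tuple[float, float]
        Low/high edge of the alpha band in Hz; default (8, 12).
    pink_exponent : list[float]
        Per-class 1/f^beta slope of the colored background.
    pink_sd : float
        RMS amplitude of the colored background, microvolts.
    noise_sd : float
        White-noise standard deviation, microvolts.
    n_records_per_class : int
        Cohort size per class.
    master_seed : int
        Single seed from which every record's seed is derived.
    """

    sampling_rate: float = 250.0
    duration: float = 60.0
    n_channels: int = 3
    channel_names: list[str] | None = None
    n_classes: int = 2
    alpha_amplitude: list[float] | None = None
    alpha_band: tuple[float, float] = (8.0, 12.0)
    pink_exponent: list[float] | None = None
    pink_sd: float = 1.0
    noise_sd: float = 1.0
    n_records_per_class: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_classes not in (2, 4):
            raise ValueError(f"n_classes must be 2 or 4, got {self.n_classes}")
        low, high = self.alpha_band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ValueError(
                f"alpha_band must satisfy 0 < low < high < Nyquist, got {self.alpha_band}"
            )
        if self.alpha_amplitude is None:
            # monotone contrast across classes, strongest rhythm = class 0
            self.alpha_amplitude = list(np.linspace(3.0, 0.5, self.n_classes))
        if self.pink_exponent is None:
            self.pink_exponent = [1.0] * self.n_classes
        for name in ("alpha_amplitude", "pink_exponent"):
            vals = getattr(self, name)
            if len(vals) != self.n_classes:
                raise ValueError(
                    f"{name} needs {self.n_classes} entries, got {len(vals)}"
                )
        if self.channel_names is None:
            names = list(_DEFAULT_CHANNELS[: self.n_channels])
            names += [f"Ch{i + 1}" for i in range(len(names), self.n_channels)]
            self.channel_names = names
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))


def record_seed(master_seed: int, class_label: int, record_index: int) -> int:
    """Stable per-record seed derived from (master_seed, class, index).

    Uses :class:`numpy.random.SeedSequence` hashing of the entropy tuple, a
    documented, platform-stable mixing function, so cohorts are reproducible
    regardless of generation order.
    """
    ss = np.random.SeedSequence([int(master_seed), int(class_label), int(record_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _colored_noise(rng: np.random.Generator, n: int, beta: float, sd: float) -> np.ndarray:
    """1/f^beta noise of length ``n`` with RMS ``sd`` (zero-mean, DC removed)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    colored = np.fft.irfft(spectrum * scale, n=n)
    rms = colored.std()
    if rms > 0:
        colored *= sd / rms
    return colored


def generate_record(
    config: SyntheticConfig, class_label: int, seed: int
) -> MultichannelRecord:
    """Generate one record; a pure function of ``(config, class_label, seed)``.

    Each channel is an independent draw of the class's signal model: the
    channels share the per-class spectral parameters but have independent
    oscillator phases/frequencies and noise.
    """
    if not 0 <= class_label < config.n_classes:
        raise ValueError(
            f"class_label {class_label} out of range for n_classes={config.n_classes}"
        )
    rng = np.random.default_rng(seed)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    low, high = config.alpha_band
    amp = config.alpha_amplitude[class_label]
    beta = config.pink_exponent[class_label]

    data = np.empty((config.n_channels, n))
    # each oscillator has amplitude a with var a^2/2; k oscillators sum to
    # variance k*a^2/2, so a = amp*sqrt(2/k) gives total RMS = amp
    osc_amp = amp * np.sqrt(2.0 / N_OSCILLATORS)
    for ch in range(config.n_channels):
        freqs = rng.uniform(low, high, size=N_OSCILLATORS)
        phases = rng.uniform(0, 2 * np.pi, size=N_OSCILLATORS)
        alpha = (osc_amp * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)
        pink = _colored_noise(rng, n, beta, config.pink_sd)
        white = rng.normal(0.0, config.noise_sd, size=n)
        data[ch] = alpha + pink + white

    return MultichannelRecord(
        data=data,
        sampling_rate=config.sampling_rate,
        channel_names=list(config.channel_names),
        subject_id=f"synth-c{class_label}",
        label=class_label,
    )


def generate_cohort(config: SyntheticConfig) -> list[MultichannelRecord]:
    """Generate the full balanced cohort: ``n_classes * n_records_per_class`` records.

    Subject ids are unique (``synth-c<label>-r<index>``); per-record seeds come
    from :func:`record_seed`, so the cohort is a pure function of the config.
    """
    records = []
    for label in range(config.n_classes):
        for idx in range(config.n_records_per_class):
            rec = generate_record(config, label, record_seed(config.master_seed, label, idx))
            rec.subject_id = f"synth-c{label}-r{idx:03d}"
            records.append(rec)
    return records
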