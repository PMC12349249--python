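"""Synthetic gas-sensor array responses for development and testing.

Each simulated recording follows first-order sensor kinetics: a flat
baseline while the chamber holds clean air, an exponential rise toward a
class- and sensor-specific plateau once the analyte is introduced, and an
exponential decay back toward baseline after the gas is switched off —
the canonical rise/plateau/decay morphology of metal-oxide sensor traces.

A "class" (a gas, or a breath category) is a signature over the sensor
array: per-sensor response amplitudes, rise/decay time constants, and onset
delays.  The ``separation`` knob scales how far class signatures spread
apart; ``noise_sd`` adds white measurement noise; ``sample_jitter`` gives
every recording its own amplitude/baseline wobble so that samples within a
class are similar but never identical.  Everything is driven by explicit
seeds, so a dataset is a pure function of its config.

This module is test scaffolding with the statistical structure of real
e-nose data, not a model of sensor physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .signal_io import (DatasetBundle, DialectConfig, RawRecording,
                        preprocess_recording, write_raw_table)

MANIFEST_NAME = "manifest.tsv"


@dataclass
class SynthConfig:
    """Full description of one synthetic dataset.

    Time quantities are in sample points; ``sampling_interval`` converts to
    seconds.  ``sensitivity`` may be given explicitly as an
    [n_classes, n_sensors] amplitude matrix; by default it is drawn from the
    class-signature stream.
    """

    n_classes: int = 4
    samples_per_class: list[int] = field(default_factory=lambda: [10, 10, 10, 10])
    n_sensors: int = 8
    n_points: int = 4000
    sampling_interval: float = 0.002
    gas_on: int = 500
    gas_off: int = 3000
    rise_tau: float = 400.0
    decay_tau: float = 600.0
    baseline: float = 0.1
    amplitude: float = 1.0
    noise_sd: float = 0.02
    drift_sd: float = 0.0
    separation: float = 1.0
    sample_jitter: float = 0.05
    sensitivity: np.ndarray | None = None
    class_prefix: str = "gas"
    role: str = "meta_test"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.samples_per_class, int):
            self.samples_per_class = [self.samples_per_class] * self.n_classes
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must list one size per class")
        if not (0 <= self.gas_on < self.gas_off <= self.n_points):
            raise ValueError("need 0 <= gas_on < gas_off <= n_points")
        if self.noise_sd < 0 or self.separation < 0:
            raise ValueError("noise_sd and separation must be non-negative")

    @property
    def class_names(self) -> list[str]:
        return [f"{self.class_prefix}_{c:02d}" for c in range(self.n_classes)]


@dataclass(frozen=True)
class ClassSignature:
    """Per-sensor response profile of one class."""

    amplitude: np.ndarray   # [n_sensors]
    rise_tau: np.ndarray    # [n_sensors]
    decay_tau: np.ndarray   # [n_sensors]
    onset: np.ndarray       # [n_sensors] absolute point index


def _class_signatures(config: SynthConfig) -> list[ClassSignature]:
    """Draw the class signatures; ``separation`` scales every between-class
    difference, so separation 0 collapses all classes onto one profile."""
    device_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    base_profile = device_rng.uniform(0.5, 1.0, size=config.n_sensors)
    sigs = []
    gas_span = config.gas_off - config.gas_on
    for c in range(config.n_classes):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101, c]))
        amp_d = rng.uniform(-0.3, 0.3, config.n_sensors)
        tau_r = rng.uniform(-0.5, 0.5, config.n_sensors)
        tau_d = rng.uniform(-0.5, 0.5, config.n_sensors)
        delay = rng.uniform(0.0, 0.08, config.n_sensors)
        if config.sensitivity is not None:
            amplitude = np.asarray(config.sensitivity, float)[c]
        else:
            amplitude = config.amplitude * np.maximum(
                base_profile + config.separation * amp_d, 0.05)
        sigs.append(ClassSignature(
            amplitude=amplitude,
            rise_tau=config.rise_tau * np.exp(0.6 * config.separation * tau_r),
            decay_tau=config.decay_tau * np.exp(0.6 * config.separation * tau_d),
            onset=(config.gas_on
                   + np.round(config.separation * delay * gas_span).astype(int)),
        ))
    return sigs


def _render_curve(config: SynthConfig, sig: ClassSignature,
                  rng: np.random.Generator) -> np.ndarray:
    """One noisy recording [n_points, n_sensors] for a class signature."""
    t = np.arange(config.n_points, dtype=float)[:, None]
    onset = sig.onset[None, :].astype(float)
    scale = rng.normal(1.0, config.sample_jitter)                     # breath "strength"
    amp = sig.amplitude[None, :] * scale * rng.normal(1.0, config.sample_jitter,
                                                      config.n_sensors)[None, :]
    baseline = config.baseline * (1.0 + rng.normal(0.0, config.sample_jitter,
                                                   config.n_sensors))[None, :]
    rise = np.clip(t - onset, 0.0, None)
    response = amp * (1.0 - np.exp(-rise / sig.rise_tau[None, :]))
    plateau = amp * (1.0 - np.exp(-(config.gas_off - onset) / sig.rise_tau[None, :]))
    after = t >= config.gas_off
    decay = plateau * np.exp(-(t - config.gas_off) / sig.decay_tau[None, :])
    curve = baseline + np.where(after, decay, response)
    if config.noise_sd > 0:
        curve = curve + rng.normal(0.0, config.noise_sd, curve.shape)
    if config.drift_sd > 0:
        slope = rng.normal(0.0, config.drift_sd, config.n_sensors)[None, :]
        curve = curve + slope * (t / config.n_points)
    return curve


def generate_raw(config: SynthConfig) -> Iterator[RawRecording]:
    """Yield the dataset's raw recordings one at a time (deterministic in
    ``config.seed``; class order, then sample order)."""
    signatures = _class_signatures(config)
    names = config.class_names
    for c, (sig, n_samples) in enumerate(zip(signatures, config.samples_per_class)):
        for i in range(n_samples):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 555, c, i]))
            yield RawRecording(_render_curve(config, sig, rng),
                               sampling_interval=config.sampling_interval,
                               label=names[c], source=config.role)


def generate_dataset(config: SynthConfig) -> DatasetBundle:
    """Generate and fully preprocess a dataset into a :class:`DatasetBundle`
    of normalized [240, n_sensors] samples."""
    samples = [preprocess_recording(rec) for rec in generate_raw(config)]
    return DatasetBundle(samples, classes=config.class_names, role=config.role)


# ---------------------------------------------------------------------------
# presets mirroring the two acquisition regimes
# ---------------------------------------------------------------------------

def metatrain_config(n_classes: int = 11, samples_per_class: int | Sequence[int] = 20,
                     separation: float = 1.0, noise_sd: float = 0.02,
                     seed: int = 0, **overrides) -> SynthConfig:
    """Long wind-tunnel-like recordings: 40,000 points at 10 ms (400 s),
    gas on from 20 s to 200 s.  Default 11 gas classes."""
    spc = list(samples_per_class) if not isinstance(samples_per_class, int) \
        else [samples_per_class] * n_classes
    return SynthConfig(
        n_classes=n_classes, samples_per_class=spc, n_points=40_000,
        sampling_interval=0.01, gas_on=2_000, gas_off=20_000,
        rise_tau=1_500.0, decay_tau=3_000.0, separation=separation,
        noise_sd=noise_sd, class_prefix="gas", role="meta_train", seed=seed,
        **overrides)


def metatest_config(samples_per_class: Sequence[int] = (40, 8, 20, 10),
                    separation: float = 1.0, noise_sd: float = 0.02,
                    seed: int = 1, **overrides) -> SynthConfig:
    """Short breath-like recordings: 4,000 points over 8 s, with the
    unequal class sizes (40/8/20/10) of a small clinical breath panel."""
    spc = list(samples_per_class)
    return SynthConfig(
        n_classes=len(spc), samples_per_class=spc, n_points=4_000,
        sampling_interval=0.002, gas_on=500, gas_off=3_000,
        rise_tau=400.0, decay_tau=600.0, separation=separation,
        noise_sd=noise_sd, class_prefix="breath", role="meta_test", seed=seed,
        **overrides)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(recordings: Iterable[RawRecording], directory: str | Path,
                  dialect: DialectConfig | None = None) -> Path:
    """Write raw recordings as delimited text readable by
    :func:`relnose.signal_io.read_raw_table`; returns the manifest path."""
    dialect = dialect or DialectConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        fname = f"raw_{i:05d}.csv"
        write_raw_table(rec, directory / fname, dialect)
        rows.append((fname, rec.label, rec.source, rec.sampling_interval))
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=["file", "label", "source", "sampling_interval"]
                 ).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_fixture(directory: str | Path,
                 dialect: DialectConfig | None = None) -> Iterator[RawRecording]:
    """Lazily read back a fixture directory written by :func:`write_fixture`."""
    from .signal_io import read_raw_table
    directory = Path(directory)
    manifest = pd.read_csv(directory / MANIFEST_NAME, sep="\t")
    for _, row in manifest.iterrows():
        yield read_raw_table(directory / row["file"], dialect,
                             label=str(row["label"]), source=str(row["source"]),
                             sampling_interval=float(row["sampling_interval"]))
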