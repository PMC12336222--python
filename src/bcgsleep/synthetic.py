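"""Synthetic BCG recordings and planted feature tables.

Real ballistocardiogram sleep datasets are rarely shareable, so every
downstream stage of this package is exercised against simulated data with
exact ground truth: heartbeat pulse trains with the characteristic
H-I-J-K-L morphology at stage-dependent RR statistics, an additive
respiratory baseline, broadband noise, and per-epoch stage labels with a
realistic five-class imbalance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

EPOCH_SECONDS = 30.0

#: Canonical stage label order used throughout the package.
STAGES = ("W", "REM", "N1", "N2", "N3")

#: Reference five-stage epoch distribution of a full-night BCG sleep study
#: (fractions of 10,201 scored 30-s epochs), in STAGES order.
STAGE_COUNTS = {"W": 1082, "REM": 2183, "N1": 442, "N2": 4414, "N3": 2080}
STAGE_PROPORTIONS = {k: v / 10201.0 for k, v in STAGE_COUNTS.items()}


@dataclass(frozen=True)
class StageProfile:
    """Stage-conditional generative parameters for the RR/respiration model.

    ``lf_amp`` / ``hf_amp`` are dimensionless modulation depths of the RR
    series at ~0.1 Hz (sympathetic, LF) and at the respiratory rate
    (vagal / RSA, HF).
    """

    stage: str
    rr_mean: float  # s
    rr_sd: float  # s
    resp_rate: float  # Hz
    lf_amp: float = 0.0
    hf_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not 0.4 <= self.rr_mean <= 1.4:
            raise ValueError("rr_mean must lie in [0.4, 1.4] s")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be >= 0")
        if not 0.1 <= self.resp_rate <= 0.5:
            raise ValueError("resp_rate must lie in [0.1, 0.5] Hz")


# Deep sleep: slow, regular heart rate with strong respiratory sinus
# arrhythmia; REM: faster, more variable, LF-dominated; wake in between.
DEFAULT_PROFILES: dict[str, StageProfile] = {
    "W": StageProfile("W", 0.80, 0.05, 0.30, lf_amp=0.05, hf_amp=0.02),
    "REM": StageProfile("REM", 0.85, 0.06, 0.28, lf_amp=0.08, hf_amp=0.02),
    "N1": StageProfile("N1", 0.95, 0.04, 0.27, lf_amp=0.04, hf_amp=0.03),
    "N2": StageProfile("N2", 1.00, 0.03, 0.25, lf_amp=0.03, hf_amp=0.04),
    "N3": StageProfile("N3", 1.05, 0.02, 0.22, lf_amp=0.01, hf_amp=0.06),
}


@dataclass
class BCGRecording:
    """A raw amplitude series plus the ground truth that generated it."""

    samples: np.ndarray
    fs: float
    truth_j_times: np.ndarray | None = None
    truth_breath_times: np.ndarray | None = None
    stages: list[str] | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def n_epochs(self) -> int:
        return int(len(self.samples) / (self.fs * EPOCH_SECONDS))

    def save(self, prefix: str | Path, seed: int | None = None) -> None:
        """Write samples as two-column CSV plus a JSON sidecar and truth CSVs."""
        prefix = Path(prefix)
        t = np.arange(len(self.samples)) / self.fs
        pd.DataFrame({"time_s": t, "amplitude": self.samples}).to_csv(
            prefix.with_suffix(".csv"), index=False
        )
        sidecar = {"fs": self.fs, "seed": seed, "n_epochs": self.n_epochs}
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        if self.stages is not None:
            pd.DataFrame(
                {"epoch_index": range(len(self.stages)), "stage": self.stages}
            ).to_csv(prefix.parent / (prefix.name + "_hypnogram.csv"), index=False)
        events = []
        if self.truth_j_times is not None:
            events += [(t, "J") for t in self.truth_j_times]
        if self.truth_breath_times is not None:
            events += [(t, "breath") for t in self.truth_breath_times]
        if events:
            events.sort()
            pd.DataFrame(events, columns=["event_time_s", "type"]).to_csv(
                prefix.parent / (prefix.name + "_truth.csv"), index=False
            )

    @classmethod
    def load(cls, prefix: str | Path) -> "BCGRecording":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        rec = cls(samples=df["amplitude"].to_numpy(), fs=float(meta["fs"]))
        hyp = prefix.parent / (prefix.name + "_hypnogram.csv")
        if hyp.exists():
            rec.stages = pd.read_csv(hyp)["stage"].tolist()
        truth = prefix.parent / (prefix.name + "_truth.csv")
        if truth.exists():
            tdf = pd.read_csv(truth)
            rec.truth_j_times = tdf.loc[tdf["type"] == "J", "event_time_s"].to_numpy()
            rec.truth_breath_times = tdf.loc[
                tdf["type"] == "breath", "event_time_s"
            ].to_numpy()
        return rec


def _heartbeat_template(fs: float, width: float = 0.12, amplitude: float = 1.0):
    """Mexican-hat-like pulse whose dominant positive deflection is the J wave.

    A Gaussian-windowed cosine produces the small flanking positive lobes
    (H, L) and the two negative troughs (I, K) around the central J peak.
    """
    sigma = width / 2.0
    half = int(round(3 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    f_osc = 0.85 / width  # I/K troughs near +/- width/1.7
    pulse = amplitude * np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2 * np.pi * f_osc * t)
    return pulse, half


def generate_hypnogram(
    n_epochs: int,
    proportions: dict[str, float] | None = None,
    mean_run: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw a per-epoch stage sequence with realistic runs and exact shares.

    Stage quotas are apportioned by largest remainder so the empirical
    distribution matches ``proportions`` to within one epoch per stage, then
    each quota is split into runs with geometric lengths (mean ``mean_run``
    epochs, i.e. a 0.9 self-transition probability) and the runs are shuffled.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    props = proportions or STAGE_PROPORTIONS
    stages = list(props)
    target = np.array([props[s] for s in stages], dtype=float)
    target = target / target.sum()
    quota = np.floor(target * n_epochs).astype(int)
    rem = target * n_epochs - quota
    for i in np.argsort(-rem)[: n_epochs - quota.sum()]:
        quota[i] += 1
    runs: list[tuple[str, int]] = []
    p_exit = 1.0 / mean_run
    for s, q in zip(stages, quota):
        left = int(q)
        while left > 0:
            run = min(int(rng.geometric(p_exit)), left)
            runs.append((s, run))
            left -= run
    order = rng.permutation(len(runs))
    out: list[str] = []
    for i in order:
        s, n = runs[i]
        out.extend([s] * n)
    return out


def generate_recording(
    profiles: dict[str, StageProfile] | None = None,
    hypnogram: Sequence[str] | None = None,
    fs: float = 100.0,
    seed: int | np.random.Generator = 0,
    noise_sigma: float = 0.05,
    heartbeat_amplitude: float = 1.0,
    respiration_amplitude: float = 0.3,
    respiratory_beat_modulation: float = 0.2,
) -> BCGRecording:
    """Synthesize a BCG trace for a hypnogram of 30-s epochs.

    The trace is a sum of heartbeat pulses centred at cumulative RR times
    drawn from each epoch's :class:`StageProfile` (RR modulated by a ~0.1 Hz
    LF sinusoid and by a sinusoid at the respiratory rate), plus a
    respiratory baseline at the stage's breathing rate and additive white
    Gaussian noise.  True J-peak and breath-peak times are recorded exactly.
    """
    if hypnogram is None or len(hypnogram) == 0:
        raise ValueError("hypnogram must be non-empty")
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz")
    profiles = profiles or DEFAULT_PROFILES
    for s in set(hypnogram):
        p = profiles[s]
        if p.rr_mean - 3 * p.rr_sd <= 0:
            raise ValueError(
                f"profile {s}: rr_mean - 3*rr_sd <= 0 would allow nonpositive intervals"
            )
    rng = np.random.default_rng(seed)
    n_epochs = len(hypnogram)
    n_samples = int(round(n_epochs * EPOCH_SECONDS * fs))
    duration = n_samples / fs

    # --- heartbeat times: cumulative RR draws, profile switching per epoch
    j_times: list[float] = []
    t = float(rng.uniform(0.1, 0.5))  # first beat offset
    while t < duration:
        j_times.append(t)
        prof = profiles[hypnogram[min(int(t // EPOCH_SECONDS), n_epochs - 1)]]
        rr = prof.rr_mean * (
            1.0
            + prof.lf_amp * np.sin(2 * np.pi * 0.1 * t)
            + prof.hf_amp * np.sin(2 * np.pi * prof.resp_rate * t)
        )
        if prof.rr_sd > 0:
            rr += rng.normal(0.0, prof.rr_sd)
        rr = max(rr, 0.25)  # physiological floor; unreachable for valid profiles
        t += rr
    j_times_arr = np.asarray(j_times)

    # --- respiratory baseline with continuous phase across stage changes
    tgrid = np.arange(n_samples) / fs
    inst_rate = np.empty(n_samples)
    for i, s in enumerate(hypnogram):
        lo = int(i * EPOCH_SECONDS * fs)
        hi = int((i + 1) * EPOCH_SECONDS * fs)
        inst_rate[lo:hi] = profiles[s].resp_rate
    phase = 2 * np.pi * np.cumsum(inst_rate) / fs
    resp = respiration_amplitude * np.sin(phase)
    # breath peaks: sine maxima, phase = pi/2 + 2*pi*k
    k = np.arange(0, int(np.ceil(phase[-1] / (2 * np.pi))) + 1)
    targets = np.pi / 2 + 2 * np.pi * k
    idx = np.searchsorted(phase, targets)
    idx = idx[(idx > 0) & (idx < n_samples)]
    breath_times = tgrid[idx]

    # --- assemble samples
    samples = resp.copy() if respiration_amplitude != 0 else np.zeros(n_samples)
    if heartbeat_amplitude != 0:
        pulse, half = _heartbeat_template(fs, amplitude=heartbeat_amplitude)
        for jt in j_times_arr:
            c = int(round(jt * fs))
            amp = 1.0 + respiratory_beat_modulation * np.sin(phase[min(c, n_samples - 1)])
            lo, hi = c - half, c + half + 1
            plo, phi_ = max(0, -lo), len(pulse) - max(0, hi - n_samples)
            samples[max(0, lo) : min(hi, n_samples)] += amp * pulse[plo:phi_]
    if noise_sigma > 0:
        samples = samples + rng.normal(0.0, noise_sigma, n_samples)

    return BCGRecording(
        samples=samples,
        fs=fs,
        truth_j_times=j_times_arr,
        truth_breath_times=breath_times,
        stages=list(hypnogram),
    )


def snr_noise_sigma(snr_db: float, fs: float = 100.0, rr_mean: float = 0.9,
                    heartbeat_amplitude: float = 1.0) -> float:
    """Noise SD giving roughly the requested SNR against the heartbeat train power."""
    pulse, _ = _heartbeat_template(fs, amplitude=heartbeat_amplitude)
    # mean signal power of one pulse repeated every rr_mean seconds
    p_sig = np.sum(pulse**2) / (rr_mean * fs)
    return float(np.sqrt(p_sig / 10 ** (snr_db / 10.0)))


@dataclass(frozen=True)
class PlantedFeatureSpec:
    """Recipe for a feature table with known informative columns."""

    n_samples: int = 2000
    n_informative: int = 10
    n_redundant: int = 20
    n_noise: int = 200
    class_proportions: tuple[float, ...] = tuple(
        STAGE_PROPORTIONS[s] for s in STAGES
    )
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if min(self.n_redundant, self.n_noise, self.n_samples) < 0:
            raise ValueError("counts must be >= 0")
        p = np.asarray(self.class_proportions)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be >= 0 and sum to 1")


def generate_feature_table(spec: PlantedFeatureSpec):
    """Build an epochs x features table with planted class signal.

    Returns ``(table, informative_names)`` where ``table`` is a DataFrame
    whose last column ``stage`` holds labels drawn from
    ``spec.class_proportions``.  Informative columns have class-dependent
    means separated by ``effect_size`` within-class SDs; redundant columns
    are noisy linear copies of informative ones; noise columns carry no
    class signal.
    """
    from itertools import combinations

    rng = np.random.default_rng(spec.seed)
    labels_idx = rng.choice(len(STAGES), size=spec.n_samples, p=spec.class_proportions)
    labels = [STAGES[i] for i in labels_idx]

    cols = {}
    informative = [f"inf_{i:02d}" for i in range(spec.n_informative)]
    # each informative feature carries one class-pair contrast (10 pairs for
    # 5 classes), so every feature holds non-substitutable information
    pairs = list(combinations(range(len(STAGES)), 2))
    for i, name in enumerate(informative):
        a, b = pairs[i % len(pairs)]
        mu = np.zeros(len(STAGES))
        mu[a], mu[b] = spec.effect_size / 2, -spec.effect_size / 2
        cols[name] = mu[labels_idx] + rng.normal(0.0, 1.0, spec.n_samples)
    for j in range(spec.n_redundant):
        src = informative[j % spec.n_informative]
        a = rng.uniform(0.5, 2.0) * rng.choice([-1, 1])
        cols[f"red_{j:02d}"] = a * cols[src] + rng.normal(0.0, 1.0, spec.n_samples)
    for j in range(spec.n_noise):
        cols[f"noise_{j:03d}"] = rng.normal(0.0, 1.0, spec.n_samples)
    table = pd.DataFrame(cols)
    table["stage"] = labels
    return table, informative
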