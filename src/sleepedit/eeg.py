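"""Vigilance-state-resolved EEG/EMG spectral analysis.

The analysis chain mirrors standard rodent sleep-EEG practice: zero-phase
band-pass filtering and decimation to 128 Hz, per-4-s-epoch Welch spectra at
0.25 Hz resolution, rebinning into a hybrid 0.5/1 Hz scheme, rule-based
vigilance-state scoring from EMG tone and the theta/delta ratio, sleep
architecture summaries on the 12:12 light/dark cycle, two spectral
normalization schemes, band powers, and the slow-wave-activity (SWA)
timecourse referenced to ZT8-12 of recording day 1.

Conventions
-----------
* Epochs are 4 s. A 4-s epoch at 128 Hz is exactly 512 samples, so a Welch
  estimate with 0.25 Hz resolution and no overlap degenerates to a single
  Hann-windowed periodogram per epoch.
* Spectral bin labels are upper edges: the 0.5 Hz bin labeled ``f`` averages
  the quarter-bins at ``f-0.25`` and ``f``; the 1 Hz bin labeled ``g``
  averages quarter-bins ``g-0.75 ... g``. Labels run 0.5..5.0 (10 bins) then
  6..25 (20 bins), covering quarter-bins 0.25-25.0 Hz.
* Zeitgeber time (ZT): ZT0 = lights on. Light phase is ZT0-12, dark ZT12-24.
  Recordings are assumed to start at ZT0 unless ``start_zt`` says otherwise.
* Transition-to-REM (TREM) epochs count toward REM *durations* but are
  excluded from NREM and REM *spectra*.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

EPOCH_S = 4.0
STATES = ("WAKE", "NREM", "REM", "TREM")
#: states whose epochs may contribute to state-resolved spectra
SPECTRAL_STATES = ("WAKE", "NREM", "REM")
PSD_FS = 128.0
PSD_NPERSEG = 512  # 4 s at 128 Hz -> 0.25 Hz resolution


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel EEG + EMG signal with an epoch-aligned, ZT-anchored axis.

    Parameters
    ----------
    eeg
        Mapping of channel name (``frontal``/``parietal``) to sample array.
    emg
        EMG sample array, same length as the EEG channels.
    fs
        Sampling rate in Hz.
    start_zt
        Zeitgeber time of the first sample, in hours (0 = lights on).
    """

    eeg: Mapping[str, np.ndarray]
    emg: np.ndarray
    fs: float
    start_zt: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.eeg:
            raise ValueError("at least one EEG channel is required")
        lengths = {len(v) for v in self.eeg.values()} | {len(self.emg)}
        if len(lengths) != 1:
            raise ValueError("EEG and EMG channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.emg)

    @property
    def n_epochs(self) -> int:
        return int(self.n_samples // (self.fs * EPOCH_S))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Write signals as CSV with a ``# fs=... start_zt=...`` header line."""
        df = pd.DataFrame({name: x for name, x in self.eeg.items()})
        df["emg"] = self.emg
        with open(path, "w") as fh:
            fh.write(f"# fs={self.fs} start_zt={self.start_zt}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Recording":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(
                    "signal CSV must start with a '# fs=... start_zt=...' line"
                )
            meta = dict(kv.split("=") for kv in header[1:].split())
            df = pd.read_csv(fh)
        emg = df.pop("emg").to_numpy(float)
        eeg = {c: df[c].to_numpy(float) for c in df.columns}
        return cls(eeg=eeg, emg=emg, fs=float(meta["fs"]),
                   start_zt=float(meta.get("start_zt", 0.0)))

    @classmethod
    def from_edf(cls, path: str | Path, emg_channel: str = "emg",
                 start_zt: float = 0.0) -> "Recording":
        """Read an EDF file (requires :mod:`mne`)."""
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data()
        names = [n.lower() for n in raw.ch_names]
        if emg_channel.lower() not in names:
            raise ValueError(f"EMG channel {emg_channel!r} not found in EDF")
        emg_i = names.index(emg_channel.lower())
        eeg = {raw.ch_names[i]: data[i] for i in range(len(names)) if i != emg_i}
        return cls(eeg=eeg, emg=data[emg_i], fs=float(raw.info["sfreq"]),
                   start_zt=start_zt)


def _phase_and_day(n_epochs: int, start_zt: float,
                   lights_off_zt: float = 12.0) -> tuple[np.ndarray, np.ndarray]:
    zt = (start_zt + np.arange(n_epochs) * EPOCH_S / 3600.0)
    day = (zt // 24).astype(int)
    zt_mod = zt % 24.0
    phase = np.where(zt_mod < lights_off_zt, "light", "dark")
    return phase, day


@dataclass
class Hypnogram:
    """Per-4-s-epoch vigilance state sequence with light/dark phase labels."""

    states: np.ndarray
    phase: np.ndarray
    day_index: np.ndarray
    start_zt: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="U4")
        self.phase = np.asarray(self.phase, dtype="U5")
        self.day_index = np.asarray(self.day_index, dtype=int)
        if not (len(self.states) == len(self.phase) == len(self.day_index)):
            raise ValueError("states, phase, and day_index must align")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown vigilance states: {sorted(bad)}")

    @classmethod
    def from_states(cls, states: Sequence[str], start_zt: float = 0.0) -> "Hypnogram":
        """Build a hypnogram from a state sequence; phases follow the 12:12 cycle."""
        states = np.asarray(states, dtype="U4")
        phase, day = _phase_and_day(len(states), start_zt)
        return cls(states=states, phase=phase, day_index=day, start_zt=start_zt)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def zt(self) -> np.ndarray:
        """ZT (hours, mod 24) of each epoch start."""
        return (self.start_zt + np.arange(len(self)) * EPOCH_S / 3600.0) % 24.0

    @property
    def hours(self) -> np.ndarray:
        """Elapsed hours since recording start per epoch."""
        return np.arange(len(self)) * EPOCH_S / 3600.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "epoch_index": np.arange(len(self)),
            "state": self.states,
            "zt_phase": self.phase,
            "day": self.day_index,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, start_zt: float = 0.0) -> "Hypnogram":
        df = pd.read_csv(path)
        if "day" in df.columns and "zt_phase" in df.columns:
            return cls(states=df["state"].to_numpy(), phase=df["zt_phase"].to_numpy(),
                       day_index=df["day"].to_numpy(), start_zt=start_zt)
        return cls.from_states(df["state"].to_numpy(), start_zt=start_zt)


@dataclass
class RawSpectra:
    """Per-epoch power spectral density at the native 0.25 Hz resolution."""

    freqs: np.ndarray            # Hz, 0 .. fs/2 in 0.25 Hz steps
    power: np.ndarray            # epoch x frequency
    channel: str = ""

    def __post_init__(self) -> None:
        if self.power.ndim != 2 or self.power.shape[1] != len(self.freqs):
            raise ValueError("power must be epoch x frequency")


def default_bin_labels() -> np.ndarray:
    """30 hybrid bin labels: 0.5..5.0 in 0.5 Hz steps, then 6..25 in 1 Hz steps."""
    return np.concatenate([np.arange(0.5, 5.01, 0.5), np.arange(6.0, 25.01, 1.0)])


@dataclass
class BinnedSpectra:
    """Epoch x bin power matrix under the hybrid 0.5/1 Hz bin scheme."""

    power: np.ndarray
    bin_labels: np.ndarray = field(default_factory=default_bin_labels)
    channel: str = ""

    def __post_init__(self) -> None:
        self.bin_labels = np.asarray(self.bin_labels, dtype=float)
        if self.power.ndim != 2 or self.power.shape[1] != len(self.bin_labels):
            raise ValueError("power must be epoch x bin")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.power, columns=[f"{b:g}" for b in self.bin_labels])
        df.insert(0, "epoch", np.arange(self.n_epochs))
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class BandDef:
    """A contiguous frequency band addressed in bin-label space (inclusive)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band lo must be < hi")

    def bin_mask(self, labels: np.ndarray) -> np.ndarray:
        return (labels >= self.lo) & (labels <= self.hi)


#: canonical bands: SWA delta (abstract definition), the narrower delta used
#: for the group contrast, sigma, and theta.
BANDS: dict[str, BandDef] = {
    "delta_swa": BandDef("delta_swa", 1.0, 4.5),
    "delta_sig": BandDef("delta_sig", 1.5, 4.5),
    "sigma": BandDef("sigma", 10.0, 15.0),
    "theta": BandDef("theta", 6.0, 9.0),
}


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(raw: Recording,
               eeg_band: tuple[float, float] = (0.1, 48.0),
               emg_band: tuple[float, float] = (10.0, 30.0),
               fs_out: float = 128.0,
               order: int = 4) -> Recording:
    """Zero-phase band-pass filtering and anti-aliased decimation.

    Each EEG channel is filtered with a 4th-order Butterworth band-pass
    (forward-backward, so zero phase) over ``eeg_band``; the EMG with
    ``emg_band``; all channels are then decimated to ``fs_out``.
    """
    fs_in = raw.fs
    for band in (eeg_band, emg_band):
        if band[1] >= fs_in / 2:
            raise ValueError(f"band edge {band[1]} Hz is at/above Nyquist "
                             f"({fs_in / 2} Hz)")
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"fs_out={fs_out} must divide fs_in={fs_in}")
    q = int(round(q))

    def run(x: np.ndarray, band: tuple[float, float]) -> np.ndarray:
        sos = signal.butter(order, band, btype="bandpass", fs=fs_in, output="sos")
        y = signal.sosfiltfilt(sos, x)
        if q > 1:
            y = signal.decimate(y, q, ftype="fir", zero_phase=True)
        return y

    eeg = {name: run(x, eeg_band) for name, x in raw.eeg.items()}
    emg = run(raw.emg, emg_band)
    return Recording(eeg=eeg, emg=emg, fs=fs_out, start_zt=raw.start_zt)


# ---------------------------------------------------------------------------
# epoch spectra
# ---------------------------------------------------------------------------

def epoch_psd(rec: Recording, channel: str = "parietal",
              epoch_s: float = EPOCH_S) -> RawSpectra:
    """Per-4-s-epoch Welch PSD at 0.25 Hz resolution.

    With 4-s epochs at 128 Hz and 0.25 Hz resolution the Welch estimate uses
    a single non-overlapping Hann-windowed 512-sample segment per epoch, i.e.
    one windowed periodogram per epoch. The trailing partial epoch is dropped.
    """
    if abs(rec.fs - PSD_FS) > 1e-9:
        raise ValueError(
            f"epoch_psd requires fs={PSD_FS:g} Hz (got {rec.fs:g}); "
            "run preprocess() first")
    if channel not in rec.eeg:
        raise ValueError(f"channel {channel!r} not in recording "
                         f"({sorted(rec.eeg)})")
    n = int(round(epoch_s * rec.fs))
    x = np.asarray(rec.eeg[channel], float)
    n_ep = len(x) // n
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    seg = x[: n_ep * n].reshape(n_ep, n)
    freqs, pxx = signal.welch(seg, fs=rec.fs, window="hann", nperseg=n,
                              noverlap=0, detrend=False, scaling="density",
                              axis=-1)
    return RawSpectra(freqs=freqs, power=pxx, channel=channel)


def rebin(raw: RawSpectra) -> BinnedSpectra:
    """Average 0.25 Hz quarter-bins into the hybrid 0.5/1 Hz scheme.

    Pairs of quarter-bins become 0.5 Hz bins labeled 0.5..5.0; groups of four
    quarter-bins spanning 5.25-25 Hz become 1 Hz bins labeled 6..25.
    """
    freqs = np.asarray(raw.freqs, float)
    df = np.diff(freqs)
    if len(freqs) < 2 or not np.allclose(df, 0.25):
        raise ValueError("input spectra must have 0.25 Hz resolution")
    if freqs[-1] < 25.0 - 1e-9 or freqs[0] > 0.25 + 1e-9:
        raise ValueError("input spectra must cover 0.25-25 Hz")
    labels = default_bin_labels()
    out = np.empty((raw.power.shape[0], len(labels)))

    def qidx(f: float) -> int:
        i = int(round((f - freqs[0]) / 0.25))
        if not np.isclose(freqs[i], f):
            raise ValueError(f"quarter-bin {f} Hz missing from input grid")
        return i

    for j, lab in enumerate(labels):
        width = 0.5 if lab <= 5.0 else 1.0
        members = [qidx(lab - k * 0.25) for k in range(int(width / 0.25))]
        out[:, j] = raw.power[:, members].mean(axis=1)
    return BinnedSpectra(power=out, bin_labels=labels, channel=raw.channel)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreThresholds:
    """Rule-based scorer thresholds.

    WAKE when epoch EMG RMS exceeds ``k_emg`` x the recording-median EMG RMS;
    otherwise REM when theta/delta >= ``rem_ratio``, NREM when the ratio
    <= ``nrem_ratio``, and TREM (mixed slow-wave/theta) in between.
    """

    k_emg: float = 1.5
    rem_ratio: float = 2.0
    nrem_ratio: float = 1.0
    theta_band: BandDef = BANDS["theta"]
    delta_band: BandDef = BANDS["delta_swa"]


def score(rec: Recording, thresholds: ScoreThresholds | None = None,
          channel: str = "parietal") -> Hypnogram:
    """Rule-based vigilance-state scoring from EMG tone and theta/delta ratio.

    A simple, transparent stand-in for machine-learning sleep scorers: high
    EMG tone marks wakefulness; among low-EMG epochs, rhythmic theta marks
    REM, dominant slow waves mark NREM, and mixed epochs are transitions to
    REM (TREM).
    """
    thr = thresholds or ScoreThresholds()
    spectra = rebin(epoch_psd(rec, channel=channel))
    n = int(round(EPOCH_S * rec.fs))
    n_ep = spectra.n_epochs
    emg = np.asarray(rec.emg, float)[: n_ep * n].reshape(n_ep, n)
    emg_rms = np.sqrt(np.mean(emg ** 2, axis=1))
    med = np.median(emg_rms)

    th = spectra.power[:, thr.theta_band.bin_mask(spectra.bin_labels)].mean(axis=1)
    de = spectra.power[:, thr.delta_band.bin_mask(spectra.bin_labels)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(de > 0, th / de, np.inf)

    states = np.full(n_ep, "TREM", dtype="U4")
    states[ratio >= thr.rem_ratio] = "REM"
    states[ratio <= thr.nrem_ratio] = "NREM"
    states[emg_rms > thr.k_emg * med] = "WAKE"
    return Hypnogram.from_states(states, start_zt=rec.start_zt)


# ---------------------------------------------------------------------------
# sleep architecture
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSummary:
    """Minutes per state/phase/day plus sleep totals.

    ``state_minutes`` counts every epoch once under its scored state (rows sum
    to 720 min per 12-h phase). ``rem_total_minutes`` folds TREM into REM, and
    sleep = NREM + REM + TREM.
    """

    state_minutes: pd.DataFrame          # index (day, phase), columns STATES
    rem_total_minutes: pd.Series         # REM + TREM, index (day, phase)
    sleep_minutes: pd.Series             # NREM + REM + TREM, index (day, phase)
    percent_sleep_in_light: float

    def to_frame(self) -> pd.DataFrame:
        df = self.state_minutes.copy()
        df["rem_total"] = self.rem_total_minutes
        df["sleep"] = self.sleep_minutes
        return df


def architecture(hyp: Hypnogram) -> ArchitectureSummary:
    """Summarize time-in-state per phase and day; TREM counts into REM totals."""
    df = pd.DataFrame({"day": hyp.day_index, "phase": hyp.phase,
                       "state": hyp.states})
    counts = (df.groupby(["day", "phase", "state"], observed=False)
              .size().unstack("state", fill_value=0))
    for s in STATES:
        if s not in counts.columns:
            counts[s] = 0
    counts = counts[list(STATES)]
    minutes = counts * (EPOCH_S / 60.0)
    rem_total = minutes["REM"] + minutes["TREM"]
    sleep = minutes["NREM"] + rem_total
    light_sleep = sleep[sleep.index.get_level_values("phase") == "light"].sum()
    total_sleep = sleep.sum()
    pct = 100.0 * light_sleep / total_sleep if total_sleep > 0 else float("nan")
    return ArchitectureSummary(state_minutes=minutes, rem_total_minutes=rem_total,
                               sleep_minutes=sleep, percent_sleep_in_light=pct)


# ---------------------------------------------------------------------------
# spectral normalizations
# ---------------------------------------------------------------------------

def _check_alignment(spec: BinnedSpectra, hyp: Hypnogram) -> None:
    if spec.n_epochs != len(hyp):
        raise ValueError(f"spectra have {spec.n_epochs} epochs but hypnogram "
                         f"has {len(hyp)}")


def _state_epoch_mask(hyp: Hypnogram, state: str, phase: str | None,
                      day: int | None) -> np.ndarray:
    m = hyp.states == state
    if phase is not None:
        m &= hyp.phase == phase
    if day is not None:
        m &= hyp.day_index == day
    return m


def normalize_cross_state(spec: BinnedSpectra, hyp: Hypnogram,
                          phase: str | None = "light", day: int | None = 0,
                          ref_day: int = 0,
                          method: str = "state_mean_sum") -> pd.DataFrame:
    """Cross-state spectral normalization.

    For each bin ``f`` and state ``s`` in {NREM, REM, WAKE}, the mean power
    over ``s``-epochs in the queried phase/day is divided by the summed power
    of that bin across the three states in the light phase of the reference
    day, x100. TREM epochs never contribute. With ``method='state_mean_sum'``
    (default) the denominator is the sum of the three state means; with
    ``'pooled'`` it is the mean over all reference epochs of the three states
    pooled (only the default satisfies the sums-to-100% identity on the
    reference window).
    """
    _check_alignment(spec, hyp)
    if method not in ("state_mean_sum", "pooled"):
        raise ValueError(f"unknown method {method!r}")

    ref_means = {}
    for s in SPECTRAL_STATES:
        m = _state_epoch_mask(hyp, s, "light", ref_day)
        if not m.any():
            raise ValueError(
                f"reference state {s} absent in light phase of day {ref_day}")
        ref_means[s] = spec.power[m].mean(axis=0)
    if method == "state_mean_sum":
        denom = sum(ref_means.values())
    else:
        pooled = np.isin(hyp.states, SPECTRAL_STATES) & \
            (hyp.phase == "light") & (hyp.day_index == ref_day)
        denom = spec.power[pooled].mean(axis=0)

    rows = {}
    for s in SPECTRAL_STATES:
        m = _state_epoch_mask(hyp, s, phase, day)
        rows[s] = (spec.power[m].mean(axis=0) / denom * 100.0
                   if m.any() else np.full(len(spec.bin_labels), np.nan))
    return pd.DataFrame(rows, index=spec.bin_labels).T


def normalize_within_state(spec: BinnedSpectra, hyp: Hypnogram, state: str,
                           phase: str | None = "light",
                           day: int | None = 0) -> pd.Series:
    """Within-state normalization: each bin as % of the state's total power."""
    _check_alignment(spec, hyp)
    if state not in SPECTRAL_STATES:
        raise ValueError(f"state must be one of {SPECTRAL_STATES}")
    m = _state_epoch_mask(hyp, state, phase, day)
    if not m.any():
        raise ValueError(f"state {state} absent in the requested window")
    v = spec.power[m].mean(axis=0)
    total = v.sum()
    if total <= 0:
        raise ValueError("state spectrum has zero total power")
    return pd.Series(v / total * 100.0, index=spec.bin_labels)


# ---------------------------------------------------------------------------
# band power and SWA timecourse
# ---------------------------------------------------------------------------

@dataclass
class BandPowerResult:
    """Per-epoch band power for one state, with per-phase means."""

    per_epoch: pd.Series          # NaN outside the requested state
    phase_mean: pd.Series         # mean over contributing epochs per phase
    band: BandDef
    state: str


def band_power(spec: BinnedSpectra, hyp: Hypnogram, band: BandDef,
               state: str = "NREM") -> BandPowerResult:
    """Mean power over the band's bins, restricted to epochs of one state.

    Band membership is inclusive at both edges in label space (e.g. delta
    1.0-4.5 resolves to labels {1.0, 1.5, ..., 4.5}; sigma 10-15 to
    {10, ..., 15}). TREM epochs are excluded unless explicitly requested.
    """
    _check_alignment(spec, hyp)
    mask = band.bin_mask(spec.bin_labels)
    if not mask.any():
        raise ValueError(f"band {band.name} ({band.lo}-{band.hi} Hz) resolves "
                         "to zero bins")
    vals = spec.power[:, mask].mean(axis=1)
    per_epoch = pd.Series(np.where(hyp.states == state, vals, np.nan),
                          name=band.name)
    phase_mean = (pd.DataFrame({"phase": hyp.phase, "v": per_epoch})
                  .groupby("phase")["v"].mean())
    return BandPowerResult(per_epoch=per_epoch, phase_mean=phase_mean,
                           band=band, state=state)


def swa_timecourse(spec: BinnedSpectra, hyp: Hypnogram,
                   interval_h: float = 1.0,
                   band: BandDef = BANDS["delta_swa"],
                   ref_zt: tuple[float, float] = (8.0, 12.0),
                   ref_day: int = 0) -> pd.Series:
    """NREM slow-wave activity per interval, % of the day-1 ZT8-12 reference.

    Per interval, the mean NREM-epoch delta power is divided by the mean NREM
    delta power in the last four hours of the light period (ZT8-12) of the
    reference day, x100. Intervals without NREM epochs are NaN.
    """
    _check_alignment(spec, hyp)
    mask = band.bin_mask(spec.bin_labels)
    delta = spec.power[:, mask].mean(axis=1)
    nrem = hyp.states == "NREM"
    zt = hyp.zt
    in_ref = nrem & (hyp.day_index == ref_day) & (zt >= ref_zt[0]) & (zt < ref_zt[1])
    if not in_ref.any():
        raise ValueError(
            f"no NREM epochs in ZT{ref_zt[0]:g}-{ref_zt[1]:g} of day {ref_day}")
    ref = delta[in_ref].mean()

    interval = np.floor(hyp.hours / interval_h).astype(int)
    out = {}
    for i in range(interval.max() + 1):
        m = nrem & (interval == i)
        out[i * interval_h] = delta[m].mean() / ref * 100.0 if m.any() else np.nan
    s = pd.Series(out, name="swa_pct")
    s.index.name = "interval_start_h"
    return s
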