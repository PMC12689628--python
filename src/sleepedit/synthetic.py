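"""Synthetic inputs with the statistical structure the analyses assume.

Every downstream stage of the package is testable without any recordings:

* :func:`gen_hypnogram` draws a vigilance-state sequence from per-epoch
  Markov chains (separate light- and dark-phase transition matrices) on the
  12:12 light/dark cycle.
* :func:`gen_eeg_emg` synthesizes EEG whose per-epoch spectral content
  follows each state's profile (1/f background plus band-limited
  oscillations: delta-dominant NREM, theta-dominant REM, broadband wake) and
  EMG whose RMS follows the state's muscle tone.
* :func:`gen_reads` produces amplicon reads with programmed edit, indel and
  sequencing-error rates, with per-read ground truth.
* :func:`gen_volume` produces plaque/microglia probability volumes with
  known blob counts, sizes, and engulfment flags.
* :func:`gen_trajectory` produces piecewise-constant-speed open-field
  trajectories kept inside the arena.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .eeg import (EPOCH_S, STATES, Hypnogram, Recording, _phase_and_day)
from .editing import EditSpec
from .kinematics import Trajectory

STATE_INDEX = {s: i for i, s in enumerate(STATES)}


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def _default_matrix_light() -> np.ndarray:
    # rows/cols in STATES order (WAKE, NREM, REM, TREM); per-4-s-epoch
    # probabilities chosen so the stationary chain sleeps ~72% of the light
    # phase (see docs/methods.md)
    return np.array([
        [0.905, 0.095, 0.000, 0.000],
        [0.020, 0.952, 0.008, 0.020],
        [0.100, 0.000, 0.900, 0.000],
        [0.300, 0.000, 0.700, 0.000],
    ])


def _default_matrix_dark() -> np.ndarray:
    # ~38% sleep in the dark phase; together with the light matrix this puts
    # ~65% of total sleep into the light phase
    return np.array([
        [0.966, 0.034, 0.000, 0.000],
        [0.040, 0.936, 0.006, 0.018],
        [0.120, 0.000, 0.880, 0.000],
        [0.300, 0.000, 0.700, 0.000],
    ])


@dataclass
class HypnogramParams:
    """Markov-chain hypnogram parameters (4-s epochs, 12:12 cycle)."""

    days: int = 1
    hours: float | None = None      # overrides days when set
    start_zt: float = 0.0
    lights_on_zt: float = 0.0
    lights_off_zt: float = 12.0
    transition_matrix_light: np.ndarray = field(default_factory=_default_matrix_light)
    transition_matrix_dark: np.ndarray = field(default_factory=_default_matrix_dark)
    seed: int = 0

    @property
    def n_epochs(self) -> int:
        hours = self.hours if self.hours is not None else self.days * 24.0
        return int(round(hours * 3600.0 / EPOCH_S))


def _validate_transition_matrix(P: np.ndarray, name: str) -> None:
    P = np.asarray(P, float)
    if P.shape != (4, 4):
        raise ValueError(f"{name}: transition matrix must be 4x4 over {STATES}")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError(f"{name}: rows must be non-negative and sum to 1")
    t = STATE_INDEX["TREM"]
    entering = [i for i in range(4) if i != t and P[i, t] > 0]
    if any(STATES[i] != "NREM" for i in entering):
        raise ValueError(f"{name}: TREM may only be entered from NREM")
    allowed_from_trem = {STATE_INDEX["REM"], STATE_INDEX["WAKE"]}
    if any(P[t, j] > 0 for j in range(4) if j not in allowed_from_trem):
        raise ValueError(f"{name}: TREM may only transition to REM or WAKE")


def gen_hypnogram(params: HypnogramParams) -> Hypnogram:
    """Sample a hypnogram from phase-dependent per-epoch Markov chains."""
    _validate_transition_matrix(params.transition_matrix_light, "light")
    _validate_transition_matrix(params.transition_matrix_dark, "dark")
    n = params.n_epochs
    if n < 1:
        raise ValueError("hypnogram must span at least one epoch")
    phase, day = _phase_and_day(n, params.start_zt, params.lights_off_zt)
    cum = {
        "light": np.cumsum(np.asarray(params.transition_matrix_light, float), axis=1),
        "dark": np.cumsum(np.asarray(params.transition_matrix_dark, float), axis=1),
    }
    rng = np.random.default_rng(params.seed)
    u = rng.random(n)
    states_i = np.empty(n, dtype=int)
    s = STATE_INDEX["WAKE"]
    for i in range(n):
        s = int(np.searchsorted(cum[phase[i]][s], u[i], side="right"))
        s = min(s, 3)
        states_i[i] = s
    states = np.asarray(STATES, dtype="U4")[states_i]
    return Hypnogram(states=states, phase=phase, day_index=day,
                     start_zt=params.start_zt)


# ---------------------------------------------------------------------------
# EEG/EMG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpectrum:
    """Target EEG composition of one vigilance state.

    ``bumps`` are band-limited oscillations given as (center Hz, Gaussian
    width Hz, integrated power); the background is ``bg_amp**2 / f**bg_alpha``
    (flattened below 0.5 Hz). ``emg_rms`` sets the EMG noise level.
    """

    bg_amp: float = 1.0
    bg_alpha: float = 1.0
    bumps: tuple[tuple[float, float, float], ...] = ()
    emg_rms: float = 1.0

    def psd(self, freqs: np.ndarray) -> np.ndarray:
        f = np.maximum(np.asarray(freqs, float), 0.5)
        s = self.bg_amp ** 2 / f ** self.bg_alpha
        for c, w, p in self.bumps:
            s = s + p * np.exp(-0.5 * ((freqs - c) / w) ** 2) / (w * np.sqrt(2 * np.pi))
        return s

    def bump_band_power(self, lo: float, hi: float) -> float:
        """Integrated oscillation power within [lo, hi] Hz (background excluded)."""
        return float(sum(p * (ndtr((hi - c) / w) - ndtr((lo - c) / w))
                         for c, w, p in self.bumps))


@dataclass
class SpectralProfile:
    """Per-state EEG spectral composition and EMG tone (arbitrary units)."""

    states: dict[str, StateSpectrum]

    def validate(self) -> None:
        missing = set(STATES) - set(self.states)
        if missing:
            raise ValueError(f"profile missing states: {sorted(missing)}")
        for name, st in self.states.items():
            if st.bg_amp < 0 or st.emg_rms < 0 or any(p < 0 for _, _, p in st.bumps):
                raise ValueError(f"{name}: powers and levels must be >= 0")
        if not (self.states["NREM"].bump_band_power(0.5, 5.0)
                > self.states["WAKE"].bump_band_power(0.5, 5.0)):
            raise ValueError("NREM delta-bump power must exceed WAKE's")
        if not (self.states["REM"].bump_band_power(6.0, 9.0)
                > self.states["NREM"].bump_band_power(6.0, 9.0)):
            raise ValueError("REM theta-bump power must exceed NREM's")

    def with_bump_scaled(self, state: str, factor: float,
                         lo: float = 0.5, hi: float = 5.0) -> "SpectralProfile":
        """Copy with the power of ``state``'s bumps centered in [lo, hi) scaled."""
        st = self.states[state]
        bumps = tuple((c, w, p * factor if lo <= c < hi else p)
                      for c, w, p in st.bumps)
        states = dict(self.states)
        states[state] = dataclasses.replace(st, bumps=bumps)
        return SpectralProfile(states=states)


def default_profile() -> SpectralProfile:
    """Default state profiles: delta-dominant NREM (with a sigma bump),
    theta-dominant REM, broadband wake with high EMG tone, mixed TREM."""
    return SpectralProfile(states={
        "WAKE": StateSpectrum(bumps=((7.0, 1.0, 0.8),), emg_rms=3.0),
        "NREM": StateSpectrum(bumps=((2.5, 1.2, 5.0), (12.5, 1.5, 1.2)),
                              emg_rms=0.5),
        "REM": StateSpectrum(bumps=((7.5, 0.8, 6.0),), emg_rms=0.3),
        "TREM": StateSpectrum(bumps=((2.5, 1.2, 0.6), (7.5, 0.8, 2.6)),
                              emg_rms=0.35),
    })


def gen_eeg_emg(hypnogram: Hypnogram, profile: SpectralProfile | None = None,
                fs: float = 128.0, seed: int = 0,
                channels: Sequence[str] = ("frontal", "parietal"),
                crossfade_s: float = 0.25) -> Recording:
    """Synthesize an epoch-stitched EEG/EMG recording following a hypnogram.

    Each 4-s epoch is drawn in the frequency domain with the amplitude
    spectrum of its state's target PSD and random phases, then stitched with
    a 0.25-s equal-power crossfade so epoch boundaries are click-free.
    EMG is white noise at the state's RMS level.
    """
    if fs < 128:
        raise ValueError("fs must be >= 128 Hz")
    if len(hypnogram) == 0:
        raise ValueError("hypnogram is empty")
    profile = profile or default_profile()
    profile.validate()

    n_ep = len(hypnogram)
    n = int(round(EPOCH_S * fs))
    c = int(round(crossfade_s * fs))
    seg_len = n + c
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    df = fs / seg_len
    state_idx = np.array([STATE_INDEX[s] for s in hypnogram.states])
    # target amplitude per rfft bin so that Var(x) ~ integral of the PSD
    amp = np.empty((4, len(freqs)))
    for name, i in STATE_INDEX.items():
        s = profile.states[name].psd(freqs)
        amp[i] = seg_len * np.sqrt(s * df / 2.0)
        amp[i, 0] = 0.0  # no DC

    rise = np.sin(np.linspace(0.0, np.pi / 2.0, c, endpoint=False)) if c else None
    rng = np.random.default_rng(seed)
    eeg = {}
    for ch in channels:
        z = rng.standard_normal((n_ep, len(freqs), 2))
        spec = (z[..., 0] + 1j * z[..., 1]) / np.sqrt(2.0) * amp[state_idx][:, :]
        seg = np.fft.irfft(spec, n=seg_len, axis=1)
        if c:
            fall = np.cos(np.linspace(0.0, np.pi / 2.0, c, endpoint=False))
            seg[1:, :c] *= rise
            tails = seg[:, n:] * fall
            core = seg[:, :n].copy()
            core[1:, :c] += tails[:-1]
            eeg[ch] = core.reshape(-1)
        else:
            eeg[ch] = seg.reshape(-1)

    levels = np.array([profile.states[s].emg_rms for s in STATES])
    emg = rng.standard_normal(n_ep * n) * np.repeat(levels[state_idx], n)
    return Recording(eeg=eeg, emg=emg, fs=fs, start_zt=hypnogram.start_zt)


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    """Programmed per-read edit/indel/error rates for amplicon simulation."""

    reference: str
    edit_spec: EditSpec
    p_edit: float = 0.13
    p_indel: float = 0.02
    p_error: float = 0.0
    indel_size_range: tuple[int, int] = (1, 5)
    indel_window_nt: int = 20       # indels fall within +-20 nt of the edit site
    n_reads: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_edit, self.p_indel, self.p_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.p_edit + self.p_indel > 1.0:
            raise ValueError("p_edit + p_indel must be <= 1")
        self.edit_spec.validate_against(self.reference)


@dataclass
class ReadSet:
    """Simulated reads with per-read ground-truth categories."""

    reads: list[str]
    truth: list[str]               # programmed category per read
    reference: str
    name: str = "sim"

    def __len__(self) -> int:
        return len(self.reads)

    def to_fastq(self, path: str | Path, quality: int = 40) -> None:
        qchar = chr(quality + 33)
        with open(path, "w") as fh:
            for i, seq in enumerate(self.reads):
                fh.write(f"@{self.name}_{i} truth={self.truth[i]}\n{seq}\n"
                         f"+\n{qchar * len(seq)}\n")

    def to_fasta_reference(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}_reference\n{self.reference}\n")


_BASES = np.array(list("ACGT"))


def gen_reads(params: ReadSimParams) -> ReadSet:
    """Simulate amplicon reads with programmed edit/indel/error rates.

    Each read is, with probability ``p_indel``, the reference with one indel
    (size drawn from ``indel_size_range``, placed within +-``indel_window_nt``
    of the edit site, mirroring where nicking-induced indels occur); with
    probability ``p_edit``, the reference with the full programmed
    substitution set; otherwise the unedited reference. Per-base sequencing
    errors at ``p_error`` are overlaid afterwards.
    """
    ref = params.reference.upper()
    spec = params.edit_spec
    rng = np.random.default_rng(params.seed)
    edited_ref = spec.apply_to(ref)
    anchor = min(p for p, _, _ in spec.substitutions)
    lo = max(0, anchor - params.indel_window_nt)
    hi = min(len(ref), anchor + params.indel_window_nt)

    u = rng.random(params.n_reads)
    reads: list[str] = []
    truth: list[str] = []
    for i in range(params.n_reads):
        if u[i] < params.p_indel:
            size = int(rng.integers(params.indel_size_range[0],
                                    params.indel_size_range[1] + 1))
            pos = int(rng.integers(lo, hi))
            if rng.random() < 0.5 and pos + size <= len(ref):  # deletion
                seq = ref[:pos] + ref[pos + size:]
            else:                                              # insertion
                ins = "".join(rng.choice(_BASES, size=size))
                seq = ref[:pos] + ins + ref[pos:]
            label = "indel"
        elif u[i] < params.p_indel + params.p_edit:
            seq, label = edited_ref, "edited"
        else:
            seq, label = ref, "unedited"
        if params.p_error > 0:
            k = rng.binomial(len(seq), params.p_error)
            if k:
                arr = np.array(list(seq))
                pos = rng.choice(len(seq), size=k, replace=False)
                for p in pos:
                    choices = _BASES[_BASES != arr[p]]
                    arr[p] = rng.choice(choices)
                seq = "".join(arr)
        reads.append(seq)
        truth.append(label)
    return ReadSet(reads=reads, truth=truth, reference=ref)


# ---------------------------------------------------------------------------
# probability volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeSimParams:
    """Blob layout for synthetic plaque/microglia probability volumes."""

    shape: tuple[int, int, int] = (48, 96, 96)
    voxel_size: tuple[float, float, float] = (3.0, 3.26, 3.26)  # z, y, x um
    n_plaques: int = 25
    plaque_radius_range: tuple[float, float] = (2.0, 4.0)
    n_microglia: int = 15
    engulfed_fraction: float = 0.5
    background_prob: float = 0.05
    min_separation: float | None = None
    seed: int = 0
    max_tries: int = 10000


@dataclass
class BlobTruth:
    """Ground truth for one simulated plaque."""

    center: tuple[float, float, float]
    radius: float
    voxel_count: int
    engulfed: bool


def _add_blob(vol: np.ndarray, center: np.ndarray, radius: float,
              peak: float) -> int:
    """Overlay one Gaussian blob (by maximum); returns its own count of
    voxels strictly above the 0.2 binarization threshold."""
    sigma = radius / np.sqrt(2.0 * np.log(peak / 0.2))  # prob > 0.2 within radius
    ext = int(np.ceil(3.5 * sigma)) + 1
    lo = np.maximum(np.floor(center).astype(int) - ext, 0)
    hi = np.minimum(np.floor(center).astype(int) + ext + 1, vol.shape)
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                             indexing="ij")
    d2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    blob = peak * np.exp(-0.5 * d2 / sigma ** 2)
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    np.maximum(vol[sub], blob, out=vol[sub])
    return int(np.count_nonzero(blob > 0.2))


def gen_volume(params: VolumeSimParams
               ) -> tuple[np.ndarray, np.ndarray, list[BlobTruth]]:
    """Simulate plaque and microglia probability volumes with known truth.

    Plaques are smooth Gaussian blobs (peak probability 0.7-0.95) whose
    supra-threshold radius equals the drawn radius; engulfed plaques are
    overlapped by a microglia blob. Low-level background noise stays strictly
    below the 0.2 binarization threshold and is combined by maximum so it
    never extends blob footprints.
    """
    rng = np.random.default_rng(params.seed)
    shape = np.asarray(params.shape, int)
    r_lo, r_hi = params.plaque_radius_range
    if r_lo < 1.0:
        raise ValueError("plaque radii must be >= 1 voxel")
    if params.background_prob >= 0.2:
        raise ValueError("background_prob must stay below the 0.2 threshold")
    sep = params.min_separation or 4.0 * r_hi + 4.0
    margin = 2.0 * r_hi + 1.0
    if np.any(shape <= 2 * margin):
        raise ValueError("volume too small for the requested blob radii")

    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < params.n_plaques:
        if tries >= params.max_tries:
            raise RuntimeError(
                f"could not place {params.n_plaques} blobs with separation "
                f"{sep:g} in shape {tuple(shape)} after {tries} tries")
        cand = rng.uniform(margin, shape - margin)
        if all(np.linalg.norm(cand - c) >= sep for c in centers):
            centers.append(cand)
        tries += 1

    plaque = np.zeros(tuple(shape))
    microglia = np.zeros(tuple(shape))
    radii = rng.uniform(r_lo, r_hi, size=params.n_plaques)
    peaks = rng.uniform(0.7, 0.95, size=params.n_plaques)
    engulfed = rng.random(params.n_plaques) < params.engulfed_fraction
    counts = [_add_blob(plaque, c, r, p)
              for c, r, p in zip(centers, radii, peaks)]
    n_extra = max(0, params.n_microglia - int(engulfed.sum()))
    for i in np.flatnonzero(engulfed):
        off = rng.uniform(-radii[i] / 2, radii[i] / 2, size=3)
        _add_blob(microglia, centers[i] + off, radii[i] * 1.2,
                  float(rng.uniform(0.6, 0.9)))
    placed = 0
    tries = 0
    while placed < n_extra and tries < params.max_tries:
        cand = rng.uniform(margin, shape - margin)
        if all(np.linalg.norm(cand - c) >= sep for c in centers):
            _add_blob(microglia, cand, float(rng.uniform(r_lo, r_hi)),
                      float(rng.uniform(0.6, 0.9)))
            placed += 1
        tries += 1

    if params.background_prob > 0:
        for vol in (plaque, microglia):
            np.maximum(vol, rng.uniform(0, params.background_prob, size=vol.shape),
                       out=vol)
    np.clip(plaque, 0.0, 1.0, out=plaque)
    np.clip(microglia, 0.0, 1.0, out=microglia)

    truth = [BlobTruth(center=tuple(c), radius=float(r), voxel_count=n,
                       engulfed=bool(e))
             for c, r, n, e in zip(centers, radii, counts, engulfed)]
    return plaque, microglia, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def gen_trajectory(profile: Sequence[tuple[float, float]],
                   frame_rate: float = 25.0,
                   arena: tuple[float, float] = (50.0, 50.0),
                   seed: int = 0,
                   heading_sigma: float = 0.25) -> Trajectory:
    """Simulate a piecewise-constant-speed open-field path.

    ``profile`` is a list of (duration_s, speed_cm_s) segments. The heading
    performs a random walk; steps that would leave the arena bounce off the
    wall, preserving the per-frame step length so the total path length is
    the programmed sum of duration x speed.
    """
    if any(s < 0 or d <= 0 for d, s in profile):
        raise ValueError("segment durations must be > 0 and speeds >= 0")
    rng = np.random.default_rng(seed)
    w, h = arena
    pos = np.array([w / 2.0, h / 2.0])
    theta = rng.uniform(0, 2 * np.pi)
    xs, ys = [pos[0]], [pos[1]]
    dt = 1.0 / frame_rate
    for duration, speed in profile:
        n_steps = int(round(duration * frame_rate))
        step = speed * dt
        for _ in range(n_steps):
            theta += rng.normal(0.0, heading_sigma)
            for _ in range(4):  # bounce off walls, re-checking after each flip
                nxt = pos + step * np.array([np.cos(theta), np.sin(theta)])
                if nxt[0] < 0 or nxt[0] > w:
                    theta = np.pi - theta
                elif nxt[1] < 0 or nxt[1] > h:
                    theta = -theta
                else:
                    break
            pos = np.clip(nxt, [0, 0], [w, h])
            xs.append(pos[0])
            ys.append(pos[1])
    return Trajectory(x=np.array(xs), y=np.array(ys), frame_rate=frame_rate,
                      arena=arena)


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

def cohort_normalized_delta(n_per_group: int = 8, reduction: float = 0.2,
                            seed: int = 0, hours: float = 4.0,
                            start_zt: float = 10.0,
                            band_lo: float = 1.0, band_hi: float = 4.5,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Dark-phase cross-state-normalized NREM delta power for two cohorts.

    The treated cohort's NREM delta bump is reduced by ``reduction``
    (default 20%). Each animal gets an independent hypnogram (spanning
    ``hours`` h starting at ``start_zt`` so the window holds both a light-
    phase reference and a dark phase) and a single-channel EEG synthesis.
    Returns (control values, treated values), one per animal.
    """
    from .eeg import epoch_psd, normalize_cross_state, rebin

    base = default_profile()
    reduced = base.with_bump_scaled("NREM", 1.0 - reduction, lo=0.5, hi=5.0)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    out = {True: [], False: []}
    for k, child in enumerate(children):
        treated = k >= n_per_group
        s1, s2 = child.generate_state(2)
        hyp = gen_hypnogram(HypnogramParams(hours=hours, start_zt=start_zt,
                                            seed=int(s1 % (2 ** 31))))
        rec = gen_eeg_emg(hyp, reduced if treated else base, fs=128.0,
                          seed=int(s2 % (2 ** 31)), channels=("parietal",))
        spec = rebin(epoch_psd(rec, channel="parietal"))
        norm = normalize_cross_state(spec, hyp, phase="dark", day=0)
        labels = norm.columns.to_numpy(float)
        sel = (labels >= band_lo) & (labels <= band_hi)
        out[treated].append(float(norm.loc["NREM"].to_numpy()[sel].mean()))
    return np.array(out[False]), np.array(out[True])
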