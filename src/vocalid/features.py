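"""Acoustic feature extraction: the 14 variables describing one contact call.

The measurement chain mirrors standard bioacoustic practice for tonal
mammal calls: the waveform is brought to an 11025 Hz analysis rate and
high-pass filtered at 50 Hz; the f0 contour is tracked with a normalized
cross-correlation pitch tracker (class-specific search band and time
step); temporal variables come from an RMS-energy onset/offset; and the
six power variables are read off a mean power spectrum of a 50 ms
fragment centred on the f0 maximum.

A second, spectrogram-peak based f0 estimator is provided purely as an
internal consistency oracle for the cross-correlation tracker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.io import wavfile

from .core import CallMeta, FeatureVector
from .synth import PITCH_SETTINGS, RATE, SynthCall

#: Normalized cross-correlation peak required to call a frame voiced.
VOICING_THRESHOLD = 0.45
#: Relative octave deviation from the local median that triggers repair.
OCTAVE_DEVIATION = 0.6


class FeatureExtractionError(RuntimeError):
    """Raised when a call cannot be measured; message carries the call id."""


@dataclass
class Waveform:
    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class PitchParams:
    """Pitch-tracking settings: search band and analysis time step."""

    floor: float
    ceiling: float
    time_step: float

    def __post_init__(self) -> None:
        if not 0 < self.floor < self.ceiling:
            raise ValueError("need 0 < floor < ceiling")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @classmethod
    def for_class(cls, caller_class: str) -> "PitchParams":
        floor, ceiling, step = PITCH_SETTINGS[caller_class]
        return cls(floor=floor, ceiling=ceiling, time_step=step)


@dataclass
class F0Contour:
    """Per-frame f0 track; unvoiced frames are NaN."""

    times: np.ndarray
    f0: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())


def load_wav(path: str | Path) -> Waveform:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Waveform(samples=data, rate=float(rate))


def preprocess(w: Waveform) -> Waveform:
    """Resample to the 11025 Hz analysis rate and high-pass at 50 Hz.

    Upsampling is refused: analysis assumes recordings made at or above
    the analysis rate.  The zero-phase 6th-order Butterworth high-pass
    (applied forward-backward) attenuates 30 Hz content by > 40 dB while
    leaving the passband above ~100 Hz essentially untouched.
    """
    if w.rate < RATE:
        raise ValueError(
            f"input rate {w.rate} Hz below analysis rate {RATE} Hz; "
            "upsampling is not supported")
    x = w.samples
    if w.rate != RATE:
        from fractions import Fraction
        frac = Fraction(RATE, int(round(w.rate))).limit_denominator(10000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator)
    sos = signal.butter(6, 50.0, btype="highpass", fs=RATE, output="sos")
    x = signal.sosfiltfilt(sos, x)
    return Waveform(samples=x, rate=RATE)


def _repair_octave_jumps(f0: np.ndarray, floor: float, ceiling: float
                         ) -> np.ndarray:
    """Deterministic surrogate for manual spectrogram-based correction.

    Frames deviating more than OCTAVE_DEVIATION from a running median of
    the voiced track are halved or doubled when that brings them closer
    to the median and keeps them inside the search band.
    """
    out = f0.copy()
    voiced = np.isfinite(out)
    if voiced.sum() < 3:
        return out
    vals = out[voiced]
    med = signal.medfilt(vals, kernel_size=min(5, 2 * (len(vals) // 2) - 1)
                         if len(vals) >= 3 else 1)
    for i, (v, m) in enumerate(zip(vals, med)):
        if m <= 0 or abs(v - m) <= OCTAVE_DEVIATION * m:
            continue
        candidates = [c for c in (v / 2, v * 2) if floor <= c <= ceiling]
        if candidates:
            best = min(candidates, key=lambda c: abs(c - m))
            if abs(best - m) < abs(v - m):
                vals[i] = best
    out[voiced] = vals
    return out


#: Dynamic-programming path costs (per-frame candidate selection).
_OCTAVE_JUMP_COST = 0.35      # per octave of f0 change between frames
_VOICED_UNVOICED_COST = 0.14
_OCTAVE_COST = 0.02           # per octave below the ceiling: breaks the tie
                              # between the true period and its multiples,
                              # which correlate equally well
_MAX_CANDIDATES = 6


def _frame_candidates(r: np.ndarray, lag_min: int, rate: float,
                      floor: float, ceiling: float
                      ) -> list[tuple[float, float]]:
    """(f0, strength) for the strongest local correlation maxima of one
    frame, with parabolic lag refinement and the octave-cost adjustment.

    Candidate strength is the interpolated peak height: at short lags the
    integer lag grid samples the correlation function well off its true
    maximum, and comparing raw samples would systematically favor
    subharmonic (longer-lag) candidates.
    """
    interior = np.flatnonzero((r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:])) + 1
    if len(interior) == 0:
        interior = np.array([int(np.argmax(r))])
    out = []
    for j in map(int, interior):
        lag = float(lag_min + j)
        height = float(r[j])
        if 0 < j < len(r) - 1:
            denom = r[j - 1] - 2 * r[j] + r[j + 1]
            if denom < 0:
                delta = 0.5 * (r[j - 1] - r[j + 1]) / denom
                lag += delta
                height -= 0.25 * (r[j - 1] - r[j + 1]) * delta
        f0 = rate / lag
        # candidates well below the voicing threshold are kept: the path
        # finder voices them only when continuity with neighboring frames
        # outweighs the unvoiced state's emission
        if floor <= f0 <= ceiling and height >= VOICING_THRESHOLD - 0.15:
            out.append((f0, min(height, 1.0)
                        - _OCTAVE_COST * np.log2(ceiling / f0)))
    out.sort(key=lambda c: -c[1])
    return out[:_MAX_CANDIDATES]


def _best_path(candidates: list[list[tuple[float, float]]]) -> np.ndarray:
    """Viterbi over per-frame f0 candidates plus an unvoiced state.

    Emission reward is the correlation strength (VOICING_THRESHOLD for the
    unvoiced state); transitions pay _OCTAVE_JUMP_COST per octave of f0
    change and _VOICED_UNVOICED_COST for voicing flips.  Deterministic.
    """
    n = len(candidates)
    states = [c + [(np.nan, VOICING_THRESHOLD)] for c in candidates]
    score = [np.array([s for _, s in states[0]])]
    back: list[np.ndarray] = []
    for i in range(1, n):
        prev_f = np.array([f for f, _ in states[i - 1]])
        prev_s = score[-1]
        cur = np.empty(len(states[i]))
        bk = np.empty(len(states[i]), dtype=int)
        for j, (f, s) in enumerate(states[i]):
            trans = np.empty(len(prev_f))
            for q, pf in enumerate(prev_f):
                if np.isnan(f) and np.isnan(pf):
                    trans[q] = 0.0
                elif np.isnan(f) or np.isnan(pf):
                    trans[q] = -_VOICED_UNVOICED_COST
                else:
                    trans[q] = -_OCTAVE_JUMP_COST * abs(np.log2(f / pf))
            tot = prev_s + trans
            bk[j] = int(np.argmax(tot))
            cur[j] = s + tot[bk[j]]
        score.append(cur)
        back.append(bk)
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(score[-1]))
    for i in range(n - 2, -1, -1):
        path[i] = back[i][path[i + 1]]
    return np.array([states[i][path[i]][0] for i in range(n)])


def _harmonic_division_repair(x: np.ndarray, rate: float, times: np.ndarray,
                              f0: np.ndarray, floor: float) -> np.ndarray:
    """Spectral surrogate for manual spectrogram-based correction of
    harmonic locks.

    When nearly all of a frame's energy sits in one high harmonic, the
    correlator locks onto that partial and reports a multiple of f0.  A
    human fixes such frames by reading the harmonic spacing off the
    spectrogram; this does the same automatically: a frame's f0 is
    divided by d (2..4) when the local spectrum shows peaks at both f0/d
    and 2 f0/d — the signature of a missed fundamental.
    """
    out = f0.copy()
    n_win = int(4.0 / floor * rate)
    nfft = 8192
    for i, (t, f) in enumerate(zip(times, f0)):
        if not np.isfinite(f):
            continue
        c = int(t * rate)
        seg = x[max(0, c - n_win // 2): c + n_win // 2]
        if len(seg) < n_win // 2:
            continue
        spec = np.abs(np.fft.rfft(seg * np.hamming(len(seg)), n=nfft)) ** 2
        freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
        ref = spec.max()
        is_max = np.zeros(len(spec), dtype=bool)
        is_max[1:-1] = (spec[1:-1] >= spec[:-2]) & (spec[1:-1] >= spec[2:])

        def has_peak(target: float, strict: bool = False) -> bool:
            # a genuine harmonic is a local spectral maximum carrying
            # appreciable energy relative to the frame peak; the
            # candidate fundamental must additionally be prominent
            # against the valley around it, which rejects both window
            # sidelobes and the broadband smear of fast f0 sweeps
            tol = max(2.0 * rate / len(seg), 0.04 * target)
            near = ((freqs >= target - tol) & (freqs <= target + tol)
                    & is_max)
            if not near.any():
                return False
            peak = spec[near].max()
            if peak < ref * 10 ** (-2.5):
                return False
            if not strict:
                return True
            around = ((freqs >= 0.55 * target) & (freqs <= 1.45 * target)
                      & ~((freqs >= target - 1.2 * tol)
                          & (freqs <= target + 1.2 * tol)))
            return around.any() and peak >= 15.0 * np.median(spec[around])

        for d in (2, 3, 4):
            cand = f / d
            if (cand >= 0.95 * floor and has_peak(cand, strict=True)
                    and (has_peak(2 * cand) or has_peak(3 * cand))):
                out[i] = cand
    return out


def extract_f0_contour(w: Waveform, p: PitchParams) -> F0Contour:
    """Track f0 by normalized cross-correlation with octave-safe smoothing.

    Each frame correlates a window of two floor-periods with itself at
    lags spanning [1/ceiling, 1/floor]; local correlation maxima become
    per-frame f0 candidates (parabolic lag interpolation), and a
    dynamic-programming path finder with octave-jump and voicing-flip
    costs selects one candidate (or unvoiced) per frame, suppressing the
    period-halving/doubling errors a greedy picker makes.  A median-based
    octave repair then corrects any residual isolated jumps.
    """
    rate = w.rate
    # restrict correlation to the pitch band: energy at high harmonics
    # otherwise dominates the correlator and causes carrier locking
    cutoff = min(1.3 * p.ceiling, 0.45 * rate)
    sos = signal.butter(4, cutoff, btype="lowpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, w.samples)
    win = int(round(1.5 / p.floor * rate))
    lag_min = max(2, int(np.floor(rate / p.ceiling)))
    lag_max = int(np.ceil(rate / p.floor)) + 1
    step = int(round(p.time_step * rate))
    seg_len = win + lag_max
    if len(x) < seg_len + step:
        raise FeatureExtractionError(
            f"call too short for pitch analysis ({len(x) / rate:.3f} s)")

    rms_global = np.sqrt(np.mean(x ** 2))
    starts = np.arange(0, len(x) - seg_len + 1, step)
    times = (starts + win / 2) / rate
    candidates: list[list[tuple[float, float]]] = []
    for s0 in starts:
        seg = x[s0:s0 + seg_len]
        base = seg[:win]
        if np.sqrt(np.mean(base ** 2)) < 1e-3 * rms_global:
            candidates.append([])
            continue
        base = base - base.mean()
        wins = sliding_window_view(seg - seg.mean(), win)[lag_min:lag_max + 1]
        num = wins @ base
        den = np.sqrt((base @ base) * np.einsum("ij,ij->i", wins, wins))
        r = num / np.maximum(den, 1e-12)
        if r.max() < VOICING_THRESHOLD:
            candidates.append([])
            continue
        candidates.append(
            _frame_candidates(r, lag_min, rate, p.floor, p.ceiling))
    f0 = _best_path(candidates)
    f0 = _harmonic_division_repair(x, rate, times, f0, p.floor)
    f0 = _repair_octave_jumps(f0, p.floor, p.ceiling)
    # the correlation pairs span [start, start + win + lag]: the estimate
    # belongs to the centre of that span, half a period past the nominal
    # window centre
    voiced = np.isfinite(f0)
    times = times.copy()
    times[voiced] += 0.5 / f0[voiced]
    return F0Contour(times=times, f0=f0)


@dataclass
class F0Stats:
    f0beg: float
    f0end: float
    f0max: float
    f0min: float
    f0mean: float
    delta_f0: float
    t_f0max: float


def measure_f0_stats(c: F0Contour) -> F0Stats:
    """Endpoint, extreme and mean f0 over the voiced frames."""
    v = c.voiced
    if v.sum() < 2:
        raise FeatureExtractionError("fewer than 2 voiced frames")
    f = c.f0[v]
    t = c.times[v]
    imax = int(np.argmax(f))
    return F0Stats(
        f0beg=float(f[0]), f0end=float(f[-1]),
        f0max=float(f[imax]), f0min=float(f.min()),
        f0mean=float(f.mean()), delta_f0=float(f[imax] - f.min()),
        t_f0max=float(t[imax]),
    )


def detect_call_bounds(w: Waveform, threshold_db: float = -25.0,
                       window_s: float = 0.010) -> tuple[float, float]:
    """Call onset/offset from a smoothed RMS envelope.

    The call spans the samples whose envelope exceeds ``threshold_db``
    relative to the envelope peak.
    """
    n_win = max(3, int(round(window_s * w.rate)))
    power = np.convolve(w.samples ** 2, np.ones(n_win) / n_win, mode="same")
    env = np.sqrt(np.maximum(power, 0.0))
    peak = env.max()
    if peak <= 0:
        raise FeatureExtractionError("silent waveform: no detectable onset")
    above = np.flatnonzero(env >= peak * 10 ** (threshold_db / 20))
    return float(above[0] / w.rate), float((above[-1] + 1) / w.rate)


def measure_temporal(
    w: Waveform, c: F0Contour,
    bounds: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """(durat, dur_to_max) from call bounds and the f0-maximum time.

    ``bounds`` may carry exact (onset, offset) for synthetic calls;
    otherwise they are detected from the energy envelope.
    """
    onset, offset = bounds if bounds is not None else detect_call_bounds(w)
    if offset <= onset:
        raise FeatureExtractionError("call offset precedes onset")
    stats = measure_f0_stats(c)
    durat = offset - onset
    dur_to_max = float(np.clip(stats.t_f0max - onset, 0.0, durat))
    return durat, dur_to_max


def mean_power_spectrum_50ms(
    w: Waveform, t_f0max: float, fragment_s: float = 0.050
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged power spectrum of the 50 ms fragment around the f0 maximum.

    Hamming-windowed 256-sample segments with 75% overlap, zero-padded to
    a 1024-point FFT and averaged (Welch).  The fragment is clipped, not
    zero-padded, at the call edges.
    """
    half = fragment_s / 2
    i0 = max(0, int(round((t_f0max - half) * w.rate)))
    i1 = min(len(w.samples), int(round((t_f0max + half) * w.rate)))
    frag = w.samples[i0:i1]
    nperseg = 256
    if len(frag) < nperseg:
        raise FeatureExtractionError(
            f"fragment of {len(frag)} samples shorter than one analysis frame")
    freqs, power = signal.welch(
        frag, fs=w.rate, window="hamming", nperseg=nperseg,
        noverlap=3 * nperseg // 4, nfft=1024, detrend=False,
        scaling="spectrum")
    return freqs, power


def measure_power_vars(
    freqs: np.ndarray, power: np.ndarray, f0_at_max: float
) -> dict:
    """fpeak, energy quartiles, power_f0 and peak_harm from one spectrum.

    A harmonic "band" is the set of FFT bins within half an f0 of the
    harmonic centre; power_f0 is the dB excess of the strongest band over
    the f0 band (0 when the f0 band itself is strongest).
    """
    total = power.sum()
    if total <= 0:
        raise FeatureExtractionError("zero-energy spectrum")
    if f0_at_max <= 0:
        raise ValueError("f0_at_max must be positive")
    fpeak = float(freqs[int(np.argmax(power))])
    cum = np.cumsum(power)
    quartiles = [float(freqs[int(np.searchsorted(cum, frac * total))])
                 for frac in (0.25, 0.50, 0.75)]
    k_count = max(1, int(freqs[-1] / f0_at_max + 0.5))
    band_energy = np.empty(k_count)
    for k in range(1, k_count + 1):
        centre = k * f0_at_max
        mask = (freqs >= centre - f0_at_max / 2) & (freqs < centre + f0_at_max / 2)
        band_energy[k - 1] = power[mask].sum()
    eps = np.finfo(float).tiny
    power_f0 = 10.0 * np.log10((band_energy.max() + eps)
                               / (band_energy[0] + eps))
    peak_harm = max(1, int(round(fpeak / f0_at_max)))
    return {
        "fpeak": fpeak, "q25": quartiles[0], "q50": quartiles[1],
        "q75": quartiles[2], "power_f0": float(max(power_f0, 0.0)),
        "peak_harm": peak_harm,
    }


def extract_features(
    w: Waveform, meta: CallMeta,
    bounds: Optional[tuple[float, float]] = None,
    pitch: Optional[PitchParams] = None,
) -> FeatureVector:
    """Run the full measurement chain on one call.

    The caller class in ``meta`` selects the pitch-tracking regime.
    Any sub-operation failure is re-raised annotated with the call id.
    """
    try:
        wp = preprocess(w)
        p = pitch or PitchParams.for_class(meta.caller_class)
        contour = extract_f0_contour(wp, p)
        stats = measure_f0_stats(contour)
        durat, dur_to_max = measure_temporal(wp, contour, bounds=bounds)
        freqs, power = mean_power_spectrum_50ms(wp, stats.t_f0max)
        pv = measure_power_vars(freqs, power, stats.f0max)
    except (FeatureExtractionError, ValueError) as exc:
        raise FeatureExtractionError(
            f"call {meta.call_id or meta.individual_id}: {exc}") from exc
    fv = FeatureVector(
        durat=durat, dur_to_max=dur_to_max,
        f0beg=stats.f0beg, f0end=stats.f0end, f0max=stats.f0max,
        f0min=stats.f0min, f0mean=stats.f0mean, delta_f0=stats.delta_f0,
        **pv)
    fv.validate()
    return fv


def extract_feature_table(
    calls: Sequence[SynthCall], use_true_bounds: bool = False
) -> pd.DataFrame:
    """Feature table (metadata + 14 features) for a batch of synthetic calls."""
    rows = []
    for call in calls:
        w = Waveform(samples=call.samples, rate=call.rate)
        bounds = (0.0, call.truth["durat"]) if use_true_bounds else None
        fv = extract_features(w, call.meta, bounds=bounds)
        rows.append({**call.meta.as_dict(), **fv.as_dict()})
    return pd.DataFrame(rows)


def estimate_f0_spectral(w: Waveform, p: PitchParams) -> F0Contour:
    """Independent spectrogram-peak f0 estimate (consistency oracle only).

    Per frame, in-band spectral local maxima within 10 dB of the
    strongest in-band peak become f0 candidates (with parabolic bin
    refinement); the same continuity path finder used by the
    cross-correlation tracker then selects the fundamental ridge — what a
    human reads off a spectrogram — robust to spectral envelopes that put
    more energy on a higher in-band harmonic.  A frame is voiced when the
    strongest in-band peak rises at least 20x above the median in-band bin
    power — a robust noise-floor reference that stays low however many
    harmonic mainlobes fill the band (noise frames reach ~7-10x).
    The measurement principle (spectral peak location) is independent of
    the lag-domain tracker it cross-checks.
    """
    x = w.samples
    step = max(1, int(round(p.time_step * w.rate)))
    # window of three floor-periods: enough to resolve the fundamental,
    # short enough to follow the contour of brief calls
    nperseg = min(int(round(3.0 / p.floor * w.rate)), len(x) - step)
    if nperseg < 64:
        raise FeatureExtractionError("call too short for spectral f0 estimate")
    freqs, times, sxx = signal.spectrogram(
        x, fs=w.rate, window="hamming", nperseg=nperseg,
        noverlap=nperseg - step, nfft=4096, detrend=False)
    band = (freqs >= p.floor) & (freqs <= p.ceiling)
    fb = freqs[band]
    binw = freqs[1] - freqs[0]
    candidates: list[list[tuple[float, float]]] = []
    for i in range(len(times)):
        spec = sxx[band, i]
        floor_power = np.median(spec)
        best = spec.max()
        if floor_power <= 0 or best < 20.0 * floor_power:
            candidates.append([])
            continue
        peaks = np.flatnonzero(
            (spec[1:-1] >= spec[:-2]) & (spec[1:-1] >= spec[2:])) + 1
        # a rising spectral envelope can leave the fundamental ~18 dB
        # below the strongest in-band harmonic; 22 dB still excludes noise
        peaks = peaks[spec[peaks] >= best / 10 ** 2.2]
        cands = []
        for j in map(int, peaks[:_MAX_CANDIDATES]):
            f_hat = fb[j]
            if 0 < j < len(fb) - 1:
                denom = spec[j - 1] - 2 * spec[j] + spec[j + 1]
                if denom < 0:
                    f_hat += 0.5 * (spec[j - 1] - spec[j + 1]) / denom * binw
            if p.floor <= f_hat <= p.ceiling:
                cands.append(float(f_hat))
        if cands:
            # the fundamental ridge is the lowest qualifying peak; higher
            # peaks stay as alternatives the continuity path may prefer
            f_low = min(cands)
            candidates.append([(f, 1.0 - 0.12 * np.log2(f / f_low))
                               for f in cands])
        else:
            candidates.append([])
    f0 = _best_path(candidates)
    f0 = _repair_octave_jumps(f0, p.floor, p.ceiling)
    return F0Contour(times=times, f0=f0)
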