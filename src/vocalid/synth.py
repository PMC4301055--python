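"""Synthetic red deer contact calls with known, controllable individuality.

The generator is a simple source model: an additive harmonic stack whose
fundamental follows a smooth cosine-segment contour rising from ``f0beg``
to ``f0max`` at time ``dur_to_max`` and falling to a terminal minimum,
with a spectral envelope that places maximum energy on a controllable
harmonic (which drives fpeak, the energy quartiles, power_f0 and
peak_harm downstream).  No vocal-tract filtering (formants) and no
nonlinear phenomena are modelled.

Individuality is injected by an intraclass-correlation parameter ``icc``:
each published feature SD is split into a between-individual component
(sd * sqrt(icc), frozen per animal as a latent mean) and a
within-individual component (sd * sqrt(1 - icc), redrawn per call), so
that across many calls the total variance matches the published value
while a fraction icc of it separates individuals.

Between-year change of voices is modelled phenomenologically: an optional
additive per-individual, per-year shift of the latent means with SD
``year_drift_sd`` expressed in units of each feature's population SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import CallMeta, FEATURE_NAMES
from .tables import BODY_MASS, POPULATION_TABLE

#: Synthesis / analysis sample rate, Hz.
RATE = 11025

#: Pitch-tracking settings per caller class: (floor Hz, ceiling Hz, time step s).
PITCH_SETTINGS: dict[str, tuple[float, float, float]] = {
    "hind": (50.0, 400.0, 0.01),
    "calf": (100.0, 1200.0, 0.005),
}

#: Latent parameters that drive waveform synthesis (subset of FEATURE_NAMES).
CONTOUR_PARAMS = ("durat", "dur_to_max", "f0beg", "f0max", "f0min")
SPECTRAL_PARAMS = ("peak_harm", "power_f0")


@dataclass
class PopulationSpec:
    """Population-level description of one caller class (hind or calf).

    ``feature_stats`` holds per-call-type (oral, nasal) mean and SD for each
    of the 14 features; defaults are the published population values.
    """

    caller_class: str = "hind"
    feature_stats: dict[str, dict[str, tuple[float, float]]] = field(default=None)
    icc: float = 0.7
    year_drift_sd: float = 0.0       # in units of each feature's population SD
    n_harmonics: int = 40
    noise_snr_db: float = 30.0
    spectral_tilt_db: float = 2.0    # dB per harmonic order
    #: cap on the emphasis excess per harmonic order of distance from the
    #: fundamental; keeps the envelope slope physical so no call degenerates
    #: into a single dominant partial (whose pitch would be ambiguous)
    max_emphasis_slope_db: float = 6.0
    rate: int = RATE

    def __post_init__(self) -> None:
        if self.caller_class not in POPULATION_TABLE:
            raise ValueError(f"unknown caller_class {self.caller_class!r}")
        if self.feature_stats is None:
            self.feature_stats = {
                ct: dict(stats)
                for ct, stats in POPULATION_TABLE[self.caller_class].items()
            }
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError(f"icc must lie in [0, 1], got {self.icc}")
        if self.year_drift_sd < 0:
            raise ValueError("year_drift_sd must be >= 0")
        for ct, stats in self.feature_stats.items():
            for name, (_, sd) in stats.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {ct}/{name}")

    def between_sd(self, call_type: str, feature: str) -> float:
        return self.feature_stats[call_type][feature][1] * np.sqrt(self.icc)

    def within_sd(self, call_type: str, feature: str) -> float:
        return self.feature_stats[call_type][feature][1] * np.sqrt(1.0 - self.icc)


@dataclass
class IndividualProfile:
    """Latent per-individual feature means (one vector per call type)."""

    individual_id: str
    caller_class: str
    sex: str
    body_mass_kg: float
    latent: dict[str, dict[str, float]]   # call_type -> feature -> latent mean


@dataclass
class SynthCall:
    """One synthesized call: waveform, metadata, and generating ground truth.

    ``truth`` records the realized contour parameters and the exact f0
    contour (the generator's own instantaneous frequency), which serves as
    the oracle for pitch-tracker round-trip tests.
    """

    samples: np.ndarray
    rate: int
    meta: CallMeta
    truth: dict


def make_population(
    spec: PopulationSpec, n_individuals: int, seed: int
) -> list[IndividualProfile]:
    """Draw ``n_individuals`` latent profiles from the population spec.

    Latent means are drawn so that, across many calls, total feature
    variance splits into a fraction ``icc`` between individuals and
    ``1 - icc`` within.  The five f0 landmarks share one latent deviate
    per individual and call type (the animal's "pitch register"), so the
    landmark ordering f0min <= f0beg, f0end <= f0max survives the
    between-individual spread; marginal variances are unchanged.
    Deterministic under a fixed seed.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    pitch_set = {"f0beg", "f0end", "f0max", "f0min", "f0mean"}
    rng = np.random.default_rng(seed)
    mass_mean, mass_sd, mass_lo, mass_hi = BODY_MASS[spec.caller_class]
    profiles = []
    for i in range(n_individuals):
        latent: dict[str, dict[str, float]] = {}
        for ct, stats in spec.feature_stats.items():
            z_pitch = rng.standard_normal()
            latent[ct] = {
                name: mean + spec.between_sd(ct, name)
                * (z_pitch if name in pitch_set else rng.standard_normal())
                for name, (mean, _) in stats.items()
            }
        sex = ("female" if spec.caller_class == "hind"
               else ("male", "female")[rng.integers(2)])
        mass = float(np.clip(rng.normal(mass_mean, mass_sd), mass_lo, mass_hi))
        profiles.append(IndividualProfile(
            individual_id=f"{spec.caller_class}{i + 1:02d}",
            caller_class=spec.caller_class,
            sex=sex,
            body_mass_kg=mass,
            latent=latent,
        ))
    return profiles


def apply_year_drift(
    spec: PopulationSpec, profiles: Sequence[IndividualProfile], seed: int
) -> list[IndividualProfile]:
    """Shift each profile's latent means by one year of drift.

    Each feature receives an independent additive shift with SD
    ``year_drift_sd`` times its population SD; identities, sex and mass
    are preserved.  With ``year_drift_sd = 0`` profiles are returned
    unchanged (copies).
    """
    rng = np.random.default_rng(seed)
    drifted = []
    for p in profiles:
        latent = {}
        for ct, means in p.latent.items():
            latent[ct] = {
                name: mu + spec.year_drift_sd
                * spec.feature_stats[ct][name][1] * rng.standard_normal()
                for name, mu in means.items()
            }
        drifted.append(replace(p, latent=latent))
    return drifted


def _repair_contour_params(
    params: dict[str, float], caller_class: str, rate: int,
    max_emphasis_slope_db: float = 6.0,
) -> dict[str, float]:
    """Enforce the physical constraints of the contour family.

    durat > dur_to_max >= 0 and f0min <= f0beg <= f0max, with f0 kept
    safely inside the class pitch-tracking band.
    """
    floor, ceiling, _ = PITCH_SETTINGS[caller_class]
    q = dict(params)
    # a call must span a dozen longest pitch periods to carry a contour
    q["durat"] = max(q["durat"], 12.0 / floor)
    q["dur_to_max"] = float(np.clip(q["dur_to_max"],
                                    0.05 * q["durat"], 0.55 * q["durat"]))
    q["f0min"] = max(q["f0min"], 1.1 * floor)
    q["f0max"] = float(np.clip(q["f0max"], q["f0min"], 0.92 * ceiling))
    q["f0beg"] = float(np.clip(q["f0beg"], q["f0min"], q["f0max"]))
    # terminal uptick: the contour ends slightly above its minimum, as
    # real calls do; keeps f0end from coinciding with f0min, which would
    # make the extracted feature set exactly collinear
    frac = min(q.get("end_rise_frac", 0.0), 0.5)
    q["f0end"] = q["f0min"] + frac * (q["f0max"] - q["f0min"])
    kmax = max(1, int(0.47 * rate / q["f0max"]))
    q["peak_harm"] = int(np.clip(round(q["peak_harm"]), 1, kmax))
    if q["peak_harm"] > 1:
        cap = max_emphasis_slope_db * (q["peak_harm"] - 1)
        q["power_f0"] = float(np.clip(q["power_f0"], 0.0, cap))
    else:
        q["power_f0"] = 0.0
    return q


def _contour(q: Mapping[str, float], rate: int) -> tuple[np.ndarray, np.ndarray]:
    """Cosine-segment f0 contour honoring the five measured landmarks.

    Rise f0beg -> f0max over [0, dur_to_max], fall f0max -> f0min over
    [dur_to_max, durat - hold], then a slow terminal rise from f0min to
    f0end over the last ``hold`` seconds.  All cosine segments have zero
    slope at their endpoints, so every landmark sits on a locally flat
    stretch that windowed analysis samples faithfully.
    """
    n = int(round(q["durat"] * rate))
    t = np.arange(n) / rate
    hold = min(0.04, 0.15 * q["durat"])
    t_rise = q["dur_to_max"]
    t_fall = max(q["durat"] - hold, t_rise + 1.0 / rate)
    f = np.full(n, q["f0min"])
    rise = t < t_rise
    f[rise] = q["f0beg"] + (q["f0max"] - q["f0beg"]) * (
        1 - np.cos(np.pi * t[rise] / t_rise)) / 2
    mid = (t >= t_rise) & (t < t_fall)
    s = (t[mid] - t_rise) / (t_fall - t_rise)
    f[mid] = q["f0min"] + (q["f0max"] - q["f0min"]) * (1 + np.cos(np.pi * s)) / 2
    tail = t >= t_fall
    if tail.any() and q["durat"] > t_fall:
        s = (t[tail] - t_fall) / (q["durat"] - t_fall)
        f[tail] = q["f0min"] + (q["f0end"] - q["f0min"]) * (
            1 - np.cos(np.pi * s)) / 2
    return t, f


def _harmonic_amplitudes(q: Mapping[str, float], n_harmonics: int,
                         tilt: float, rate: int) -> np.ndarray:
    """Linear amplitudes of the harmonic stack (index 0 = fundamental).

    Spectral envelope in dB: a linear tilt of ``tilt`` dB per harmonic
    plus a Gaussian emphasis (width 1.2 orders) centred on the target
    peak harmonic, scaled so that the realized level difference between
    the peak harmonic and the fundamental equals power_f0 exactly.
    """
    kmax = min(n_harmonics, max(1, int(0.47 * rate / q["f0max"])))
    k = np.arange(1, kmax + 1, dtype=float)
    kp, w = q["peak_harm"], 1.2
    level = -tilt * (k - 1)
    if kp > 1:
        g = np.exp(-((k - kp) ** 2) / (2 * w ** 2))
        boost = (q["power_f0"] + tilt * (kp - 1)) / (1 - np.exp(
            -((kp - 1) ** 2) / (2 * w ** 2)))
        level = level + boost * g
    return 10.0 ** (level / 20.0)


def synth_call(
    spec: PopulationSpec,
    profile: IndividualProfile,
    call_type: str,
    seed: int,
    year: Optional[int] = None,
    session_id: Optional[str] = None,
    call_id: Optional[str] = None,
) -> SynthCall:
    """Synthesize one call of ``profile``; within-call parameter jitter is
    drawn from the within-individual SDs of ``spec``."""
    if call_type not in spec.feature_stats:
        raise ValueError(f"unknown call_type {call_type!r}")
    rng = np.random.default_rng(seed)
    lat = profile.latent[call_type]
    if lat["f0beg"] > lat["f0max"] or lat["f0min"] > lat["f0max"]:
        raise ValueError(
            f"{profile.individual_id}: latent contour violates "
            "f0beg, f0min <= f0max")
    params = {
        name: lat[name] + spec.within_sd(call_type, name) * rng.standard_normal()
        for name in CONTOUR_PARAMS + SPECTRAL_PARAMS
    }
    params["end_rise_frac"] = 0.15 * abs(rng.standard_normal())
    q = _repair_contour_params(params, profile.caller_class, spec.rate,
                               spec.max_emphasis_slope_db)

    t, f0 = _contour(q, spec.rate)
    phase = 2 * np.pi * np.cumsum(f0) / spec.rate
    amps = _harmonic_amplitudes(q, spec.n_harmonics, spec.spectral_tilt_db,
                                spec.rate)
    x = np.zeros_like(t)
    for ki, a in enumerate(amps, start=1):
        x += a * np.sin(ki * phase)
    x *= 0.9 / np.max(np.abs(x))

    # 10 ms raised-cosine onset/offset to avoid clicks
    nfade = min(int(0.010 * spec.rate), len(x) // 4)
    if nfade > 0:
        ramp = (1 - np.cos(np.pi * np.arange(nfade) / nfade)) / 2
        x[:nfade] *= ramp
        x[-nfade:] *= ramp[::-1]

    if np.isfinite(spec.noise_snr_db):
        sigma = np.sqrt(np.mean(x ** 2)) * 10 ** (-spec.noise_snr_db / 20)
        x = x + rng.normal(0.0, sigma, len(x))

    meta = CallMeta(
        individual_id=profile.individual_id,
        call_type=call_type,
        caller_class=profile.caller_class,
        sex=profile.sex,
        year=year,
        session_id=session_id,
        body_mass_kg=profile.body_mass_kg,
        call_id=call_id or f"{profile.individual_id}-{call_type}-{seed}",
    )
    truth = {k: v for k, v in q.items() if k != "end_rise_frac"}
    truth["contour_times"] = t
    truth["contour_f0"] = f0
    return SynthCall(samples=x, rate=spec.rate, meta=meta, truth=truth)


def synth_call_batch(
    spec: PopulationSpec,
    profiles: Sequence[IndividualProfile],
    call_types: Sequence[str],
    n_calls_per_type: int,
    seed: int,
    year: Optional[int] = None,
) -> list[SynthCall]:
    """Synthesize ``n_calls_per_type`` calls of each type for every profile."""
    if n_calls_per_type < 1:
        raise ValueError("n_calls_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    calls = []
    for profile in profiles:
        for ct in call_types:
            for j in range(n_calls_per_type):
                sub = int(rng.integers(2 ** 31))
                cid = f"{profile.individual_id}-{ct}-{year or 0}-{j:03d}"
                calls.append(synth_call(spec, profile, ct, sub, year=year,
                                        call_id=cid))
    return calls


def sample_features_direct(
    spec: PopulationSpec,
    profiles: Sequence[IndividualProfile],
    n_calls_per_type: int,
    seed: int,
    call_types: Sequence[str] = ("oral", "nasal"),
    year: Optional[int] = None,
) -> pd.DataFrame:
    """Sample feature rows directly from the latent model, bypassing audio.

    Each row is the individual's latent mean plus within-individual
    Gaussian noise, so marginal means/SDs match the spec and the
    between/within variance split honors ``icc``.  Used for fast
    statistical simulations; the audio path is the full pipeline.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if n_calls_per_type < 1:
        raise ValueError("n_calls_per_type must be >= 1")
    if n_calls_per_type < 2:
        import warnings
        warnings.warn("fewer than 2 calls per individual: unusable for DFA",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    rows = []
    for profile in profiles:
        for ct in call_types:
            lat = profile.latent[ct]
            for j in range(n_calls_per_type):
                feats = {
                    name: lat[name]
                    + spec.within_sd(ct, name) * rng.standard_normal()
                    for name in FEATURE_NAMES
                }
                meta = CallMeta(
                    individual_id=profile.individual_id, call_type=ct,
                    caller_class=profile.caller_class, sex=profile.sex,
                    year=year, body_mass_kg=profile.body_mass_kg,
                    call_id=f"{profile.individual_id}-{ct}-{year or 0}-{j:03d}",
                )
                rows.append({**meta.as_dict(), **feats})
    return pd.DataFrame(rows)


def draw_group_sizes(
    n_groups: int, total: int, low: int, high: int, seed: int
) -> np.ndarray:
    """Group sizes drawn uniformly from [low, high] then adjusted to ``total``.

    Used to emulate designs where only the per-animal range and the grand
    total of calls are known.
    """
    if not low * n_groups <= total <= high * n_groups:
        raise ValueError(f"total {total} unreachable with {n_groups} groups "
                         f"in [{low}, {high}]")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(low, high + 1, n_groups)
    while sizes.sum() != total:
        i = rng.integers(n_groups)
        if sizes.sum() < total and sizes[i] < high:
            sizes[i] += 1
        elif sizes.sum() > total and sizes[i] > low:
            sizes[i] -= 1
    return sizes


def gaussian_null_table(
    group_sizes: Sequence[int], n_vars: int, seed: int
) -> pd.DataFrame:
    """No-signal reference table: iid standard-normal features, fixed labels.

    Valid as a chance-level design for discriminant classification because
    the classifier is affine-invariant: any Gaussian table with labels
    carrying no information yields the same accuracy distribution.
    """
    group_sizes = np.asarray(group_sizes, dtype=int)
    if np.any(group_sizes < 2):
        raise ValueError("every group needs >= 2 rows")
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(group_sizes.sum())
    X = rng.standard_normal((n, n_vars))
    labels = np.repeat([f"g{i + 1:02d}" for i in range(len(group_sizes))],
                       group_sizes)
    df = pd.DataFrame(X, columns=[f"var{j + 1:02d}" for j in range(n_vars)])
    df.insert(0, "individual_id", labels)
    return df


def save_calls(calls: Sequence[SynthCall], outdir: str | Path) -> Path:
    """Write 16-bit PCM WAV files plus a sidecar CSV of metadata and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for call in calls:
        fname = f"{call.meta.call_id}.wav"
        pcm = np.clip(call.samples, -1.0, 1.0)
        wavfile.write(outdir / fname, call.rate, (pcm * 32767).astype(np.int16))
        row = {"file": fname, **call.meta.as_dict()}
        row.update({f"true_{k}": v for k, v in call.truth.items()
                    if not k.startswith("contour_")})
        rows.append(row)
    sidecar = outdir / "calls.csv"
    pd.DataFrame(rows).to_csv(sidecar, index=False)
    return sidecar
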