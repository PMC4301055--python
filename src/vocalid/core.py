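"""Shared domain types: call metadata and the 14-variable acoustic feature set.

The feature set follows the standard bioacoustic description of tonal
contact calls: two temporal variables, six fundamental-frequency (f0)
variables measured on the pitch contour, and six power variables measured
on a mean power spectrum around the f0 maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

#: Canonical order of the 14 measured acoustic variables.
FEATURE_NAMES: tuple[str, ...] = (
    "durat",        # call duration, s
    "dur_to_max",   # onset -> f0 maximum, s
    "f0beg",        # f0 at first voiced frame, Hz
    "f0end",        # f0 at last voiced frame, Hz
    "f0max",        # maximum f0, Hz
    "f0min",        # minimum f0, Hz
    "f0mean",       # mean f0 over voiced frames, Hz
    "delta_f0",     # depth of frequency modulation, f0max - f0min, Hz
    "fpeak",        # frequency of maximum spectral amplitude, Hz
    "q25",          # lower energy quartile, Hz
    "q50",          # medium energy quartile, Hz
    "q75",          # upper energy quartile, Hz
    "power_f0",     # dB of peak harmonic band above the f0 band, >= 0
    "peak_harm",    # order of the harmonic carrying maximum energy, >= 1
)

#: The 11 variables entering discriminant analysis. fpeak and peak_harm are
#: excluded (heavily non-normal) and f0min is excluded because delta_f0 is
#: derived from it.
DFA_VARIABLES: tuple[str, ...] = (
    "durat", "dur_to_max", "f0beg", "f0end", "f0max", "f0mean",
    "delta_f0", "q25", "q50", "q75", "power_f0",
)

#: Metadata columns written alongside features in CSV tables.
META_COLUMNS: tuple[str, ...] = (
    "call_id", "individual_id", "call_type", "caller_class",
    "sex", "year", "session_id", "body_mass_kg",
)


@dataclass
class CallMeta:
    """Identity and grouping labels plus covariates for a single call."""

    individual_id: str
    call_type: str                 # "oral" | "nasal"
    caller_class: str = "hind"     # "hind" | "calf"
    sex: str = "unknown"           # "male" | "female" | "unknown"
    year: Optional[int] = None
    session_id: Optional[str] = None
    body_mass_kg: Optional[float] = None
    call_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.call_type not in ("oral", "nasal"):
            raise ValueError(f"call_type must be oral|nasal, got {self.call_type!r}")
        if self.caller_class not in ("hind", "calf"):
            raise ValueError(
                f"caller_class must be hind|calf, got {self.caller_class!r}")

    def as_dict(self) -> dict:
        d = asdict(self)
        return {k: d[k] for k in META_COLUMNS}


@dataclass
class FeatureVector:
    """The 14 measured acoustic variables of one call.

    Invariants (checked in :meth:`validate`): f0min <= f0beg, f0end, f0mean
    <= f0max; delta_f0 == f0max - f0min; 0 <= dur_to_max <= durat;
    q25 <= q50 <= q75; power_f0 >= 0; peak_harm >= 1.
    """

    durat: float
    dur_to_max: float
    f0beg: float
    f0end: float
    f0max: float
    f0min: float
    f0mean: float
    delta_f0: float
    fpeak: float
    q25: float
    q50: float
    q75: float
    power_f0: float
    peak_harm: int

    def validate(self, atol: float = 1e-6) -> None:
        fv = self
        if not (fv.f0min - atol <= min(fv.f0beg, fv.f0end, fv.f0mean)
                and max(fv.f0beg, fv.f0end, fv.f0mean) <= fv.f0max + atol):
            raise ValueError("f0 extremes do not bracket f0beg/f0end/f0mean")
        if abs(fv.delta_f0 - (fv.f0max - fv.f0min)) > atol:
            raise ValueError("delta_f0 != f0max - f0min")
        if not (-atol <= fv.dur_to_max <= fv.durat + atol):
            raise ValueError("dur_to_max outside [0, durat]")
        if not (fv.q25 <= fv.q50 + atol and fv.q50 <= fv.q75 + atol):
            raise ValueError("energy quartiles not monotone")
        if fv.power_f0 < -atol:
            raise ValueError("power_f0 negative")
        if fv.peak_harm < 1:
            raise ValueError("peak_harm < 1")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_NAMES}
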