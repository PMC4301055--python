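"""Published population-level feature statistics used as generator defaults.

Means and standard deviations of the 14 acoustic variables of oral and
nasal contact calls of farmed Iberian red deer hinds (n = 28) and calves
(n = 31), as reported in the source study of mother/offspring vocal
individuality.  The printed SDs conflate between- and within-individual
variance; the synthesizer splits them with an intraclass-correlation
parameter (see :mod:`vocalid.synth`).

Body-mass statistics correspond to the animals whose calls entered the
discriminant analyses (22 hinds, 17 calves).
"""

from __future__ import annotations

# {caller_class: {call_type: {feature: (mean, sd)}}}
POPULATION_TABLE: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "hind": {
        "oral": {
            "durat": (0.759, 0.235),
            "dur_to_max": (0.230, 0.098),
            "f0beg": (137.0, 33.0),
            "f0end": (89.0, 19.0),
            "f0max": (180.0, 31.0),
            "f0min": (95.0, 18.0),
            "f0mean": (153.0, 25.0),
            "delta_f0": (85.0, 26.0),
            "fpeak": (1418.0, 555.0),
            "q25": (952.0, 285.0),
            "q50": (1731.0, 255.0),
            "q75": (2471.0, 252.0),
            "power_f0": (13.90, 5.76),
            "peak_harm": (8.2, 3.3),
        },
        "nasal": {
            "durat": (0.791, 0.253),
            "dur_to_max": (0.308, 0.138),
            "f0beg": (128.0, 29.0),
            "f0end": (89.0, 16.0),
            "f0max": (173.0, 32.0),
            "f0min": (93.0, 14.0),
            "f0mean": (148.0, 24.0),
            "delta_f0": (80.0, 29.0),
            "fpeak": (1060.0, 568.0),
            "q25": (713.0, 250.0),
            "q50": (1632.0, 257.0),
            "q75": (2534.0, 261.0),
            "power_f0": (5.38, 4.10),
            "peak_harm": (6.1, 3.1),
        },
    },
    "calf": {
        "oral": {
            "durat": (0.264, 0.080),
            "dur_to_max": (0.311, 0.078),
            "f0beg": (773.0, 113.0),
            "f0end": (518.0, 96.0),
            "f0max": (875.0, 99.0),
            "f0min": (554.0, 93.0),
            "f0mean": (778.0, 87.0),
            "delta_f0": (321.0, 77.0),
            "fpeak": (2973.0, 684.0),
            "q25": (1681.0, 506.0),
            "q50": (2987.0, 384.0),
            "q75": (3730.0, 238.0),
            "power_f0": (10.49, 5.67),
            "peak_harm": (3.5, 0.9),
        },
        "nasal": {
            "durat": (0.230, 0.039),
            "dur_to_max": (0.300, 0.133),
            "f0beg": (695.0, 122.0),
            "f0end": (481.0, 58.0),
            "f0max": (781.0, 103.0),
            "f0min": (512.0, 76.0),
            "f0mean": (694.0, 79.0),
            "delta_f0": (269.0, 92.0),
            "fpeak": (2289.0, 948.0),
            "q25": (1163.0, 387.0),
            "q50": (2488.0, 515.0),
            "q75": (3564.0, 395.0),
            "power_f0": (6.90, 6.98),
            "peak_harm": (3.0, 1.3),
        },
    },
}

# {caller_class: (mean_kg, sd_kg, min_kg, max_kg)}
BODY_MASS: dict[str, tuple[float, float, float, float]] = {
    "hind": (104.8, 12.2, 85.3, 121.5),
    "calf": (16.0, 4.4, 10.0, 25.8),
}
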