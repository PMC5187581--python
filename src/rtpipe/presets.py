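"""Dataset presets mirroring the experiment shapes the pipeline targets.

``anomer_pair``: two sugar anomers measured on four junctions (the pairwise
discrimination experiment).  ``ten_class_pool``: the ten most abundant
mammalian monosaccharides pooled into one multi-class problem.
``concentration_series``: a Langmuir titration of one analyte.
``contamination_stress``: elevated servo-artifact and common-class fractions
for filter stress-testing.
"""

from __future__ import annotations

import numpy as np

from .io import ClassProfile, GeneratorConfig, default_classes

#: the ten most abundant mammalian monosaccharides
TEN_MONOSACCHARIDES = [
    "glucose", "galactose", "mannose", "fucose", "xylose", "ribose",
    "GlcNAc", "GalNAc", "glucuronate", "Neu5Ac",
]


def ten_class_profiles() -> list[ClassProfile]:
    """Ten analyte profiles plus water, spread over a parameter lattice.

    Neighbouring classes overlap in any single parameter; the joint
    (amplitude, dwell, spectral) signature separates them.
    """
    profiles = []
    rng = np.random.default_rng(20161213)  # fixed lattice jitter
    amps = np.linspace(np.log(34.0), np.log(60.0), 10)
    ons = np.linspace(0.7e-3, 2.2e-3, 10)
    corners = np.linspace(1500.0, 4500.0, 10)
    order = rng.permutation(10)
    for i, name in enumerate(TEN_MONOSACCHARIDES):
        profiles.append(ClassProfile(
            name,
            amp_log_mean=float(amps[i]),
            amp_log_sd=0.30,
            on_dwell_mean=float(ons[order[i]]),
            off_dwell_mean=float(ons[order[i]]) * 1.4,
            spectral_corner=float(corners[(i * 3) % 10]),
            cluster_len_mean=5.0,
            capture_weight=1.0,
        ))
    water = [c for c in default_classes() if c.name == "water"][0]
    profiles.append(water)
    return profiles


def preset_config(name: str, duration: float = 60.0) -> GeneratorConfig:
    """A generator configuration for a named preset."""
    if name == "anomer_pair":
        return GeneratorConfig(duration=duration, n_junctions=4)
    if name == "ten_class_pool":
        return GeneratorConfig(duration=duration, n_junctions=4,
                               classes=ten_class_profiles())
    if name == "concentration_series":
        return GeneratorConfig(duration=duration, water_fraction=0.0,
                               zpiezo_contam_fraction=0.0)
    if name == "contamination_stress":
        return GeneratorConfig(duration=duration, n_junctions=2,
                               water_fraction=0.6,
                               zpiezo_contam_fraction=0.3)
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ["anomer_pair", "ten_class_pool", "concentration_series",
           "contamination_stress"]


def preset_labels(name: str) -> list[str]:
    if name == "anomer_pair":
        return ["alphaMGlu", "betaMGlu"]
    if name == "ten_class_pool":
        return list(TEN_MONOSACCHARIDES)
    if name == "contamination_stress":
        return ["alphaMGlu", "betaMGlu"]
    if name == "concentration_series":
        return ["alphaMGlu"]
    raise ValueError(f"unknown preset {name!r}")
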