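"""Published reference values for the Hainan central mountainous area (CMA) study.

These are the study's published summary tables — class areas per epoch and
the landscape-pattern index table (patch counts, class areas in hectares and
the derived indices) — shipped as inputs so the index formulas can be
exercised and cross-checked against the published values without the
original rasters, which are not publicly deposited.
"""

from __future__ import annotations

#: Class areas (km²) per epoch for the six-class CMA scheme.
CMA_CLASS_AREAS_KM2: dict[str, dict[str, float]] = {
    "2000": {"cultivated": 599.16, "forest": 5264.29, "orchard": 733.58,
             "grassland": 440.33, "water": 49.47, "construction": 28.57},
    "2010": {"cultivated": 592.63, "forest": 5308.71, "orchard": 716.57,
             "grassland": 408.68, "water": 57.41, "construction": 31.42},
    "2018": {"cultivated": 583.70, "forest": 5286.44, "orchard": 707.12,
             "grassland": 407.00, "water": 69.74, "construction": 61.42},
}

#: Published landscape-pattern index table: per class and epoch, patch count
#: n, class area A (hectares) and the published indices C (fragmentation),
#: N (separation), F (fractal dimension), E (disturbance, weights 0.5/0.3/0.2).
CMA_PATTERN_TABLE: dict[tuple[str, str], dict[str, float]] = {
    ("cultivated", "2000"): {"n": 1398, "A_ha": 59916, "C": 0.0233, "N": 0.2632, "F": 1.1040, "E": 0.3114},
    ("cultivated", "2010"): {"n": 1311, "A_ha": 59263, "C": 0.0221, "N": 0.2577, "F": 1.1104, "E": 0.3104},
    ("cultivated", "2018"): {"n": 1318, "A_ha": 58370, "C": 0.0226, "N": 0.2623, "F": 1.1101, "E": 0.3120},
    ("forest", "2000"): {"n": 400, "A_ha": 526429, "C": 0.0008, "N": 0.0160, "F": 1.0773, "E": 0.2206},
    ("forest", "2010"): {"n": 380, "A_ha": 530871, "C": 0.0007, "N": 0.0155, "F": 1.0815, "E": 0.2213},
    ("forest", "2018"): {"n": 419, "A_ha": 528644, "C": 0.0008, "N": 0.0163, "F": 1.0828, "E": 0.2219},
    ("orchard", "2000"): {"n": 481, "A_ha": 73358, "C": 0.0066, "N": 0.1261, "F": 1.0901, "E": 0.2591},
    ("orchard", "2010"): {"n": 490, "A_ha": 71657, "C": 0.0068, "N": 0.1303, "F": 1.0884, "E": 0.2602},
    ("orchard", "2018"): {"n": 493, "A_ha": 70712, "C": 0.0070, "N": 0.1324, "F": 1.0906, "E": 0.2613},
    ("grassland", "2000"): {"n": 1242, "A_ha": 44033, "C": 0.0282, "N": 0.3376, "F": 1.1031, "E": 0.3360},
    ("grassland", "2010"): {"n": 1216, "A_ha": 40868, "C": 0.0298, "N": 0.3599, "F": 1.1043, "E": 0.3437},
    ("grassland", "2018"): {"n": 1212, "A_ha": 40700, "C": 0.0298, "N": 0.3608, "F": 1.1036, "E": 0.3438},
    ("water", "2000"): {"n": 172, "A_ha": 4947, "C": 0.0348, "N": 1.1181, "F": 1.1102, "E": 0.5748},
    ("water", "2010"): {"n": 162, "A_ha": 5741, "C": 0.0282, "N": 0.9351, "F": 1.1125, "E": 0.5172},
    ("water", "2018"): {"n": 175, "A_ha": 6974, "C": 0.0251, "N": 0.8000, "F": 1.1135, "E": 0.4752},
    ("construction", "2000"): {"n": 224, "A_ha": 2857, "C": 0.0784, "N": 2.2092, "F": 1.0561, "E": 0.9132},
    ("construction", "2010"): {"n": 225, "A_ha": 3142, "C": 0.0716, "N": 2.0133, "F": 1.0586, "E": 0.8515},
    ("construction", "2018"): {"n": 314, "A_ha": 6142, "C": 0.0511, "N": 1.2168, "F": 1.0596, "E": 0.6025},
}

CLASSES = ["cultivated", "forest", "orchard", "grassland", "water", "construction"]


def landscape_area_ha(year: str) -> float:
    """Total landscape area A (ha) for an epoch: sum of the published class areas."""
    return sum(CMA_PATTERN_TABLE[(c, year)]["A_ha"] for c in CLASSES)
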