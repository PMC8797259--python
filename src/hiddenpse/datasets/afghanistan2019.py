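"""Published summary tables of the 2019 eight-city Afghanistan PWID
size-estimation study.

These are the city-level inputs a reproduction run needs: adult
population denominators, the 2012 unique-object priors, the sentinel
drop-in-center monthly series, key-informant and wisdom-of-the-crowds
sex counts, and the per-method prevalence rows of the synthesis table.
Raw field data (hotspot lists, survey records, capture cell counts)
were never published, so city-level method estimates appear here as
printed inputs, not as quantities this package can recompute.
"""

from __future__ import annotations

from ..types import MonthlySeries

CITIES = ("Kabul", "Herat", "Mazar", "Jalalabad", "Kunduz", "Faizabad", "Kandahar", "Zaranj")

#: adult population 15-64 by city: (male, female)
ADULT_POP: dict[str, tuple[int, int]] = {
    "Kabul": (1_125_624, 1_100_063),
    "Herat": (150_110, 141_226),
    "Mazar": (125_377, 120_343),
    "Jalalabad": (70_099, 67_769),
    "Kunduz": (48_871, 47_129),
    "Faizabad": (10_189, 9_721),
    "Kandahar": (134_936, 130_419),
    "Zaranj": (8_039, 7_617),
}

#: 2012 unique-object priors: city -> (point, lower, upper) persons
PRIORS_2012: dict[str, tuple[float, float, float]] = {
    "Kabul": (12_546, 6_682, 27_292),
    "Herat": (1_211, 958, 1_582),
    "Mazar": (1_495, 1_210, 1_895),
    "Jalalabad": (1_466, 1_069, 2_101),
}
PRIORS_2012_POOLED = (16_719, 9_919, 32_870)
PRIORS_2012_POOLED_MALE_POP = 1_471_210

#: reverse-tracking worked example: one hotspot's key-informant count,
#: the city key-informant total, and the enumerated count
RTM_EXAMPLE = {"ki_count": 22, "ki_total": 135, "enum_count": 20}

#: Kabul service-multiplier inputs: unduplicated clients and survey share
KABUL_SM_INPUTS = {"benchmark": 898, "proportion": 0.383}

#: sentinel-city monthly drop-in-center clients (Jan..Dec, 2018);
#: data collection overlapped January-March
MONTHLY_2018: dict[str, list[int]] = {
    "Faizabad": [55, 53, 55, 62, 55, 68, 65, 71, 76, 78, 80, 86],
    "Kunduz": [475, 479, 479, 487, 506, 524, 447, 515, 525, 531, 582, 634],
}
COLLECTION_MONTHS = (1, 2, 3)

#: the seasonality factor the study applied (pooled ratio rounded to 10%)
APPLIED_SEASONALITY = 1.10

#: (male, female) counts by city: key informants / focus groups
KI_SEX_COUNTS: dict[str, tuple[int, int]] = {
    "Kabul": (1_185, 4),
    "Herat": (345, 9),
    "Mazar": (420, 1),
    "Jalalabad": (232, 1),
    "Kunduz": (485, 1),
    "Faizabad": (36, 6),
    "Kandahar": (258, 1),
    "Zaranj": (102, 2),
}

#: (male, female) counts by city: wisdom of the crowds
WOTC_SEX_COUNTS: dict[str, tuple[int, int]] = {
    "Kabul": (4_615, 234),
    "Herat": (360, 5),
    "Mazar": (201, 7),
    "Jalalabad": (238, 10),
    "Kunduz": (152, 2),
    "Faizabad": (16, 4),
    "Kandahar": (135, 2),
    "Zaranj": (515, 134),
}

#: male-to-total ratio applied in the published chain
GLOBAL_MALE_TO_TOTAL = 0.96

#: per-method male prevalence rows (%: point, lower, upper) of the
#: synthesis table, keyed city -> method label
SYNTHESIS_INPUTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "Kabul": {
        "prior": (1.11, 0.59, 2.42),
        "rtm": (0.67, 0.46, 0.89),
        "uom": (0.46, 0.33, 0.76),
        "crc_dga": (0.21, 0.11, 0.33),
        "sm1": (0.21, 0.17, 0.27),
        "wotc": (0.41, 0.36, 0.46),
    },
    "Herat": {
        "prior": (0.81, 0.64, 1.05),
        "rtm": (0.16, 0.13, 0.19),
        "uom": (0.29, 0.23, 0.38),
        "crc_dga": (0.58, 0.28, 0.74),
        "sm1": (0.06, 0.06, 0.07),
        "sm2": (0.15, 0.14, 0.16),
        "wotc": (0.24, 0.21, 0.27),
    },
    "Mazar": {
        "prior": (1.19, 0.97, 1.51),
        "rtm": (0.36, 0.30, 0.42),
        "uom": (0.25, 0.20, 0.33),
        "crc_dga": (0.65, 0.58, 0.73),
        "sm1": (0.54, 0.46, 0.65),
        "wotc": (0.16, 0.14, 0.18),
    },
    "Jalalabad": {
        "prior": (2.09, 1.52, 3.00),
        "rtm": (0.43, 0.34, 0.52),
        "uom": (0.49, 0.36, 0.73),
        "crc_dga": (1.12, 1.02, 1.25),
        "sm1": (0.34, 0.34, 0.36),
        "wotc": (0.34, 0.29, 0.39),
    },
    "Kunduz": {
        "prior": (1.75, 1.45, 2.41),
        "rtm": (2.12, 1.57, 2.67),
        "uom": (0.44, 0.37, 0.55),
        "crc_dga": (1.65, 1.56, 1.76),
        "sm1": (3.49, 2.51, 5.76),
        "wotc": (0.31, 0.20, 0.41),
    },
    "Faizabad": {
        "prior": (3.83, 2.59, 4.90),
        "rtm": (0.55, 0.43, 0.67),
        "uom": (0.37, 0.34, 0.39),
        "crc_dga": (2.39, 2.22, 2.61),
        "sm1": (1.20, 0.91, 1.74),
    },
    "Kandahar": {
        "prior": (0.72, 0.50, 1.02),
        "rtm": (0.19, 0.14, 0.24),
        "uom": (0.30, 0.23, 0.41),
        "crc_dga": (0.60, 0.51, 0.78),
        "sm1": (1.27, 1.08, 1.53),
        "wotc": (0.10, 0.08, 0.13),
    },
    "Zaranj": {
        "prior": (6.90, 5.06, 9.64),
        "rtm": (9.34, 6.12, 12.58),
        "uom": (3.13, 2.46, 4.34),
        "crc_dga": (9.85, 9.17, 10.64),
        "sm1": (11.20, 10.04, 12.65),
        "sm2": (10.46, 9.11, 12.27),
        "wotc": (6.41, 5.60, 7.21),
    },
}

#: published consensus rows (%: point, lower, upper) - soft reference
PUBLISHED_ANCHORED: dict[str, tuple[float, float, float]] = {
    "Kabul": (0.38, 0.34, 0.42),
    "Herat": (0.12, 0.11, 0.12),
    "Mazar": (0.32, 0.30, 0.34),
    "Jalalabad": (0.37, 0.36, 0.38),
    "Kunduz": (1.27, 1.19, 1.35),
    "Faizabad": (0.49, 0.47, 0.52),
    "Kandahar": (0.28, 0.25, 0.32),
    "Zaranj": (8.74, 8.27, 9.21),
}
PUBLISHED_ANCHORED_VA: dict[str, tuple[float, float, float]] = {
    "Kabul": (0.47, 0.33, 0.64),
    "Herat": (0.41, 0.33, 0.50),
    "Mazar": (0.83, 0.65, 1.04),
    "Jalalabad": (0.86, 0.67, 1.07),
    "Kunduz": (1.84, 1.32, 2.43),
    "Faizabad": (2.93, 2.21, 3.72),
    "Kandahar": (0.76, 0.58, 0.96),
    "Zaranj": (8.53, 6.60, 10.57),
}

#: published male subtotal for the 23 extrapolated provincial capitals
#: (point, lower, upper) and their adult male population - the raw
#: proxy table behind these rows was not published, so they enter the
#: national aggregation as fixed inputs
EXTRAPOLATED_MALE_SUBTOTAL = (1_627, 1_200, 2_129)
EXTRAPOLATED_FEMALE_SUBTOTAL = (78, 61, 101)
EXTRAPOLATED_TOTAL_SUBTOTAL = (1_705, 1_261, 2_230)
EXTRAPOLATED_MALE_POP = 232_367
EXTRAPOLATED_FEMALE_POP = 218_314

#: national adult populations 15-64 (male, female)
NATIONAL_ADULT_POP = (7_948_784, 8_055_068)
URBAN_31_MALE_POP = 1_905_612
URBAN_31_FEMALE_POP = 1_842_601


def monthly_series() -> list[MonthlySeries]:
    """Sentinel-city series as validated :class:`MonthlySeries`."""
    return [
        MonthlySeries(
            city=city,
            counts=[float(v) for v in counts],
            collected=[m in COLLECTION_MONTHS for m in range(1, 13)],
        )
        for city, counts in MONTHLY_2018.items()
    ]
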