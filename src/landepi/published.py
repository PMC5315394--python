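"""Summary counts and estimates from the Spanish childhood CNS-tumour
case-control study that this package's synthetic generator emulates.

These are the registry-level facts the simulator is calibrated to: the
case series (714 incident CNS tumours, 1996-2011, five autonomous
regions), its subgroup and regional breakdown, the matched-control design
(6 controls per case, 4284 in total), and the adjusted odds ratios of the
published full model, which serve as default "true" effects for
parameter-recovery simulations.
"""

from __future__ import annotations

N_CASES = 714
MATCH_RATIO = 6
N_CONTROLS = N_CASES * MATCH_RATIO  # 4284
N_SAME_ADDRESS_CASES = 332  # cases whose birth and diagnosis address coincide
INVALID_GEOCODE_FRACTION = 0.02

STUDY_YEARS = (1996, 2011)

REGIONS = ("Aragon", "Basque Country", "Catalonia", "Madrid", "Navarre")

#: cases by region: total, boys, girls
CASES_BY_REGION = {
    "Aragon": (52, 30, 22),
    "Catalonia": (343, 178, 165),
    "Madrid": (201, 111, 90),
    "Navarre": (35, 23, 12),
    "Basque Country": (83, 42, 41),
}

#: ICCC-3 group III subgroups: (cases, boys, girls, same-address cases)
CASES_BY_SUBGROUP = {
    "ependymoma": (94, 55, 39, 55),
    "astrocytoma": (258, 129, 129, 112),
    "iiet": (171, 102, 69, 78),
    "other_gliomas": (88, 38, 50, 40),
    "other_specified": (72, 46, 26, 28),
    "unspecified": (31, 14, 17, 19),
}

SUBGROUPS = tuple(CASES_BY_SUBGROUP)

#: default multinomial for simulated case subgroup labels
SUBGROUP_SHARES = {k: v[0] / N_CASES for k, v in CASES_BY_SUBGROUP.items()}

#: census "socioeconomic condition" range observed across tracts
SES_RANGE = (0.46, 1.57)

#: adjusted odds ratios of the published full model, total CNS tumours.
#: GCI is per 10-percentage-point increase; SES quartiles vs Q1;
#: environment categories vs rural.
TOTAL_CNS_OR = {
    "gci10": 1.22,
    "ses_q2": 0.97,
    "ses_q3": 1.01,
    "ses_q4": 1.37,
    "env_industrial": 0.96,
    "env_intersection": 1.20,
    "env_urban": 0.90,
}

#: full-model 2x2 margins usable for crude-OR arithmetic checks:
#: {term: (cases_exposed, cases_reference, controls_exposed, controls_reference)}
TOTAL_CNS_COUNTS = {
    "ses_q4_vs_q1": (229, 152, 1135, 1135),
    "industrial_vs_rural": (301, 88, 1837, 421),
}

#: distance sweep used to choose the industrial-exposure distance D (metres)
D_SWEEP_METRES = (1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 4000.0, 5000.0)
CHOSEN_D_METRES = 2000.0
OUTER_RING_METRES = 5000.0
BUFFER_RADIUS_METRES = 1000.0
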