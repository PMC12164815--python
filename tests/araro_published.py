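"""Published summary statistics from the Araró dust arsenic study.

Frozen reference values used as table-driven oracles: the deterministic
consistency chain between the published dose and risk tables, and the
±20% bands the stochastic reproduction tests target.  Dermal cells are
deliberately absent from the chain data — the published dermal doses are
not reproducible from the published parameter set (see docs/methods.md)
and serve only as a documented-mismatch check.
"""

from dustrisk.params import AgeGroup, Pathway

P, E, T, A = AgeGroup.PRESCHOOLER, AgeGroup.ELEMENTARY, AgeGroup.ADOLESCENT, AgeGroup.ADULT

# Mean ADD (mg/kg/day), oral and inhalation pathways.
ADD_MEAN = {
    (P, Pathway.ORAL): 1.05e-4,
    (E, Pathway.ORAL): 5.26e-5,
    (T, Pathway.ORAL): 8.34e-6,
    (A, Pathway.ORAL): 7.36e-6,
    (P, Pathway.INHALATION): 7.24e-9,
    (E, Pathway.INHALATION): 4.63e-9,
    (T, Pathway.INHALATION): 3.20e-9,
    (A, Pathway.INHALATION): 2.83e-9,
}

# Mean HQ; inhalation values are printed to one significant figure.
HQ_MEAN = {
    (P, Pathway.ORAL): 0.3485,
    (E, Pathway.ORAL): 0.1752,
    (T, Pathway.ORAL): 0.0278,
    (A, Pathway.ORAL): 0.0245,
    (P, Pathway.INHALATION): 0.0005,
    (E, Pathway.INHALATION): 0.0003,
    (T, Pathway.INHALATION): 0.0002,
    (A, Pathway.INHALATION): 0.0002,
}

# Mean oral carcinogenic risk (published convention CR = cADD/SF).
CR_ORAL_MEAN = {P: 3.36e-6, E: 4.42e-6}

# Published dermal cells (NOT reproducible from the parameter set).
DERMAL_ADD_MEDIAN = {P: 6.09e-5}

# Medians / means targeted by the stochastic reproduction checks.
MC_TARGETS = {
    "preschooler_oral_add_median": 9.59e-5,
    "preschooler_inhalation_add_median": 6.61e-9,
    "adult_oral_add_median": 6.12e-6,
    "adolescent_oral_add_median": 7.39e-6,
    "preschooler_oral_hq_median": 0.3187,
    "elementary_oral_hq_mean": 0.1752,
    "preschooler_oral_cr_median": 3.07e-6,
}

AT_DAYS = {P: 1_229.0, E: 3_087.0, T: 5_558.0, A: 15_029.0}
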