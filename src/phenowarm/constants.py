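"""Shared vocabulary: phenophases, phenoperiods, treatment labels, schemas."""

# The six standardized phenophases, in seasonal order.
PHENOPHASES = (
    "green_up",
    "flowering",
    "end_of_flowering",
    "fruiting",
    "seed_dispersal",
    "leaf_senescence",
)

# Phenoperiods are spans between a starting and an ending phenophase.
PHENOPERIODS = {
    "growth": ("green_up", "leaf_senescence"),
    "flowering": ("flowering", "end_of_flowering"),
    "fruiting": ("fruiting", "seed_dispersal"),
}

TREATMENTS = ("control", "otc")

MOISTURE_CLASSES = ("dry", "moist", "wet")

DEPLOYMENTS = ("year_round", "summer_only")

# Fallback lower-bound floors (DOY) used when an event precedes the first
# census visit of the season; phenophases without a stated floor fall back
# to the green-up floor with a warning.
FALLBACK_FLOORS = {
    "green_up": 100,
    "flowering": 120,
    "end_of_flowering": 120,
}
DEFAULT_FALLBACK_FLOOR = 100
FALLBACK_OFFSET_DAYS = 21

# Long-format observation schema shared between the generator and prep.
OBSERVATION_COLUMNS = (
    "site",
    "subsite",
    "plot",
    "year",
    "treatment",
    "species",
    "phenophase",
    "doy",
    "prior_visit",
)

CLIMATE_COLUMNS = ("site", "year", "doy", "tmean", "is_missing")
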