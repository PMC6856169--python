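"""Land-cover and soil-group code conventions shared by all stages.

Thirteen Landsat-derived land types are aggregated into six classes; all
grids in this package carry the aggregate integer codes below.
"""

FOREST = 1
GRASSLAND = 2
WETLAND = 3
FARMLAND = 4
ARTIFICIAL = 5
BARE = 6

CLASS_CODES = (FOREST, GRASSLAND, WETLAND, FARMLAND, ARTIFICIAL, BARE)

CLASS_NAMES = {
    FOREST: "forest",
    GRASSLAND: "grassland",
    WETLAND: "wetland",
    FARMLAND: "farmland",
    ARTIFICIAL: "artificial",
    BARE: "bare",
}
NAME_TO_CODE = {v: k for k, v in CLASS_NAMES.items()}

#: classes counted as vegetated for the local-climate-regulation reference
VEGETATED = (FOREST, GRASSLAND, WETLAND, FARMLAND)

#: hydrologic soil groups, coded 1..4 in grids
SOIL_GROUPS = ("A", "B", "C", "D")
SOIL_CODE = {g: i + 1 for i, g in enumerate(SOIL_GROUPS)}
SOIL_NAME = {i + 1: g for i, g in enumerate(SOIL_GROUPS)}

#: ecosystem-service categories of the benefit-transfer valuation
SERVICE_CATEGORIES = ("provisioning", "supporting", "regulating", "cultural")
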