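"""Published reference values from the Salvador, Brazil case study.

The method was originally applied to Salvador (2000 census, 30 m
land-cover classification of a 2002 Landsat TM scene). The fitted
canonical correlations and loadings reported for that city ship here as
a reference configuration, so replication-style runs can map new
land-cover/census inputs with the published weights instead of
refitting. They are reference data, not defaults: the pipeline always
uses loadings from its own fitted model unless explicitly pointed at
these.
"""

from __future__ import annotations

import numpy as np

#: Canonical correlations of the five dimensions (descending).
SALVADOR_CANONICAL_CORRELATIONS = np.array([0.586, 0.347, 0.113, 0.042, 0.010])

#: Observation counts per variable set.
SALVADOR_P = 5
SALVADOR_Q = 5

#: Dimension-1 land-cover loadings over (CO, WP, TR, PA, TX).
SALVADOR_D1_LANDCOVER_LOADINGS = np.array([0.559, -0.348, -0.067, -0.535, -0.130])

#: Dimension-2 socioeconomic loadings over (BA, WA, GA, IN, CR).
SALVADOR_D2_SOCIO_LOADINGS = np.array([0.944, -0.711, 0.689, -0.526, 0.245])

#: Dimension-1 socioeconomic loadings over (BA, WA, GA, IN, CR).
SALVADOR_D1_SOCIO_LOADINGS = np.array([0.057, -0.128, 0.051, -0.845, 0.645])

#: Combination weights for the final map (the first two canonical correlations).
SALVADOR_COMBINE_WEIGHTS = (0.586, 0.347)

#: Descriptive rows for four Salvador communities: socioeconomic variables
#: (IN currency units/month; BA, WA, GA, CR proportions) and land-cover
#: variables (CO, WP, TR, PA percent of impervious; TX intensity units).
SALVADOR_COMMUNITIES: dict[str, dict[str, dict[str, float]]] = {
    "Barrio da Paz": {
        "socio": {"BA": 0.072, "WA": 0.814, "GA": 0.025, "IN": 216.742, "CR": 0.236},
        "landcover": {"CO": 70.824, "WP": 0.000, "TR": 0.014, "PA": 29.163, "TX": 16.340},
    },
    "Pau da Lima": {
        "socio": {"BA": 0.157, "WA": 0.607, "GA": 0.003, "IN": 163.570, "CR": 0.152},
        "landcover": {"CO": 21.873, "WP": 0.000, "TR": 0.146, "PA": 34.236, "TX": 24.790},
    },
    "Nordeste Amaralina": {
        "socio": {"BA": 0.003, "WA": 0.981, "GA": 0.000, "IN": 391.503, "CR": 0.135},
        "landcover": {"CO": 90.361, "WP": 0.000, "TR": 0.127, "PA": 4.756, "TX": 33.190},
    },
    "Barra": {
        "socio": {"BA": 0.000, "WA": 1.000, "GA": 0.000, "IN": 2851.771, "CR": 0.060},
        "landcover": {"CO": 19.469, "WP": 19.469, "TR": 0.061, "PA": 58.406, "TX": 15.380},
    },
}
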