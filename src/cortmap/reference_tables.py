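"""Published cohort summary statistics used as generator defaults.

Demographics and alignment angles are group means and SDs; regional
standardized CBT (x10^-3) is given as mean with 95% CI, from which the SD is
back-computed as ``sqrt(n) * halfwidth / 1.96``.  The correlation defaults
link the MCT coronal inclination to the most proximal-medial standardized CBT
per group.  Groups: OA male (n=22), OA female (n=38), healthy male (n=28),
healthy female (n=25).
"""

from __future__ import annotations

import io

import pandas as pd

GROUP_N = {"oa_male": 22, "oa_female": 38, "healthy_male": 28, "healthy_female": 25}

# (mean, sd) per group
DEMOGRAPHICS = {
    "oa_male": {"age": (73.5, 7.6), "height": (162.8, 6.4), "weight": (66.0, 8.6),
                "bmi": (24.9, 2.9), "fta": (186.8, 2.7), "mct": (12.2, 4.1)},
    "oa_female": {"age": (73.6, 6.5), "height": (148.9, 5.5), "weight": (59.0, 8.6),
                  "bmi": (26.6, 3.7), "fta": (189.3, 4.5), "mct": (12.3, 4.5)},
    "healthy_male": {"age": (71.3, 6.1), "height": (166.2, 4.6), "weight": (63.6, 7.3),
                     "bmi": (23.0, 2.1), "fta": (178.5, 2.5), "mct": (9.3, 2.7)},
    "healthy_female": {"age": (67.7, 5.5), "height": (155.4, 5.3), "weight": (48.3, 5.0),
                       "bmi": (20.0, 1.6), "fta": (175.4, 2.1), "mct": (6.9, 2.3)},
}

# MCT <-> most proximal-medial standardized CBT correlation per group
MCT_CBT_CORRELATION = {"oa_male": 0.594, "oa_female": 0.554,
                       "healthy_male": -0.211, "healthy_female": 0.164}

# standardized CBT (x10^-3): mean and 95% CI per height band, sector and group
_REGIONAL_CSV = """height_band,sector,group,mean,ci_lo,ci_hi
total,medial,oa_male,17.9,16.7,19.1
total,medial,oa_female,17.5,16.8,18.1
total,medial,healthy_male,17.1,16.4,17.7
total,medial,healthy_female,17.4,16.6,18.2
total,lateral,oa_male,16.6,15.8,17.4
total,lateral,oa_female,16.9,16.3,17.6
total,lateral,healthy_male,17.3,16.6,18.0
total,lateral,healthy_female,18.1,17.5,18.7
total,anterior,oa_male,23.5,21.8,25.1
total,anterior,oa_female,21.6,20.3,22.8
total,anterior,healthy_male,23.9,22.7,25.1
total,anterior,healthy_female,23.5,22.5,24.5
total,posterior,oa_male,15.6,14.9,16.2
total,posterior,oa_female,15.0,14.5,15.5
total,posterior,healthy_male,16.1,15.6,16.5
total,posterior,healthy_female,16.0,15.5,16.5
most_proximal,medial,oa_male,17.3,16.3,18.2
most_proximal,medial,oa_female,17.6,16.9,18.3
most_proximal,medial,healthy_male,16.8,15.8,17.7
most_proximal,medial,healthy_female,17.1,16.3,17.9
most_proximal,lateral,oa_male,14.9,14.2,15.6
most_proximal,lateral,oa_female,15.9,15.3,16.6
most_proximal,lateral,healthy_male,16.8,16.1,17.5
most_proximal,lateral,healthy_female,17.6,16.9,18.4
most_proximal,anterior,oa_male,20.4,18.9,21.9
most_proximal,anterior,oa_female,20.6,19.1,22.0
most_proximal,anterior,healthy_male,22.7,21.2,24.3
most_proximal,anterior,healthy_female,23.5,22.4,24.6
most_proximal,posterior,oa_male,14.6,14.1,15.1
most_proximal,posterior,oa_female,15.5,14.8,16.2
most_proximal,posterior,healthy_male,15.6,15.1,16.1
most_proximal,posterior,healthy_female,16.7,15.7,17.6
proximal,medial,oa_male,16.8,15.6,18.0
proximal,medial,oa_female,17.8,16.9,18.6
proximal,medial,healthy_male,17.1,16.3,18.0
proximal,medial,healthy_female,16.8,15.6,17.9
proximal,lateral,oa_male,16.0,15.0,16.9
proximal,lateral,oa_female,16.4,15.7,17.0
proximal,lateral,healthy_male,17.1,16.3,18.0
proximal,lateral,healthy_female,18.2,17.3,19.1
proximal,anterior,oa_male,21.5,19.7,23.2
proximal,anterior,oa_female,19.9,18.8,21.1
proximal,anterior,healthy_male,21.9,20.9,22.9
proximal,anterior,healthy_female,22.2,21.0,23.4
proximal,posterior,oa_male,15.3,14.7,16.0
proximal,posterior,oa_female,15.4,14.7,16.0
proximal,posterior,healthy_male,16.3,15.6,16.9
proximal,posterior,healthy_female,16.1,15.4,16.9
central_proximal,medial,oa_male,16.8,15.5,18.1
central_proximal,medial,oa_female,17.2,16.4,18.0
central_proximal,medial,healthy_male,16.4,15.3,17.5
central_proximal,medial,healthy_female,17.6,16.6,18.6
central_proximal,lateral,oa_male,16.1,15.2,16.9
central_proximal,lateral,oa_female,17.0,16.3,17.8
central_proximal,lateral,healthy_male,17.2,15.9,18.5
central_proximal,lateral,healthy_female,18.2,17.2,19.2
central_proximal,anterior,oa_male,24.2,22.2,26.2
central_proximal,anterior,oa_female,21.4,19.9,22.8
central_proximal,anterior,healthy_male,24.0,22.7,25.3
central_proximal,anterior,healthy_female,24.1,22.9,25.3
central_proximal,posterior,oa_male,15.7,14.8,16.6
central_proximal,posterior,oa_female,15.2,14.6,15.9
central_proximal,posterior,healthy_male,15.8,15.2,16.4
central_proximal,posterior,healthy_female,15.5,15.0,16.0
central_distal,medial,oa_male,19.1,17.4,20.7
central_distal,medial,oa_female,17.5,16.5,18.4
central_distal,medial,healthy_male,17.4,16.2,18.6
central_distal,medial,healthy_female,17.4,15.8,18.9
central_distal,lateral,oa_male,17.1,16.1,18.0
central_distal,lateral,oa_female,17.7,16.9,18.6
central_distal,lateral,healthy_male,17.5,16.6,18.4
central_distal,lateral,healthy_female,18.4,17.3,19.5
central_distal,anterior,oa_male,26.4,24.3,28.5
central_distal,anterior,oa_female,23.2,21.5,25.0
central_distal,anterior,healthy_male,27.0,25.2,28.9
central_distal,anterior,healthy_female,24.4,23.2,25.7
central_distal,posterior,oa_male,15.9,15.0,16.8
central_distal,posterior,oa_female,14.5,14.0,15.0
central_distal,posterior,healthy_male,16.2,15.5,16.9
central_distal,posterior,healthy_female,15.4,14.8,16.1
distal,medial,oa_male,20.1,18.1,22.1
distal,medial,oa_female,17.7,16.7,18.6
distal,medial,healthy_male,18.1,16.9,19.3
distal,medial,healthy_female,17.2,15.8,18.7
distal,lateral,oa_male,18.3,17.1,19.5
distal,lateral,oa_female,17.6,16.5,18.6
distal,lateral,healthy_male,18.0,17.2,18.7
distal,lateral,healthy_female,18.7,18.0,19.4
distal,anterior,oa_male,26.6,24.5,28.8
distal,anterior,oa_female,23.9,22.3,25.5
distal,anterior,healthy_male,27.5,25.6,29.4
distal,anterior,healthy_female,24.6,23.1,26.1
distal,posterior,oa_male,16.7,15.8,17.5
distal,posterior,oa_female,14.5,14.0,15.1
distal,posterior,healthy_male,16.6,15.9,17.3
distal,posterior,healthy_female,15.5,15.0,16.0
most_distal,medial,oa_male,19.3,16.7,21.8
most_distal,medial,oa_female,16.9,16.0,17.8
most_distal,medial,healthy_male,17.5,16.3,18.8
most_distal,medial,healthy_female,18.9,17.3,20.4
most_distal,lateral,oa_male,19.4,17.8,20.9
most_distal,lateral,oa_female,17.4,16.5,18.3
most_distal,lateral,healthy_male,18.9,17.7,20.0
most_distal,lateral,healthy_female,19.0,18.1,19.9
most_distal,anterior,oa_male,25.1,23.0,27.3
most_distal,anterior,oa_female,22.6,21.4,23.7
most_distal,anterior,healthy_male,26.2,24.3,28.1
most_distal,anterior,healthy_female,24.5,22.9,26.1
most_distal,posterior,oa_male,16.1,15.2,17.0
most_distal,posterior,oa_female,14.4,13.8,15.0
most_distal,posterior,healthy_male,16.9,16.2,17.5
most_distal,posterior,healthy_female,15.5,14.9,16.1
"""


def regional_reference() -> pd.DataFrame:
    """Regional standardized-CBT reference with back-computed SDs."""
    df = pd.read_csv(io.StringIO(_REGIONAL_CSV))
    n = df["group"].map(GROUP_N)
    half = (df["ci_hi"] - df["ci_lo"]) / 2.0
    df["sd"] = (n**0.5) * half / 1.96
    return df
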