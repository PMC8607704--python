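"""Small built-in example datasets.

The seven European perch (*Perca fluviatilis*) study lakes — their WGS84
sampling coordinates and the published prioritisation table of all 21
population pairs (standardised proxy distances, pair sums, and cluster
identities) — used in worked examples and as reference inputs for the
prioritisation arithmetic.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

# (degrees, minutes, seconds) north / east for each study lake
_LAKE_DMS = {
    "VAL": ((61, 13, 8.0), (25, 7, 5.0)),       # Valkea-Müstajärvi, Finland
    "ISO": ((60, 57, 21.0), (26, 13, 3.0)),     # Iso-Valkjärvi, Finland
    "KIE": ((53, 47, 54.0), (20, 44, 45.0)),    # Kierzlinskie, Poland
    "GEN": ((46, 22, 7.20), (6, 27, 14.73)),    # Geneva, France
    "BOU": ((45, 44, 12.469), (5, 52, 1.617)),  # Bourget, France
    "HOH": ((53, 55, 10.369), (12, 13, 6.005)), # Hohen Sprenzer, Germany
    "BAL": ((46, 54, 23.375), (18, 2, 43.119)), # Balaton, Hungary
}

# Published prioritisation of the 21 population pairs: number of
# significantly diverging traits, trait-based distance sum and cluster,
# standardised proxy distances (habitat, hydrologic, genetic), their sum,
# and the proxy cluster letter.
_PRIORITISATION_CSV = """\
pair,n_significant_kta,kta_sum,kta_cluster,habitat,hydrologic,genetic,proxy_sum,proxy_cluster
VAL-GEN,5/9,3.63,1,0.85,0.96,0.82,2.63,A
VAL-BOU,4/9,3.02,2,0.79,0.96,0.81,2.56,A
VAL-HOH,4/9,3.23,2,0.56,1,0.94,2.5,A
ISO-GEN,3/9,2.64,2,0.82,0.9,0.77,2.49,A
ISO-BOU,3/9,2.97,2,0.68,0.99,0.77,2.44,A
ISO-HOH,3/9,2.80,2,0.53,0.95,0.86,2.34,A
GEN-BAL,5/9,3.99,1,0.89,0.49,0.93,2.31,A
VAL-BAL,5/9,3.20,2,0.57,0.71,1,2.28,A
BOU-BAL,5/9,3.80,1,0.78,0.57,0.92,2.27,A
ISO-BAL,3/9,2.46,3,0.48,0.66,0.95,2.09,B
BOU-HOH,2/9,2.34,3,0.85,0.67,0.54,2.06,B
GEN-HOH,2/9,2.57,3,1,0.58,0.45,2.03,B
HOH-BAL,4/9,3.85,1,0.41,0.56,0.98,1.95,B
VAL-KIE,3/9,3.22,2,0.26,0.7,0.96,1.92,B
KIE-BAL,5/9,3.81,1,0.39,0.43,0.99,1.81,B
KIE-BOU,1/9,1.80,3,0.65,0.73,0.41,1.79,B
ISO-KIE,5/9,3.66,1,0.24,0.65,0.85,1.74,B
KIE-GEN,2/9,2.93,2,0.75,0.64,0.19,1.58,B
KIE-HOH,3/9,2.11,3,0.29,0.68,0.6,1.57,B
VAL-ISO,3/9,2.07,3,0.09,0.24,0.56,0.89,C
GEN-BOU,1/9,2.17,3,0.49,0.2,0,0.69,C
"""

PROXY_COLUMNS = ["habitat", "hydrologic", "genetic"]


def _dms_to_decimal(dms: tuple[float, float, float]) -> float:
    d, m, s = dms
    return d + m / 60.0 + s / 3600.0


def load_lake_coordinates() -> pd.DataFrame:
    """WGS84 decimal-degree coordinates of the seven study lakes."""
    rows = {
        lake: {
            "latitude": _dms_to_decimal(lat),
            "longitude": _dms_to_decimal(lon),
        }
        for lake, (lat, lon) in _LAKE_DMS.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "population"
    return df


def load_prioritisation_example() -> pd.DataFrame:
    """The published 21-pair prioritisation table.

    Columns: pair, n_significant_kta, kta_sum, kta_cluster, the three
    standardised proxy distances (habitat, hydrologic, genetic), proxy_sum,
    proxy_cluster.
    """
    df = pd.read_csv(
        StringIO(_PRIORITISATION_CSV),
        dtype={"n_significant_kta": str, "kta_cluster": int, "proxy_cluster": str},
    )
    return df.set_index("pair")
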