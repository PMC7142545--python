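"""Small bundled datasets.

``read_mapping_summary`` is the published read-mapping summary of the 15
pea aphid RNA-seq libraries (GEO GSE56830, mapped to the Acyr 2.0 genome):
total reads, mapped reads, and the printed mapping rate per library.  It
serves as a worked-example input for :func:`aphidnet.data.mapping_rate`.
"""

from __future__ import annotations

import pandas as pd

_READ_MAPPING_ROWS = [
    # (type, total_reads, mapped_reads, printed_rate_pct)
    ("F1_WF", 93097593, 79389596, 85.3),
    ("F1_UWF", 101313506, 88512217, 87.4),
    ("F1_SF", 91946734, 82783997, 90.0),
    ("I18_WF", 109616712, 80872988, 73.8),
    ("I18_UWF", 82776192, 59534227, 71.9),
    ("BK11_WF", 102979257, 97275709, 94.5),
    ("BK11_UWF", 106808567, 96654529, 90.5),
    ("F1_WM", 80133908, 67200794, 83.9),
    ("F1_UWM", 68817463, 62643966, 91.0),
    ("I18_WM", 100710783, 63792363, 63.3),
    ("I18_UWM", 94077934, 63733175, 67.7),
    ("I18_SF", 106615474, 92694245, 86.9),
    ("BK11_WM", 82734259, 70391904, 85.1),
    ("BK11_UWM", 71796221, 66195361, 92.2),
    ("BK11_SF", 90793111, 87397909, 96.3),
]


def read_mapping_summary() -> pd.DataFrame:
    """Read-mapping summary of the 15 aphid libraries as a DataFrame."""
    return pd.DataFrame(
        _READ_MAPPING_ROWS,
        columns=["type", "total_reads", "mapped_reads", "printed_rate_pct"],
    ).set_index("type")
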