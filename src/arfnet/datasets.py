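"""Small published data tables used in examples and reproduction checks.

``SEGREGATION_COUNTS`` holds the hygromycin-resistance segregation counts of
T1 progenies from the rolB-transgenic tobacco study this package models:
(line, resistant, sensitive, expected ratio a:b).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["SEGREGATION_COUNTS", "segregation_counts_frame"]

#: line, hygromycin-resistant seedlings, sensitive seedlings, expected ratio
SEGREGATION_COUNTS: tuple[tuple[str, int, int, tuple[int, int]], ...] = (
    ("Nontransformed", 0, 175, (3, 1)),
    ("EV2", 93, 41, (3, 1)),
    ("cRolB1", 163, 26, (6, 1)),
    ("cRolB2", 121, 45, (3, 1)),
    ("cRolB3", 65, 46, (2, 1)),
    ("cRolB7", 66, 34, (2, 1)),
    ("cRolB8", 60, 36, (2, 1)),
)


def segregation_counts_frame() -> pd.DataFrame:
    """The counts as the segregation TSV schema (ratio formatted 'a:b')."""
    return pd.DataFrame(
        [
            {"line": line, "resistant": r, "sensitive": s, "ratio": f"{a}:{b}"}
            for line, r, s, (a, b) in SEGREGATION_COUNTS
        ]
    )
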