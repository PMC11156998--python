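"""Small reference tables used in examples and summary-arithmetic checks."""

from __future__ import annotations

import pandas as pd

from .roh import ROH_CLASS_LABELS


def goat_roh_counts() -> pd.DataFrame:
    """Published ROH counts per length class for a 13-population goat
    whole-genome resequencing panel (78 animals).

    Index: population; columns: ``total`` plus the four ROH length classes
    (100-150 kb, >150-250 kb, >250-400 kb, >400 kb).  Useful for
    demonstrating :func:`popsig.roh.summarize_counts` and for checking the
    length-class share arithmetic of such tables.
    """
    rows = {
        "Arab": (4964, 2929, 1448, 418, 169),
        "Fellata": (3133, 2071, 871, 168, 23),
        "Oromo": (4113, 2661, 1124, 262, 66),
        "Abergelle": (2701, 1660, 791, 184, 66),
        "Keffa": (1721, 1040, 510, 121, 50),
        "Gumuz": (6964, 3615, 2133, 754, 462),
        "Woyto-Guji": (5761, 3322, 1668, 470, 301),
        "Boran": (3984, 2614, 1112, 214, 44),
        "Unknown": (5119, 2665, 1506, 607, 341),
        "Thyolo": (10979, 5897, 3676, 1102, 304),
        "Guera": (4608, 2621, 1278, 443, 266),
        "Saanen": (909, 664, 220, 20, 5),
        "Tibetan": (2954, 1932, 827, 170, 25),
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["total", *ROH_CLASS_LABELS]
    )
    df.index.name = "population"
    return df
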