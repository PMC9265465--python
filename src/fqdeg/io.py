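"""CSV helpers shared by the fixtures, the CLI and the loaders.

Published tables often use the typographic minus (U+2212); it is accepted on
read and normalised to the ASCII hyphen-minus.  All writers emit plain
ASCII, UTF-8, comma-separated, '.' decimal, header mandatory.
"""

from __future__ import annotations

import io as _io
import os
import tempfile
from pathlib import Path

import pandas as pd

MINUS_SIGN = "−"


def read_csv(path, **kwargs) -> pd.DataFrame:
    """pandas.read_csv with U+2212 minus normalisation."""
    text = Path(path).read_text(encoding="utf-8")
    return pd.read_csv(_io.StringIO(text.replace(MINUS_SIGN, "-")), **kwargs)


def write_csv_atomic(df: pd.DataFrame, path, **kwargs) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, index=False, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
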