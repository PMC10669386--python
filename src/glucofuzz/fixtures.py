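"""Packaged study-table fixtures.

Three small CSV tables ship with the package, reproducing the printed
measurements of the 15-participant pilot study: ``table1`` (reference
glucose, fingertip/tear voltages, demographics and device estimates),
``table2`` (the same readings with the fuzzy-predicted ± error half-width),
and ``table3`` (per-participant means and standard deviations from the
reference device, the prototype device, and the fuzzy model).  Files are
verified against frozen SHA-256 checksums on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .errors import FixtureLookupError

_CHECKSUMS = {
    "table1": "df1605a1570c99121b80a87df48711723dbf43c38e257648fc536439af3d13f8",
    "table2": "18a5ff1a913229a8ab3cfdc93d03eb1a4f480ecf84bfbbd27d3cd50bfc3ee188",
    "table3": "fb8eee858ee5031e6852dd06ecb17fc3b85aefeed8058b3c76dd00c3ed2cf2db",
}

FIXTURE_NAMES = tuple(_CHECKSUMS)


def load_fixture(name: str) -> pd.DataFrame:
    """Return the named packaged table verbatim as a DataFrame.

    Flag columns in ``table1`` keep their printed string form
    (``Pos``/``Neg``, ``Yes``/``No``); use
    :func:`glucofuzz.calibration.normalize_table` for boolean coercion.
    """
    if name not in _CHECKSUMS:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        )
    ref = resources.files("glucofuzz.data") / f"{name}.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureLookupError(f"fixture {name!r} failed its checksum")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
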