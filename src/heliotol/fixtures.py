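"""Packaged reference tables from the published 48-accession screen.

Two small tables ship with the package so the late pipeline stages can
be exercised without raw replicate data:

* ``descriptive_stats`` — per-trait range, mean +- SD and CV under
  control and high-light stress (the calibration source of the
  synthetic-cohort generator);
* ``ci_ranking`` — the 48 accession codes and names with their
  comprehensive-index (CI) values and published ranks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    "descriptive_stats": "table_descriptive_stats.csv",
    "ci_ranking": "table_ci_ranking.csv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table by name.

    ``name`` is one of ``descriptive_stats`` or ``ci_ranking``.
    """
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FILES)}")
    ref = resources.files("heliotol.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
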