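"""Packaged reference tables from the Naples disease-hotspot case study.

Two small CSV fixtures ship with the package:

``naples_hotspots.csv``
    Summary of the 24 circular hotspots detected among the residences of
    oto-laryngo-pharyngeal patients in the province of Naples: area (km^2),
    membership standard deviation and reliability, as published.

``naples_hotspot_classes.csv``
    The same 24 hotspots with the three-class reliability label produced by
    the thematic map and the label independently assigned by a panel of
    expert physicians.  Note that hotspot 23 (reliability 0.61) carries the
    published label "Mean" even though the stated rule puts values above 0.6
    in "High"; the fixture preserves the published label as printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("fuzzyhotspots.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype={"id": str})


def load_naples_hotspots() -> pd.DataFrame:
    """24 hotspots: columns id, area_km2, std_dev, reliability."""
    return _load("naples_hotspots.csv")


def load_naples_classes() -> pd.DataFrame:
    """24 hotspots: columns id, reliability, reliability_class, expert_class."""
    return _load("naples_hotspot_classes.csv")
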