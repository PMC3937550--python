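"""Packaged reference tables.

Two small CSV fixtures ship with the package: the affective-sound stimulus
metadata (IADS reference numbers with sub-group mean pleasantness/arousal
ratings) and a reference summary of grand means/SDs of reproduced duration
by valence and encoded duration.  Both are loaded as pandas DataFrames.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_stimuli", "load_grand_means"]


def _read_csv(name: str) -> pd.DataFrame:
    ref = resources.files("reprotime.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_stimuli() -> pd.DataFrame:
    """Stimulus metadata: iads_id, group (P/N/E), subgroup (a/b/c),
    pleasantness_mean, arousal_mean (sub-group means on a 1-9 scale)."""
    return _read_csv("stimuli.csv").astype({"iads_id": str})


def load_grand_means() -> pd.DataFrame:
    """Reference grand means/SDs of reproduced duration: valence (P/N/E/All),
    s_sec, mean_sec, sd_sec."""
    return _read_csv("grand_means.csv")
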