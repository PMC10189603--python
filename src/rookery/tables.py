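"""Bundled study-season tables and their summaries.

The package ships the published 2017 nesting-season tables (nest records
with inferred maternity, and per-female nesting/mate summaries) as plain
TSV.  These are inputs for worked examples: the raw genotypes behind them
are not distributed here.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("rookery.data").joinpath(name)


def load_nest_table() -> pd.DataFrame:
    """The 41 sampled nests of the 2017 season with inferred mothers."""
    with resources.as_file(_data_path("nests_2017.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"observed_mother": str, "inferred_mother": str})


def load_female_table() -> pd.DataFrame:
    """Per-female nesting summaries and reconstructed mates (2017 season)."""
    with resources.as_file(_data_path("females_2017.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"female": str, "mate": str})


def normalize_mother(label: str) -> str:
    """Strip low-support asterisks; 159/160 count as one maternal identity."""
    label = str(label).rstrip("*")
    return "159" if label in {"159", "160", "160/159", "159/160"} else label


def normalize_father(label: str) -> str:
    """Zero-pad sire labels (P8 -> P08)."""
    label = str(label)
    if label.startswith("P") and label[1:].isdigit():
        return f"P{int(label[1:]):02d}"
    return label


def distinct_mothers(nests: pd.DataFrame) -> set[str]:
    return {normalize_mother(m) for m in nests["inferred_mother"]}


def distinct_fathers(females: pd.DataFrame) -> set[str]:
    return {normalize_father(m) for m in females["mate"]}


def female_summary(females: pd.DataFrame) -> pd.DataFrame:
    """Recompute mean offspring per nest (1 decimal) from printed totals."""
    out = females.copy()
    out["mean_per_nest_recomputed"] = (out["n_offspring"] / out["n_nests"]).round(1)
    return out
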