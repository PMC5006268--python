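"""Embedded reference data: experimental (MEA, medium-activity wells) and
previously published simulated feature quartiles per measurement time
point, the per-stage connectivity schedule, and the published selected
parameter upper bounds."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .network import ParameterBounds

__all__ = [
    "load_reference_quartiles",
    "mea_reference",
    "sim_reference",
    "selected_bounds",
    "connectivity_schedule",
    "MTPS",
]

MTPS = (1, 2, 3, 4, 5, 6)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.files("maturesim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_quartiles() -> pd.DataFrame:
    return _read_tsv("reference_quartiles.tsv")


def _by_source(source: str) -> pd.DataFrame:
    df = load_reference_quartiles()
    df = df[df["source"] == source].drop(columns="source")
    out = df.set_index(["mtp", "feature"])[["q1", "median", "q3"]]
    bad = out[~(out["q1"] <= out["median"])]
    bad2 = out[~(out["median"] <= out["q3"])]
    if len(bad) or len(bad2):  # guards against fixture corruption
        raise ValueError("reference table violates Q1 <= median <= Q3")
    return out


def mea_reference() -> pd.DataFrame:
    """Experimental quartiles (medium-activity group), indexed by
    (mtp, feature)."""
    return _by_source("mea")


def sim_reference() -> pd.DataFrame:
    """Published simulated-network quartiles, indexed by (mtp, feature)."""
    return _by_source("sim")


def selected_bounds() -> dict:
    """Published selected parameter upper bounds, ``{mtp: ParameterBounds}``."""
    df = _read_tsv("selected_bounds.tsv")
    return {
        int(r["mtp"]): ParameterBounds(
            c_upper=float(r["c_upper"]),
            y_exc_upper=float(r["y_exc_upper"]),
            y_inh_upper=float(r["y_inh_upper"]),
        )
        for _, r in df.iterrows()
    }


def connectivity_schedule() -> dict:
    """Connection probability per measurement time point, ``{mtp: p}``."""
    df = _read_tsv("selected_bounds.tsv")
    return {
        int(r["mtp"]): float(r["connection_probability"])
        for _, r in df.iterrows()
    }
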