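"""Loaders for the packaged fixture data.

The chronogram is an approximation assembled for desk-scale runs: it follows
the published clade-level topology, with the divergence of the Ujiji lineage
at 3.55 Mya, the Hanang/Mbulu lineage at 2.36 Mya and the root calibrated at
10.5 Mya; the remaining internal node ages are assigned by equal subdivision
and are NOT posterior estimates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dec import DECModelSpec
from .trees import read_newick


def _data_path(name: str):
    return resources.files("fukomys.data") / name


def load_chronogram():
    """Approximate clade-level chronogram (ages in Mya)."""
    return read_newick(str(_data_path("chronogram_fig3_approx.nwk")))


def load_tip_ranges() -> dict[str, frozenset]:
    df = pd.read_csv(_data_path("tip_ranges.csv"))
    return {
        row["taxon"]: frozenset(a.strip() for a in row["areas"].split(","))
        for _, row in df.iterrows()
    }


def load_dec_spec(name: str) -> DECModelSpec:
    """Model specs: 'm0' (unconstrained), 'm1' (adjacent-area composites),
    'stratified' (M1 ranges + the four-epoch dispersal matrices)."""
    if name == "m0":
        return DECModelSpec.m0()
    if name == "m1":
        return DECModelSpec.m1()
    if name == "stratified":
        strat = DECModelSpec.from_json(_data_path("dec_stratified.json"))
        m1 = DECModelSpec.m1()
        return DECModelSpec(
            areas=strat.areas,
            allowed_ranges=m1.allowed_ranges,
            epochs=strat.epochs,
            root_prior=strat.root_prior,
        )
    raise ValueError(f"unknown DEC model {name!r}; use m0, m1 or stratified")
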