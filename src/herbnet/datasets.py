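"""Packaged reference fixtures.

Small plain-text tables shipped with the package: the 32-row potential-
compound candidate list of the Liangxue Tongyu prescription (post-rescue,
with OB/DL as published), the two animal-ingredient compounds (Taurine
from BB, Lumbrokinase from PA, no OB/DL on record), the eight-ingredient
prescription manifest, and the two 2^3 factorial OD450 cell-summary
blocks of the compound-combination experiment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .catalog import CompoundTable, Ingredient, load_compound_table, load_ingredient_manifest
from .factorial import FactorialDesign

__all__ = [
    "load_potential_compounds",
    "load_animal_compounds",
    "load_ingredients",
    "rescue_whitelist",
    "load_factorial_block",
    "FACTORIAL_BLOCKS",
]

FACTORIAL_BLOCKS = {
    "taurine": ("factorial_taurine_block.tsv", ("Taurine", "Paeonol", "Geniposide")),
    "ginsenoside": (
        "factorial_ginsenoside_block.tsv",
        ("Ginsenoside Rg1", "Ginsenoside Rb1", "Notoginsenoside R1"),
    ),
}


def _data_path(name: str):
    return resources.files("herbnet.data").joinpath(name)


def load_ingredients() -> dict[str, Ingredient]:
    """The eight-ingredient prescription manifest."""
    with resources.as_file(_data_path("ingredients.yaml")) as path:
        return load_ingredient_manifest(path)


def load_potential_compounds() -> CompoundTable:
    """The 32 potential-compound candidates of the six herbal ingredients."""
    with resources.as_file(_data_path("potential_compounds.tsv")) as path:
        return load_compound_table(path, ingredients=load_ingredients())


def load_animal_compounds() -> CompoundTable:
    """Taurine (BB) and Lumbrokinase (PA): literature-supported, no OB/DL."""
    with resources.as_file(_data_path("animal_compounds.tsv")) as path:
        return load_compound_table(path, ingredients=load_ingredients())


def rescue_whitelist() -> list[str]:
    """Ids rescued by literature evidence: every candidate plus the two
    animal-ingredient compounds."""
    return load_potential_compounds().ids + load_animal_compounds().ids


def load_factorial_block(block: str) -> tuple[FactorialDesign, pd.DataFrame]:
    """One 2^3 OD450 cell-summary block: 'taurine' or 'ginsenoside'.

    Returns the design (doses 2.5/5.0 umol/L coded -1/+1) and a summary
    frame with factor dose columns plus n, mean, sd.
    """
    try:
        fname, factors = FACTORIAL_BLOCKS[block]
    except KeyError:
        raise KeyError(f"unknown block {block!r}; expected one of {sorted(FACTORIAL_BLOCKS)}")
    with resources.as_file(_data_path(fname)) as path:
        frame = pd.read_csv(path, sep="\t")
    design = FactorialDesign(factors, levels={f: (2.5, 5.0) for f in factors})
    return design, frame
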