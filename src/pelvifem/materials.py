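"""Material parameter tables: bundled tissue data and CSV round-trips.

Two parameter tables ship with the package, both fitted three-term
polynomial coefficients collected from uniaxial tensile experiments in the
tissue-mechanics literature:

* ``fascia_constituents`` -- the endopelvic fascia constituents
  (elastin-collagen fibre compound, adipose tissue, passive smooth muscle);
* ``pelvic_structures`` -- whole pelvic structures (organs, ligaments,
  fascia regions, muscle).

The elastin-rich fascia region is the collagen-rich one with every
coefficient reduced by 75%, reflecting the measured average stiffness
contrast between elastin- and collagen-dominated connective tissue.

CSV schema (MPa): ``name,c10_mpa,c01_mpa,c20_mpa``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .constitutive import (
    DEFAULT_FASCIA_COMPOSITION,
    HyperelasticParams,
    MixtureComposition,
    VoigtMixture,
)

__all__ = [
    "derive_elastin_rich",
    "fascia_mixture",
    "load_fascia_constituents",
    "load_parameter_csv",
    "load_pelvic_structures",
    "save_parameter_csv",
]

_CSV_COLUMNS = ["name", "c10_mpa", "c01_mpa", "c20_mpa"]


def _params_from_frame(frame: pd.DataFrame) -> dict[str, HyperelasticParams]:
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"parameter table missing columns: {missing}")
    table: dict[str, HyperelasticParams] = {}
    for row in frame.itertuples(index=False):
        table[str(row.name)] = HyperelasticParams(
            name=str(row.name),
            c10=float(row.c10_mpa),
            c01=float(row.c01_mpa),
            c20=float(row.c20_mpa),
        )
    return table


def load_parameter_csv(path: str | Path) -> dict[str, HyperelasticParams]:
    """Read a ``name,c10_mpa,c01_mpa,c20_mpa`` table into parameter records."""
    return _params_from_frame(pd.read_csv(path))


def save_parameter_csv(
    params: dict[str, HyperelasticParams] | list[HyperelasticParams],
    path: str | Path,
) -> None:
    """Write parameter records back out in the package CSV schema."""
    records = params.values() if isinstance(params, dict) else params
    frame = pd.DataFrame(
        [
            {"name": p.name, "c10_mpa": p.c10, "c01_mpa": p.c01, "c20_mpa": p.c20}
            for p in records
        ],
        columns=_CSV_COLUMNS,
    )
    frame.to_csv(path, index=False)


def _bundled(name: str) -> dict[str, HyperelasticParams]:
    with resources.files("pelvifem.data").joinpath(name).open("r") as handle:
        return _params_from_frame(pd.read_csv(handle))


def load_fascia_constituents() -> dict[str, HyperelasticParams]:
    """Bundled constituent parameters of the endopelvic fascia."""
    return _bundled("fascia_constituents.csv")


def load_pelvic_structures() -> dict[str, HyperelasticParams]:
    """Bundled parameters of the pelvic organs, ligaments, fasciae, muscle."""
    return _bundled("pelvic_structures.csv")


def derive_elastin_rich(
    collagen_params: HyperelasticParams,
    reduction: float = 0.75,
    name: str | None = None,
) -> HyperelasticParams:
    """Elastin-rich fascia parameters from the collagen-rich ones.

    Every coefficient is multiplied by ``(1 - reduction)``; the default 75%
    reduction is the adopted average stiffness difference between the
    collagen-rich distal and elastin-rich proximal fascia regions.
    """
    if not (0.0 <= reduction < 1.0):
        raise ValueError(f"reduction must lie in [0, 1), got {reduction}")
    return collagen_params.scaled(
        1.0 - reduction, name=name or f"{collagen_params.name}_elastin_rich"
    )


def fascia_mixture(
    composition: MixtureComposition = DEFAULT_FASCIA_COMPOSITION,
) -> VoigtMixture:
    """Voigt mixture for the composite endopelvic fascia (bulk response)."""
    table = load_fascia_constituents()
    return VoigtMixture.from_composition(
        composition,
        fas=table["collagen_elastin_fascia"],
        ad=table["adipose"],
        sm=table["smooth_muscle"],
    )
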