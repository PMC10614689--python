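"""Reference cohort-mean kinetic parameters shipped with the package.

Cohort means and standard deviations of the plasma and tissue parameters
estimated for the anti-PD-L1 IgG1 C4 and its FcRn-binding-deficient
(H310A/H435Q) mutant in ultrasound-treated glioblastoma-bearing mice.
They parameterise the synthetic-cohort generator and the dose-normalised
exposure simulations.

Regions: 'contralateral' (healthy hemisphere, one-tissue model),
't1w_mri_ce' (tumour enhancing on post-contrast T1w MRI) and 'pet_ce'
(tumour enhancing on PET but not on T1w MRI), both two-tissue.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_model import Dosing, PlasmaParams, TissueParams

__all__ = [
    "FORMATS",
    "REGIONS",
    "ONE_TISSUE_REGIONS",
    "plasma_table",
    "tissue_table",
    "plasma_means",
    "plasma_sds",
    "tissue_means",
    "tissue_sds",
    "reference_dosing",
]

FORMATS = ("C4", "C4FcMUT")
REGIONS = ("contralateral", "t1w_mri_ce", "pet_ce")
ONE_TISSUE_REGIONS = ("contralateral",)

#: Injected activity (MBq) and specific activity (MBq/nmol) per format.
_DOSING = {"C4": (3.5, 4.97), "C4FcMUT": (3.5, 9.89)}


def _load(name: str) -> pd.DataFrame:
    with resources.files("fuspet").joinpath("refdata", name).open() as fh:
        return pd.read_csv(fh)


def plasma_table() -> pd.DataFrame:
    """Long-format table: format, parameter, mean, sd."""
    return _load("plasma_params.csv")


def tissue_table() -> pd.DataFrame:
    """Long-format table: format, region, parameter, mean, sd."""
    return _load("tissue_params.csv")


def _check_format(fmt: str) -> None:
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def plasma_means(fmt: str) -> PlasmaParams:
    _check_format(fmt)
    df = plasma_table()
    vals = df[df["format"] == fmt].set_index("parameter")["mean"]
    return PlasmaParams(Vc=vals["Vc"], k10=vals["k10"], k12=vals["k12"], k21=vals["k21"])


def plasma_sds(fmt: str) -> dict[str, float]:
    _check_format(fmt)
    df = plasma_table()
    return df[df["format"] == fmt].set_index("parameter")["sd"].to_dict()


def tissue_means(fmt: str, region: str) -> TissueParams:
    _check_format(fmt)
    df = tissue_table()
    sel = df[(df["format"] == fmt) & (df["region"] == region)]
    if sel.empty:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    vals = sel.set_index("parameter")["mean"].to_dict()
    return TissueParams(
        K_FUS=vals["K_FUS"],
        t_FUS=vals["t_FUS"],
        K1=vals["K1"],
        k2=vals["k2"],
        vB=vals["vB"],
        k3=vals.get("k3", 0.0),
        k4=vals.get("k4", 0.0),
    )


def tissue_sds(fmt: str, region: str) -> dict[str, float]:
    _check_format(fmt)
    df = tissue_table()
    sel = df[(df["format"] == fmt) & (df["region"] == region)]
    if sel.empty:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    return sel.set_index("parameter")["sd"].to_dict()


def reference_dosing(fmt: str) -> Dosing:
    _check_format(fmt)
    activity, specific = _DOSING[fmt]
    return Dosing(injected_activity=activity, specific_activity=specific)
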