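"""Published population parameter sets for DEX and BET.

These are the final typical values, inter-individual variances and
residual variances of the crossover-study analysis in healthy non-pregnant
women.  They are the package-wide defaults: the synthetic-study generator
draws from them, the regimen simulator uses them, and parameter-recovery
tests treat them as ground truth.

Units follow the package convention (L/h, L, 1/h, dimensionless; variances
on the natural-log scale).
"""

from __future__ import annotations

import numpy as np

from .likelihood import PopulationParams
from .model import StructuralParams

__all__ = [
    "DEX_TYPICALS", "BET_TYPICALS",
    "DEX_POPULATION", "BET_POPULATION",
    "DEX_OMEGA_BLOCKS", "BET_OMEGA_BLOCKS",
    "LLOQ", "MEAN_BODY_WEIGHT", "WEIGHT_RANGE",
    "population_for",
]

#: assay lower limit of quantification, ng/mL (both drugs)
LLOQ = 0.1

#: mean body weight (kg) used for per-kg normalization
MEAN_BODY_WEIGHT = 56.8

#: reported body-weight range (kg) of the study population
WEIGHT_RANGE = (47.0, 68.7)

DEX_TYPICALS = StructuralParams(
    cl_f=9.29,    # apparent clearance CL/F_IM, L/h
    vp_f=51.3,    # apparent central volume Vp/F_IM, L
    cld_f=0.538,  # apparent distributional clearance CL_D/F_IM, L/h
    vt_f=5.06,    # apparent peripheral volume VT/F_IM, L
    ka_im=0.460,  # IM phosphate absorption rate, 1/h
    ka_po=0.936,  # oral absorption rate, 1/h
    fr=1.04,      # F_PO/F_IM
)

BET_TYPICALS = StructuralParams(
    cl_f=5.95,
    vp_f=67.5,
    cld_f=0.173,
    vt_f=4.94,
    ka_im=0.971,
    ka_po=1.21,
    fr=0.935,
    ka_ima=0.00638,  # acetate hydrolysis/absorption rate, 1/h (flip-flop)
    fra=0.819,       # F_IMa/F_IM
)

# DEX: the central-volume IIV estimated near zero and was fixed there, so
# Vp/F carries no eta; no covariances were estimable with useful precision.
_DEX_IIV = ("cl_f", "ka_im", "ka_po")
_DEX_OMEGA = np.diag([0.0265, 0.0633, 0.395])

DEX_POPULATION = PopulationParams(
    theta=DEX_TYPICALS,
    iiv_names=_DEX_IIV,
    omega=_DEX_OMEGA,
    sigma2=0.0455,
)

DEX_OMEGA_BLOCKS = (("cl_f",), ("ka_im",), ("ka_po",))

# BET: individual CL/F and Vp/F estimates correlated, so their covariance
# (0.0155, correlation 0.78) is part of the final model.
_BET_IIV = ("cl_f", "vp_f", "ka_im", "ka_ima", "ka_po", "fr", "fra")
_BET_OMEGA = np.diag([0.0210, 0.0188, 0.0441, 0.147, 0.241, 0.0182, 0.00773])
_BET_OMEGA[0, 1] = _BET_OMEGA[1, 0] = 0.0155

BET_POPULATION = PopulationParams(
    theta=BET_TYPICALS,
    iiv_names=_BET_IIV,
    omega=_BET_OMEGA,
    sigma2=0.0211,
)

BET_OMEGA_BLOCKS = (("cl_f", "vp_f"), ("ka_im",), ("ka_ima",),
                    ("ka_po",), ("fr",), ("fra",))


def population_for(drug: str) -> PopulationParams:
    drug = drug.upper()
    if drug == "DEX":
        return DEX_POPULATION
    if drug == "BET":
        return BET_POPULATION
    raise ValueError(f"unknown drug {drug!r} (expected DEX or BET)")


def omega_blocks_for(drug: str):
    return DEX_OMEGA_BLOCKS if drug.upper() == "DEX" else BET_OMEGA_BLOCKS
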