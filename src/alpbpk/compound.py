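"""Compound description and dose/unit conversions.

Atractylodin is the marker active constituent of *Atractylodes lancea* (AL)
rhizome extract, making up roughly 14% of the extract by mass.  Doses are
entered as mg of whole extract and converted to µmol of active compound via
the extract fraction and molecular weight.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator


class CompoundProperties(BaseModel, frozen=True):
    """Physicochemical and binding parameters of the simulated active.

    Parameters
    ----------
    mw : molecular weight, g/mol
    log_p : octanol/water partition coefficient (log10)
    pka : negative log of the acid dissociation constant
    fu : unbound fraction in plasma, in (0, 1]
    rbp : blood-to-plasma concentration ratio
    papp : apparent membrane permeability, cm/s
    solubility : aqueous solubility, mg/mL
    extract_fraction : mass fraction of active in the whole extract, in (0, 1]
    """

    name: str = "atractylodin"
    mw: float = Field(gt=0)
    log_p: float = 0.0
    pka: float = Field(gt=0)
    fu: float = Field(gt=0, le=1)
    rbp: float = Field(gt=0)
    papp: float = Field(gt=0)
    solubility: float = Field(gt=0)
    extract_fraction: float = Field(gt=0, le=1)

    @model_validator(mode="after")
    def _check_positive(self) -> "CompoundProperties":
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        return self


#: Default parameter set for atractylodin.  The binding/permeability values are
#: documented placeholders (no public reference table exists for this compound);
#: they are held fixed while the four kinetic parameters are calibrated.
ATRACTYLODIN = CompoundProperties(
    name="atractylodin",
    mw=182.22,
    log_p=3.8,
    pka=9.9,
    fu=0.10,
    rbp=1.5,
    papp=2.0e-5,
    solubility=0.012,
    extract_fraction=0.14,
)


def dose_to_active_umol(dose_mg_extract: float, compound: CompoundProperties) -> float:
    """Convert an AL-extract dose (mg) to µmol of active compound.

    ``dose × extract_fraction`` gives mg of active; dividing by MW (g/mol)
    and scaling by 1000 yields µmol.
    """
    if dose_mg_extract < 0:
        raise ValueError("dose must be non-negative")
    return dose_mg_extract * compound.extract_fraction / compound.mw * 1000.0
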