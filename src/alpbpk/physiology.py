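"""Reference human physiology for the whole-body PBPK model.

The tissue set is the conventional minimal whole-body collection: lung, heart,
brain, muscle, adipose, skin, bone, kidney, spleen, gut, liver and a lumped
rest-of-body compartment, plus arterial and venous blood pools.  Organ volumes
are stored per kg body weight and blood flows as fractions of cardiac output;
``build_physiology`` scales both linearly to the requested body weight.

The liver entry in ``flows`` is the *hepatic arterial* flow only; gut and
spleen venous outflow drains into the liver (portal inflow), so total hepatic
blood flow is ``Q_liver + Q_gut + Q_spleen``.  With that convention the flow
entries over all non-lung tissues sum exactly to cardiac output.
"""

from __future__ import annotations

from typing import Dict

from pydantic import BaseModel, Field, model_validator

#: Perfused tissue compartments (lung is in series with the blood pools).
TISSUES = (
    "lung",
    "heart",
    "brain",
    "muscle",
    "adipose",
    "skin",
    "bone",
    "kidney",
    "spleen",
    "gut",
    "liver",
    "rest",
)

#: Tissues whose arterial inflow is specified in ``flows`` (everything but lung).
FLOW_TISSUES = tuple(t for t in TISSUES if t != "lung")

# Organ volumes, L per kg body weight (adult reference scaled from a 60 kg
# subject).  "rest" lumps unenumerated perfused mass.
REFERENCE_VOLUMES_L_PER_KG: Dict[str, float] = {
    "lung": 0.0076,
    "heart": 0.0047,
    "brain": 0.0200,
    "muscle": 0.4000,
    "adipose": 0.1600,
    "skin": 0.0371,
    "bone": 0.0856,
    "kidney": 0.0044,
    "spleen": 0.0026,
    "gut": 0.0171,
    "liver": 0.0260,
    "rest": 0.1000,
    "arterial": 0.0257,
    "venous": 0.0514,
}

# Regional blood flows as fractions of cardiac output.  The liver fraction is
# hepatic arterial only (portal flow arrives via gut + spleen).
REFERENCE_FLOW_FRACTIONS: Dict[str, float] = {
    "heart": 0.040,
    "brain": 0.120,
    "muscle": 0.170,
    "adipose": 0.050,
    "skin": 0.050,
    "bone": 0.050,
    "kidney": 0.190,
    "spleen": 0.020,
    "gut": 0.160,
    "liver": 0.065,
    "rest": 0.085,
}

#: Cardiac output per kg body weight, L/h/kg (≈5.2 L/min for a 60 kg adult).
REFERENCE_CARDIAC_OUTPUT_L_PER_H_PER_KG = 5.2


class PhysiologyProfile(BaseModel, frozen=True):
    """Organ volumes (L), regional blood flows (L/h) and cardiac output.

    ``flows`` covers every non-lung tissue and sums to ``cardiac_output``;
    the liver entry is hepatic arterial flow (see module docstring).
    """

    body_weight: float = Field(gt=0)
    age: float = Field(ge=0)
    hematocrit: float = Field(gt=0, lt=1, default=0.45)
    volumes: Dict[str, float]
    flows: Dict[str, float]
    cardiac_output: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_structure(self) -> "PhysiologyProfile":
        missing_v = set(TISSUES) | {"arterial", "venous"}
        missing_v -= set(self.volumes)
        if missing_v:
            raise ValueError(f"missing volumes for: {sorted(missing_v)}")
        missing_q = set(FLOW_TISSUES) - set(self.flows)
        if missing_q:
            raise ValueError(f"missing flows for: {sorted(missing_q)}")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("all volumes must be positive")
        if any(q <= 0 for q in self.flows.values()):
            raise ValueError("all flows must be positive")
        total_q = sum(self.flows.values())
        if abs(total_q - self.cardiac_output) > 1e-6 * self.cardiac_output:
            raise ValueError(
                f"tissue flows sum to {total_q:.6g} L/h but cardiac output is "
                f"{self.cardiac_output:.6g} L/h"
            )
        return self

    @property
    def total_hepatic_flow(self) -> float:
        """Hepatic arterial + portal (gut + spleen) blood flow, L/h."""
        return self.flows["liver"] + self.flows["gut"] + self.flows["spleen"]


def build_physiology(body_weight: float = 60.0, age: float = 40.0) -> PhysiologyProfile:
    """Build an adult physiology scaled linearly to body weight.

    The supported age range is 18-60 years (the healthy-adult population the
    model is parameterised for); other ages raise ``ValueError``.
    """
    if not 18.0 <= age <= 60.0:
        raise ValueError(f"age {age} outside the supported 18-60 y adult range")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    co = REFERENCE_CARDIAC_OUTPUT_L_PER_H_PER_KG * body_weight
    volumes = {k: v * body_weight for k, v in REFERENCE_VOLUMES_L_PER_KG.items()}
    flows = {k: f * co for k, f in REFERENCE_FLOW_FRACTIONS.items()}
    return PhysiologyProfile(
        body_weight=body_weight,
        age=age,
        volumes=volumes,
        flows=flows,
        cardiac_output=co,
    )
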