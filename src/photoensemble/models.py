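"""The 12-member model registry.

Each member is a factorial combination of three process hypotheses:

* TPU limitation: absent (1) or included (2);
* limiting-rate selection: strict minimum (1) or quadratic smoothing (2);
* electron transport: non-rectangular hyperbola with J_max (1), the Harley
  hyperbola with J_max (2), or the Collatz linear response with no J_max (3).

Carboxylation has a single representation, giving labels of the form M1xyz
(x=TPU, y=selection, z=electron transport).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = ["ModelConfig", "MODEL_IDS", "model_from_id", "all_models"]

ETRANS_HYPOTHESES = ("nonrect_fw", "hyperbola_harley", "linear_cbgb")
SELECTION_HYPOTHESES = ("minimum", "quadratic_smoothing")

_ETRANS_CODE = {h: i + 1 for i, h in enumerate(ETRANS_HYPOTHESES)}
_SELECTION_CODE = {h: i + 1 for i, h in enumerate(SELECTION_HYPOTHESES)}


@dataclass(frozen=True)
class ModelConfig:
    """One hypothesis combination of the ensemble."""

    tpu_included: bool = False
    selection: str = "minimum"
    etrans_hypothesis: str = "nonrect_fw"

    def __post_init__(self):
        if self.selection not in SELECTION_HYPOTHESES:
            raise ValueError(f"unknown selection hypothesis: {self.selection!r}")
        if self.etrans_hypothesis not in ETRANS_HYPOTHESES:
            raise ValueError(
                f"unknown electron transport hypothesis: {self.etrans_hypothesis!r}"
            )

    @property
    def model_id(self) -> str:
        return "M1{}{}{}".format(
            2 if self.tpu_included else 1,
            _SELECTION_CODE[self.selection],
            _ETRANS_CODE[self.etrans_hypothesis],
        )


def model_from_id(model_id: str) -> ModelConfig:
    """Parse an M1xyz label back into its hypothesis choices."""
    if (
        len(model_id) != 5
        or not model_id.startswith("M1")
        or model_id[2] not in "12"
        or model_id[3] not in "12"
        or model_id[4] not in "123"
    ):
        raise ValueError(f"invalid model id: {model_id!r}")
    return ModelConfig(
        tpu_included=model_id[2] == "2",
        selection=SELECTION_HYPOTHESES[int(model_id[3]) - 1],
        etrans_hypothesis=ETRANS_HYPOTHESES[int(model_id[4]) - 1],
    )


def all_models() -> list[ModelConfig]:
    """All 12 hypothesis combinations in M1111..M1223 order."""
    return [
        ModelConfig(tpu_included=tpu, selection=sel, etrans_hypothesis=et)
        for tpu, sel, et in product(
            (False, True), SELECTION_HYPOTHESES, ETRANS_HYPOTHESES
        )
    ]


MODEL_IDS = tuple(m.model_id for m in all_models())
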