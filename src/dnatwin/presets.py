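"""Process-step presets, shipped as YAML data files.

Presets bundle the error rates and biases characterized for the common
workflow building blocks: electrochemical and material-deposition synthesis,
Taq-family and Q5 PCR, accelerated aging, and iSeq 100 sequencing.  They are
data, not code: ``load_preset`` returns the raw dictionary, and the
``*_params`` helpers turn presets into the parameter objects that the process
steps consume, with keyword overrides for any field.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .errors import (
    PositionalRateProfile,
    RunLengthLaw,
    make_positional_profile,
    substitution_matrix_from_patterns,
)
from .steps import AgingParams, PCRParams, SequencingParams, SynthesisParams

SYNTHESIS_PRESETS = ("electrochemical", "material_deposition")
PCR_PRESETS = ("taq", "q5")
SEQUENCING_PRESETS = ("iseq100",)

_FILES = {
    "electrochemical": "synthesis_electrochemical.yaml",
    "material_deposition": "synthesis_material_deposition.yaml",
    "taq": "pcr_taq.yaml",
    "q5": "pcr_q5.yaml",
    "aging": "aging.yaml",
    "iseq100": "sequencing_iseq100.yaml",
}


def load_preset(name: str) -> dict:
    """Load a named preset's raw YAML dictionary."""
    if name not in _FILES:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(_FILES)}")
    ref = resources.files("dnatwin").joinpath("data", _FILES[name])
    return yaml.safe_load(ref.read_text())


def _deletion_profile(spec: dict, length: int) -> PositionalRateProfile | None:
    if spec is None or spec.get("mean_rate", 0) == 0:
        return None
    return make_positional_profile(
        mean_rate=spec["mean_rate"],
        terminal_rate=spec.get("terminal_rate"),
        length=length,
        shape=spec.get("shape", "flat"),
        direction=spec.get("direction", "read"),
    )


def synthesis_params(
    preset: str = "material_deposition",
    mean_coverage: float = 200.0,
    gc_constrained: bool = False,
    payload_length: int = 150,
    **overrides,
) -> SynthesisParams:
    d = load_preset(preset)
    sigma_key = "coverage_sigma_gc_constrained" if gc_constrained else "coverage_sigma"
    params = SynthesisParams(
        mean_coverage=mean_coverage,
        coverage_sigma=d[sigma_key],
        deletion_profile=_deletion_profile(d.get("deletion"), payload_length),
        run_law=RunLengthLaw.from_dict(d["run_law"]),
        substitution_rate=d.get("substitution_rate", 0.0),
        insertion_rate=d.get("insertion_rate", 1e-4),
        provider_preset=d["name"],
    )
    for key, val in overrides.items():
        setattr(params, key, val)
    return params


def pcr_params(preset: str = "taq", cycles: int = 15, **overrides) -> PCRParams:
    d = load_preset(preset)
    params = PCRParams(
        cycles=cycles,
        mean_efficiency=d["mean_efficiency"],
        efficiency_sigma=d["efficiency_sigma"],
        substitution_rate_taq=d["substitution_rate_taq"],
        fidelity_relative_to_taq=d["fidelity_relative_to_taq"],
        matrix=substitution_matrix_from_patterns(d["pattern_weights"]),
    )
    for key, val in overrides.items():
        setattr(params, key, val)
    return params


def aging_params(half_lives: float = 1.0, **overrides) -> AgingParams:
    d = load_preset("aging")
    params = AgingParams(
        half_lives=half_lives,
        substitution_rate_per_half_life=d["substitution_rate_per_half_life"],
        matrix=substitution_matrix_from_patterns(d["pattern_weights"]),
        deletion_rate=d.get("deletion_rate", 0.0),
    )
    for key, val in overrides.items():
        setattr(params, key, val)
    return params


def sequencing_params(
    preset: str = "iseq100", read_count: int = 100_000, **overrides
) -> SequencingParams:
    d = load_preset(preset)
    shape = np.asarray(d["profile_shape"], dtype=float)
    shape = shape / shape.mean()
    params = SequencingParams(
        read_count=read_count,
        read_length=d["read_length"],
        forward_profile=PositionalRateProfile(
            np.clip(shape * d["forward_mean_rate"], 0, 1)
        ),
        reverse_profile=PositionalRateProfile(
            np.clip(shape * d["reverse_mean_rate"], 0, 1)
        ),
        matrix_forward=substitution_matrix_from_patterns(d["pattern_weights_forward"]),
        matrix_reverse=substitution_matrix_from_patterns(d["pattern_weights_reverse"]),
        indel_rate=d.get("indel_rate", 5e-5),
    )
    for key, val in overrides.items():
        setattr(params, key, val)
    return params
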