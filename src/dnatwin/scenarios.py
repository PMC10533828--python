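"""End-to-end storage scenarios and workflow configuration.

The central case study asks how physical redundancy during storage controls
sequence dropout.  A prototypical workflow — synthesis at mean coverage 200,
20 amplification cycles, dilution to a target physical coverage, storage for
one half-life, 30 more cycles, and iSeq sequencing — is instantiated in a
high-fidelity *best case* (material-deposition synthesis, Q5-class
polymerase) and a low-fidelity *worst case* (electrochemical synthesis,
Taq-class polymerase).  ``run_scenario`` sweeps the storage coverage and
reports dropout counting either all mapped reads or only error-free reads;
the gap between the two curves is the head-room available to an error
correction code that can exploit erroneous reads.

Dropout fractions are per-reference quantities, so scenarios scale down to
desk size (default 2000 of the full 12000 references) without changing their
expectation; the ``scale`` parameter controls this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis, presets, steps
from .pools import ReferencePool, generate_reference_pool
from .seqio import ReadSet

FULL_REFERENCE_COUNT = 12_000
PAYLOAD_LENGTH = 150
DEFAULT_COVERAGES = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)


@dataclass
class ScenarioPreset:
    """A named storage scenario: synthesis/polymerase choices and structure."""

    name: str
    synthesis_preset: str
    pcr_preset: str
    synthesis_coverage: float = 200.0
    pre_storage_cycles: int = 20
    post_storage_cycles: int = 30
    storage_half_lives: float = 1.0
    sequencing_preset: str = "iseq100"
    sweep: tuple = DEFAULT_COVERAGES
    description: str = ""
    extra: dict = field(default_factory=dict)


_SCENARIOS = {
    "best_case": ScenarioPreset(
        name="best_case",
        synthesis_preset="material_deposition",
        pcr_preset="q5",
        description="low-error, low-bias workflow: material-deposition "
        "synthesis and a high-fidelity (280x Taq) polymerase",
    ),
    "worst_case": ScenarioPreset(
        name="worst_case",
        synthesis_preset="electrochemical",
        pcr_preset="taq",
        description="high-error, high-bias workflow: electrochemical "
        "synthesis and a Taq-class polymerase",
    ),
    "pcr_titration": ScenarioPreset(
        name="pcr_titration",
        synthesis_preset="material_deposition",
        pcr_preset="taq",
        description="re-amplification series, 15-90 cycles in rounds of 15",
        extra={"cycle_points": (15, 30, 45, 60, 75, 90)},
    ),
    "aging_series": ScenarioPreset(
        name="aging_series",
        synthesis_preset="material_deposition",
        pcr_preset="taq",
        description="accelerated-aging series over 0-8 half-lives",
        extra={"half_life_points": (0.0, 2.0, 4.0, 6.0, 8.0)},
    ),
    "generational": ScenarioPreset(
        name="generational",
        synthesis_preset="electrochemical",
        pcr_preset="taq",
        description="repeated dilute-and-reamplify generations (>100 "
        "cumulative cycles) from an electrochemical pool with partially "
        "GC-constrained coverage bias",
        extra={
            "coverage_sigma": 0.94,
            "efficiency_sigma": 0.012,
            "generations": 6,
            "cycles_per_generation": 20,
            "dilution_coverage": 200.0,
        },
    ),
}


def scenario_preset(name: str) -> ScenarioPreset:
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(_SCENARIOS)}")
    return _SCENARIOS[name]


def _scaled_references(scale: float, seed) -> ReferencePool:
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    n = max(2, int(round(FULL_REFERENCE_COUNT * scale)))
    return generate_reference_pool(n, PAYLOAD_LENGTH, seed=seed)


def run_scenario(
    preset: ScenarioPreset | str,
    seed: int = 0,
    scale: float = 1.0 / 6.0,
    coverages=None,
    reads_per_reference: int = 30,
    max_molecules: float = 5e5,
    min_similarity: float = 0.85,
) -> pd.DataFrame:
    """Sweep storage coverage for a scenario and measure sequence dropout.

    For every coverage point the workflow synthesize -> PCR -> dilute ->
    age -> PCR -> sequence is run, reads are mapped back to the references by
    alignment, and two dropout numbers are recorded: the fraction of
    references with no mapped read at all, and the fraction with no
    *error-free* read.  Synthesis and the first amplification are shared
    across the sweep (they happen before the storage dilution).
    """
    if isinstance(preset, str):
        preset = scenario_preset(preset)
    if preset.name == "generational":
        raise ValueError("the generational preset is run via run_generational()")
    if coverages is None:
        coverages = preset.sweep
    if any(c <= 0 for c in coverages):
        raise ValueError("sweep coverages must be positive")

    root = np.random.SeedSequence(entropy=seed)
    refs = _scaled_references(scale, np.random.default_rng(root.spawn(1)[0]))
    n_refs = len(refs)

    syn = presets.synthesis_params(
        preset.synthesis_preset, mean_coverage=preset.synthesis_coverage
    )
    pool0 = steps.synthesize(
        refs, syn, np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    )
    pcr1 = presets.pcr_params(
        preset.pcr_preset, cycles=preset.pre_storage_cycles, max_molecules=max_molecules
    )
    pool1 = steps.pcr(
        pool0, pcr1, np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    )

    rows = []
    for point, cov in enumerate(coverages):
        sub = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(3, point))
        )
        pool = steps.dilute(pool1, cov, sub)
        pool = steps.age(pool, presets.aging_params(preset.storage_half_lives), sub)
        pcr2 = presets.pcr_params(
            preset.pcr_preset, cycles=preset.post_storage_cycles, max_molecules=max_molecules
        )
        pool = steps.pcr(pool, pcr2, sub)
        seq = presets.sequencing_params(
            preset.sequencing_preset, read_count=reads_per_reference * n_refs
        )
        reads = steps.sequence(pool, seq, sub)
        mappings = analysis.map_reads(
            reads, refs, min_similarity=min_similarity, read_length=seq.read_length
        )
        rows.append(
            {
                "coverage": cov,
                "dropout_all_reads": analysis.dropout_rate(mappings, refs),
                "dropout_error_free": analysis.dropout_rate(
                    mappings, refs, error_free_only=True
                ),
                "n_read_pairs": len(reads),
                "n_mapped_reads": len(mappings),
            }
        )
    return pd.DataFrame(rows)


def run_generational(
    seed: int = 0,
    scale: float = 1.0 / 6.0,
    reads_per_reference: int = 30,
    max_molecules: float = 5e5,
) -> pd.DataFrame:
    """Chained dilute-and-reamplify generations for qualitative comparison.

    Emulates master-pool/progeny experiments: an electrochemically
    synthesized pool with strong coverage bias is repeatedly diluted and
    re-amplified, accumulating well over 100 PCR cycles.  Reports per-
    generation error rates and dropout.
    """
    cfg = scenario_preset("generational").extra
    root = np.random.SeedSequence(entropy=seed)
    refs = _scaled_references(scale, np.random.default_rng(root.spawn(1)[0]))
    syn = presets.synthesis_params(
        "electrochemical", mean_coverage=200.0, coverage_sigma=cfg["coverage_sigma"]
    )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    pool = steps.synthesize(refs, syn, rng)
    rows = []
    for gen in range(cfg["generations"]):
        sub = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2, gen)))
        pcr = presets.pcr_params(
            "taq",
            cycles=cfg["cycles_per_generation"],
            efficiency_sigma=cfg["efficiency_sigma"],
            max_molecules=max_molecules,
        )
        pool = steps.pcr(pool, pcr, sub)
        seq = presets.sequencing_params("iseq100", read_count=reads_per_reference * len(refs))
        reads = steps.sequence(pool, seq, sub)
        mappings = analysis.map_reads(reads, refs, read_length=seq.read_length)
        report = analysis.error_rates(mappings, refs)
        rows.append(
            {
                "generation": gen,
                "cumulative_cycles": (gen + 1) * cfg["cycles_per_generation"],
                "sub_rate": report.rates["sub"],
                "del_rate": report.rates["del"],
                "dropout_all_reads": analysis.dropout_rate(mappings, refs),
            }
        )
        pool = steps.dilute(pool, cfg["dilution_coverage"], sub)
    return pd.DataFrame(rows)


def downsample_reads(reads: ReadSet, n: int, seed: int = 0) -> ReadSet:
    """Uniform subset of ``n`` read pairs without replacement, pairs intact."""
    if n > len(reads):
        raise ValueError(f"cannot downsample {len(reads)} pairs to {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(reads), size=n, replace=False))
    return ReadSet(
        r1=[reads.r1[i] for i in keep],
        r2=[reads.r2[i] for i in keep],
        ids=[reads.ids[i] for i in keep],
        true_ref=[reads.true_ref[i] for i in keep] if reads.true_ref else None,
    )


# ---------------------------------------------------------------------------
# workflow configuration documents


def parse_workflow_config(doc: dict) -> list[tuple[str, object]]:
    """Turn a YAML/JSON workflow document into ``run_workflow`` steps.

    The document holds an ordered ``steps`` list; each entry names a step and
    optionally a preset, plus parameter overrides, e.g.::

        steps:
          - step: synthesize
            preset: material_deposition
            mean_coverage: 200
          - step: pcr
            preset: taq
            cycles: 15
          - step: dilute
            target_mean_coverage: 10
          - step: age
            half_lives: 1
          - step: sequence
            preset: iseq100
            read_count: 100000
    """
    if "steps" not in doc or not isinstance(doc["steps"], list):
        raise ValueError("workflow document needs an ordered 'steps' list")
    out: list[tuple[str, object]] = []
    for i, entry in enumerate(doc["steps"]):
        entry = dict(entry)
        name = entry.pop("step", None)
        preset = entry.pop("preset", None)
        if name == "synthesize":
            params = presets.synthesis_params(preset or "material_deposition", **entry)
        elif name == "pcr":
            params = presets.pcr_params(preset or "taq", **entry)
        elif name == "age":
            params = presets.aging_params(**entry)
        elif name == "dilute":
            params = entry.pop("target_mean_coverage", None)
            if params is None or entry:
                raise ValueError(f"step {i}: dilute takes only target_mean_coverage")
        elif name == "sequence":
            params = presets.sequencing_params(preset or "iseq100", **entry)
        else:
            raise ValueError(f"step {i}: unknown step {name!r}")
        out.append((name, params))
    return out
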