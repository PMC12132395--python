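"""Shared locations and the study-scale scenario used by every driver."""

from pathlib import Path

from orthocensus.synthdata import ScenarioParams, generate_scenario

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scenario"
RESULTS = ROOT / "results"

#: Study conditions: 500 families across three focal assemblies plus the
#: reference annotation, 5 ingroup and 15 outgroup species; 20% duplication
#: (half collapsed in the reference), 5% reference-missing, 5% pseudogene.
STUDY_PARAMS = ScenarioParams(seed=1203)


def study_scenario():
    """(Re)generate the deterministic study scenario under scratch/."""
    RESULTS.mkdir(exist_ok=True)
    return generate_scenario(STUDY_PARAMS, SCRATCH)
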