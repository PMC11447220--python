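"""Shared configuration for the analysis scripts.

All four stages operate on one workspace under scratch/workspace, driven by
a single pipeline config with one master seed.  Run the scripts in order:

    python analysis/01_simulate.py
    python analysis/02_train_signature.py
    python analysis/03_score_cohorts.py
    python analysis/04_validate_associations.py
"""

from pathlib import Path

import tp53phenocopy as tp

ROOT = Path(__file__).resolve().parent.parent
WORKSPACE = ROOT / "scratch" / "workspace"
RESULTS = ROOT / "results"

SEED = 20240

# six cohorts of 1000 samples: C1+C2 train the signature, C3 measures
# held-out accuracy, C4-C6 (n = 3000, matching the scale of the pooled
# neoadjuvant compendium) carry the clinical association analyses
SIMULATION = dict(n_samples_per_cohort=1000, n_cohorts=6)

TRAIN_COHORTS = ("C1", "C2")
HELDOUT_COHORT = "C3"
CLINICAL_COHORTS = ("C4", "C5", "C6")


def pipeline_config() -> tp.PipelineConfig:
    WORKSPACE.mkdir(parents=True, exist_ok=True)
    return tp.PipelineConfig(workdir=str(WORKSPACE), seed=SEED,
                             simulation=dict(SIMULATION), reference_batch="C1")
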