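"""End-to-end cohort run: simulate, segment, classify, report.

Renders a six-patient phantom cohort spanning all four patient-level change
categories (stable / increased / decreased / mixed), simulates two
near-perfect readers, then runs the full pipeline: per-stone volumetry,
per-kidney change labels, patient aggregation, radiomics extraction and the
agreement/AUC report.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from stoneburden.io import PipelineConfig
from stoneburden.pipeline import demo_scenarios, run_pipeline, write_cohort

workdir = Path(tempfile.mkdtemp(prefix="stoneburden_"))
near_perfect = np.full((3, 3), 0.015)
np.fill_diagonal(near_perfect, 0.97)

cohort = write_cohort(demo_scenarios(seed=1), workdir / "cohort",
                      reader_confusions=(near_perfect, near_perfect), seed=1)
config = PipelineConfig(input_dir=str(cohort), output_dir=str(workdir / "out"),
                        threshold_hu=130, band=0.15, seed=1, kappa_bootstrap=2000)
report = run_pipeline(config)

print("kidney labels :", report["kidney_label_counts"])
print("patient labels:", report["patient_label_counts"])
print("unweighted kappa:", report["agreement"]["kappa_unweighted"])
print("outputs:", sorted(p.name for p in (workdir / "out").iterdir()))
print(json.dumps(report["agreement"]["reader_vs_reference_auc"]["reader1"],
                 indent=2))
# The six phantoms produce all four patient categories; the two simulated
# readers agree near-perfectly with each other and with the volumetric
# reference, mirroring a high-agreement reading session.
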