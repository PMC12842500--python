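"""Inter-reader agreement and reader-vs-reference AUC.

Cohen's kappa on a 475-measurement contingency table of two readers'
(decreased / increased / stable) calls, then a simulated near-perfect
reader scored one-vs-rest against a volumetric reference.
"""

import numpy as np

from stoneburden.phantom import ReaderSimSpec, simulate_readers
from stoneburden.stats_eval import (AgreementMatrix, cohen_kappa,
                                    reader_vs_reference_auc)

matrix = AgreementMatrix(
    counts=np.array([[148, 0, 2], [4, 132, 6], [2, 0, 181]]),
    category_order=("decreased", "increased", "stable"),
)
for scheme in ("unweighted", "linear"):
    res = cohen_kappa(matrix, scheme, n_boot=10_000, seed=0)
    print(f"{scheme:10s} kappa = {res.estimate:.4f} "
          f"(95% CI {res.ci_lower:.3f}-{res.ci_upper:.3f}, N = {matrix.n})")

# a simulated reader that is right 90% of the time, scored per class
rng = np.random.default_rng(5)
reference = list(rng.choice(("decreased", "stable", "increased"), size=2000))
confusion = np.full((3, 3), 0.05)
np.fill_diagonal(confusion, 0.90)
reader = simulate_readers(reference, ReaderSimSpec(confusion, seed=6))
for target in ("stable", "decreased", "increased"):
    res = reader_vs_reference_auc(reader, reference, target)
    print(f"reader vs reference, {target:9s}: ROC AUC {res.auc_roc:.3f}, "
          f"PRC AUC {res.auc_prc:.3f} ({res.n_pos} pos / {res.n_neg} neg)")
# Both kappa schemes round to 0.96 — near-perfect agreement.  The 90%-correct
# reader reaches one-vs-rest ROC AUCs near 0.9 for every category.
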