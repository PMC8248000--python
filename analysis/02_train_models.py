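#!/usr/bin/env python
"""Train the two detection models at the study conditions: PCA replicate
outlier screen (99% central interval on the summed PC1–3 scores), then
PLS-R (4 components, cocaine wt%) and PLS-DA (2 components, cocaine
presence) on their respective preprocessing chains, with 10-segment
replicate-grouped cross-validation. Persists the model bundle."""

import logging
from pathlib import Path

import numpy as np

from ramscreen.workflow import ExperimentConfig, train_models

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

OUT = Path("results")
SEED = 2024


def main():
    cfg = ExperimentConfig(seed=SEED)
    bundle = train_models(cfg)

    print(f"training spectra generated: {bundle.n_generated}")
    print(f"outliers removed by PCA screen: "
          f"{bundle.n_generated - bundle.n_fit} "
          f"({100 * (bundle.n_generated - bundle.n_fit) / bundle.n_generated:.2f}%)")
    evx = bundle.plsr.explained_x_variance
    print(f"PLS-R explained X-variance per component: "
          f"{np.round(100 * evx, 2).tolist()} "
          f"(cumulative {100 * evx.sum():.2f}%)")
    print(f"PLS-R RMSEP_cv by components: "
          f"{np.round(bundle.cv_plsr.rmsep_cv, 2).tolist()} wt%")
    print(f"PLS-DA RMSEP_cv by components: "
          f"{np.round(bundle.cv_plsda.rmsep_cv, 3).tolist()}")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "models.json").write_text(bundle.to_json(), encoding="utf-8")
    print(f"model bundle -> {OUT/'models.json'}")


if __name__ == "__main__":
    main()
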