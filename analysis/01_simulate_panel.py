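#!/usr/bin/env python
"""Generate the synthetic study data: the binary cocaine/cutting-agent
mixture panel (88 samples, tenfold scans) and the case-like sample sets
with street-purity distributions. Writes both as csv-wide tables under
results/data/ together with the compound-library fixture."""

import logging
from pathlib import Path

from ramscreen.spectra_io import default_grid, write_spectrum_table
from ramscreen.synthetic import (builtin_compound_library, derive_seed,
                                 generate_binary_panel,
                                 generate_case_like_set, library_to_yaml)
from ramscreen.workflow import ExperimentConfig

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")

OUT = Path("results/data")
SEED = 2024


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ExperimentConfig(seed=SEED)
    library = builtin_compound_library()
    grid = default_grid()

    panel = generate_binary_panel(
        library=library, agents=cfg.panel.agents, levels=cfg.panel.levels,
        replicates=cfg.panel.replicates, instrument=cfg.instrument.build(),
        grid=grid, seed=derive_seed(SEED, "panel"))
    write_spectrum_table(panel, OUT / "binary_panel.csv")
    n_unique = len({m.sample_id for m in panel.metas})
    n_mix = len({m.sample_id for m in panel.metas
                 if 0 < m.cocaine_wt_pct < 100})
    print(f"binary panel: {n_unique} unique samples ({n_mix} strict "
          f"mixtures), {len(panel)} spectra -> {OUT/'binary_panel.csv'}")

    cases = generate_case_like_set(
        n_hcl=cfg.case_set.n_hcl, n_base=cfg.case_set.n_base,
        n_negative=cfg.case_set.n_negative,
        replicates=cfg.case_set.replicates,
        instrument=cfg.instrument.build(), grid=grid,
        seed=derive_seed(SEED, "case-set"), library=library)
    write_spectrum_table(cases, OUT / "case_like.csv")
    n_pos = sum(m.cocaine_wt_pct > 0 for m in cases.metas)
    print(f"case-like set: {len(cases)} spectra ({n_pos} cocaine-containing) "
          f"-> {OUT/'case_like.csv'}")

    library_to_yaml(library, OUT / "compound_library.yaml")
    print(f"compound library fixture -> {OUT/'compound_library.yaml'}")


if __name__ == "__main__":
    main()
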