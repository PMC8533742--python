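#!/usr/bin/env python
"""Time-course differential expression and the DE-count pattern classifier.

Tests every time point against the 1 h reference within each strain
(exact NB test, |FC| >= 2 and p <= 0.01), counts DE comparisons per
strain, and selects genes DE in at most two W37 comparisons but more
than three D37 comparisons — the de-repression signature.  Writes
results/04_de_patterns.tsv.
"""

import importlib.util
import pandas as pd

from rdrmap import pipeline

spec = importlib.util.spec_from_file_location("peaks_driver",
                                              "analysis/02_call_peaks.py")
peaks_driver = importlib.util.module_from_spec(spec)
spec.loader.exec_module(peaks_driver)


def main() -> None:
    cfg, _genome, _tracks, counts, meta = peaks_driver.load()
    results, patterns = pipeline.stage_de(cfg, counts, meta)
    patterns.to_csv("results/04_de_patterns.tsv", sep="\t", index=False)
    truth = pd.read_csv("scratch/fixture/ground_truth.tsv", sep="\t")
    regulon = set(truth[truth.kind == "regulon"].gene_id)
    confounders = set(truth[truth.kind == "confounder"].gene_id)
    selected = set(patterns[patterns.selected].gene_id)
    print(f"{int(results.is_de.sum())} DE calls over "
          f"{results[['strain', 'time']].drop_duplicates().shape[0]} comparisons")
    print(f"{len(selected)} genes match the DE-count pattern "
          f"(W37<=2 and D37>3)")
    print(f"  regulon recovered: {len(selected & regulon)}/{len(regulon)}; "
          f"confounders leaking in: {len(selected & confounders)}")


if __name__ == "__main__":
    main()
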