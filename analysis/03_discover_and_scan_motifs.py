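#!/usr/bin/env python
"""Discover the operator motif from peak sequences and scan all promoters.

ZOOPS EM (palindromic and unconstrained runs pooled by BIC) on the
intergenic consensus-peak sequences yields up to four PSSMs; every CDS
promoter window (-500..+100 around the start codon) is then scanned with
each PSSM at match p <= 1e-4 and the hit union kept.  Writes
results/03_motifs.meme and results/03_motif_hits.tsv.
"""

import importlib.util
import pandas as pd

from rdrmap import motif, pipeline

spec = importlib.util.spec_from_file_location("peaks_driver",
                                              "analysis/02_call_peaks.py")
peaks_driver = importlib.util.module_from_spec(spec)
spec.loader.exec_module(peaks_driver)


def main() -> None:
    cfg, genome, tracks, _counts, _meta = peaks_driver.load()
    retained, _ = pipeline.stage_callpeaks(cfg, genome, tracks)
    results = pipeline.stage_discover(cfg, genome, retained)
    motif.write_meme([r.pssm for r in results], "results/03_motifs.meme")
    hits = pipeline.stage_scan(cfg, genome, [r.pssm for r in results])
    frame = motif.hits_to_frame(hits)
    frame.to_csv("results/03_motif_hits.tsv", sep="\t", index=False)
    fixture_pssm, _ = motif.rdrm_fixture_pssm()
    best = results[0].pssm
    print(f"{len(results)} PSSMs retained; best: width {best.width}, "
          f"IC {best.information_content():.1f} bits")
    print(f"best consensus:    {motif.iupac_consensus(best)}")
    print(f"fixture consensus: {motif.iupac_consensus(fixture_pssm)}")
    print(f"{len(frame)} promoter hits in "
          f"{frame.gene_id.nunique()} genes at p<=1e-4")


if __name__ == "__main__":
    main()
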