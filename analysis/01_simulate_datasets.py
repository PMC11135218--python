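#!/usr/bin/env python
"""Generate the synthetic study datasets.

Emulates the benchmarked microarray collection at 10x-reduced shapes:
a medium-regime planted matrix (200 genes x 60 samples, 4 clusters),
its heteroscedastic-column twin, and a 3-disease collection with 9
shared genes and unequal sample counts (60/72/60).  Matrices land
under scratch/data/ (bulky, regenerable); truth labels and planted
shared-gene means under results/data/.
"""

from analysis_util import ensure_data

if __name__ == "__main__":
    ensure_data(force=True, verbose=True)
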