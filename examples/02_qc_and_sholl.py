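"""Reconstruction QC and Sholl analysis.

Builds a tree with deliberate defects (a sub-micrometre spur and an
over-branched node), repairs it, then computes a Sholl profile and its
summaries on a clean arbor.
"""

import pandas as pd

from morphoscreen import (label_compartments, qc_repair, sholl_profile,
                          sholl_summary)
from morphoscreen.swc import NODE_COLUMNS, NeuronReconstruction
from morphoscreen.synth import NeuronSimParams, gen_neuron

rows = [
    (1, 1, 0, 0, 0, 5, -1),
    (2, 3, 0, 20, 0, 1, 1),
    (3, 3, 0.5, 20, 0, 1, 2),     # spurious 0.5 um spur
    (4, 3, -8, 35, 0, 1, 2),
    (5, 3, 0, 35, 0, 1, 2),
    (6, 3, 8, 35, 0, 1, 2),       # node 2 has >2 daughters
]
defective = NeuronReconstruction(pd.DataFrame(rows, columns=NODE_COLUMNS), 1)
repaired, report = qc_repair(defective)
print("QC report:", report.to_dict())
# the spur (<1 um) is pruned; the over-branched node is reported, not fixed

recon, _, _ = gen_neuron(NeuronSimParams(seed=3))
lab = label_compartments(recon)
prof = sholl_profile(recon, lab, "global", step_um=10)
print("Sholl radii        :", prof.radii.astype(int).tolist())
print("Sholl intersections:", prof.intersections.tolist())
print("summary:", {k: round(v, 2) for k, v in sholl_summary(prof).items()})
# peak_radius is where the arbor is densest; centroid/dispersion summarize
# how far from the soma the branching mass sits and how spread out it is.
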