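"""Generate one synthetic pyramidal arbor and measure it.

Builds a basal/trunk/oblique/tuft tree with known construction, labels its
compartments from scratch, and prints a few compartment-resolved metrics
next to the generator's closed-form record — the two should agree.
"""

from morphoscreen import compute_metrics, label_compartments
from morphoscreen.synth import NeuronSimParams, gen_neuron

params = NeuronSimParams(n_basal_roots=3, basal_depth=2, trunk_length_um=180,
                         n_obliques=3, tuft_depth=2, jitter_sd_um=0.0, seed=7)
recon, truth_labels, record = gen_neuron(params)
labeling = label_compartments(recon)
row = compute_metrics(recon, labeling)

print(f"nodes: {len(recon.nodes)}")
for name in ("basal_branch_number", "trunk_length", "tuft_total_length",
             "global_total_length"):
    key = {"basal_branch_number": "basal_branch_number",
           "trunk_length": "trunk_length",
           "tuft_total_length": "tuft_length",
           "global_total_length": "total_length"}[name]
    print(f"{name:22s} measured={row[name]:9.3f}  construction={record[key]:9.3f}")
print("labels recovered:", labeling.labels == truth_labels.labels)
# At zero jitter the engine reproduces the construction exactly and the
# compartment segmentation recovers the generator's ground truth.
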