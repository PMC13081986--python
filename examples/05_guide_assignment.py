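"""Dual-guide vector assignment and pairing statistics.

Simulates per-cell guide calls under a co-detection/contamination model,
combines them into perturbation assignments (matched pairs collapse to
singlets), and compares the observed matched-pair fraction among two-guide
cells with the chance level from the guide-frequency formula.
"""

from morphoscreen import assign_guides, pairing_stats
from morphoscreen.synth import GuideSimParams, gen_guide_assignments

calls, library, truth = gen_guide_assignments(GuideSimParams(
    n_pairs=8, n_cells=2000, co_detection_rate=0.4,
    cross_contamination_rate=0.05, seed=2))

assigned = assign_guides(calls, library)
print(assigned["status"].value_counts().to_string())

singlets = assigned[assigned["status"] == "singlet"].set_index("cell_id")
truth = truth.set_index("cell_id")
vec_pert = dict(zip(library["vector"], library["perturbation"]))
correct = (singlets["perturbation"]
           == truth.loc[singlets.index, "true_vector"].map(vec_pert)).mean()
print(f"singlet assignment accuracy vs ground truth: {correct:.3f}")

stats = pairing_stats(calls, library)
print(f"matched-pair fraction among two-guide cells: {stats['observed']:.3f}")
print(f"chance level (frequency-weighted):           {stats['chance']:.3f}")
# Co-detection of a vector's two guides drives the observed fraction far
# above chance — the signature of reliable perturbation identity.
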