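"""Stratify signature exposures by A/B chromatin compartment and test for
compartment-differential contributions, plus the fallback eigenvector
compartment caller on a toy Hi-C contact matrix."""

import numpy as np

from lymphsig import (SyntheticConfig, annotate_variants,
                      call_compartments_from_contacts, compare_compartments,
                      fit_by_compartment, generate_cohort)

data = generate_cohort(SyntheticConfig(seed=7))

annotated = annotate_variants(data.records, data.track)
print(annotated["compartment"].value_counts().to_string())

per_comp = fit_by_compartment(annotated, data.track, data.signatures,
                              data.genome)
fl = {s for s, g in data.sample_groups.items() if g == "FL-like"}
table = compare_compartments(per_comp[per_comp["sample"].isin(fl)])
print("\nFL-like group, paired Wilcoxon A vs B (Bonferroni-adjusted):")
print(table[["signature", "mean_A", "mean_B", "p_raw", "p_bonferroni"]]
      .round(4).to_string(index=False))
# The generator plants a +1 log-odds canonical-AID shift toward the
# active compartment in FL-like samples; that signature should be the
# one with adjusted p < 0.05, with the remaining exposures showing the
# compensating opposite drift that simplex closure forces.

# fallback caller: two interleaved compartment blocks in a contact matrix
labels = np.array([0] * 6 + [1] * 6 + [0] * 6)
contacts = np.where(np.equal.outer(labels, labels), 2.0, 0.5)
contacts += np.random.default_rng(0).uniform(0, 0.05, contacts.shape)
contacts = (contacts + contacts.T) / 2
gene_density = (labels == 0).astype(float)   # block 0 is gene dense
track = call_compartments_from_contacts(contacts, bin_size=100_000,
                                        orientation=gene_density)
print("\neigenvector compartment call on a toy contact matrix:")
print(track.to_string(index=False))
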