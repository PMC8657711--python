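"""Classify somatic SNVs into the 96 trinucleotide categories and
summarize the substitution spectrum and per-sample burden."""

from lymphsig import (SyntheticConfig, build_context_matrix, generate_cohort,
                      substitution_spectrum, summarize_burden)

data = generate_cohort(SyntheticConfig(seed=7))
matrix, skipped = build_context_matrix(data.records, data.genome)
print(f"context matrix: {matrix.shape[0]} categories x "
      f"{matrix.shape[1]} samples, {int(matrix.to_numpy().sum())} mutations "
      f"({skipped.total} skipped)")

spectrum = substitution_spectrum(matrix)
print("substitution fractions:")
print(spectrum.fractions.round(3).to_string())
print(f"Ti/Tv ratio:        {spectrum.titv:.2f} "
      "(transitions per transversion)")
print(f"C>T at CpG:         {spectrum.cpg_fraction_of_ct:.1%} of all C>T "
      "(the spontaneous-deamination fingerprint)")

burden, tests = summarize_burden(data.records, target_size_mb=50,
                                 groups=data.sample_groups)
print(burden.groupby("group")[["n_mutations", "rate_per_mb"]].median()
      .round(2).to_string())
print(f"burden difference between groups: t-test p = {tests['count_p']:.2e}")
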