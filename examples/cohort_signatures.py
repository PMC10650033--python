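"""Simulate a small virtual cohort and summarize its mutational signatures.

Each patient's tumor is grown to their sampled diagnosis burden; a gene
counts as mutated in a patient when >= 5% of tumor cells carry its
sensitizing mutation.  Prints the per-gene percentage of mutated patients
and how many genes are mutated per patient, then compares the model
frequencies against a synthetic reference using a two-proportion z-test.
"""

from intrares import compare_frequencies, generate_target_fixture, simulate_cohort

N = 150  # desk-scale cohort; the full study scale is 10,000
cohort = simulate_cohort(N, seed=42)
freqs = cohort.frequencies()

print(f"cohort of {N} virtual patients, per-gene % mutated:")
print(freqs.round(2).to_string())
print("\nmutated genes per patient (XOR gate keeps this at 0 or 1 almost always):")
print(cohort.mutated_gene_counts().to_string())

targets = generate_target_fixture(seed=5)
comparison = compare_frequencies(
    freqs, {g.value: p for g, p in targets.percentages.items()}, n_model=N, n_data=950
)
print("\nmodel vs synthetic reference frequencies (two-proportion z-test):")
print(comparison.round(3).to_string(index=False))
print("p >= 0.05 ('passed') means no significant model-data difference for that gene.")
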