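"""Simulate a lipidomics cohort and run the univariate volcano screen.

Generates the emulated study design (152 PCOS cases vs 50 controls, ~1100
lipid features with two strongly differential species planted), log-transforms
the intensities, and screens each feature with the rule
"fold change > 2 or < 0.5 and BH-adjusted p < 0.05".
"""

from lipopanel import SyntheticConfig, generate_dataset, impute_and_log, volcano_screen

table, truth = generate_dataset(SyntheticConfig(seed=1))
print(f"cohort: {table.n_samples} samples x {table.n_features} lipid features")
print(f"planted strong markers: {truth['strong']}")

log = impute_and_log(table)
screen = volcano_screen(log)
hits = screen[screen["passes"]].sort_values("adjusted_p")
print(f"\n{len(hits)} differential lipid(s) pass the volcano filter:")
print(hits[["fold_change", "log2_fc", "adjusted_p"]].round(4).to_string())
print("\nEach row: case/control raw-intensity ratio, its log2, and the")
print("BH-adjusted p-value; the planted markers should sit near the top.")
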