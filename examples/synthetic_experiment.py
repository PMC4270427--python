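"""Generate a synthetic outcome table with the real experimental design.

Draws 65 replicates for each of the ten diameters from the mixture of
the simulator's outcome distribution (weight lambda) and a uniform
distribution over the three outcomes — the exact statistical model the
fitting stage assumes — and writes both long and aggregated CSVs.
"""

from slimechoice import DesignSpec, StrainSpec, generate_experiment, write_table

strain = StrainSpec("synthetic-japan", k=2.5, T=1.5, lam=0.9239)
table = generate_experiment(strain, DesignSpec(seed=7))

print(f"{len(table.long)} replicate rows; outcome counts by diameter:")
print(table.counts.to_string(index=False))

write_table(table, "synthetic_long.csv", format="long")
write_table(table, "synthetic_counts.csv", format="aggregated")
print("written: synthetic_long.csv (one row per trial), "
      "synthetic_counts.csv (counts per mass)")
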