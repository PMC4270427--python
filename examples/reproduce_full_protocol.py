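"""Full-scale fitting protocol for real experiment tables.

Reproducing the published per-strain best-fit triples requires the raw
experimental spreadsheet (per-trial outcomes for the three strains at
the ten diameters, 65 replicates each) and the full protocol: k from
0.5 to 3.5 and T from 0.5 to 2.0 in steps of 0.1 (31 x 16 cells),
lambda in steps of 0.01, and 1000 simulator realisations per cell and
mass — several hours of compute on one CPU.  This script runs that
protocol end to end given such a file; it is a reproduction script, not
part of the test suite.

Usage:
    python examples/reproduce_full_protocol.py raw_data.xlsx [strain ...]

The spreadsheet is ingested via the column-mapping reader; adapt
COLUMN_MAP below to the file's actual headers.
"""

import sys

from slimechoice import MCConfig, ModelParams, SimulatorCache, grid_fit, read_table

# adapt to the raw file's layout: file column -> canonical name
COLUMN_MAP = {
    # "Strain": "strain",
    # "Diameter (cm)": "diameter_cm",
    # "Replicate": "replicate",
    # "Outcome": "outcome",
}

if len(sys.argv) < 2:
    sys.exit(__doc__)
path = sys.argv[1]
strains = sys.argv[2:] or ["Japan", "Australian", "American"]

template = MCConfig(params=ModelParams(k=1.0, d=1.0, T=1.0, n=2, M=1.0),
                    n_realisations=1000)
# one cache shared across strains: every (k, T, M) distribution is reused
cache = SimulatorCache(template, seed=2014)

for strain in strains:
    table = read_table(path, strain=strain, column_map=COLUMN_MAP or None)
    fit = grid_fit(table, cache=cache, seed=2014)  # default full grids
    print(f"{strain}: k={fit.k_hat}  T={fit.T_hat}  lambda={fit.lambda_hat:.4f}  "
          f"sse={fit.sse:.5f}")
    fit.save(f"fit_{strain.lower()}.json")
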