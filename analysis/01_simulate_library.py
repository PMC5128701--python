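#!/usr/bin/env python
"""Generate the default mock clone library and write it to results/library/.

The mock community mirrors the structure of the real crystallizer-pond
library: 26 lineages over 15 genera with the bundled per-OTU clone counts
(109 clones), reference identities from 90 to 99%, plus 3 injected
midpoint-fusion chimeras (112 records total).
"""

import argparse
from pathlib import Path

from ardra.simulate import CommunitySpec, generate

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path, default=Path("results/library"))
args = parser.parse_args()

library = generate(CommunitySpec(seed=args.seed))
library.write(args.outdir)

truth = library.truth
print(f"wrote {len(library.clones)} clones to {args.outdir}/")
print(f"  lineages: {truth.loc[~truth.is_chimera, 'true_lineage'].nunique()}")
named = truth.loc[~truth.is_chimera, "true_genus"]
print(f"  named genera: {named[named != 'Unclassified'].nunique()}")
print(f"  chimeras: {int(truth.is_chimera.sum())}")
print(f"  references: {len(library.references.records)}")
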