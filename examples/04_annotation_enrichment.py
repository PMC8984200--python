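"""Candidate genes in sweep regions and gene-set enrichment.

Places 100 genes on a 10 Mb chromosome, declares one candidate sweep
region spanning 20 of them, and tests three gene sets for
over-representation with the hypergeometric upper tail and BH-FDR.
"""

import pandas as pd

import keelscan as ks

genes, sets = ks.simulate_annotation(
    100, {"chr1": 10_000_000}, seed=5, set_sizes=(10, 20, 30)
)
region = pd.DataFrame(
    {
        "chrom": ["chr1"],
        "start": [genes.iloc[30]["start"]],
        "end": [genes.iloc[49]["end"]],
        "max_window_fst": [0.31],
    }
)
candidates = ks.genes_in_regions(genes, region)
print(f"candidate genes overlapping the region: {len(candidates)}")

enrichment = ks.fisher_enrich(
    candidates["gene_id"].tolist(), genes["gene_id"].tolist(), sets
)
print(enrichment.to_string(index=False))
print(
    "\np_value is P[X >= overlap] for X ~ Hypergeom(universe, term size,\n"
    "candidates); p_adjusted is the BH-FDR across the tested terms."
)
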