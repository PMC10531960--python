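#!/usr/bin/env python
"""Validate that the pipeline detects neofunctionalization signal in
simulated tandem-duplication data.

Simulates gene families in which one paralog clade's stem evolved at
three times the base rate and carries forced non-conservative switches
at designated tuning sites, then checks that (a) the accelerated
(der) clade shows the larger mean ML divergence from the outgroup in
nearly every replicate and (b) the tuning-site survey recovers most of
the truly shifted sites as derived_in_focal calls.

Writes results/duplication_recovery.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from hemiopsin import evodist, simdata, tuning
from hemiopsin.seqio import SiteMap

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-divergence-seeds", type=int, default=50)
    parser.add_argument("--n-recovery-seeds", type=int, default=50)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    model = evodist.jtt_model()
    gamma = evodist.discrete_gamma(1.0, 4)

    wins = 0
    for k in range(args.n_divergence_seeds):
        dup = simdata.make_duplication_scenario(
            4, 3.0, 0, 300, seed=args.seed + k, model=model, gamma=gamma
        )
        aln, _ = simdata.simulate_alignment(dup.scenario)
        out = dup.outgroup_members[0]

        def mean_div(members):
            return np.mean([
                evodist.pairwise_ml_distance(
                    aln.sequence(m), aln.sequence(out), model, gamma
                ).distance for m in members
            ])

        wins += mean_div(dup.uv_der_members) > mean_div(dup.uv_anc_members)

    fractions = []
    for k in range(args.n_recovery_seeds):
        dup = simdata.make_duplication_scenario(
            4, 3.0, 5, 500, seed=args.seed + 5000 + k, model=model, gamma=gamma
        )
        aln, truth = simdata.simulate_alignment(dup.scenario)
        sm = SiteMap("sim", "sim", {c: c for c in range(1, aln.length + 1)})
        rep = tuning.survey_clades(
            aln, sm,
            tuning.CladeDefinition("UV-anc", dup.uv_anc_members),
            tuning.CladeDefinition("UV-der", dup.uv_der_members),
            tuning.CladeDefinition("outgroup", dup.outgroup_members),
            catalog=frozenset(),
        )
        recovered = {s for s, _ in rep.derived_sites("UV-der")}
        truly = set(truth.shifted_sites["der_clade"])
        fractions.append(len(recovered & truly) / len(truly))

    out = {
        "der_more_divergent_fraction": wins / args.n_divergence_seeds,
        "median_shifted_site_recovery": float(np.median(fractions)),
        "n_divergence_seeds": args.n_divergence_seeds,
        "n_recovery_seeds": args.n_recovery_seeds,
        "seed": args.seed,
    }
    print(f"der clade more divergent from outgroup in "
          f"{wins}/{args.n_divergence_seeds} replicates; median recovery "
          f"of truly shifted sites {out['median_shifted_site_recovery']:.2f}")
    (RESULTS / "duplication_recovery.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
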