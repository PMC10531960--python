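"""Tuning-site survey: derived non-conservative substitution calling.

The core procedure behind the opsin paralog comparison: for every
alignment column with a reference site number, collect the residue
states of an outgroup set (defining the ancestral state), a focal
paralog clade, and its sister paralog clade, then decide whether the
focal clade carries a *derived non-conservative* replacement — i.e. a
residue set disjoint from both the ancestral and sister states, with
the sister still matching the outgroups, and at least one focal
residue physicochemically dissimilar from every ancestral residue.

Two focal passes (UV-der vs UV-anc and the reverse) give the per-clade
derived-site lists; comparing two lineages' UV-der lists separates
parallel from lineage-specific candidate tuning substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import AMBIGUOUS, GAP, Alignment, SiteMap

#: Residue groups within which a replacement is considered conservative.
#: Deliberately minimal: branched aliphatics and the two long basics.
DEFAULT_CONSERVATIVE_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("ILV"),
    frozenset("RK"),
)

#: Default catalog of previously proposed/demonstrated spectral tuning
#: sites, in bovine Rhodopsin numbering.
DEFAULT_TUNING_CATALOG: frozenset[tuple[int, str]] = frozenset(
    {(90, "Rhodopsin"), (105, "Rhodopsin"), (125, "Rhodopsin"),
     (293, "Rhodopsin"), (294, "Rhodopsin")}
)

SiteKey = tuple[int, str]  # (site number, numbering scheme)


def site_label(site: int, scheme: str) -> str:
    """Render a site key the way the field prints it: ``90`` or ``29*``."""
    return f"{site}*" if scheme != "Rhodopsin" else str(site)


@dataclass(frozen=True)
class CladeDefinition:
    label: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"clade {self.label!r} has no members")


@dataclass
class SiteStates:
    """Residue state sets at one mapped site for one focal/sister split."""

    site: int
    scheme: str
    ancestral: frozenset[str]
    focal: frozenset[str]
    sister: frozenset[str]
    raw: dict[str, str]
    ambiguous_reason: str | None = None


@dataclass
class SiteClassification:
    site: int
    scheme: str
    verdict: str  # derived_in_focal | retained | shared_derived | ambiguous
    replacement: tuple[str, str] | None = None  # (ancestral, derived) residues
    catalog_hit: bool = False
    note: str = ""

    @property
    def key(self) -> SiteKey:
        return (self.site, self.scheme)


def is_conservative(
    x: str,
    a: str,
    groups: Sequence[frozenset[str]] = DEFAULT_CONSERVATIVE_GROUPS,
) -> bool:
    """True iff residues ``x`` and ``a`` co-occur in some group (or are equal)."""
    if x == a:
        return True
    return any(x in g and a in g for g in groups)


def collect_site_states(
    aln: Alignment,
    sitemap: SiteMap,
    site: int,
    focal: CladeDefinition,
    sister: CladeDefinition,
    outgroups: CladeDefinition,
    minor_variant_fraction: float = 0.25,
) -> SiteStates:
    """Gather residue state sets at one reference site.

    The ancestral and sister sets are plain unions of the observed
    residues; the focal set keeps only residues carried by more than
    ``minor_variant_fraction`` of the focal members, so that a single
    divergent sequence does not veto a clade-wide replacement call.
    Gaps and ``X`` never enter any set; a clade that is all-gap at the
    column is flagged ambiguous rather than silently empty.
    """
    col = sitemap.site_to_column.get(site)
    if col is None:
        raise KeyError(f"site {site} is not mapped in scheme {sitemap.scheme!r}")

    def residues(ids: Iterable[str]) -> list[str]:
        return [
            aln.sequence(i)[col - 1]
            for i in ids
            if aln.sequence(i)[col - 1] not in (GAP, AMBIGUOUS)
        ]

    raw = {i: aln.sequence(i)[col - 1] for i in (*focal.members, *sister.members, *outgroups.members)}
    anc = residues(outgroups.members)
    sis = residues(sister.members)
    foc = residues(focal.members)

    reason = None
    for label, present, clade in (
        ("outgroup", anc, outgroups),
        ("sister", sis, sister),
        ("focal", foc, focal),
    ):
        if not present:
            reason = f"no informative residues in {label} clade {clade.label!r}"
            break

    n_focal = len(focal.members)
    focal_set = frozenset(
        r for r in set(foc) if foc.count(r) / n_focal > minor_variant_fraction
    )
    if not focal_set and foc:
        # every focal residue fell under the minor-variant threshold;
        # fall back to the full set rather than an empty one
        focal_set = frozenset(foc)

    return SiteStates(
        site=site,
        scheme=sitemap.scheme,
        ancestral=frozenset(anc),
        focal=focal_set,
        sister=frozenset(sis),
        raw=raw,
        ambiguous_reason=reason,
    )


def classify_site(
    states: SiteStates,
    groups: Sequence[frozenset[str]] = DEFAULT_CONSERVATIVE_GROUPS,
    catalog: frozenset[SiteKey] = DEFAULT_TUNING_CATALOG,
) -> SiteClassification:
    """Assign one verdict to a site for the focal clade.

    ``derived_in_focal`` requires (i) the focal set shares nothing with
    the ancestral set, (ii) nor with the sister set, (iii) the sister
    still carries an ancestral residue (so the pre-duplication state is
    inferable), and (iv) at least one focal residue is non-conservative
    against every ancestral residue. Focal sets overlapping the
    ancestral set are ``retained``; novel focal states shared with the
    sister are ``shared_derived`` (the change predates the paralog
    split). Everything else — empty state sets, sister-not-ancestral
    configurations, purely conservative novelties — is ``ambiguous``
    with the reason recorded in ``note``.
    """
    hit = (states.site, states.scheme) in catalog
    base = dict(site=states.site, scheme=states.scheme, catalog_hit=hit)
    if states.ambiguous_reason:
        return SiteClassification(verdict="ambiguous", note=states.ambiguous_reason, **base)

    A, F, S = states.ancestral, states.focal, states.sister
    if F & A:
        return SiteClassification(verdict="retained", **base)
    if F & S:
        return SiteClassification(verdict="shared_derived", **base)
    if not S & A:
        return SiteClassification(
            verdict="ambiguous", note="sister_not_ancestral", **base
        )
    # focal is novel relative to both ancestral and sister states
    nonconservative = [
        x for x in sorted(F) if all(not is_conservative(x, a, groups) for a in A)
    ]
    if not nonconservative:
        return SiteClassification(
            verdict="ambiguous", note="conservative_change", **base
        )
    derived = nonconservative[0]
    ancestral_res = sorted(A)[0] if len(A) == 1 else "/".join(sorted(A))
    return SiteClassification(
        verdict="derived_in_focal",
        replacement=(ancestral_res, derived),
        **base,
    )


@dataclass
class SurveyReport:
    """Per-site classifications for both focal passes over one lineage."""

    lineage: str
    focal_labels: tuple[str, str]  # (UV-der label, UV-anc label)
    classifications: dict[str, dict[SiteKey, SiteClassification]]
    minor_variant_fraction: float
    catalog: frozenset[SiteKey]

    def derived_sites(self, focal_label: str) -> list[SiteKey]:
        return sorted(
            k
            for k, c in self.classifications[focal_label].items()
            if c.verdict == "derived_in_focal"
        )

    def derived_count(self, focal_label: str) -> int:
        return len(self.derived_sites(focal_label))

    def ambiguous_sites(self, focal_label: str) -> list[tuple[SiteKey, str]]:
        return sorted(
            (k, c.note)
            for k, c in self.classifications[focal_label].items()
            if c.verdict == "ambiguous"
        )

    def catalog_matches(self) -> list[SiteKey]:
        """Derived sites (either focal pass) that hit the tuning-site catalog."""
        hits = {
            k
            for by_site in self.classifications.values()
            for k, c in by_site.items()
            if c.verdict == "derived_in_focal" and c.catalog_hit
        }
        return sorted(hits)

    def replacement(self, focal_label: str, key: SiteKey) -> tuple[str, str] | None:
        return self.classifications[focal_label][key].replacement

    def to_rows(self) -> list[dict]:
        rows = []
        for focal_label, by_site in self.classifications.items():
            for (site, scheme), c in sorted(by_site.items()):
                rows.append(
                    {
                        "lineage": self.lineage,
                        "focal": focal_label,
                        "site": site_label(site, scheme),
                        "scheme": scheme,
                        "verdict": c.verdict,
                        "replacement": "->".join(c.replacement) if c.replacement else "",
                        "catalog_hit": c.catalog_hit,
                        "note": c.note,
                    }
                )
        return rows


def survey_clades(
    aln: Alignment,
    sitemaps: SiteMap | Sequence[SiteMap],
    uv_anc: CladeDefinition,
    uv_der: CladeDefinition,
    outgroups: CladeDefinition,
    catalog: frozenset[SiteKey] = DEFAULT_TUNING_CATALOG,
    groups: Sequence[frozenset[str]] = DEFAULT_CONSERVATIVE_GROUPS,
    minor_variant_fraction: float = 0.25,
    lineage: str = "",
) -> SurveyReport:
    """Classify every mapped site twice, once per focal clade.

    Pass 1 takes UV-der as focal with UV-anc as sister; pass 2 swaps
    them. Ambiguous sites are reported separately and never enter the
    derived counts.
    """
    if isinstance(sitemaps, SiteMap):
        sitemaps = [sitemaps]
    overlap = (set(uv_anc.members) & set(uv_der.members)) | (
        set(uv_anc.members) | set(uv_der.members)
    ) & set(outgroups.members)
    if overlap:
        raise ValueError(f"clades are not disjoint: {sorted(overlap)}")

    classifications: dict[str, dict[SiteKey, SiteClassification]] = {
        uv_der.label: {},
        uv_anc.label: {},
    }
    for sm in sitemaps:
        for site in sorted(sm.site_to_column):
            for focal, sister in ((uv_der, uv_anc), (uv_anc, uv_der)):
                states = collect_site_states(
                    aln, sm, site, focal, sister, outgroups, minor_variant_fraction
                )
                c = classify_site(states, groups, catalog)
                classifications[focal.label][(site, sm.scheme)] = c
    return SurveyReport(
        lineage=lineage or f"{uv_der.label}/{uv_anc.label}",
        focal_labels=(uv_der.label, uv_anc.label),
        classifications=classifications,
        minor_variant_fraction=minor_variant_fraction,
        catalog=catalog,
    )


@dataclass
class ParallelReport:
    """Cross-lineage comparison of UV-der derived-site sets."""

    lineages: tuple[str, str]
    parallel_sites: list[SiteKey]
    parallel_kind: dict[SiteKey, str]  # identical_replacement | residue_divergent
    replacements: dict[SiteKey, tuple[tuple[str, str] | None, tuple[str, str] | None]]
    non_shared_sites: list[SiteKey]

    @property
    def n_parallel(self) -> int:
        return len(self.parallel_sites)

    @property
    def n_non_shared(self) -> int:
        return len(self.non_shared_sites)


def compare_lineages(report_x: SurveyReport, report_y: SurveyReport) -> ParallelReport:
    """Intersect and difference the two lineages' UV-der derived-site sets.

    Sites are compared as (number, scheme) pairs, so positions in the
    alternate (beetle UV-opsin-2) numbering never collide with
    Rhodopsin-numbered positions.
    """
    der_x = report_x.focal_labels[0]
    der_y = report_y.focal_labels[0]
    set_x = set(report_x.derived_sites(der_x))
    set_y = set(report_y.derived_sites(der_y))
    parallel = sorted(set_x & set_y)
    kind: dict[SiteKey, str] = {}
    repl: dict[SiteKey, tuple] = {}
    for k in parallel:
        rx = report_x.replacement(der_x, k)
        ry = report_y.replacement(der_y, k)
        repl[k] = (rx, ry)
        same = rx is not None and ry is not None and rx[1] == ry[1]
        kind[k] = "identical_replacement" if same else "residue_divergent"
    return ParallelReport(
        lineages=(report_x.lineage, report_y.lineage),
        parallel_sites=parallel,
        parallel_kind=kind,
        replacements=repl,
        non_shared_sites=sorted(set_x ^ set_y),
    )


def read_catalog_tsv(path: str | Path) -> frozenset[SiteKey]:
    """Read a tuning-site catalog as TSV with columns ``site`` and ``scheme``."""
    entries = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            entries.add((int(parts[idx["site"]]), parts[idx["scheme"]]))
    return frozenset(entries)


def read_clades_tsv(path: str | Path) -> dict[str, CladeDefinition]:
    """Read clade definitions as TSV with columns ``clade`` and ``member``."""
    members: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            members.setdefault(parts[idx["clade"]], []).append(parts[idx["member"]])
    return {label: CladeDefinition(label, tuple(m)) for label, m in members.items()}
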