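"""Loaders for the shipped desk-scale fixtures.

These encode the published ground truth the pipeline is validated
against: the tandem-locus coordinate table, the per-site residue state
matrix of the UV-opsin paralog clades of aphids and planthoppers, the
hemipteran species tree with the B-opsin presence/absence scores, the
UV-opsin gene trees, and the tuning-site catalog.

The state matrix is expanded into a concrete protein alignment (one
column per surveyed site) by distributing clade-wide variants as
evenly as possible over the clade members and assigning each
parenthesized minor variant to exactly one member — exactly the
configuration the survey's minor-variant filter is designed around.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import dendropy

from .genomics import LocusRecord, read_locus_table
from .reconcile import PresenceMatrix, read_newick
from .seqio import Alignment, SiteMap
from .tuning import CladeDefinition, read_catalog_tsv, read_clades_tsv

APHID_SPECIES = ("Apis", "Mper", "Rmai", "Sfla", "Cced")
PLANTHOPPER_SPECIES = ("Nlug", "Lstri", "Sfur")
APHID_OUTGROUPS = ("Pcel_UVop", "Dcit_UVop", "Focc_UVop")
PLANTHOPPER_OUTGROUPS = ("Ncin_UVop", "Evit_UVop", "Monu_UVop")


def data_path(name: str) -> Path:
    return Path(str(resources.files("hemiopsin").joinpath("data", name)))


def parse_state_cell(cell: str) -> tuple[list[str], list[str]]:
    """Split a state-matrix cell into (major variants, minor variants)."""
    minors = re.findall(r"\(([A-Z])\)", cell)
    majors = [t for t in re.split(r"[/,]", re.sub(r"\([A-Z]\)", "", cell)) if t]
    return majors, minors


def expand_cell(cell: str, members: tuple[str, ...]) -> dict[str, str]:
    """Assign one residue per member for a state-matrix cell.

    Minor variants occupy one member each (from the end of the member
    list); major variants split the remaining members as evenly as
    possible, earlier variants taking the extras.
    """
    majors, minors = parse_state_cell(cell)
    k = len(members)
    slots = k - len(minors)
    if slots < len(majors) or slots < 0:
        raise ValueError(f"cell {cell!r} needs more members than {k}")
    counts = [slots // len(majors)] * len(majors)
    for i in range(slots % len(majors)):
        counts[i] += 1
    residues: list[str] = []
    for res, c in zip(majors, counts):
        residues.extend([res] * c)
    residues.extend(minors)
    return dict(zip(members, residues))


def _read_state_rows() -> list[dict[str, str]]:
    rows = []
    with open(data_path("paralog_site_states.tsv")) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            rows.append(dict(zip(header, parts)))
    return rows


def paralog_state_fixture(lineage: str) -> dict:
    """Expand the shipped state matrix into an alignment plus metadata.

    Returns a dict with keys ``alignment``, ``sitemaps`` (one per
    numbering scheme), ``uv_anc``, ``uv_der``, ``outgroups``.
    """
    if lineage == "aphid":
        species, outgroups = APHID_SPECIES, APHID_OUTGROUPS
        cols = ("aphid_ancestral", "aphid_uv_anc", "aphid_uv_der")
    elif lineage == "planthopper":
        species, outgroups = PLANTHOPPER_SPECIES, PLANTHOPPER_OUTGROUPS
        cols = ("ph_ancestral", "ph_uv_anc", "ph_uv_der")
    else:
        raise ValueError(f"unknown lineage {lineage!r}")
    anc_members = tuple(f"{s}_UVanc" for s in species)
    der_members = tuple(f"{s}_UVder" for s in species)

    rows = _read_state_rows()
    seqs: dict[str, list[str]] = {m: [] for m in (*outgroups, *anc_members, *der_members)}
    scheme_cols: dict[str, dict[int, int]] = {}
    for col_idx, row in enumerate(rows, start=1):
        scheme_cols.setdefault(row["scheme"], {})[col_idx] = int(row["site"])
        for cell_col, members in zip(cols, (outgroups, anc_members, der_members)):
            for member, res in expand_cell(row[cell_col], members).items():
                seqs[member].append(res)

    aln = Alignment(tuple((m, "".join(s)) for m, s in seqs.items()))
    sitemaps = [
        SiteMap(reference_id=scheme, scheme=scheme, column_to_site=mapping)
        for scheme, mapping in scheme_cols.items()
    ]
    return {
        "alignment": aln,
        "sitemaps": sitemaps,
        "uv_anc": CladeDefinition("UV-anc", anc_members),
        "uv_der": CladeDefinition("UV-der", der_members),
        "outgroups": CladeDefinition("outgroup", outgroups),
    }


def tandem_locus_records() -> list[LocusRecord]:
    return read_locus_table(data_path("tandem_loci.tsv"))


def species_tree() -> dendropy.Tree:
    return read_newick(data_path("species_tree.nwk").read_text())


def bopsin_presence() -> PresenceMatrix:
    return PresenceMatrix.from_tsv(data_path("bopsin_presence.tsv"))


def uv_gene_tree(lineage: str) -> tuple[dendropy.Tree, dict[str, str]]:
    """The UV-opsin gene-tree fixture plus its leaf -> species map."""
    name = {"aphid": "aphid_uv_gene_tree.nwk", "planthopper": "planthopper_uv_gene_tree.nwk"}[
        lineage
    ]
    tree = read_newick(data_path(name).read_text())
    leaf_map = {
        lf.taxon.label: lf.taxon.label.split("_")[0] for lf in tree.leaf_node_iter()
    }
    return tree, leaf_map


def tuning_catalog():
    return read_catalog_tsv(data_path("tuning_catalog.tsv"))


def clade_definitions(lineage: str) -> dict[str, CladeDefinition]:
    name = {"aphid": "aphid_clades.tsv", "planthopper": "planthopper_clades.tsv"}[lineage]
    return read_clades_tsv(data_path(name))
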