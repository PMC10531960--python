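"""Protein sequence evolution simulator for pipeline validation.

Generates alignments with the statistical structure the analysis
assumes: JTT substitution dynamics along a newick tree, discrete-gamma
site rate heterogeneity (rates drawn per site, not marginalized),
optional per-branch rate multipliers (clock violation), and forced
residue switches at designated "tuning" sites on a named branch —
the simplest generative analog of a selective sweep that is inherited
by all descendants.

Scenario builders emit the matched gene tree / species tree / leaf-map
triples needed to exercise reconciliation, rate tests, and the
tuning-site survey end to end, together with a truth record for
assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np

from ._jtt_data import AMINO_ACIDS
from .evodist import GammaRates, SubstitutionModel, N_STATES
from .seqio import Alignment

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class SimulationScenario:
    tree: str                       # newick with branch lengths; internal labels name branches
    model: SubstitutionModel
    gamma: GammaRates
    length: int
    seed: int
    branch_rates: dict[str, float] = field(default_factory=dict)
    # branch label -> {1-based site -> residue or None (auto-pick)}
    forced_sites: dict[str, dict[int, str | None]] = field(default_factory=dict)

    def __post_init__(self):
        if any(m <= 0 for m in self.branch_rates.values()):
            raise ValueError("branch rate multipliers must be positive")
        for sites in self.forced_sites.values():
            for site, res in sites.items():
                if not 1 <= site <= self.length:
                    raise ValueError(f"forced site {site} outside 1..{self.length}")
                if res is not None and res not in _AA_INDEX:
                    raise ValueError(f"invalid forced residue {res!r}")


@dataclass
class TruthRecord:
    tree: str
    branch_rates: dict[str, float]
    site_rates: np.ndarray
    true_distances: dict[tuple[str, str], float]
    duplication_branch: str | None
    shifted_sites: dict[str, dict[int, str]]  # branch -> site -> forced residue
    seed: int


def _branch_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


def _true_path_distances(
    tree: dendropy.Tree, branch_rates: Mapping[str, float]
) -> dict[tuple[str, str], float]:
    """Expected substitutions/site between every leaf pair."""
    leaves = list(tree.leaf_node_iter())
    dist: dict[tuple[str, str], float] = {}

    def up_path(node):
        path = {}
        total = 0.0
        while node.parent_node is not None:
            total += (node.edge.length or 0.0) * branch_rates.get(_branch_label(node), 1.0)
            node = node.parent_node
            path[id(node)] = total
        return path

    for i, a in enumerate(leaves):
        pa = up_path(a)
        for b in leaves[i + 1:]:
            pb = up_path(b)
            shared = [n for n in pb if n in pa]
            # the first shared ancestor encountered walking up from b
            # is the MRCA because up_path accumulates monotonically
            mrca = min(shared, key=lambda n: pb[n])
            key = tuple(sorted((a.taxon.label, b.taxon.label)))
            dist[key] = pa[mrca] + pb[mrca]
    return dist


def simulate_alignment(scenario: SimulationScenario) -> tuple[Alignment, TruthRecord]:
    """Evolve a root sequence along the scenario tree.

    The root sequence is drawn from the model's equilibrium
    frequencies; each site is assigned one discrete-gamma category for
    the whole tree; each branch applies P(length * branch rate * site
    rate). Forced sites are overwritten on the named branch after
    normal evolution and inherited below. Deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng(scenario.seed)
    tree = dendropy.Tree.get(
        data=scenario.tree, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    L = scenario.length
    model, gamma = scenario.model, scenario.gamma
    pi = model.frequencies

    cats = rng.integers(0, gamma.ncat, size=L)
    site_rates = gamma.rates[cats]
    root_state = rng.choice(N_STATES, size=L, p=pi)

    states: dict[int, np.ndarray] = {id(tree.seed_node): root_state}
    # forced states active at a node (inherited and held fixed below
    # the branch they were introduced on, like a sweep under selection)
    active: dict[int, dict[int, int]] = {id(tree.seed_node): {}}
    shifted: dict[str, dict[int, str]] = {}

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_state = states[id(node.parent_node)]
        label = _branch_label(node)
        mult = scenario.branch_rates.get(label, 1.0)
        t = (node.edge.length or 0.0) * mult
        child = parent_state.copy()
        if t > 0:
            u = rng.random(L)
            for c in range(gamma.ncat):
                idx = np.nonzero(cats == c)[0]
                if idx.size == 0:
                    continue
                P = model.transition_matrix(t, gamma.rates[c])
                cum = np.cumsum(P[parent_state[idx]], axis=1)
                child[idx] = (cum > u[idx, None]).argmax(axis=1)
        held = dict(active[id(node.parent_node)])
        if label in scenario.forced_sites:
            forced_here: dict[int, str] = {}
            for site, res in scenario.forced_sites[label].items():
                if res is None:
                    cur = int(parent_state[site - 1])
                    choices = [
                        j for j in range(N_STATES)
                        if j != cur and not _conservative_idx(j, cur)
                    ]
                    res = AMINO_ACIDS[choices[rng.integers(len(choices))]]
                held[site] = _AA_INDEX[res]
                forced_here[site] = res
            shifted[label] = forced_here
        for site, code in held.items():
            child[site - 1] = code
        active[id(node)] = held
        states[id(node)] = child

    records = tuple(
        (lf.taxon.label, "".join(AMINO_ACIDS[s] for s in states[id(lf)]))
        for lf in tree.leaf_node_iter()
    )
    truth = TruthRecord(
        tree=scenario.tree,
        branch_rates=dict(scenario.branch_rates),
        site_rates=site_rates,
        true_distances=_true_path_distances(tree, scenario.branch_rates),
        duplication_branch=None,
        shifted_sites=shifted,
        seed=scenario.seed,
    )
    return Alignment(records), truth


def _conservative_idx(i: int, j: int) -> bool:
    from .tuning import DEFAULT_CONSERVATIVE_GROUPS

    a, b = AMINO_ACIDS[i], AMINO_ACIDS[j]
    return any(a in g and b in g for g in DEFAULT_CONSERVATIVE_GROUPS)


def _pectinate_ultrametric(
    names: list[str], step: float, prefix: str = "N", top_label: str | None = None
) -> str:
    """Pectinate ultrametric newick over ``names`` with node heights
    step, 2*step, ... Internal nodes labeled ``prefix``1, ``prefix``2,
    ...; the deepest node takes ``top_label`` when given."""
    newick = names[0]
    height = 0.0
    last = len(names) - 1
    for k, name in enumerate(names[1:], start=1):
        new_h = step * k
        label = top_label if (k == last and top_label is not None) else f"{prefix}{k}"
        newick = f"({newick}:{new_h - height:g},{name}:{new_h:g}){label}"
        height = new_h
    return newick + ";"


@dataclass
class DuplicationScenario:
    scenario: SimulationScenario
    gene_tree: str
    species_tree: str
    leaf_species_map: dict[str, str]
    uv_anc_members: tuple[str, ...]
    uv_der_members: tuple[str, ...]
    outgroup_members: tuple[str, ...]
    duplication_branch: str
    tuning_sites: tuple[int, ...]


def make_duplication_scenario(
    n_species: int,
    stem_multiplier: float,
    n_tuning_sites: int,
    length: int,
    seed: int,
    model: SubstitutionModel | None = None,
    gamma: GammaRates | None = None,
) -> DuplicationScenario:
    """Tandem-duplication scenario mirroring paralog neofunctionalization.

    A gene duplication on the ingroup stem yields two paralog clades
    ("anc" and "der") that each track the species tree; the der stem
    branch evolves at ``stem_multiplier`` times the base rate and
    carries forced non-conservative switches at ``n_tuning_sites``
    random sites. An outgroup singleton roots everything.
    """
    if n_species < 3:
        raise ValueError("need at least 3 ingroup species")
    if stem_multiplier <= 0:
        raise ValueError("stem multiplier must be positive")
    if model is None or gamma is None:
        from .evodist import discrete_gamma, jtt_model

        model = model or jtt_model()
        gamma = gamma or discrete_gamma(1.0, 4)

    rng = np.random.default_rng(seed)
    species = [f"S{i+1}" for i in range(n_species)]
    step = 0.03
    crown = step * (n_species - 1)
    stem = 0.1
    sp_newick = _pectinate_ultrametric(species, step, top_label="Ingroup")[:-1]
    species_tree = f"({sp_newick}:{stem:g},SO:{crown + stem:g})Root;"

    def paralog_copy(suffix: str) -> str:
        return _pectinate_ultrametric(
            [f"{s}_{suffix}" for s in species], step,
            prefix=f"{suffix}", top_label=f"{suffix}_clade",
        )[:-1]

    gene_tree = (
        f"(({paralog_copy('anc')}:{stem / 2:g},"
        f"{paralog_copy('der')}:{stem / 2:g})dup:{stem / 2:g},"
        f"O_out:{crown + stem:g})Root;"
    )
    tuning_sites = tuple(
        sorted(rng.choice(np.arange(1, length + 1), size=n_tuning_sites, replace=False))
    ) if n_tuning_sites else ()

    scenario = SimulationScenario(
        tree=gene_tree,
        model=model,
        gamma=gamma,
        length=length,
        seed=int(rng.integers(2**31 - 1)),
        branch_rates={"der_clade": stem_multiplier},
        forced_sites={"der_clade": {s: None for s in tuning_sites}},
    )
    leaf_map = {f"{s}_anc": s for s in species}
    leaf_map.update({f"{s}_der": s for s in species})
    leaf_map["O_out"] = "SO"
    return DuplicationScenario(
        scenario=scenario,
        gene_tree=gene_tree,
        species_tree=species_tree,
        leaf_species_map=leaf_map,
        uv_anc_members=tuple(f"{s}_anc" for s in species),
        uv_der_members=tuple(f"{s}_der" for s in species),
        outgroup_members=("O_out",),
        duplication_branch="Ingroup",
        tuning_sites=tuning_sites,
    )


def simulate_clock_pair(
    n_taxa: int,
    violating_taxon: str | None,
    multiplier: float,
    length: int,
    seed: int,
    model: SubstitutionModel | None = None,
    gamma: GammaRates | None = None,
) -> tuple[Alignment, str, TruthRecord]:
    """Ultrametric tree with one optionally rate-scaled terminal branch.

    ``multiplier`` 1 (or ``violating_taxon`` None) gives null data for
    type-I error calibration; larger multipliers give power/alternative
    data. Returns (alignment, rooted topology newick, truth record).
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if model is None or gamma is None:
        from .evodist import discrete_gamma, jtt_model

        model = model or jtt_model()
        gamma = gamma or discrete_gamma(1.0, 4)
    taxa = [f"T{i+1}" for i in range(n_taxa)]
    if violating_taxon is not None and violating_taxon not in taxa:
        raise ValueError(f"{violating_taxon!r} not among taxa {taxa}")
    tree = _pectinate_ultrametric(taxa, 0.08)
    rates = (
        {violating_taxon: multiplier}
        if violating_taxon is not None and multiplier != 1.0
        else {}
    )
    scenario = SimulationScenario(
        tree=tree, model=model, gamma=gamma, length=length, seed=seed,
        branch_rates=rates,
    )
    aln, truth = simulate_alignment(scenario)
    return aln, tree, truth
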