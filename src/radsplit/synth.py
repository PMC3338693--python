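"""Synthetic study generator: a colobine-like rapid radiation.

Emulates the study design this pipeline is built for: 18 taxa (14 ingroup
colobine-like species, 4 outgroup primates), 44 slow nuclear non-coding
loci (~4% mean pairwise divergence) and one fast, non-recombining
mitochondrial partition set (~18.5% mean divergence, split into
protein/rRNA/tRNA/control-region sub-partitions), with gene-tree
discordance arising from incomplete lineage sorting across the short
radiation internodes and, optionally, a single introgression pulse.

Model: the multispecies coalescent (Hudson construction). Species-tree
branch lengths are in coalescent units of 2N generations with one haploid
lineage sampled per species; within a species-tree branch carrying j
lineages, pairs coalesce at rate C(j,2) per unit. An introgression pulse
reroutes each lineage present in the recipient branch at the event time to
the donor branch with the stated probability (backwards in time), which is
how a one-time hybridization event appears to sampled gene copies.

Gene-tree branch lengths are reported as rate-integrated lengths: each
lineage accumulates (per-species-branch rate scaler) x (time) along its
path, so with all scalers at 1 lengths are plain coalescent units; a
per-locus substitution-rate scale then converts them to expected
substitutions per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .models import SubstitutionModel
from .seqio import Alignment, Locus
from .trees import Node, Tree, TreeError, tree_from_newick

__all__ = [
    "SpeciesTreeSpec",
    "IntrogressionEvent",
    "SimulationConfig",
    "StudyBundle",
    "build_species_tree",
    "sample_gene_tree",
    "simulate_alignment",
    "generate_study",
    "default_species_spec",
    "default_introgression_event",
    "expected_pairwise_coal_distance",
    "divergence_to_subs_scale",
    "DEFAULT_TAXA",
    "MT_PARTITIONS",
]

# ---------------------------------------------------------------------------
# defaults: the study-shaped radiation
# ---------------------------------------------------------------------------

DEFAULT_TAXA = (
    "Presbytis_melalophos",
    "Pygathrix_nemaeus",
    "Rhinopithecus_roxellana",
    "Rhinopithecus_bieti",
    "Rhinopithecus_avunculus",
    "Nasalis_larvatus",
    "Trachypithecus_hatinhensis",
    "Trachypithecus_germaini",
    "Trachypithecus_shortridgei",
    "Semnopithecus_entellus",
    "Semnopithecus_johnii",
    "Semnopithecus_vetulus",
    "Colobus_guereza",
    "Piliocolobus_badius",
    "Macaca_mulatta",
    "Pongo_abelii",
    "Pan_troglodytes",
    "Homo_sapiens",
)

DEFAULT_OUTGROUP = ("Macaca_mulatta", "Pongo_abelii", "Pan_troglodytes", "Homo_sapiens")

#: ultrametric true tree, branch lengths in coalescent units (2N gens).
#: The ingroup mirrors the radiation pattern: a Presbytis + odd-nosed clade
#: and a Semnopithecus + Trachypithecus clade, with short (0.4 unit)
#: internodes across the Asian radiation driving ILS.
DEFAULT_TOPOLOGY = (
    "((((((("
    "Pygathrix_nemaeus:3.0,((Rhinopithecus_bieti:1.2,Rhinopithecus_roxellana:1.2)"
    ":0.8,Rhinopithecus_avunculus:2.0):1.0):0.4,Nasalis_larvatus:3.4):0.4,"
    "Presbytis_melalophos:3.8):0.4,"
    "((Semnopithecus_entellus:2.2,(Semnopithecus_johnii:1.2,"
    "Semnopithecus_vetulus:1.2):1.0):1.0,((Trachypithecus_hatinhensis:1.0,"
    "Trachypithecus_shortridgei:1.0):0.8,Trachypithecus_germaini:1.8):1.4):1.0)"
    ":1.8,(Colobus_guereza:3.0,Piliocolobus_badius:3.0):3.0):4.0,"
    "Macaca_mulatta:10.0):4.0,"
    "(Pongo_abelii:8.5,(Homo_sapiens:4.5,Pan_troglodytes:4.5):4.0):5.5);"
)

#: mt sub-partitions: (aligned length, relative divergence vs the whole
#: molecule, locus class). Lengths total 16,527; relative divergences give
#: each sub-partition its own rate multiplier around the molecule-wide
#: target.
MT_PARTITIONS: dict[str, tuple[int, float, str]] = {
    "ND1": (957, 19.0 / 18.5, "mt_protein"),
    "ND2": (1044, 22.8 / 18.5, "mt_protein"),
    "COX1": (1545, 16.9 / 18.5, "mt_protein"),
    "COX2": (684, 17.1 / 18.5, "mt_protein"),
    "ATP8": (211, 28.8 / 18.5, "mt_protein"),
    "ATP6": (681, 23.6 / 18.5, "mt_protein"),
    "COX3": (784, 18.6 / 18.5, "mt_protein"),
    "ND3": (346, 23.4 / 18.5, "mt_protein"),
    "ND4L": (297, 19.8 / 18.5, "mt_protein"),
    "ND4": (1378, 21.0 / 18.5, "mt_protein"),
    "ND5": (1806, 22.4 / 18.5, "mt_protein"),
    "ND6": (528, 18.9 / 18.5, "mt_protein"),
    "CYTB": (1135, 20.7 / 18.5, "mt_protein"),
    "12SrRNA": (961, 10.9 / 18.5, "mt_rRNA"),
    "16SrRNA": (1582, 12.7 / 18.5, "mt_rRNA"),
    "tRNA": (1573, 12.1 / 18.5, "mt_tRNA"),
    "D-loop": (1015, 24.8 / 18.5, "mt_CR"),
}

DEFAULT_NUCLEAR_MODEL = SubstitutionModel(
    family="HKY85",
    base_freqs=(0.30, 0.20, 0.20, 0.30),
    exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
    alpha=0.7034,
)
DEFAULT_MT_MODEL = SubstitutionModel(
    family="GTR",
    base_freqs=(0.31, 0.31, 0.13, 0.25),
    exchangeabilities=(1.0, 12.0, 1.0, 1.0, 15.0, 1.0),
    p_inv=0.4328,
    alpha=1.0995,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesTreeSpec:
    """The true species tree: topology newick with branch lengths in
    coalescent units, optional internal-branch overrides (clade -> new
    length; the clade's node ages shift rigidly) and per-branch
    substitution-rate scalers keyed by the clade below the branch."""

    taxon_labels: tuple[str, ...] = DEFAULT_TAXA
    topology: str = DEFAULT_TOPOLOGY
    internode_lengths: dict = field(default_factory=dict)
    branch_rate_scalers: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IntrogressionEvent:
    """A single pulse: at ``time`` (coalescent units before present) each
    lineage in ``recipient_branch`` reroutes to ``donor_branch`` with
    probability ``proportion``."""

    donor_branch: frozenset
    recipient_branch: frozenset
    time: float
    proportion: float

    def __post_init__(self):
        object.__setattr__(self, "donor_branch", frozenset(self.donor_branch))
        object.__setattr__(self, "recipient_branch", frozenset(self.recipient_branch))
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError(f"proportion must be in [0, 1], got {self.proportion}")
        if self.time < 0:
            raise ValueError("event time must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    n_nuclear_loci: int = 44
    nuclear_length_range: tuple[int, int] = (337, 868)
    nuclear_rate_scale: float = 0.04  # target mean pairwise divergence
    mt_partition_lengths: dict = field(
        default_factory=lambda: {k: v[0] for k, v in MT_PARTITIONS.items()}
    )
    mt_rate_scale: float = 0.185  # target molecule-wide mean divergence
    nuclear_model: SubstitutionModel = DEFAULT_NUCLEAR_MODEL
    mt_model: SubstitutionModel = DEFAULT_MT_MODEL
    introgression: Optional[IntrogressionEvent] = None
    introgression_scope: str = "mt"  # {"mt", "nuclear", "all"}
    species_spec: SpeciesTreeSpec = field(default_factory=SpeciesTreeSpec)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.nuclear_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("bad nuclear length range")
        if self.nuclear_rate_scale <= 0 or self.mt_rate_scale <= 0:
            raise ValueError("rate scales must be positive")
        if any(v <= 0 for v in self.mt_partition_lengths.values()):
            raise ValueError("mt partition lengths must be positive")
        if self.introgression_scope not in ("mt", "nuclear", "all"):
            raise ValueError("introgression_scope must be mt, nuclear or all")
        if self.n_nuclear_loci < 0:
            raise ValueError("n_nuclear_loci must be >= 0")


@dataclass
class StudyBundle:
    """Everything a run needs: the truth, one gene tree per locus (mt
    sub-partitions share the single mt gene tree), loci, and a manifest."""

    species_tree: Tree
    gene_trees: dict[str, Tree]
    loci: list[Locus]
    manifest: list[dict]

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(names) != len(set(names)):
            raise ValueError("duplicate locus names")
        if set(names) != set(self.gene_trees) or len(names) != len(self.manifest):
            raise ValueError("loci / gene_trees / manifest out of sync")
        sp = set(self.species_tree.leaf_names())
        for name, gt in self.gene_trees.items():
            if set(gt.leaf_names()) != sp:
                raise ValueError(f"gene tree {name} has wrong leaf set")

    def nuclear_loci(self) -> list[Locus]:
        return [l for l in self.loci if l.locus_class == "nuclear_noncoding"]

    def mt_loci(self) -> list[Locus]:
        return [l for l in self.loci if l.locus_class.startswith("mt_")]


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _node_ages(tree: Tree, tol: float = 1e-6) -> dict[int, float]:
    ages: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            ages[id(node)] = 0.0
            continue
        cand = []
        for child in node.children:
            if child.length is None or child.length < 0 or not math.isfinite(child.length):
                raise TreeError("species tree needs finite non-negative branch lengths")
            cand.append(ages[id(child)] + child.length)
        if max(cand) - min(cand) > tol:
            raise TreeError(
                "species tree must be ultrametric in coalescent units "
                f"(node ages disagree: {cand})"
            )
        ages[id(node)] = sum(cand) / len(cand)
    return ages


def _clades(tree: Tree) -> dict[int, frozenset]:
    out: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            out[id(node)] = frozenset([node.name])
        else:
            out[id(node)] = frozenset().union(*(out[id(c)] for c in node.children))
    return out


def build_species_tree(spec: SpeciesTreeSpec) -> Tree:
    """Validate and materialize the true species tree (supports set to 1)."""
    labels = tuple(spec.taxon_labels)
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate taxon labels in species tree spec")
    tree = tree_from_newick(spec.topology)
    if set(tree.leaf_names()) != set(labels):
        raise TreeError("topology leaves do not match taxon_labels")
    if not tree.is_binary():
        raise TreeError("species tree topology must be binary")
    _node_ages(tree)  # validates lengths + ultrametricity
    clades = _clades(tree)
    by_clade = {clades[id(n)]: n for n in tree.postorder()}
    for key, new_len in spec.internode_lengths.items():
        key = frozenset(key)
        if key not in by_clade or by_clade[key].parent is None or len(key) < 2:
            raise TreeError(f"internode override names a missing internal branch: {sorted(key)}")
        if new_len < 0 or not math.isfinite(new_len):
            raise TreeError("internode lengths must be finite and >= 0")
        node = by_clade[key]
        delta = node.length - new_len  # subtree moves up (towards present) by delta
        node.length = new_len
        for desc in _subtree_nodes(node):
            if desc is node:
                continue
            if desc.is_leaf:
                desc.length += delta
                if desc.length < 0:
                    raise TreeError("internode override would push tips below the present")
    _node_ages(tree)  # re-validate
    for key, scale in spec.branch_rate_scalers.items():
        if frozenset(key) not in by_clade:
            raise TreeError(f"rate scaler names a missing branch: {sorted(key)}")
        if scale <= 0:
            raise TreeError("rate scalers must be positive")
    for node in tree.internal_nodes():
        node.support = 1.0
    return tree


def _subtree_nodes(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def default_species_spec() -> SpeciesTreeSpec:
    return SpeciesTreeSpec()


def default_introgression_event() -> IntrogressionEvent:
    """The mito-nuclear discordance regime: the mt lineage of the
    Presbytis-like taxon is captured by the Trachypithecus-like stem
    (an ancient hybridization pulse fixing the foreign mitochondrion)."""
    donor = frozenset(["Trachypithecus_hatinhensis", "Trachypithecus_shortridgei"])
    recipient = frozenset(["Presbytis_melalophos"])
    return IntrogressionEvent(
        donor_branch=donor, recipient_branch=recipient, time=1.05, proportion=1.0
    )


# ---------------------------------------------------------------------------
# multispecies coalescent
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("node", "birth", "subs", "seg_start")

    def __init__(self, node: Node, time: float):
        self.node = node
        self.birth = time
        self.subs = 0.0
        self.seg_start = time

    def flush(self, time: float, scaler: float) -> None:
        self.subs += scaler * (time - self.seg_start)
        self.seg_start = time

    def close(self, time: float, scaler: float) -> None:
        self.flush(time, scaler)
        self.node.length = self.subs


def sample_gene_tree(
    species_tree: Tree,
    event: Optional[IntrogressionEvent] = None,
    seed: int = 0,
    rate_scalers: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tree:
    """Sample one gene tree under the multispecies coalescent.

    One lineage per species; branch lengths of the returned tree are
    rate-scaler-integrated coalescent times (plain coalescent units when no
    scalers are given).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if species_tree.n_leaves() == 1:
        return Tree(Node(species_tree.leaf_names()[0]))
    ages = _node_ages(species_tree)
    clades = _clades(species_tree)
    scalers = {frozenset(k): float(v) for k, v in (rate_scalers or {}).items()}

    def scaler(key: frozenset) -> float:
        return scalers.get(key, 1.0)

    # branch key -> (start age, end age); the branch above each node
    span: dict[frozenset, tuple[float, float]] = {}
    parent_key: dict[frozenset, frozenset] = {}
    for node in species_tree.postorder():
        key = clades[id(node)]
        top = ages[id(node.parent)] if node.parent is not None else math.inf
        span[key] = (ages[id(node)], top)
        if node.parent is not None:
            parent_key[key] = clades[id(node.parent)]

    if event is not None:
        for name, key in (("donor", event.donor_branch), ("recipient", event.recipient_branch)):
            if key not in span:
                raise TreeError(f"introgression {name} branch not in the species tree: {sorted(key)}")
            lo, hi = span[key]
            if not (lo <= event.time < hi):
                raise TreeError(
                    f"introgression {name} branch not active at time {event.time} "
                    f"(branch spans [{lo}, {hi}))"
                )

    active: dict[frozenset, list[_Lineage]] = {}
    for leaf in species_tree.leaves():
        key = clades[id(leaf)]
        active[key] = [_Lineage(Node(leaf.name), 0.0)]

    boundaries: list[tuple[float, int, object]] = []
    for node in species_tree.internal_nodes():
        boundaries.append((ages[id(node)], 1, node))
    if event is not None:
        boundaries.append((event.time, 0, event))
    boundaries.sort(key=lambda b: (b[0], b[1]))

    def coalesce_within(key: frozenset, t0: float, t1: float) -> None:
        lins = active[key]
        cur = t0
        while len(lins) >= 2:
            rate = len(lins) * (len(lins) - 1) / 2.0
            cur = cur + rng.exponential(1.0 / rate)
            if cur >= t1:
                return
            i, j = sorted(rng.choice(len(lins), size=2, replace=False))
            a, b = lins[j], lins[i]  # pop higher index first
            del lins[j], lins[i]
            parent = Node()
            for child in (b, a):
                child.close(cur, scaler(key))
                parent.add_child(child.node)
            lins.append(_Lineage(parent, cur))

    t_prev = 0.0
    for time, kind, payload in boundaries:
        for key in list(active):
            lo, _ = span[key]
            coalesce_within(key, max(t_prev, lo), time)
        if kind == 0:  # introgression pulse
            ev: IntrogressionEvent = payload
            movers = []
            for lin in list(active.get(ev.recipient_branch, [])):
                if rng.random() < ev.proportion:
                    lin.flush(time, scaler(ev.recipient_branch))
                    active[ev.recipient_branch].remove(lin)
                    movers.append(lin)
            active.setdefault(ev.donor_branch, []).extend(movers)
        else:  # speciation: children branches merge into the parent branch
            node: Node = payload
            key = clades[id(node)]
            merged: list[_Lineage] = []
            for child in node.children:
                ckey = clades[id(child)]
                for lin in active.pop(ckey, []):
                    lin.flush(time, scaler(ckey))
                    merged.append(lin)
            merged.extend(active.get(key, []))
            active[key] = merged
        t_prev = time

    root_key = clades[id(species_tree.root)]
    lins = active[root_key]
    cur = t_prev
    while len(lins) >= 2:
        rate = len(lins) * (len(lins) - 1) / 2.0
        cur = cur + rng.exponential(1.0 / rate)
        i, j = sorted(rng.choice(len(lins), size=2, replace=False))
        a, b = lins[j], lins[i]
        del lins[j], lins[i]
        parent = Node()
        for child in (b, a):
            child.close(cur, scaler(root_key))
            parent.add_child(child.node)
        lins.append(_Lineage(parent, cur))
    return Tree(lins[0].node)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(
    gene_tree: Tree, model: SubstitutionModel, length: int, seed: int = 0
) -> Alignment:
    """Evolve ``length`` independent sites down ``gene_tree`` (branch
    lengths in expected substitutions per site). Root states draw from the
    model's stationary frequencies; each site keeps one rate category
    (invariant or one of the k gamma categories) for its whole history."""
    if length <= 0:
        raise ValueError(f"alignment length must be positive, got {length}")
    rng = np.random.default_rng(seed)
    rates, weights = model.category_rates()
    cat = rng.choice(len(rates), size=length, p=weights)
    freqs = np.asarray(model.base_freqs)
    left, lam, right = model.eigen()
    states: dict[int, np.ndarray] = {
        id(gene_tree.root): rng.choice(4, size=length, p=freqs)
    }
    for node in gene_tree.preorder():
        if node.parent is None:
            continue
        if node.length is None or node.length < 0:
            raise ValueError("gene tree needs non-negative branch lengths")
        child = np.empty(length, dtype=np.int64)
        parent_states = states[id(node.parent)]
        for ci, r in enumerate(rates):
            idx = np.nonzero(cat == ci)[0]
            if idx.size == 0:
                continue
            if r == 0.0 or node.length == 0.0:
                child[idx] = parent_states[idx]
                continue
            p = (left * np.exp(lam * (node.length * r))) @ right
            p = np.clip(p, 0.0, None)
            p /= p.sum(axis=1, keepdims=True)
            cum = np.cumsum(p, axis=1)
            u = rng.random(idx.size)
            child[idx] = (u[:, None] > cum[parent_states[idx]]).sum(axis=1)
        states[id(node)] = child
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    pairs = []
    for leaf in gene_tree.leaves():
        row = alphabet[states[id(leaf)]].tobytes().decode()
        pairs.append((leaf.name, row))
    pairs.sort()
    return Alignment.from_pairs(pairs)


# ---------------------------------------------------------------------------
# calibration: coalescent units -> substitutions per site
# ---------------------------------------------------------------------------

def expected_pairwise_coal_distance(species_tree: Tree) -> float:
    """Mean over taxon pairs of the expected gene-tree path length in
    coalescent units: twice the species divergence time plus the expected
    excess of 2 (a pair coalesces ~1 unit above its species' split)."""
    ages = _node_ages(species_tree)
    clades = _clades(species_tree)
    leaves = species_tree.leaf_names()
    # MRCA age per pair via smallest containing clade
    nodes = sorted(
        (len(clades[id(n)]), ages[id(n)], clades[id(n)])
        for n in species_tree.internal_nodes()
    )
    total, count = 0.0, 0
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            for _, age, clade in nodes:
                if a in clade and b in clade:
                    total += 2.0 * age + 2.0
                    count += 1
                    break
    return total / count


def expected_divergence(model: SubstitutionModel, d: float) -> float:
    """Expected p-distance between two sequences separated by ``d``
    substitutions/site under ``model`` (mixture-averaged)."""
    rates, weights = model.category_rates()
    freqs = np.asarray(model.base_freqs)
    left, lam, right = model.eigen()
    p = 0.0
    for r, w in zip(rates, weights):
        pm = (left * np.exp(lam * (d * r))) @ right
        p += w * (1.0 - float(np.dot(freqs, np.diag(pm))))
    return p


def divergence_to_subs_scale(
    model: SubstitutionModel, target_divergence: float, mean_coal_distance: float
) -> float:
    """Substitutions/site per coalescent unit so the expected mean pairwise
    p-distance hits ``target_divergence`` on the given species tree."""
    ceiling = expected_divergence(model, 50.0)
    if target_divergence >= ceiling:
        raise ValueError(
            f"target divergence {target_divergence} unreachable "
            f"(saturation at {ceiling:.3f})"
        )
    d = brentq(lambda x: expected_divergence(model, x) - target_divergence, 1e-9, 50.0)
    return d / mean_coal_distance


# ---------------------------------------------------------------------------
# the bundle
# ---------------------------------------------------------------------------

def _scale_tree(tree: Tree, factor: float) -> Tree:
    out = tree.copy()
    for node in out.postorder():
        if node.parent is not None and node.length is not None:
            node.length *= factor
    return out


def generate_study(config: SimulationConfig) -> StudyBundle:
    """Simulate the full study bundle; identical config (seed included)
    yields a bit-for-bit identical bundle."""
    species = build_species_tree(config.species_spec)
    scalers = config.species_spec.branch_rate_scalers
    mean_coal = expected_pairwise_coal_distance(species)
    nuc_rate = divergence_to_subs_scale(
        config.nuclear_model, config.nuclear_rate_scale, mean_coal
    )
    ss = np.random.SeedSequence(config.seed)
    n = config.n_nuclear_loci
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n + 2 + len(config.mt_partition_lengths))]
    rng_len = np.random.default_rng(seeds[0])
    lo, hi = config.nuclear_length_range
    lengths = rng_len.integers(lo, hi + 1, size=n)

    nuclear_event = config.introgression if config.introgression_scope in ("nuclear", "all") else None
    mt_event = config.introgression if config.introgression_scope in ("mt", "all") else None

    gene_trees: dict[str, Tree] = {}
    loci: list[Locus] = []
    manifest: list[dict] = []
    for i in range(n):
        name = f"nuc{i + 1:02d}"
        tseed, aseed = seeds[1 + 2 * i], seeds[2 + 2 * i]
        gt = sample_gene_tree(species, event=nuclear_event, seed=tseed, rate_scalers=scalers)
        scaled = _scale_tree(gt, nuc_rate)
        aln = simulate_alignment(scaled, config.nuclear_model, int(lengths[i]), seed=aseed)
        gene_trees[name] = gt
        loci.append(Locus(name, aln, "nuclear_noncoding"))
        manifest.append(
            {
                "locus": name,
                "locus_class": "nuclear_noncoding",
                "model": config.nuclear_model.model_id,
                "length": int(lengths[i]),
                "tree_seed": tseed,
                "aln_seed": aseed,
                "subs_per_coal_unit": nuc_rate,
            }
        )

    # the mt molecule: ONE non-recombining locus, one shared gene tree
    mt_tree_seed = seeds[1 + 2 * n]
    mt_tree = sample_gene_tree(species, event=mt_event, seed=mt_tree_seed, rate_scalers=scalers)
    for j, (pname, plen) in enumerate(sorted(config.mt_partition_lengths.items())):
        rel, pclass = (
            MT_PARTITIONS[pname][1:] if pname in MT_PARTITIONS else (1.0, "mt_protein")
        )
        target = min(config.mt_rate_scale * rel, 0.70)
        mt_rate = divergence_to_subs_scale(config.mt_model, target, mean_coal)
        aseed = seeds[2 + 2 * n + j]
        scaled = _scale_tree(mt_tree, mt_rate)
        aln = simulate_alignment(scaled, config.mt_model, int(plen), seed=aseed)
        gene_trees[pname] = mt_tree
        loci.append(Locus(pname, aln, pclass))
        manifest.append(
            {
                "locus": pname,
                "locus_class": pclass,
                "model": config.mt_model.model_id,
                "length": int(plen),
                "tree_seed": mt_tree_seed,
                "aln_seed": aseed,
                "subs_per_coal_unit": mt_rate,
            }
        )
    return StudyBundle(species_tree=species, gene_trees=gene_trees, loci=loci, manifest=manifest)
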