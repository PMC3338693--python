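"""Felsenstein-pruning likelihood engine with +I/+G mixtures, branch-length
optimization, NNI hill-climbing tree search, and AIC model selection.

Site patterns are compressed once per alignment; gaps and IUPAC ambiguity
codes enter as partial likelihood 1 over their compatible states. The +I
class is a zero-rate mixture component; the mixture's mean rate is
rescaled to 1 so branch lengths remain expected substitutions per site
under the full model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .models import FAMILIES, STATES, SubstitutionModel, model_from_id
from .seqio import AMBIGUITY, Alignment
from .trees import Node, Tree, TreeError

__all__ = [
    "CompressedAlignment",
    "PruningEngine",
    "LikelihoodError",
    "ModelFitResult",
    "log_likelihood",
    "sitewise_lnL",
    "optimize_branch_lengths",
    "nni_search",
    "select_model_aic",
    "root_at_leaf",
    "DEFAULT_CANDIDATES",
    "BRANCH_MIN",
    "BRANCH_MAX",
]

BRANCH_MIN = 1e-9
BRANCH_MAX = 10.0

#: the 12-model selection ladder
DEFAULT_CANDIDATES = tuple(
    f"{fam}{suffix}"
    for fam in ("JC69", "K80", "HKY85", "GTR")
    for suffix in ("", "+I", "+G")
)


class LikelihoodError(ArithmeticError):
    """Raised when a likelihood evaluation is not finite."""


class CompressedAlignment:
    """Unique site patterns with weights and an expansion index."""

    def __init__(self, alignment: Alignment):
        self.alignment = alignment
        self.labels = alignment.labels
        mat = np.frombuffer("".join(alignment.rows).encode(), dtype="S1").reshape(
            alignment.n_taxa, alignment.n_cols
        )
        patterns, inverse, counts = np.unique(
            mat.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_taxa, n_patterns)
        self.site_to_pattern = inverse.ravel()
        self.weights = counts.astype(float)
        self.n_patterns = self.patterns.shape[1]
        self.n_sites = alignment.n_cols
        # tip conditionals, (n_patterns, 4) of 0/1 per taxon
        self._tips = {}
        for i, label in enumerate(self.labels):
            cl = np.empty((self.n_patterns, 4))
            row = self.patterns[i]
            for char in np.unique(row):
                ch = char.decode()
                vec = np.zeros(4)
                for s in AMBIGUITY[ch]:
                    vec[STATES.index(s)] = 1.0
                cl[row == char] = vec
            self._tips[label] = cl

    def tip(self, label: str) -> np.ndarray:
        return self._tips[label]


class PruningEngine:
    """lnL of trees over one compressed alignment and one model."""

    def __init__(self, data, model: SubstitutionModel):
        if isinstance(data, Alignment):
            data = CompressedAlignment(data)
        self.data: CompressedAlignment = data
        self.model = model
        self.left, self.lam, self.right = model.eigen()
        self.rates, self.cat_weights = model.category_rates()
        self.freqs = np.asarray(model.base_freqs)

    def _pmat(self, t: float, rate: float) -> np.ndarray:
        if rate == 0.0 or t == 0.0:
            return np.eye(4)
        p = (self.left * np.exp(self.lam * (t * rate))) @ self.right
        return np.clip(p, 0.0, None)

    def _site_likelihoods(self, tree: Tree) -> tuple[np.ndarray, np.ndarray]:
        """(likelihood, log_scaler) per pattern, mixed over rate categories."""
        for node in tree.postorder():
            if node.parent is not None and node.length is None:
                raise LikelihoodError("tree has unknown branch lengths")
        data = self.data
        total = np.zeros(data.n_patterns)
        logscale_out = np.zeros(data.n_patterns)
        per_cat = []
        for rate, w in zip(self.rates, self.cat_weights):
            partial: dict[int, np.ndarray] = {}
            logscale: dict[int, np.ndarray] = {}
            for node in tree.postorder():
                if node.is_leaf:
                    partial[id(node)] = data.tip(node.name)
                    logscale[id(node)] = np.zeros(data.n_patterns)
                    continue
                prod = np.ones((data.n_patterns, 4))
                ls = np.zeros(data.n_patterns)
                for child in node.children:
                    p = self._pmat(child.length, rate)
                    prod = prod * (partial[id(child)] @ p.T)
                    ls = ls + logscale[id(child)]
                mx = prod.max(axis=1)
                safe = np.where(mx > 0, mx, 1.0)
                partial[id(node)] = prod / safe[:, None]
                logscale[id(node)] = ls + np.log(safe)
            lik = partial[id(tree.root)] @ self.freqs
            per_cat.append((w, lik, logscale[id(tree.root)]))
        # combine categories on a common log scale
        ref = per_cat[0][2]
        for w, lik, ls in per_cat:
            total = total + w * lik * np.exp(ls - ref)
        return total, ref

    def lnl(self, tree: Tree) -> float:
        lik, ls = self._site_likelihoods(tree)
        if (lik <= 0).any():
            raise LikelihoodError("zero site likelihood (conflicting states on a zero-length path?)")
        value = float(np.dot(self.data.weights, np.log(lik) + ls))
        if not math.isfinite(value):
            raise LikelihoodError("non-finite log-likelihood")
        return value

    def sitewise(self, tree: Tree) -> np.ndarray:
        lik, ls = self._site_likelihoods(tree)
        if (lik <= 0).any():
            raise LikelihoodError("zero site likelihood")
        per_pattern = np.log(lik) + ls
        return per_pattern[self.data.site_to_pattern]

    # ------------------------------------------------------------ fast edges
    def branch_context(self, tree: Tree) -> dict:
        """Inside (subtree) and outside partials for every edge, per rate
        category, so the likelihood becomes a cheap 1-D function of any one
        branch length: lnL(t) = sum_pat w log sum_c w_c B' P_c(t) D."""
        data = self.data
        ctx: dict[int, list] = {}
        for rate, w in zip(self.rates, self.cat_weights):
            down: dict[int, np.ndarray] = {}
            dls: dict[int, np.ndarray] = {}
            edge_p: dict[int, np.ndarray] = {}
            for node in tree.postorder():
                if node.is_leaf:
                    down[id(node)] = data.tip(node.name)
                    dls[id(node)] = np.zeros(data.n_patterns)
                else:
                    prod = np.ones((data.n_patterns, 4))
                    ls = np.zeros(data.n_patterns)
                    for child in node.children:
                        p = self._pmat(child.length, rate)
                        edge_p[id(child)] = p
                        prod = prod * (down[id(child)] @ p.T)
                        ls = ls + dls[id(child)]
                    mx = prod.max(axis=1)
                    safe = np.where(mx > 0, mx, 1.0)
                    down[id(node)] = prod / safe[:, None]
                    dls[id(node)] = ls + np.log(safe)
            # outside partial A(u): data outside subtree(u) given the state
            # at u, prior included; B(v) = A(parent) x sibling contributions
            A: dict[int, np.ndarray] = {id(tree.root): np.tile(self.freqs, (data.n_patterns, 1))}
            als: dict[int, np.ndarray] = {id(tree.root): np.zeros(data.n_patterns)}
            B: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            for node in tree.preorder():
                if node.is_leaf:
                    continue
                contribs = {
                    id(c): down[id(c)] @ edge_p[id(c)].T for c in node.children
                }
                for child in node.children:
                    b = A[id(node)].copy()
                    bls = als[id(node)].copy()
                    for other in node.children:
                        if other is child:
                            continue
                        b = b * contribs[id(other)]
                        bls = bls + dls[id(other)]
                    mx = b.max(axis=1)
                    safe = np.where(mx > 0, mx, 1.0)
                    b = b / safe[:, None]
                    bls = bls + np.log(safe)
                    B[id(child)] = (b, bls)
                    if not child.is_leaf:
                        A[id(child)] = b @ edge_p[id(child)]
                        als[id(child)] = bls
            for node in tree.postorder():
                if node.parent is None:
                    continue
                b, bls = B[id(node)]
                ctx.setdefault(id(node), []).append(
                    (w, rate, b, down[id(node)], bls + dls[id(node)])
                )
        return ctx

    def edge_lnl(self, ctx: dict, node, t: float) -> float:
        """lnL of the tree with the branch above ``node`` set to ``t``,
        using (possibly slightly stale) cached partials."""
        cats = ctx[id(node)]
        ref = cats[0][4]
        for _, _, _, _, sc in cats:
            ref = np.maximum(ref, sc)
        total = np.zeros(self.data.n_patterns)
        for w, rate, b, d, sc in cats:
            p = self._pmat(t, rate)
            e = (b * (d @ p.T)).sum(axis=1)
            total = total + w * e * np.exp(sc - ref)
        if (total <= 0).any():
            return -np.inf
        return float(np.dot(self.data.weights, np.log(total) + ref))


def log_likelihood(tree: Tree, alignment: Alignment, model: SubstitutionModel) -> float:
    return PruningEngine(alignment, model).lnl(tree)


def sitewise_lnL(tree: Tree, alignment: Alignment, model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihoods; sums to :func:`log_likelihood`."""
    return PruningEngine(alignment, model).sitewise(tree)


# ---------------------------------------------------------------------------
# branch-length optimization
# ---------------------------------------------------------------------------

def _optimizable_edges(tree: Tree) -> list[Node]:
    """Every edge, except that a degree-2 root contributes one edge only
    (the two root-adjacent half-edges describe a single unrooted branch)."""
    nodes = [n for n in tree.postorder() if n.parent is not None]
    if len(tree.root.children) == 2:
        a, b = tree.root.children
        # fold b's half onto a once, then pin b
        if b.length and b.length > BRANCH_MIN:
            a.length = (a.length or 0.0) + b.length
            b.length = BRANCH_MIN
        nodes = [n for n in nodes if n is not b]
    return nodes


def optimize_branch_lengths(
    tree: Tree,
    alignment_or_engine,
    model: Optional[SubstitutionModel] = None,
    tol: float = 1e-6,
    max_sweeps: int = 25,
) -> tuple[Tree, float]:
    """Coordinate-wise branch-length optimization; lnL never decreases.

    Sweeps every branch with bounded scalar optimization in
    [BRANCH_MIN, BRANCH_MAX] until the sweep improvement drops below
    ``tol``. Returns (tree copy with optimized lengths, final lnL).
    """
    engine = (
        alignment_or_engine
        if isinstance(alignment_or_engine, PruningEngine)
        else PruningEngine(alignment_or_engine, model)
    )
    tree = tree.copy()
    for node in tree.postorder():
        if node.parent is not None and (node.length is None or node.length < BRANCH_MIN):
            node.length = max(BRANCH_MIN, 0.05 if node.length is None else node.length)
        if node.parent is not None:
            node.length = min(node.length, BRANCH_MAX)
    edges = _optimizable_edges(tree)
    current = engine.lnl(tree)
    for _ in range(max_sweeps):
        start = current
        current = _sweep_edges(engine, tree, edges, current)[1]
        if current - start < tol:
            break
    return tree, current


def _sweep_edges(
    engine: PruningEngine, tree: Tree, edges: Sequence[Node], current: float
) -> tuple[Tree, float]:
    """One coordinate sweep over ``edges`` using cached edge partials.

    The cached outside partials go slightly stale as earlier edges in the
    sweep move, so the sweep result is re-checked with a full evaluation
    and rolled back wholesale if it did not improve — lnL is monotone
    across sweeps by construction.
    """
    old_lengths = {id(n): n.length for n in edges}
    ctx = engine.branch_context(tree)
    for node in edges:
        here = engine.edge_lnl(ctx, node, node.length)

        def neg(t, node=node):
            return -engine.edge_lnl(ctx, node, t)

        res = minimize_scalar(
            neg,
            bounds=(BRANCH_MIN, BRANCH_MAX),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun > here:
            node.length = float(res.x)
    new = engine.lnl(tree)
    if new < current:
        for node in edges:
            node.length = old_lengths[id(node)]
        return tree, current
    return tree, new


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def root_at_leaf(tree: Tree, leaf_name: Optional[str] = None) -> Tree:
    """Canonical rooted form: a degree-2 root whose first child is the
    anchor leaf (default: lexicographically smallest label)."""
    if leaf_name is None:
        leaf_name = min(tree.leaf_names())
    for leaf in tree.leaves():
        if leaf.name == leaf_name:
            rerooted = tree.reroot_at_edge(leaf)
            # put the anchor leaf first
            rerooted.root.children.sort(key=lambda c: 0 if c.is_leaf and c.name == leaf_name else 1)
            return rerooted
    raise TreeError(f"no leaf named {leaf_name!r}")


def canonical_newick(tree: Tree) -> str:
    """Topology-only newick with sorted children; used for deterministic
    tie-breaking and topology identity."""
    t = root_at_leaf(tree)

    def key(node: Node) -> str:
        if node.is_leaf:
            return node.name
        parts = sorted(key(c) for c in node.children)
        return "(" + ",".join(parts) + ")"

    return key(t.root) + ";"


def _internal_edges(tree: Tree) -> list[Node]:
    """Child nodes of internal edges in a rooted-at-leaf tree (n-3 of them
    for a binary tree on n leaves)."""
    out = []
    for node in tree.postorder():
        if (
            not node.is_leaf
            and node.parent is not None
            and node.parent is not tree.root
        ):
            out.append(node)
    return out


def nni_neighbors(tree: Tree) -> list[Tree]:
    """All NNI rearrangements of a binary tree (rooted-at-leaf form),
    two per internal edge, in deterministic order."""
    base = root_at_leaf(tree)
    # address nodes by their path from the root so we can redo moves on copies
    def path_of(node: Node) -> tuple[int, ...]:
        path = []
        while node.parent is not None:
            path.append(node.parent.children.index(node))
            node = node.parent
        return tuple(reversed(path))

    def at(tree: Tree, path) -> Node:
        node = tree.root
        for i in path:
            node = node.children[i]
        return node

    result = []
    for v in _internal_edges(base):
        vpath = path_of(v)
        for which in (0, 1):
            cand = base.copy()
            cv = at(cand, vpath)
            cu = cv.parent
            # u's other child swaps with one child of v
            w = cu.children[1 - cu.children.index(cv)]
            c = cv.children[which]
            iu, iv = cu.children.index(w), cv.children.index(c)
            cu.children[iu], cv.children[iv] = c, w
            c.parent, w.parent = cu, cv
            result.append(cand)
    return result


def nni_search(
    start_tree: Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    max_rounds: int = 20,
    tol: float = 1e-6,
) -> tuple[Tree, float]:
    """NNI hill-climbing under likelihood.

    Candidate moves are scored with the central branch re-optimized (all
    other lengths held); the best strictly improving move is accepted and
    followed by a full branch-length sweep. Deterministic: candidates are
    enumerated in a fixed order and exact ties broken by smallest canonical
    newick. Stops at a local optimum or ``max_rounds``.
    """
    engine = PruningEngine(alignment, model)
    tree, current = optimize_branch_lengths(start_tree, engine, tol=tol)
    for _ in range(max_rounds):
        best: Optional[tuple[float, str, Tree]] = None
        for cand in nni_neighbors(tree):
            cand, lnl = _optimize_recent_edges(cand, engine)
            key = (lnl, canonical_newick(cand))
            if best is None or lnl > best[0] + 1e-12 or (
                abs(lnl - best[0]) <= 1e-12 and key[1] < best[1]
            ):
                best = (lnl, key[1], cand)
        if best is None or best[0] <= current + tol:
            break
        tree, current = optimize_branch_lengths(best[2], engine, tol=tol)
    return tree, current


def _optimize_recent_edges(tree: Tree, engine: PruningEngine) -> tuple[Tree, float]:
    """Cheap scoring of an NNI candidate: one sweep over internal edges."""
    return _sweep_edges(engine, tree, _internal_edges(tree), engine.lnl(tree))


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFitResult:
    """One fitted candidate: AIC = 2 k - 2 lnL with k counting the model's
    free parameters plus the shared branch lengths."""

    model_id: str
    lnL: float
    n_params: int
    aic: float
    model: SubstitutionModel
    tree: Tree

    def __post_init__(self):
        if abs(self.aic - (2 * self.n_params - 2 * self.lnL)) > 1e-6:
            raise ValueError("AIC inconsistent with lnL and n_params")


def empirical_base_freqs(alignment: Alignment) -> tuple[float, ...]:
    counts = np.zeros(4)
    for row in alignment.rows:
        for i, s in enumerate(STATES):
            counts[i] += row.count(s)
    if counts.sum() == 0:
        return (0.25,) * 4
    freqs = (counts + 1.0) / (counts.sum() + 4.0)  # tiny pseudocount
    return tuple(freqs / freqs.sum())


def _pack(model: SubstitutionModel) -> tuple[np.ndarray, list[str]]:
    spec = FAMILIES[model.family]
    x, names = [], []
    ex = model.exchangeabilities
    if model.family in ("K80", "HKY85"):
        x.append(math.log(ex[1])); names.append("kappa")
    elif model.family == "TN93":
        x.extend([math.log(ex[1]), math.log(ex[4])]); names.extend(["k1", "k2"])
    elif model.family == "GTR":
        for i in (0, 1, 2, 3, 4):  # GT (index 5) anchors at 1
            x.append(math.log(ex[i] / ex[5])); names.append(f"ex{i}")
    if spec["free_freqs"]:
        f = np.asarray(model.base_freqs)
        x.extend(np.log(f[:3] / f[3])); names.extend(["fA", "fC", "fG"])
    if model.p_inv > 0:
        p = min(max(model.p_inv, 1e-4), 0.999)
        x.append(math.log(p / (1 - p))); names.append("p_inv")
    if model.alpha is not None:
        x.append(math.log(model.alpha)); names.append("alpha")
    return np.array(x), names


def _unpack(x: np.ndarray, names: list[str], template: SubstitutionModel) -> SubstitutionModel:
    # clamp transformed coordinates so exp/logistic stay finite
    vals = {k: min(max(float(v), -30.0), 30.0) for k, v in zip(names, x)}
    ex = list(template.exchangeabilities)
    if "kappa" in vals:
        ex = [1.0, math.exp(vals["kappa"]), 1.0, 1.0, math.exp(vals["kappa"]), 1.0]
    if "k1" in vals:
        ex = [1.0, math.exp(vals["k1"]), 1.0, 1.0, math.exp(vals["k2"]), 1.0]
    if "ex0" in vals:
        ex = [math.exp(vals[f"ex{i}"]) for i in range(5)] + [1.0]
    ex = [min(max(e, 1e-6), 1e6) for e in ex]
    freqs = template.base_freqs
    if "fA" in vals:
        raw = np.exp(np.array([vals["fA"], vals["fC"], vals["fG"], 0.0]))
        freqs = tuple(raw / raw.sum())
    p_inv = template.p_inv
    if "p_inv" in vals:
        p_inv = 1.0 / (1.0 + math.exp(-vals["p_inv"]))
        p_inv = min(p_inv, 0.99)
    alpha = template.alpha
    if "alpha" in vals:
        alpha = min(max(math.exp(vals["alpha"]), 1e-3), 1e3)
    return template.with_params(
        exchangeabilities=tuple(ex), base_freqs=freqs, p_inv=p_inv, alpha=alpha
    )


def fit_model(
    alignment: Alignment,
    base_topology: Tree,
    model_id: str,
    rounds: int = 2,
) -> ModelFitResult:
    """Optimize one candidate's free parameters and branch lengths on a
    fixed topology (alternating parameter / branch-length optimization)."""
    data = CompressedAlignment(alignment)
    freqs = (
        empirical_base_freqs(alignment)
        if FAMILIES[model_id.split("+")[0]]["free_freqs"]
        else (0.25,) * 4
    )
    model = model_from_id(model_id, base_freqs=freqs, kappa=2.0, p_inv=0.01, alpha=0.5)
    tree = base_topology.copy()
    # branch lengths only need AIC-scale (~0.1 lnL) precision here
    sweep_tol = 1e-3
    tree, lnl = optimize_branch_lengths(tree, PruningEngine(data, model), tol=sweep_tol)
    x, names = _pack(model)
    for _ in range(rounds):
        before = lnl
        if len(names):

            def neg(xv):
                try:
                    m = _unpack(xv, names, model)
                    return -PruningEngine(data, m).lnl(tree)
                except (LikelihoodError, ValueError):
                    return np.inf

            res = minimize(
                neg, x, method="Nelder-Mead",
                options={"maxiter": 60 * max(1, len(names)), "fatol": 1e-3, "xatol": 1e-3},
            )
            if -res.fun > lnl:
                x = res.x
                model = _unpack(x, names, model)
        tree, lnl = optimize_branch_lengths(
            tree, PruningEngine(data, model), tol=sweep_tol
        )
        if lnl - before < 0.05:  # joint optimum reached at AIC-relevant scale
            break
    n_branches = sum(1 for n in tree.postorder() if n.parent is not None)
    if len(tree.root.children) == 2:
        n_branches -= 1  # degree-2 root: two half-edges, one unrooted branch
    k = model.n_free_params + n_branches
    return ModelFitResult(
        model_id=model_id, lnL=lnl, n_params=k, aic=2 * k - 2 * lnl,
        model=model, tree=tree,
    )


def select_model_aic(
    alignment: Alignment,
    base_topology: Tree,
    candidate_set: Sequence[str] = DEFAULT_CANDIDATES,
) -> list[ModelFitResult]:
    """Fit each candidate on the fixed base topology; sorted by AIC
    ascending (ties: fewer parameters, then model id)."""
    if not candidate_set:
        raise ValueError("candidate set must be nonempty")
    fits = [fit_model(alignment, base_topology, mid) for mid in candidate_set]
    fits.sort(key=lambda r: (r.aic, r.n_params, r.model_id))
    return fits
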