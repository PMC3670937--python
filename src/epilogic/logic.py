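"""Logic regression for case-control SNP data.

A logic-regression model predicts disease status from Boolean combinations
("logic trees") of binary genotype covariates:

    logit P(case) = b0 + sum_i b_i L_i(X)

where each L_i is a rooted binary tree whose internal nodes are AND/OR and
whose leaves are binary covariates or their complements.  Each SNP yields
two covariates, a dominant carrier indicator (dosage >= 1) and a recessive
homozygote indicator (dosage == 2), both against the minor allele.

Tree space is searched by simulated annealing with Metropolis acceptance on
the binomial deviance of the refitted model; model size (number of trees,
total leaves) is chosen by stratified k-fold cross-validation on held-out
deviance, and significance of the selected model is assessed by permuting
the case-control labels and re-running the search at the selected size.

Scoring exploits the fact that with t trees the likelihood depends on the
data only through the 2^t cells of the cross-classification of tree outputs,
so each candidate is refit by weighted IRLS on at most 2^t aggregated rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import MISSING, CohortDataset

# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

AND, OR = "AND", "OR"


@dataclass
class Leaf:
    index: int          # column into the binary covariate matrix
    negate: bool = False

    def copy(self) -> "Leaf":
        return Leaf(self.index, self.negate)


@dataclass
class Node:
    op: str             # AND | OR
    left: "Node | Leaf"
    right: "Node | Leaf"

    def copy(self) -> "Node":
        return Node(self.op, self.left.copy(), self.right.copy())


@dataclass
class LogicTree:
    """A Boolean expression over binary covariates as a rooted binary tree."""

    root: Node | Leaf

    def copy(self) -> "LogicTree":
        return LogicTree(self.root.copy())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in _iter_leaves(self.root))

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Per-subject Boolean output on covariate matrix X (n x p, 0/1)."""
        return _eval_node(self.root, np.asarray(X, dtype=bool))

    def to_string(self, names: list[str] | None = None) -> str:
        return _node_str(self.root, names)


def _iter_leaves(node):
    if isinstance(node, Leaf):
        yield node
    else:
        yield from _iter_leaves(node.left)
        yield from _iter_leaves(node.right)


def _iter_internal(node):
    if isinstance(node, Node):
        yield node
        yield from _iter_internal(node.left)
        yield from _iter_internal(node.right)


def _eval_node(node, X: np.ndarray) -> np.ndarray:
    if isinstance(node, Leaf):
        col = X[:, node.index]
        return ~col if node.negate else col
    l = _eval_node(node.left, X)
    r = _eval_node(node.right, X)
    return (l & r) if node.op == AND else (l | r)


def _node_str(node, names) -> str:
    if isinstance(node, Leaf):
        name = names[node.index] if names else f"x{node.index}"
        return f"NOT({name})" if node.negate else name
    return f"{node.op}({_node_str(node.left, names)}, {_node_str(node.right, names)})"


def evaluate_tree(tree: LogicTree, covariates: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`LogicTree.evaluate`."""
    return tree.evaluate(covariates)


def parse_tree(text: str, names: list[str]) -> LogicTree:
    """Parse the prefix serialization, e.g. ``AND(OR(rs1_dom, rs2_rec), NOT(rs3_dom))``."""
    name_idx = {n: i for i, n in enumerate(names)}
    pos = 0

    def skip_ws():
        nonlocal pos
        while pos < len(text) and text[pos] in " \t":
            pos += 1

    def parse() -> Node | Leaf:
        nonlocal pos
        skip_ws()
        start = pos
        while pos < len(text) and text[pos] not in "(),":
            pos += 1
        token = text[start:pos].strip()
        if pos < len(text) and text[pos] == "(":
            pos += 1  # consume '('
            if token in (AND, OR):
                left = parse()
                skip_ws()
                if text[pos] != ",":
                    raise ValueError(f"expected ',' at position {pos} in {text!r}")
                pos += 1
                right = parse()
                skip_ws()
                if text[pos] != ")":
                    raise ValueError(f"expected ')' at position {pos} in {text!r}")
                pos += 1
                return Node(token, left, right)
            if token == "NOT":
                inner = parse()
                skip_ws()
                if text[pos] != ")":
                    raise ValueError(f"expected ')' at position {pos} in {text!r}")
                pos += 1
                if not isinstance(inner, Leaf):
                    raise ValueError("NOT() applies to leaves only")
                return Leaf(inner.index, not inner.negate)
            raise ValueError(f"unknown operator {token!r}")
        if token not in name_idx:
            raise ValueError(f"unknown covariate {token!r}")
        return Leaf(name_idx[token])

    root = parse()
    skip_ws()
    if pos != len(text):
        raise ValueError(f"trailing input at position {pos} in {text!r}")
    return LogicTree(root)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

@dataclass
class BinaryCovariate:
    snp_id: str
    coding: str          # "dominant" | "recessive"
    values: np.ndarray   # 0/1 per subject

    @property
    def name(self) -> str:
        return f"{self.snp_id}_{'dom' if self.coding == 'dominant' else 'rec'}"


def binarize_genotypes(data: CohortDataset) -> list[BinaryCovariate]:
    """Recode each SNP into dominant and recessive minor-allele indicators.

    Dominant: 1 iff dosage >= 1 (carrier); recessive: 1 iff dosage == 2
    (homozygous minor), so recessive implies dominant for every subject.
    Requires a complete-case dataset (apply ``complete_case_filter`` first).
    """
    if (data.genotypes == MISSING).any():
        raise ValueError(
            "missing genotypes present; apply complete_case_filter before binarizing"
        )
    out: list[BinaryCovariate] = []
    for j, snp in enumerate(data.snps):
        d = data.genotypes[:, j]
        out.append(BinaryCovariate(snp.snp_id, "dominant", (d >= 1).astype(np.uint8)))
        out.append(BinaryCovariate(snp.snp_id, "recessive", (d == 2).astype(np.uint8)))
    return out


def covariate_matrix(covariates: list[BinaryCovariate]) -> tuple[np.ndarray, list[str]]:
    """Stack BinaryCovariates into an (n, p) uint8 matrix plus column names."""
    X = np.column_stack([c.values for c in covariates]).astype(np.uint8)
    return X, [c.name for c in covariates]


# ---------------------------------------------------------------------------
# Model and scoring
# ---------------------------------------------------------------------------

@dataclass
class LogicModel:
    """Fitted logic-regression model: intercept + coefficients over trees."""

    intercept: float
    coefficients: np.ndarray
    trees: list[LogicTree]
    score: float                  # binomial deviance of the refitted model
    converged: bool = True
    flagged: str = ""

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def total_leaves(self) -> int:
        return sum(t.n_leaves for t in self.trees)

    def tree_outputs(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([t.evaluate(X) for t in self.trees])

    def predict_logit(self, X: np.ndarray) -> np.ndarray:
        L = self.tree_outputs(X).astype(float)
        return self.intercept + L @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.predict_logit(X)))

    def deviance_on(self, X: np.ndarray, y: np.ndarray) -> float:
        """Held-out binomial deviance with the already-fitted coefficients."""
        eta = self.predict_logit(X)
        y = np.asarray(y, dtype=float)
        return float(2.0 * (np.logaddexp(0.0, eta) - y * eta).sum())

    def to_string(self, names: list[str] | None = None) -> str:
        parts = [f"{self.intercept:+.4f}"]
        for b, t in zip(self.coefficients, self.trees):
            parts.append(f"{b:+.4f} * {t.to_string(names)}")
        return " ".join(parts)


def _aggregate_cells(outs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse subjects into the 2^t cells of the tree-output cross-tab.

    Returns (design, k, n): unique 0/1 design rows with intercept, case
    counts and totals per occupied cell.
    """
    t = outs.shape[1]
    code = np.zeros(outs.shape[0], dtype=np.int64)
    for j in range(t):
        code |= outs[:, j].astype(np.int64) << j
    n_cells = 1 << t
    tot = np.bincount(code, minlength=n_cells).astype(float)
    k = np.bincount(code, weights=y, minlength=n_cells)
    occ = tot > 0
    cells = np.nonzero(occ)[0]
    design = np.empty((cells.size, t + 1))
    design[:, 0] = 1.0
    for j in range(t):
        design[:, j + 1] = (cells >> j) & 1
    return design, k[occ], tot[occ]


def _binom_deviance(eta: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    # -2 sum [k log p + (n-k) log(1-p)] without the binomial coefficient,
    # i.e. identical to the subject-level Bernoulli deviance
    return float(2.0 * ((n * np.logaddexp(0.0, eta)) - k * eta).sum())


def _irls_binomial(design: np.ndarray, k: np.ndarray, n: np.ndarray,
                   max_iter: int = 30, cap: float = 30.0) -> tuple[np.ndarray, float, bool]:
    """Weighted IRLS on aggregated binomial rows; returns (beta, deviance, ok)."""
    ncols = design.shape[1]
    if design.shape[0] == ncols:
        # saturated model: cell probabilities are k/n, coefficients by solve
        p = np.clip(k / n, 1e-12, 1 - 1e-12)
        eta = np.clip(np.log(p / (1 - p)), -cap, cap)
        dev = -2.0 * (k * np.log(p) + (n - k) * np.log1p(-p))
        try:
            beta = np.linalg.solve(design, eta)
            return beta, float(dev.sum()), True
        except np.linalg.LinAlgError:
            pass
    beta = np.zeros(ncols)
    ktot, ntot = k.sum(), n.sum()
    beta[0] = math.log((ktot + 0.5) / (ntot - ktot + 0.5))
    dev = _binom_deviance(design @ beta, k, n)
    ok = True
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = design.T @ (k - n * mu)
        if np.max(np.abs(score)) < 1e-9:
            break
        w = n * mu * (1.0 - mu)
        info = design.T @ (design * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            ok = False
            break
        new = beta + step
        new_dev = _binom_deviance(design @ new, k, n)
        h = 0
        while new_dev > dev + 1e-10 and h < 10:
            step *= 0.5
            new = beta + step
            new_dev = _binom_deviance(design @ new, k, n)
            h += 1
        beta = np.clip(new, -cap, cap)
        if np.any(np.abs(new) >= cap):
            dev = _binom_deviance(design @ beta, k, n)
            break
        if abs(dev - new_dev) < 1e-12 * (abs(dev) + 1.0):
            dev = new_dev
            break
        dev = new_dev
    return beta, _binom_deviance(design @ beta, k, n), ok


def _prepare_cells(trees: list[LogicTree], X: np.ndarray, y: np.ndarray):
    """Tree outputs, usable columns, and the aggregated binomial cells.

    Constant or duplicate tree-output columns would make the cell design
    singular, so they are dropped (flagged); the deviance of the reduced
    model is still well-defined.
    """
    outs = np.column_stack([t.evaluate(X) for t in trees]).astype(np.uint8)
    t = outs.shape[1]
    keep: list[int] = []
    seen: dict[bytes, int] = {}
    flagged = ""
    for j in range(t):
        col = outs[:, j]
        if not col.any() or col.all():
            flagged = "constant tree output dropped"
            continue
        key = np.packbits(col).tobytes()
        if key in seen:
            flagged = "duplicate tree output dropped"
            continue
        seen[key] = j
        keep.append(j)
    cells = _aggregate_cells(outs[:, keep], y) if keep else None
    return outs, keep, flagged, cells


def _score_trees(trees: list[LogicTree], X: np.ndarray, y: np.ndarray,
                 cache: dict | None = None) -> float:
    """Deviance of the refitted model; optionally cached on the cell counts.

    The binomial deviance depends on the data only through the per-cell case
    and total counts, so candidates revisited during annealing are free.
    """
    _, keep, _, cells = _prepare_cells(trees, X, y)
    if cells is None:
        return null_deviance(y)
    design, k, n = cells
    if cache is None:
        return _irls_binomial(design, k, n)[1]
    # the occupied-cell design pattern must be in the key: identical (k, n)
    # vectors over different cell subsets are different models
    key = (design.shape, design.tobytes(), k.tobytes(), n.tobytes())
    dev = cache.get(key)
    if dev is None:
        dev = _irls_binomial(design, k, n)[1]
        cache[key] = dev
    return dev


def _fit_trees(trees: list[LogicTree], X: np.ndarray, y: np.ndarray) -> LogicModel:
    """Refit intercept and per-tree coefficients; score = binomial deviance."""
    y = np.asarray(y, dtype=float)
    outs, keep, flagged, cells = _prepare_cells(trees, X, y)
    t = outs.shape[1]
    if cells is not None:
        design, k, n = cells
        beta, dev, ok = _irls_binomial(design, k, n)
    else:
        p = y.mean()
        beta = np.array([math.log(p / (1 - p))]) if 0 < p < 1 else np.array([0.0])
        dev = _binom_deviance(np.full(1, beta[0]), np.array([y.sum()]), np.array([float(y.size)]))
        ok = True
    coefs = np.zeros(t)
    for pos, j in enumerate(keep):
        coefs[j] = beta[pos + 1]
    return LogicModel(intercept=float(beta[0]), coefficients=coefs,
                      trees=trees, score=dev, converged=ok, flagged=flagged)


def model_score(trees: list[LogicTree] | LogicModel, covariates: np.ndarray,
                y: np.ndarray) -> float:
    """Deviance of the logistic model on the tree outputs, coefficients refit."""
    if isinstance(trees, LogicModel):
        trees = trees.trees
    return _fit_trees(trees, covariates, y).score


def null_deviance(y: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    k, n = y.sum(), float(y.size)
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return float(-2.0 * (k * math.log(p) + (n - k) * math.log(1 - p)))


# ---------------------------------------------------------------------------
# Move set
# ---------------------------------------------------------------------------

def _enumerate_moves(trees: list[LogicTree], max_total_leaves: int,
                     n_covariates: int) -> list[tuple]:
    """All admissible (move_type, tree_index, site_index) triples.

    Move types: alternate-leaf, toggle-complement, alternate-operator,
    split-leaf, delete-leaf, grow-branch, prune-branch.  The tree count is
    fixed: a single-leaf tree admits neither delete-leaf nor prune-branch.
    """
    total = sum(t.n_leaves for t in trees)
    room = total < max_total_leaves
    moves: list[tuple] = []
    for ti, tree in enumerate(trees):
        leaves = list(_iter_leaves(tree.root))
        internals = list(_iter_internal(tree.root))
        for li in range(len(leaves)):
            if n_covariates > 1:
                moves.append(("alternate_leaf", ti, li))
            moves.append(("toggle_complement", ti, li))
            if room:
                moves.append(("split_leaf", ti, li))
            if len(leaves) > 1:
                moves.append(("delete_leaf", ti, li))
        for ni in range(len(internals)):
            moves.append(("alternate_operator", ti, ni))
            moves.append(("prune_branch", ti, ni))
            if room:
                moves.append(("grow_branch", ti, ni))
    return moves


def _replace_child(tree: LogicTree, old, new) -> None:
    """Replace node ``old`` (by identity) with ``new`` inside ``tree``."""
    if tree.root is old:
        tree.root = new
        return
    for node in _iter_internal(tree.root):
        if node.left is old:
            node.left = new
            return
        if node.right is old:
            node.right = new
            return
    raise RuntimeError("node not found in tree")


def _apply_move(trees: list[LogicTree], move: tuple, rng: np.random.Generator,
                n_covariates: int) -> list[LogicTree]:
    kind, ti, si = move
    new_trees = [t.copy() if i == ti else t for i, t in enumerate(trees)]
    tree = new_trees[ti]
    leaves = list(_iter_leaves(tree.root))
    internals = list(_iter_internal(tree.root))
    if kind == "alternate_leaf":
        leaf = leaves[si]
        choices = [c for c in range(n_covariates) if c != leaf.index]
        leaf.index = int(rng.choice(choices))
    elif kind == "toggle_complement":
        leaves[si].negate = not leaves[si].negate
    elif kind == "alternate_operator":
        node = internals[si]
        node.op = OR if node.op == AND else AND
    elif kind == "split_leaf":
        leaf = leaves[si]
        new_leaf = Leaf(int(rng.integers(n_covariates)), bool(rng.integers(2)))
        _replace_child(tree, leaf, Node(AND if rng.integers(2) else OR, leaf, new_leaf))
    elif kind == "delete_leaf":
        leaf = leaves[si]
        parent = next(n for n in internals if n.left is leaf or n.right is leaf)
        sibling = parent.right if parent.left is leaf else parent.left
        _replace_child(tree, parent, sibling)
    elif kind == "grow_branch":
        node = internals[si]
        new_leaf = Leaf(int(rng.integers(n_covariates)), bool(rng.integers(2)))
        _replace_child(tree, node, Node(AND if rng.integers(2) else OR, node, new_leaf))
    elif kind == "prune_branch":
        node = internals[si]
        child = node.left if rng.integers(2) else node.right
        _replace_child(tree, node, child)
    else:  # pragma: no cover
        raise ValueError(f"unknown move {kind}")
    return new_trees


def propose_move(trees: list[LogicTree], rng: np.random.Generator,
                 max_total_leaves: int, n_covariates: int) -> tuple[list[LogicTree], bool]:
    """One uniformly chosen admissible move; (input, False) when none exists."""
    moves = _enumerate_moves(trees, max_total_leaves, n_covariates)
    if not moves:
        return trees, False
    move = moves[int(rng.integers(len(moves)))]
    return _apply_move(trees, move, rng, n_covariates), True


def _neighborhood(trees: list[LogicTree], max_total_leaves: int, n_covariates: int):
    """Every distinct one-move neighbor, enumerated deterministically.

    Unlike :func:`propose_move` (which draws the randomized parts of a move),
    this expands each move type over all its concrete realizations — every
    replacement leaf/sign, both operators for splits and grows, both children
    for prunes — for use in greedy descent.
    """
    total = sum(t.n_leaves for t in trees)
    room = total < max_total_leaves
    signed = [(c, neg) for c in range(n_covariates) for neg in (False, True)]
    for ti, tree in enumerate(trees):
        leaves = list(_iter_leaves(tree.root))
        internals = list(_iter_internal(tree.root))

        def emit(mutate):
            new = tree.copy()
            mutate(new)
            out = list(trees)
            out[ti] = new
            return out

        for li, leaf in enumerate(leaves):
            for c, neg in signed:
                if (c, neg) != (leaf.index, leaf.negate):
                    yield emit(lambda t, li=li, c=c, neg=neg: _set_leaf(t, li, c, neg))
            if room:
                for op in (AND, OR):
                    for c, neg in signed:
                        yield emit(lambda t, li=li, op=op, c=c, neg=neg:
                                   _split_at(t, li, op, c, neg))
            if len(leaves) > 1:
                yield emit(lambda t, li=li: _delete_at(t, li))
        for ni in range(len(internals)):
            yield emit(lambda t, ni=ni: _flip_op(t, ni))
            for side in (0, 1):
                yield emit(lambda t, ni=ni, side=side: _prune_at(t, ni, side))


def _set_leaf(tree: LogicTree, li: int, c: int, neg: bool) -> None:
    leaf = list(_iter_leaves(tree.root))[li]
    leaf.index, leaf.negate = c, neg


def _split_at(tree: LogicTree, li: int, op: str, c: int, neg: bool) -> None:
    leaf = list(_iter_leaves(tree.root))[li]
    _replace_child(tree, leaf, Node(op, leaf, Leaf(c, neg)))


def _delete_at(tree: LogicTree, li: int) -> None:
    leaf = list(_iter_leaves(tree.root))[li]
    parent = next(n for n in _iter_internal(tree.root)
                  if n.left is leaf or n.right is leaf)
    sibling = parent.right if parent.left is leaf else parent.left
    _replace_child(tree, parent, sibling)


def _flip_op(tree: LogicTree, ni: int) -> None:
    node = list(_iter_internal(tree.root))[ni]
    node.op = OR if node.op == AND else AND


def _prune_at(tree: LogicTree, ni: int, side: int) -> None:
    node = list(_iter_internal(tree.root))[ni]
    _replace_child(tree, node, node.right if side else node.left)


def greedy_polish(trees: list[LogicTree], X: np.ndarray, y: np.ndarray,
                  max_total_leaves: int, cache: dict | None = None,
                  max_passes: int = 20) -> tuple[list[LogicTree], float]:
    """Steepest-descent over the full one-move neighborhood until no move improves."""
    cache = {} if cache is None else cache
    n_cov = X.shape[1]
    cur = _score_trees(trees, X, y, cache)
    for _ in range(max_passes):
        best_cand, best_s = None, cur
        for cand in _neighborhood(trees, max_total_leaves, n_cov):
            s = _score_trees(cand, X, y, cache)
            if s < best_s - 1e-9:
                best_cand, best_s = cand, s
        if best_cand is None:
            break
        trees, cur = best_cand, best_s
    return trees, cur


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the tree search.

    ``start_temp=None`` auto-tunes the initial temperature so that roughly
    90% of score-worsening moves are accepted at the start.  The default end
    temperature of 1.0 deviance unit keeps small-barrier basin hops alive to
    the end of the chain: the returned model is the best ever visited (then
    greedily polished), so a warm finish only improves exploration — a
    near-zero end temperature freezes the chain in whichever basin it
    occupies once typical score changes exceed the temperature.
    """

    start_temp: float | None = None
    end_temp: float = 1.0
    n_iterations: int = 50_000

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.end_temp <= 0:
            raise ValueError("end_temp must be positive")
        if self.start_temp is not None and self.start_temp <= self.end_temp:
            raise ValueError("start_temp must exceed end_temp")


def _initial_trees(n_trees: int, n_covariates: int, rng: np.random.Generator) -> list[LogicTree]:
    idx = rng.choice(n_covariates, size=min(n_trees, n_covariates), replace=False)
    idx = np.resize(idx, n_trees)
    return [LogicTree(Leaf(int(i))) for i in idx]


def _autotune_temp(trees, X, y, rng, max_total_leaves, n_cov, cache, n_probe=60) -> float:
    cur = _score_trees(trees, X, y, cache)
    deltas = []
    for _ in range(n_probe):
        cand, ok = propose_move(trees, rng, max_total_leaves, n_cov)
        if not ok:
            break
        d = _score_trees(cand, X, y, cache) - cur
        if d > 0:
            deltas.append(d)
    if not deltas:
        return 1.0
    return float(np.mean(deltas) / math.log(1 / 0.9))


def anneal_fit(
    covariates: np.ndarray,
    y: np.ndarray,
    n_trees: int = 2,
    max_total_leaves: int = 8,
    schedule: AnnealSchedule | None = None,
    seed: int | np.random.Generator | None = None,
    polish: bool = True,
) -> LogicModel:
    """Search logic-tree space by simulated annealing on model deviance.

    Metropolis acceptance: a move is accepted when its deviance change
    Delta <= 0, otherwise with probability exp(-Delta / T) under geometric
    cooling.  Returns the best-ever model (coefficients refitted), fully
    reproducible given the seed.  With ``polish`` (default) the best-ever
    model is refined by deterministic steepest descent over the full one-move
    neighborhood, which cheaply repairs near-misses of the stochastic search.
    """
    X = np.ascontiguousarray(covariates, dtype=np.uint8)
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one covariate")
    if y.min() == y.max():
        raise ValueError("need both cases and controls")
    if n_trees < 1 or max_total_leaves < n_trees:
        raise ValueError("invalid model size constraints")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sched = schedule or AnnealSchedule()
    n_cov = X.shape[1]

    cache: dict = {}
    trees = _initial_trees(n_trees, n_cov, rng)
    cur_score = _score_trees(trees, X, y, cache)
    best_trees, best_score = trees, cur_score
    if sched.n_iterations == 0:
        return _fit_trees(best_trees, X, y)

    t0 = sched.start_temp if sched.start_temp is not None else max(
        _autotune_temp(trees, X, y, rng, max_total_leaves, n_cov, cache), 2 * sched.end_temp
    )
    t1 = sched.end_temp
    ratio = (t1 / t0) ** (1.0 / max(sched.n_iterations - 1, 1))
    temp = t0
    for _ in range(sched.n_iterations):
        cand, ok = propose_move(trees, rng, max_total_leaves, n_cov)
        if ok:
            cand_score = _score_trees(cand, X, y, cache)
            delta = cand_score - cur_score
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                trees, cur_score = cand, cand_score
                if cur_score < best_score - 1e-12:
                    best_trees, best_score = trees, cur_score
        temp *= ratio
    if polish:
        best_trees, best_score = greedy_polish(best_trees, X, y, max_total_leaves, cache)
    return _fit_trees(best_trees, X, y)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def _enumerate_trees(n_covariates: int, max_leaves: int):
    """Yield every tree with up to ``max_leaves`` (<= 3) leaves.

    Left-nested shapes with ordered operands cover all trees up to operand
    commutativity; the search space must stay below 10^6 candidates.
    """
    if max_leaves > 3:
        raise ValueError("exhaustive enumeration supports at most 3 leaves")
    p = n_covariates
    space = 2 * p + 4 * (2 * p) ** 2 + 8 * (2 * p) ** 3
    if space > 1_000_000:
        raise ValueError(f"search space too large ({space} candidates)")
    leaves = [Leaf(i, neg) for i in range(p) for neg in (False, True)]
    for lf in leaves:
        yield LogicTree(lf.copy())
    if max_leaves >= 2:
        for op in (AND, OR):
            for a in leaves:
                for b in leaves:
                    yield LogicTree(Node(op, a.copy(), b.copy()))
    if max_leaves >= 3:
        for op1 in (AND, OR):
            for op2 in (AND, OR):
                for a in leaves:
                    for b in leaves:
                        for c in leaves:
                            yield LogicTree(Node(op1, Node(op2, a.copy(), b.copy()), c.copy()))


def exhaustive_fit(covariates: np.ndarray, y: np.ndarray,
                   n_trees: int = 1, max_total_leaves: int = 3) -> LogicModel:
    """Global minimum-deviance single-tree model by full enumeration.

    Serves as the independent oracle for the annealing search on small
    instances; restricted to one tree and at most three leaves.
    """
    if n_trees != 1:
        raise ValueError("exhaustive_fit supports a single tree only")
    X = np.ascontiguousarray(covariates, dtype=np.uint8)
    y = np.asarray(y, dtype=float)
    best: LogicModel | None = None
    seen: dict[bytes, float] = {}
    for tree in _enumerate_trees(X.shape[1], max_total_leaves):
        out = tree.evaluate(X)
        key = np.packbits(out).tobytes()
        if key in seen:
            continue  # Boolean-equivalent on this dataset; same score
        model = _fit_trees([tree], X, y)
        seen[key] = model.score
        if best is None or model.score < best.score - 1e-12:
            best = model
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Cross-validation and permutation inference
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    grid: dict[tuple[int, int], float]          # (n_trees, leaves) -> mean held-out deviance
    selected: tuple[int, int]
    grid_se: dict[tuple[int, int], float] = field(default_factory=dict)
    fold_assignments: np.ndarray = field(repr=False, default=None)


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold ids preserving case/control proportions (round-robin within class)."""
    y = np.asarray(y)
    n = y.size
    if k < 2 or k > n:
        raise ValueError("k must be in [2, n]")
    folds = np.empty(n, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        folds[idx] = np.arange(idx.size) % k
    return folds


def cross_validate(
    covariates: np.ndarray,
    y: np.ndarray,
    tree_range=(1, 2),
    leaf_range=(1, 2, 3, 4, 5, 6, 7, 8),
    k: int = 10,
    seed: int | np.random.Generator | None = None,
    schedule: AnnealSchedule | None = None,
    one_se_rule: bool = True,
) -> CVResult:
    """Select (n_trees, max_total_leaves) by mean held-out deviance.

    Folds are stratified by case status.  For every grid cell with
    leaves >= trees, the annealing search runs on each training split and the
    held-out deviance uses the training-fitted coefficients.

    With ``one_se_rule`` (default) the selected size is the most parsimonious
    cell (fewest leaves, then fewest trees) whose mean held-out deviance lies
    within one standard error of the best cell — cells statistically
    indistinguishable from the minimum count as ties, and ties break toward
    the smaller model.  ``one_se_rule=False`` selects the exact minimizer
    (ties still break toward fewer leaves, then fewer trees).
    """
    X = np.ascontiguousarray(covariates, dtype=np.uint8)
    y = np.asarray(y, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = stratified_folds(y, k, rng)
    grid: dict[tuple[int, int], float] = {}
    grid_se: dict[tuple[int, int], float] = {}
    for t in sorted(tree_range):
        for L in sorted(leaf_range):
            if L < t:
                continue
            devs = []
            for f in range(k):
                tr, te = folds != f, folds == f
                if y[tr].min() == y[tr].max():
                    raise ValueError(f"fold {f}: training split lost a class")
                model = anneal_fit(X[tr], y[tr], n_trees=t, max_total_leaves=L,
                                   schedule=schedule, seed=rng)
                devs.append(model.deviance_on(X[te], y[te]) if te.any() else np.nan)
            devs = np.asarray(devs, dtype=float)
            grid[(t, L)] = float(np.nanmean(devs))
            n_ok = int(np.isfinite(devs).sum())
            grid_se[(t, L)] = float(np.nanstd(devs, ddof=1) / np.sqrt(n_ok)) if n_ok > 1 else 0.0
    best = min(grid, key=lambda key: (grid[key], key[1], key[0]))
    if one_se_rule:
        cutoff = grid[best] + grid_se[best]
        selected = min((key for key in grid if grid[key] <= cutoff),
                       key=lambda key: (key[1], key[0], grid[key]))
    else:
        selected = best
    return CVResult(grid=grid, selected=selected, grid_se=grid_se, fold_assignments=folds)


@dataclass
class PermutationResult:
    observed_score: float
    permuted_scores: list[float]
    p: float
    n_perm: int
    seed: int | None = None


def permutation_test(
    covariates: np.ndarray,
    y: np.ndarray,
    selected_size: tuple[int, int],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    schedule: AnnealSchedule | None = None,
    observed_score: float | None = None,
) -> PermutationResult:
    """Permutation test of the selected logic model against label shuffles.

    Each permutation shuffles the case-control labels and re-runs the full
    annealing search at the selected model size; the p-value is
    (1 + #{permuted score <= observed}) / (n_perm + 1), so p >= 1/(n_perm+1).
    Deviance is one-sided by construction (smaller = better fit).
    """
    X = np.ascontiguousarray(covariates, dtype=np.uint8)
    y = np.asarray(y, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t, L = selected_size
    if observed_score is None:
        observed_score = anneal_fit(X, y, n_trees=t, max_total_leaves=L,
                                    schedule=schedule, seed=rng).score
    permuted = []
    for _ in range(n_perm):
        yp = y[rng.permutation(y.size)]
        m = anneal_fit(X, yp, n_trees=t, max_total_leaves=L,
                       schedule=schedule, seed=rng)
        permuted.append(m.score)
    n_le = sum(1 for s in permuted if s <= observed_score)
    p = (1 + n_le) / (n_perm + 1)
    return PermutationResult(observed_score=float(observed_score),
                             permuted_scores=permuted, p=float(p), n_perm=n_perm,
                             seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, ClassifierMixin  # noqa: E402
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array  # noqa: E402


class LogicRegressionClassifier(BaseEstimator, ClassifierMixin):
    """Logic regression as a scikit-learn classifier.

    Fits Boolean logic trees over binary covariates by simulated annealing
    under binomial-deviance scoring.  ``X`` must be a 0/1 covariate matrix
    (e.g. from :func:`binarize_genotypes` / :func:`covariate_matrix`);
    ``y`` binary case status.

    Parameters
    ----------
    n_trees : number of logic trees in the model.
    max_total_leaves : total leaf budget across trees.
    n_iterations : annealing iterations.
    start_temp : initial temperature; None auto-tunes to ~90% acceptance.
    end_temp : final temperature of the geometric cooling schedule.
    cv : if not None, number of stratified folds used to select
        (n_trees, max_total_leaves) over ``tree_range`` x ``leaf_range``
        before the final fit.
    random_state : seed for the search.

    Attributes
    ----------
    model_ : fitted :class:`LogicModel`.
    deviance_ : binomial deviance of ``model_`` on the training data.
    cv_result_ : :class:`CVResult` when ``cv`` is set.
    """

    def __init__(self, n_trees: int = 2, max_total_leaves: int = 4,
                 n_iterations: int = 50_000, start_temp: float | None = None,
                 end_temp: float = 1.0, cv: int | None = None,
                 tree_range=(1, 2), leaf_range=(1, 2, 3, 4, 5, 6, 7, 8),
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.max_total_leaves = max_total_leaves
        self.n_iterations = n_iterations
        self.start_temp = start_temp
        self.end_temp = end_temp
        self.cv = cv
        self.tree_range = tree_range
        self.leaf_range = leaf_range
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be a binary (0/1) covariate matrix")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("LogicRegressionClassifier requires two classes")
        yb = (y == self.classes_[1]).astype(float)
        rng = np.random.default_rng(self.random_state)
        sched = AnnealSchedule(start_temp=self.start_temp, end_temp=self.end_temp,
                               n_iterations=self.n_iterations)
        n_trees, leaves = self.n_trees, self.max_total_leaves
        if self.cv is not None:
            self.cv_result_ = cross_validate(X, yb, self.tree_range, self.leaf_range,
                                             k=self.cv, seed=rng, schedule=sched)
            n_trees, leaves = self.cv_result_.selected
        self.model_ = anneal_fit(X, yb, n_trees=n_trees, max_total_leaves=leaves,
                                 schedule=sched, seed=rng)
        self.deviance_ = self.model_.score
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        p1 = self.model_.predict_proba(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]
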