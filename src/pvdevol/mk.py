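"""Mk models of discrete pyoverdine-type evolution.

Fits equal-rates (ER), symmetric (SYM) and gamma-rate SYM Markov models of a
k-state unordered character on a fixed tree by maximum likelihood
(Felsenstein pruning), compares them by AIC/likelihood-ratio, and computes
marginal ancestral state probabilities at internal nodes.

Conventions: flat root prior over the k states; missing tips contribute
all-ones partial likelihoods; gamma rate heterogeneity uses ``ncat``
equal-probability categories represented by their category means (mean rate
1, shape ``alpha``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import linalg, optimize, special, stats

MISSING = "missing"

RATE_BOUNDS = (1e-8, 1e3)
ALPHA_BOUNDS = (0.05, 1e4)  # upper end ~rate-homogeneous; keeps SYM nested in gamma-SYM


@dataclass(frozen=True)
class MkModelSpec:
    k: int
    parameterization: str = "ER"  # ER | SYM
    gamma: bool = False
    ncat: int = 10

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need k >= 2 states")
        if self.parameterization not in ("ER", "SYM"):
            raise ValueError("parameterization must be ER or SYM")
        if self.ncat < 1:
            raise ValueError("ncat must be >= 1")

    @property
    def n_rates(self) -> int:
        return 1 if self.parameterization == "ER" else self.k * (self.k - 1) // 2

    @property
    def n_params(self) -> int:
        return self.n_rates + (1 if self.gamma else 0)

    @property
    def name(self) -> str:
        base = self.parameterization
        return f"gamma-{base}(ncat={self.ncat})" if self.gamma else base


@dataclass
class FitResult:
    spec: MkModelSpec
    log_likelihood: float
    rates: np.ndarray
    alpha: float | None = None
    converged: bool = True

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    @property
    def q_matrix(self) -> np.ndarray:
        return build_q(self.spec, self.rates)


def build_q(spec: MkModelSpec, rates) -> np.ndarray:
    """Symmetric instantaneous rate matrix; diagonal = -(row sum of off-diagonals)."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if len(rates) != spec.n_rates:
        raise ValueError(f"{spec.parameterization} with k={spec.k} needs {spec.n_rates} rates")
    k = spec.k
    q = np.zeros((k, k))
    if spec.parameterization == "ER":
        q[:] = rates[0]
    else:
        iu = np.triu_indices(k, 1)
        q[iu] = rates
        q.T[iu] = rates
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def gamma_category_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability categories of Gamma(alpha, mean 1)."""
    if ncat == 1:
        return np.ones(1)
    edges = stats.gamma.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    upper = special.gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = special.gammainc(alpha + 1.0, edges[:-1] * alpha)
    return ncat * (upper - lower)


class _TreeIndex:
    """Flattened postorder arrays for fast repeated pruning on one tree."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.children = [
            [self.index[id(c)] for c in n.child_nodes()] for n in nodes
        ]
        self.lengths = np.array(
            [n.edge.length if n.edge.length is not None else 0.0 for n in nodes]
        )
        self.tip_labels = [
            n.taxon.label if n.is_leaf() else None for n in nodes
        ]
        self.root = len(nodes) - 1


def _tip_partials(idx: _TreeIndex, tip_states: dict, k: int) -> np.ndarray:
    L = np.ones((len(idx.nodes), k))
    for i, label in enumerate(idx.tip_labels):
        if label is None:
            continue
        if label not in tip_states:
            raise ValueError(f"tip {label} missing from tip states")
        state = tip_states[label]
        if state == MISSING or state is None:
            continue
        state = int(state)
        if not 0 <= state < k:
            raise ValueError(f"state {state} out of range for k={k}")
        L[i] = 0.0
        L[i, state] = 1.0
    return L


def _transition_matrices(q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) for every branch at once via eigendecomposition of symmetric Q."""
    if np.allclose(q, q.T, atol=1e-10):
        lam, vec = np.linalg.eigh(q)
        expo = np.exp(np.outer(lengths, lam))  # (n, k)
        p = np.einsum("ij,nj,kj->nik", vec, expo, vec)
    else:  # pragma: no cover - ER/SYM matrices are symmetric
        p = np.stack([linalg.expm(q * t) for t in lengths])
    return np.clip(p, 0.0, None)


def _prune(idx: _TreeIndex, tips: np.ndarray, p: np.ndarray):
    """Scaled postorder partials; returns (partials, log-scaler sum per node subtree)."""
    n, k = tips.shape
    partials = tips.copy()
    logscale = np.zeros(n)
    for i, children in enumerate(idx.children):
        if not children:
            continue
        acc = np.ones(k)
        ls = 0.0
        for c in children:
            acc = acc * (p[c] @ partials[c])
            ls += logscale[c]
        m = acc.max()
        if m <= 0:
            return None, None  # impossible data under this Q
        partials[i] = acc / m
        logscale[i] = ls + np.log(m)
    return partials, logscale


def mk_loglik(tree, tip_states: dict, q: np.ndarray, gamma_rates=None) -> float:
    """Log-likelihood of tip states under Q (optionally averaged over gamma categories)."""
    idx = tree if isinstance(tree, _TreeIndex) else _TreeIndex(tree)
    k = q.shape[0]
    tips = _tip_partials(idx, tip_states, k)
    cats = np.ones(1) if gamma_rates is None else np.asarray(gamma_rates, dtype=float)
    logls = []
    for r in cats:
        p = _transition_matrices(q * r, idx.lengths)
        partials, logscale = _prune(idx, tips, p)
        if partials is None:
            return -np.inf
        root_like = partials[idx.root].mean()  # flat root prior
        logls.append(np.log(root_like) + logscale[idx.root])
    return float(special.logsumexp(logls) - np.log(len(cats)))


def fit_mk(tree, tip_states: dict, spec: MkModelSpec, n_inits: int = 5) -> FitResult:
    """Maximum-likelihood rates (and gamma shape) by bounded L-BFGS-B.

    The likelihood is evaluated at ``n_inits`` log-spaced initial rate values
    scaled to the tree length; optimization starts from the two best.
    """
    idx = _TreeIndex(tree)
    observed = {
        s for s in tip_states.values() if s not in (MISSING, None)
    }
    if len(observed) < 2:
        warnings.warn("fewer than 2 observed states; rate is not identifiable")
    k = spec.k
    tree_len = max(idx.lengths.sum(), 1e-6)
    scale = max(len(observed), 2) / tree_len

    def unpack(x):
        if spec.gamma:
            return np.exp(x[:-1]), float(np.exp(x[-1]))
        return np.exp(x), None

    def negloglik(x):
        rates, alpha = unpack(x)
        q = build_q(spec, rates)
        gr = gamma_category_rates(alpha, spec.ncat) if spec.gamma else None
        ll = mk_loglik(idx, tip_states, q, gr)
        return -ll if np.isfinite(ll) else 1e10

    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])
    bounds = [(lo, hi)] * spec.n_rates
    if spec.gamma:
        bounds.append((np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1])))

    inits = []
    for mult in np.geomspace(0.01, 10.0, n_inits):
        x0 = np.full(spec.n_rates, np.log(np.clip(scale * mult, *RATE_BOUNDS)))
        if spec.gamma:
            x0 = np.append(x0, 0.0)  # alpha = 1
        inits.append(x0)
    scored = sorted(inits, key=negloglik)

    best = None
    for x0 in scored[:2]:
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    rates, alpha = unpack(best.x)
    return FitResult(
        spec=spec,
        log_likelihood=-float(best.fun),
        rates=np.asarray(rates),
        alpha=alpha,
        converged=bool(best.success),
    )


@dataclass
class ModelComparison:
    ranking: list  # FitResults, ascending AIC
    lrt: list = field(default_factory=list)  # (simple name, complex name, 2dlogL, df)


def _nested(a: MkModelSpec, b: MkModelSpec) -> bool:
    """True if model a is nested in model b."""
    if a.k != b.k:
        return False
    if a.parameterization == "ER" and b.parameterization == "SYM" and a.gamma == b.gamma:
        return True
    if a.parameterization == b.parameterization and not a.gamma and b.gamma:
        return True
    return False


def compare_models(fits: list) -> ModelComparison:
    ranking = sorted(fits, key=lambda f: (f.aic, f.spec.name))
    lrt = []
    for a in fits:
        for b in fits:
            if _nested(a.spec, b.spec):
                lrt.append(
                    (
                        a.spec.name,
                        b.spec.name,
                        2.0 * (b.log_likelihood - a.log_likelihood),
                        b.n_params - a.n_params,
                    )
                )
    return ModelComparison(ranking=ranking, lrt=lrt)


def marginal_ancestral_states(tree, tip_states: dict, q: np.ndarray, gamma_rates=None) -> dict:
    """Marginal posterior state probabilities for every internal node.

    Combines each node's subtree partial likelihood with the likelihood of
    the rest of the tree (flat root prior); with gamma categories the
    per-category joints are averaged before normalizing. Keys are internal
    node labels where present, else ``node<i>`` in postorder.
    """
    idx = _TreeIndex(tree)
    k = q.shape[0]
    tips = _tip_partials(idx, tip_states, k)
    cats = np.ones(1) if gamma_rates is None else np.asarray(gamma_rates, dtype=float)

    n = len(idx.nodes)
    internal = [i for i, ch in enumerate(idx.children) if ch]
    per_cat = []  # (contrib, total-log-scaler per node) for each category
    for r in cats:
        p = _transition_matrices(q * r, idx.lengths)
        partials, logscale = _prune(idx, tips, p)
        if partials is None:
            raise ValueError("data impossible under supplied Q")
        # up-pass: up[i, s] is the (scaled) likelihood of everything outside
        # node i's subtree given state s at node i, including the root prior
        up = np.zeros((n, k))
        up_ls = np.zeros(n)
        up[idx.root] = 1.0 / k
        for i in reversed(range(n)):
            children = idx.children[i]
            for c in children:
                msgs = np.ones(k)
                ls = 0.0
                for s in children:
                    if s != c:
                        msgs = msgs * (p[s] @ partials[s])
                        ls += logscale[s]
                pre = up[i] * msgs
                up[c] = pre @ p[c]
                m = up[c].max()
                if m > 0:
                    up[c] /= m
                    up_ls[c] = up_ls[i] + ls + np.log(m)
        total = logscale + up_ls  # per-node log scalers of down*up product
        per_cat.append((partials * up, total))

    # average per-category joints on one common log scale before normalizing
    ref = max(t[idx.root] for _, t in per_cat)
    joint = np.zeros((n, k))
    for contrib, total in per_cat:
        for i in internal:
            joint[i] += np.exp(total[i] - ref) * contrib[i] / len(cats)

    out = {}
    for j, i in enumerate(internal):
        node = idx.nodes[i]
        label = node.label if node.label else f"node{i}"
        vec = joint[i]
        out[label] = vec / vec.sum()
    return out


def states_from_labels(tip_labels: dict) -> tuple:
    """Encode arbitrary tip state labels as 0..k-1; returns (tip_states, label list)."""
    levels = sorted({v for v in tip_labels.values() if v not in (MISSING, None)})
    enc = {lab: i for i, lab in enumerate(levels)}
    states = {
        tip: (MISSING if v in (MISSING, None) else enc[v]) for tip, v in tip_labels.items()
    }
    return states, levels
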