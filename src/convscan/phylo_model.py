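"""Continuous-time Markov substitution models, pruning likelihoods, and
marginal maximum-likelihood ancestral sequence reconstruction.

The model is the standard general time-reversible amino-acid process: a
symmetric exchangeability matrix S and stationary frequencies pi define the
rate matrix Q_ij = S_ij * pi_j (i != j), with rows summing to zero and the
normalisation -sum_i pi_i Q_ii = 1 so branch lengths are expected
substitutions per site.  Transition probabilities P(t) = exp(Qt) are obtained
from the symmetric eigendecomposition of diag(pi)^(1/2) Q diag(pi)^(-1/2),
which is numerically exact for reversible Q.

Site likelihoods use the pruning (sum-product) algorithm over the rooted
tree; per-node rescaling keeps partials in range for deep trees.  Marginal
ancestral reconstruction combines the "inside" (subtree) partials with an
"outside" pass from the root, giving for every internal node and site the
exact posterior over states given all tip data.  Empirical matrices (LG,
WAG, JTT) are shipped as PAML-format .dat files.

Rate heterogeneity across sites (discrete gamma) is supported but off by
default.
"""

from __future__ import annotations

import math
import warnings
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .seqio import AA_ALPHABET, GAP, MISSING, STOP, Msa, PhyloTree, ValidationError

_SHIPPED = {"LG": "lg.dat", "WAG": "wag.dat", "JTT": "jtt.dat"}


class SubstitutionModel:
    """Reversible substitution model over an arbitrary state alphabet.

    Parameters
    ----------
    exchangeabilities : (k, k) array
        Symmetric, non-negative off-diagonal; the diagonal is ignored.
    frequencies : (k,) array
        Stationary distribution; must be positive and sum to 1.
    alphabet : str
        One character per state; defaults to the 20 amino acids in PAML
        order (ARNDCQEGHILKMFPSTWYV).
    gamma_shape, n_rate_categories :
        Optional discrete-gamma rate heterogeneity (mean-1 category rates,
        equal weights, category means of the quantile bins).
    """

    def __init__(
        self,
        exchangeabilities,
        frequencies,
        alphabet: str = AA_ALPHABET,
        name: str = "custom",
        gamma_shape: Optional[float] = None,
        n_rate_categories: int = 4,
    ):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        k = len(alphabet)
        if S.shape != (k, k):
            raise ValidationError(f"exchangeability matrix must be {k}x{k}")
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValidationError("exchangeability matrix must be symmetric")
        off = S[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValidationError("negative exchangeability")
        # published .dat frequency vectors routinely miss 1 by ~1e-6
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-4:
            raise ValidationError("frequencies must be positive and sum to 1")
        pi = pi / pi.sum()

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(np.dot(pi, np.diag(Q)))
        if scale <= 0:
            raise ValidationError("degenerate rate matrix (zero total rate)")
        Q /= scale

        self.alphabet = alphabet
        self.name = name
        self.S = S
        self.pi = pi
        self.Q = Q
        self.index = {c: i for i, c in enumerate(alphabet)}

        # symmetric eigendecomposition: B = D^(1/2) Q D^(-1/2) is symmetric
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = (B + B.T) / 2.0
        self._eigval, U = np.linalg.eigh(B)
        self._left = U.T * d[None, :]          # U' D^(1/2)
        self._right = U / d[:, None]           # D^(-1/2) U

        if gamma_shape is not None and gamma_shape <= 0:
            raise ValidationError("gamma shape must be positive")
        self.gamma_shape = gamma_shape
        self.n_rate_categories = n_rate_categories

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def rate_categories(self) -> np.ndarray:
        """Mean-1 discrete-gamma category rates (equal-weight quantile bins)."""
        if self.gamma_shape is None:
            return np.array([1.0])
        a, k = self.gamma_shape, self.n_rate_categories
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # category mean of a Gamma(a, 1/a) on [lo, hi):
        # a * (F_{a+1}(hi) - F_{a+1}(lo)) / (F_a(hi) - F_a(lo)) / a, weights 1/k
        upper = gamma_dist.cdf(edges[1:], a + 1, scale=1.0 / a)
        lower = gamma_dist.cdf(edges[:-1], a + 1, scale=1.0 / a)
        rates = (upper - lower) * k
        return rates / rates.mean()

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, tiny negative entries are clipped."""
        if t < 0 or not math.isfinite(t):
            raise ValidationError(f"invalid branch length {t}")
        P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        neg = P < 0
        if neg.any():
            worst = float(-P[neg].min())
            if worst > 1e-9:
                raise ValidationError(
                    f"matrix exponential produced entry {-worst} at t={t}")
            P[neg] = 0.0
        P /= P.sum(axis=1, keepdims=True)
        return P

    def encode(self, residue: str) -> np.ndarray:
        """Tip partial vector: one-hot for a state, all-ones for missing."""
        if residue in (GAP, MISSING, STOP):
            return np.ones(self.n_states)
        i = self.index.get(residue)
        if i is None:
            raise ValidationError(f"residue {residue!r} outside model alphabet")
        v = np.zeros(self.n_states)
        v[i] = 1.0
        return v


def _parse_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    values: list[float] = []
    for line in text.splitlines():
        for tok in line.replace(",", " ").split():
            try:
                values.append(float(tok))
            except ValueError:
                break  # trailing commentary on some .dat files
    k = 20
    n_lower = k * (k - 1) // 2
    if len(values) < n_lower + k:
        raise ValidationError("matrix file too short for a 20-state model")
    S = np.zeros((k, k))
    pos = 0
    for i in range(1, k):
        for j in range(i):
            S[i, j] = S[j, i] = values[pos]
            pos += 1
    pi = np.array(values[pos:pos + k])
    return S, pi


def empirical_frequencies(msa: Msa, alphabet: str = AA_ALPHABET,
                          pseudocount: float = 0.5) -> np.ndarray:
    """Observed residue frequencies of an alignment (the "+F" option)."""
    counts = np.full(len(alphabet), pseudocount)
    index = {c: i for i, c in enumerate(alphabet)}
    for _, seq in msa.records:
        for c in seq:
            i = index.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def load_model(
    name_or_path: str,
    frequencies: Optional[Sequence[float]] = None,
    msa_for_frequencies: Optional[Msa] = None,
    gamma_shape: Optional[float] = None,
    n_rate_categories: int = 4,
) -> SubstitutionModel:
    """Load a shipped empirical matrix (``"LG"``, ``"WAG"``, ``"JTT"``) or a
    PAML-format .dat file from a path; optionally override the stationary
    frequencies, e.g. with :func:`empirical_frequencies` of an alignment.
    """
    key = name_or_path.upper()
    if key in _SHIPPED:
        text = resources.files("convscan").joinpath(
            f"data/{_SHIPPED[key]}").read_text()
        name = key
    else:
        with open(name_or_path) as fh:
            text = fh.read()
        name = name_or_path
    S, pi = _parse_paml_dat(text)
    if msa_for_frequencies is not None:
        pi = empirical_frequencies(msa_for_frequencies)
        name += "+F"
    if frequencies is not None:
        pi = np.asarray(frequencies, dtype=float)
    return SubstitutionModel(S, pi, name=name, gamma_shape=gamma_shape,
                             n_rate_categories=n_rate_categories)


# ---------------------------------------------------------------------------
# Pruning likelihoods
# ---------------------------------------------------------------------------

def _tip_partials(tree: PhyloTree, msa: Msa, model: SubstitutionModel) -> dict[int, np.ndarray]:
    """(n_sites, k) tip partial matrix per leaf index."""
    out = {}
    for leaf in tree.leaves():
        try:
            seq = msa.sequence(leaf.name)
        except KeyError:
            raise ValidationError(f"leaf {leaf.name!r} missing from alignment")
        out[leaf.index] = np.stack([model.encode(c) for c in seq])
    return out


def _prune(tree, tips, model, rate: float, scale: float = 1.0):
    """Inside pass.  Returns (inside, to_parent, log_scaler) keyed by node index.

    inside[v][s, i]   : P(tip data below v | state i at v), rescaled
    to_parent[v][s,j] : sum_i P_v(t)[j, i] * inside[v][s, i]
    log_scaler[s]     : accumulated log of rescaling factors per site
    """
    inside: dict[int, np.ndarray] = {}
    to_parent: dict[int, np.ndarray] = {}
    log_scaler = None
    for node in tree.postorder():
        if node.is_leaf:
            part = tips[node.index]
        else:
            part = np.ones_like(to_parent[node.children[0].index])
            for child in node.children:
                part = part * to_parent[child.index]
            mx = part.max(axis=1)
            mx[mx == 0.0] = 1.0
            part = part / mx[:, None]
            log_scaler = (np.log(mx) if log_scaler is None
                          else log_scaler + np.log(mx))
        inside[node.index] = part
        if node is not tree.root:
            P = model.transition_matrix(node.length * rate * scale)
            to_parent[node.index] = part @ P.T
    n_sites = next(iter(inside.values())).shape[0]
    if log_scaler is None:
        log_scaler = np.zeros(n_sites)
    return inside, to_parent, log_scaler


def site_log_likelihoods(
    tree: PhyloTree,
    msa: Msa,
    model: SubstitutionModel,
    branch_scale: float = 1.0,
) -> np.ndarray:
    """Per-site log-likelihoods under the pruning algorithm.

    Gaps, ``X`` and ``*`` at tips are uninformative (partial vector of
    ones).  With gamma rates, each site's likelihood is the equal-weight
    mean over rate categories.
    """
    tips = _tip_partials(tree, msa, model)
    per_cat = []
    for rate in model.rate_categories():
        inside, _, log_scaler = _prune(tree, tips, model, rate, branch_scale)
        root_lik = inside[tree.root.index] @ model.pi
        with np.errstate(divide="ignore"):
            per_cat.append(np.log(root_lik) + log_scaler)
    stacked = np.stack(per_cat)
    mx = stacked.max(axis=0)
    return mx + np.log(np.exp(stacked - mx[None, :]).mean(axis=0))


def site_likelihood(
    tree: PhyloTree,
    column: Mapping[str, str] | str,
    model: SubstitutionModel,
) -> float:
    """Likelihood of a single site pattern.

    ``column`` maps leaf labels to residues, or is a residue string in the
    order of :attr:`PhyloTree.leaf_labels`.
    """
    if isinstance(column, str):
        labels = tree.leaf_labels
        if len(column) != len(labels):
            raise ValidationError("pattern length != number of leaves")
        column = dict(zip(labels, column))
    msa = Msa([(label, column[label]) for label in tree.leaf_labels])
    return float(np.exp(site_log_likelihoods(tree, msa, model)[0]))


def log_likelihood(tree, msa, model, branch_scale: float = 1.0) -> float:
    return float(site_log_likelihoods(tree, msa, model, branch_scale).sum())


# ---------------------------------------------------------------------------
# Marginal ancestral reconstruction
# ---------------------------------------------------------------------------

class AncestralStateTable:
    """Marginal posteriors, MAP states and tie flags for internal nodes.

    Internal nodes are keyed by their postorder index in the tree used for
    reconstruction; the root is ``tree.root.index``.
    """

    def __init__(self, tree: PhyloTree, model: SubstitutionModel,
                 posteriors: dict[int, np.ndarray], tie_tol: float = 1e-9):
        self.tree = tree
        self.alphabet = model.alphabet
        self.posteriors = posteriors
        self.map_state: dict[int, list[str]] = {}
        self.map_posterior: dict[int, np.ndarray] = {}
        self.tied: dict[int, np.ndarray] = {}
        for idx, post in posteriors.items():
            best = post.max(axis=1)
            states, ties = [], []
            for s in range(post.shape[0]):
                winners = [i for i in range(post.shape[1])
                           if post[s, i] >= best[s] - tie_tol]
                # lexicographic tie-break by one-letter code, tie flag set
                states.append(min((model.alphabet[i] for i in winners)))
                ties.append(len(winners) > 1)
            self.map_state[idx] = states
            self.map_posterior[idx] = best
            self.tied[idx] = np.array(ties)

    @property
    def n_sites(self) -> int:
        return next(iter(self.posteriors.values())).shape[0]

    def posterior(self, node_index: int, site: int) -> np.ndarray:
        return self.posteriors[node_index][site]

    def map_sequence(self, node_index: int) -> str:
        return "".join(self.map_state[node_index])

    def to_frame(self):
        import pandas as pd
        rows = []
        for idx in sorted(self.posteriors):
            for s in range(self.n_sites):
                rows.append({
                    "node": idx,
                    "site": s + 1,
                    "map_state": self.map_state[idx][s],
                    "map_posterior": float(self.map_posterior[idx][s]),
                    "tied": bool(self.tied[idx][s]),
                })
        return pd.DataFrame(rows)


def marginal_asr(
    tree: PhyloTree,
    msa: Msa,
    model: SubstitutionModel,
    branch_scale: float = 1.0,
) -> AncestralStateTable:
    """Exact marginal posteriors for every internal node at every site.

    Inside-outside computation: the inside pass gives subtree partials, the
    outside pass propagates root-side information down; their product,
    normalised, is the posterior P(state at node | all tips).  With gamma
    rates, category posteriors are averaged with weights proportional to the
    per-category site likelihoods.
    """
    if not any(not n.is_leaf for n in tree.nodes):
        raise ValidationError("tree has no internal node")
    tips = _tip_partials(tree, msa, model)
    rates = model.rate_categories()
    n_sites = msa.n_columns

    per_cat_post: list[dict[int, np.ndarray]] = []
    log_lik = np.zeros((len(rates), n_sites))
    for ci, rate in enumerate(rates):
        inside, to_parent, log_scaler = _prune(tree, tips, model, rate,
                                               branch_scale)
        outside: dict[int, np.ndarray] = {tree.root.index:
                                          np.tile(model.pi, (n_sites, 1))}
        for node in tree.preorder():
            if node.is_leaf:
                continue
            out_here = outside[node.index]
            for child in node.children:
                sib = out_here.copy()
                for other in node.children:
                    if other is not child:
                        sib = sib * to_parent[other.index]
                P = model.transition_matrix(child.length * rate * branch_scale)
                outside[child.index] = sib @ P
        site_lik = (inside[tree.root.index] * outside[tree.root.index]).sum(axis=1)
        with np.errstate(divide="ignore"):
            log_lik[ci] = np.log(site_lik) + log_scaler
        cat = {}
        for node in tree.internal_nodes():
            joint = inside[node.index] * outside[node.index]
            cat[node.index] = joint / joint.sum(axis=1, keepdims=True)
        per_cat_post.append(cat)

    # category weights per site: equal priors times category likelihoods
    mx = log_lik.max(axis=0)
    w = np.exp(log_lik - mx[None, :])
    w /= w.sum(axis=0, keepdims=True)
    posteriors = {}
    for idx in per_cat_post[0]:
        acc = np.zeros_like(per_cat_post[0][idx])
        for ci in range(len(rates)):
            acc += per_cat_post[ci][idx] * w[ci][:, None]
        posteriors[idx] = acc
    return AncestralStateTable(tree, model, posteriors)


# ---------------------------------------------------------------------------
# Branch-scale fitting
# ---------------------------------------------------------------------------

def fit_branch_scale(
    tree: PhyloTree,
    msa: Msa,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (1e-4, 1e3),
) -> float:
    """ML estimate of a global branch-length multiplier.

    Useful when a user tree is not in substitutions/site.  Maximises the
    total log-likelihood over log(c); for an all-constant alignment (or one
    with no informative variation among ungapped columns) the likelihood is
    flat-to-decreasing and 1.0 is returned with a warning.
    """
    if msa.n_sequences < 2:
        raise ValidationError("need at least 2 sequences")

    variable = any(len({c for c in msa.column(j) if c not in (GAP, MISSING, STOP)}) > 1
                   for j in range(msa.n_columns))
    if not variable:
        warnings.warn("alignment has no variable sites; branch scale fixed at 1")
        return 1.0

    def neg(log_c: float) -> float:
        return -log_likelihood(tree, msa, model, branch_scale=math.exp(log_c))

    res = minimize_scalar(neg, bounds=(math.log(bounds[0]), math.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-6})
    c_hat = float(math.exp(res.x))
    # contract: log-likelihood at the estimate never below the c = 1 baseline
    if neg(math.log(c_hat)) > neg(0.0):
        return 1.0
    return c_hat
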