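"""Reversible amino-acid substitution model and pruning likelihood.

The default model is WAG (Whelan & Goldman 2001): a general
time-reversible rate matrix ``Q_ij = s_ij * pi_j`` (i != j) built from
published exchangeabilities ``s`` and stationary frequencies ``pi``,
normalised to one expected substitution per site per unit branch length.
Transition probabilities ``P(t) = expm(Q t)`` come from the symmetric
eigendecomposition of ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which is
exact for reversible models and gives P for any t at the cost of a 20x20
similarity transform.

Site likelihoods are computed by Felsenstein pruning with per-node
rescaling; gaps and X in the alignment are treated as missing data
(all-ones partials). Among-site rate variation is available as a
discrete-gamma mixture (``n_gamma_cats`` > 1) but is off by default, the
reference trees being fit under plain WAG.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from ._wag import AA_ORDER, WAG_FREQS, wag_exchangeabilities

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
MISSING = set("-X?.")

BRANCH_MIN, BRANCH_MAX = 1e-8, 10.0


class SubstitutionModel:
    """Reversible 20-state substitution model with optional +Gamma."""

    def __init__(self, name: str = "WAG", exchangeabilities=None, freqs=None,
                 n_gamma_cats: int = 1, alpha: float = 1.0):
        if exchangeabilities is None or freqs is None:
            if name != "WAG":
                raise ValueError(f"unknown built-in model {name!r}")
            exchangeabilities = wag_exchangeabilities()
            freqs = WAG_FREQS
        self.name = name
        self.exchangeabilities = np.asarray(exchangeabilities, float)
        self.freqs = np.asarray(freqs, float)
        if self.exchangeabilities.shape != (20, 20):
            raise ValueError("exchangeabilities must be 20x20")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeabilities must be symmetric")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            self.freqs = self.freqs / self.freqs.sum()
        if np.any(self.freqs <= 0):
            raise ValueError("all stationary frequencies must be positive")
        if n_gamma_cats < 1:
            raise ValueError("n_gamma_cats must be >= 1")
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.n_gamma_cats = int(n_gamma_cats)
        self.alpha = float(alpha)
        self._decompose()

    def _decompose(self):
        Q = build_rate_matrix(self)
        self.Q = Q
        pi = self.freqs
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]   # diag(sq) Q diag(1/sq), symmetric
        B = 0.5 * (B + B.T)
        lam, U = np.linalg.eigh(B)
        self._lam = lam
        self._left = U / sq[:, None]          # diag(1/sqrt(pi)) U
        self._right = (U * sq[:, None]).T     # U' diag(sqrt(pi))

    def rates(self) -> np.ndarray:
        return gamma_category_rates(self.alpha, self.n_gamma_cats)

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); rows sum to 1, entries clamped at 0."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def with_frequencies(self, freqs) -> "SubstitutionModel":
        """Same exchangeabilities, different stationary frequencies (+F)."""
        return SubstitutionModel(self.name + "+F", self.exchangeabilities,
                                 np.asarray(freqs, float),
                                 self.n_gamma_cats, self.alpha)

    def to_dict(self) -> dict:
        return {"name": "WAG" if self.name.startswith("WAG") else self.name,
                "n_gamma_cats": self.n_gamma_cats, "alpha": self.alpha,
                "freqs": [float(f) for f in self.freqs]}

    @classmethod
    def from_dict(cls, d: dict) -> "SubstitutionModel":
        base = cls(d.get("name", "WAG"),
                   n_gamma_cats=d.get("n_gamma_cats", 1),
                   alpha=d.get("alpha", 1.0))
        if "freqs" in d and not np.allclose(d["freqs"], WAG_FREQS):
            return base.with_frequencies(d["freqs"])
        return base


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Q_ij = s_ij pi_j, rows summing to zero, unit mean rate."""
    s = model.exchangeabilities
    pi = model.freqs
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.sum(pi * np.diag(Q))
    return Q / mean_rate


def gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rate of each of k equal-probability discrete-gamma categories.

    Shape and rate are both ``alpha`` so the continuous mean is 1; the
    category means are exact gamma partial expectations, and average to 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.array([1.0])
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(edges, alpha + 1, scale=1.0 / alpha)
    return k * np.diff(upper)


def empirical_frequencies(aln, pseudocount: float = 0.5) -> np.ndarray:
    """Amino-acid frequencies observed in an alignment (for +F models)."""
    counts = np.full(20, pseudocount)
    for row in aln.rows.values():
        for c in row:
            i = AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def tip_partial(row: str) -> np.ndarray:
    """(n_sites, 20) conditional likelihoods for an observed sequence row."""
    L = np.zeros((len(row), 20))
    for j, c in enumerate(row):
        if c in MISSING:
            L[j, :] = 1.0
        else:
            i = AA_INDEX.get(c)
            if i is None:
                raise ValueError(f"illegal residue {c!r} in alignment row")
            L[j, i] = 1.0
    return L


def _down_partials(tree, rowmap, model, rate: float):
    """Postorder conditional likelihoods per node, with per-site rescaling.

    Returns (partials, scales): partials[node.index] is (n_sites, 20),
    scales[node.index] the accumulated log scale per site.
    """
    partials = {}
    scales = {}
    for n in tree.postorder():
        if n.is_tip:
            partials[n.index] = rowmap[n.name]
            scales[n.index] = np.zeros(rowmap[n.name].shape[0])
        else:
            L = None
            sc = None
            for c in n.children:
                P = model.transition_probs((c.length or 0.0) * rate)
                contrib = partials[c.index] @ P.T
                L = contrib if L is None else L * contrib
                sc = scales[c.index].copy() if sc is None else sc + scales[c.index]
            m = L.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            L = L / m[:, None]
            sc = sc + np.log(m)
            partials[n.index] = L
            scales[n.index] = sc
    return partials, scales


def pruning_loglik(tree, aln, model: SubstitutionModel) -> float:
    """Felsenstein pruning log-likelihood of an alignment on a tree.

    Every tip label must have an alignment row; rows are on reference
    columns. With a gamma mixture the per-site likelihood is the average
    over categories.
    """
    rows = aln.rows if hasattr(aln, "rows") else dict(aln)
    missing = [t for t in tree.tip_names() if t not in rows]
    if missing:
        raise ValueError(f"tips without alignment rows: {missing}")
    rowmap = {t: tip_partial(rows[t]) for t in tree.tip_names()}
    rates = model.rates()
    site_logs = []
    for r in rates:
        partials, scales = _down_partials(tree, rowmap, model, r)
        root = tree.root.index
        site_l = partials[root] @ model.freqs
        site_logs.append(np.log(site_l) + scales[root])
    site_logs = np.array(site_logs)  # (k, n_sites)
    return float(np.sum(logsumexp(site_logs, axis=0) - np.log(len(rates))))


def optimize_branch(tree, edge_id: int, aln, model: SubstitutionModel,
                    bounds=(BRANCH_MIN, BRANCH_MAX), tol: float = 1e-6):
    """Maximize the log-likelihood over one branch length (in place).

    Derivative-free bounded scalar optimization; the branch is only
    updated when the refit does not lose likelihood, so the returned
    log-likelihood never drops below the starting one.
    """
    if not (0 <= bounds[0] < bounds[1]):
        raise ValueError("invalid branch-length bounds")
    node = tree.edge_node(edge_id)
    start_len = node.length if node.length is not None else 0.1

    def neg(t):
        node.length = float(t)
        return -pruning_loglik(tree, aln, model)

    start_ll = -neg(start_len)
    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": tol})
    if -res.fun >= start_ll:
        node.length = float(res.x)
        return float(res.x), float(-res.fun)
    node.length = start_len
    return float(start_len), float(start_ll)
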