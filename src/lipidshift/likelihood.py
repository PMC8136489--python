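"""Felsenstein pruning over the 61 sense-codon states.

Gaps and ambiguous codons are missing data (partial likelihood 1 for every
state).  Site patterns are compressed before pruning, and per-node scaling
guards against underflow on deep alignments.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from .alignment import CodonAlignment
from .codon_model import (
    CodonModelParams,
    N_CODONS,
    codon_index_row,
    eigen_decompose,
    expected_rate,
    gy94_unscaled,
    probs_from_eigen,
)


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a file path or a literal Newick string."""
    text = None
    p = Path(str(source))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    if text is None:
        text = str(source)
    tree = dendropy.Tree.get(data=text, schema="newick")
    return tree


def check_concordance(aln: CodonAlignment, tree: dendropy.Tree) -> None:
    """Raise if the tree's leaf set differs from the alignment's taxa."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    taxa = set(aln.taxa)
    if leaves != taxa:
        only_tree = sorted(leaves - taxa)
        only_aln = sorted(taxa - leaves)
        raise ValueError(
            "tree/alignment taxa mismatch: "
            f"only in tree {only_tree}; only in alignment {only_aln}"
        )


class PruningEngine:
    """Reusable pruning scaffold for one (alignment, tree) pair.

    Precomputes the post-order traversal, branch lengths, and compressed
    site patterns so repeated likelihood evaluations during optimization
    only pay for the linear algebra.
    """

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree):
        check_concordance(aln, tree)
        self.aln = aln
        self.n_sites = aln.n_sites
        taxon_row = {t: i for i, t in enumerate(aln.taxa)}

        states = np.stack([codon_index_row(r) for r in aln.rows])  # (taxa, sites)
        patterns, inverse = np.unique(states, axis=1, return_inverse=True)
        self.patterns = patterns          # (n_taxa, n_patterns)
        self.pattern_of_site = inverse    # (n_sites,)
        self.n_patterns = patterns.shape[1]
        # monomorphic data cannot identify mixture parameters
        self.has_variation = any(
            len({s for s in patterns[:, p] if s >= 0}) > 1
            for p in range(self.n_patterns)
        )

        self.postorder: list[dendropy.Node] = list(tree.postorder_node_iter())
        self.node_id = {id(n): k for k, n in enumerate(self.postorder)}
        self.leaf_row: dict[int, int] = {}
        self.children: dict[int, list[tuple[int, float]]] = {}
        for node in self.postorder:
            k = self.node_id[id(node)]
            if node.is_leaf():
                self.leaf_row[k] = taxon_row[node.taxon.label]
            else:
                self.children[k] = [
                    (self.node_id[id(ch)], ch.edge.length or 0.0)
                    for ch in node.child_nodes()
                ]
        self.root_id = self.node_id[id(self.postorder[-1])]

        # one-hot leaf partials with missing data as all-ones
        self._leaf_partials: dict[int, np.ndarray] = {}
        for k, row in self.leaf_row.items():
            part = np.zeros((self.n_patterns, N_CODONS))
            st = self.patterns[row]
            miss = st < 0
            part[np.arange(self.n_patterns)[~miss], st[~miss]] = 1.0
            part[miss] = 1.0
            self._leaf_partials[k] = part

    def _pattern_logliks(
        self, Qs: list[np.ndarray], pi: np.ndarray, multiplier: float
    ) -> np.ndarray:
        """Per-pattern log-likelihood for every rate class, shape
        (n_classes, n_patterns); classes are pruned jointly via stacked
        batch matmuls."""
        k_classes = len(Qs)
        safe_pi = np.maximum(pi, 1e-12)
        sqrt_pi = np.sqrt(safe_pi)
        S = (sqrt_pi[None, :, None] * np.stack(Qs)) / sqrt_pi[None, None, :]
        S = 0.5 * (S + S.transpose(0, 2, 1))
        vals, vecs = np.linalg.eigh(S)  # (k, 61), (k, 61, 61)

        partials: dict[int, np.ndarray] = {}
        scale_log = np.zeros((k_classes, self.n_patterns))
        for node in self.postorder:
            nid = self.node_id[id(node)]
            if node.is_leaf():
                continue
            prod = None
            for child_id, blen in self.children[nid]:
                expo = np.exp(vals * (blen * multiplier))  # (k, 61)
                inner = np.matmul(
                    vecs * expo[:, None, :], vecs.transpose(0, 2, 1)
                )
                P = (1.0 / sqrt_pi)[None, :, None] * inner \
                    * sqrt_pi[None, None, :]
                np.clip(P, 0.0, None, out=P)
                child_part = (
                    self._leaf_partials[child_id]
                    if child_id in self._leaf_partials
                    else partials.pop(child_id)
                )
                term = child_part @ P.transpose(0, 2, 1)
                prod = term if prod is None else prod * term
            mx = prod.max(axis=2)
            mx[mx == 0.0] = 1.0
            partials[nid] = prod / mx[:, :, None]
            scale_log += np.log(mx)
        if self.root_id in self._leaf_partials:  # single-leaf degenerate tree
            root_part = np.broadcast_to(
                self._leaf_partials[self.root_id],
                (k_classes, self.n_patterns, N_CODONS),
            )
        else:
            root_part = partials[self.root_id]
        lik = root_part @ pi
        with np.errstate(divide="ignore"):
            return np.log(lik) + scale_log

    def site_class_log_likelihoods(
        self,
        pi: np.ndarray,
        kappa: float,
        omegas: np.ndarray,
        props: np.ndarray,
        branch_scale: float = 1.0,
        normalize_mixture: bool = True,
    ) -> np.ndarray:
        """Per-site log-likelihood for every omega class, shape (k, n_sites).

        With ``normalize_mixture=True`` (default) branch lengths are
        expected substitutions per codon site under the full mixture:
        each class generator is divided by the mixture-averaged
        unnormalized rate (the PAML convention), then all branches are
        stretched by ``branch_scale``.  With ``normalize_mixture=False``
        the raw GY94 generators are used and ``branch_scale`` is an
        absolute branch multiplier, which makes each class's likelihood
        depend on its own omega only (the separable convention used when
        the scale has been calibrated once under M0).
        """
        omegas = np.asarray(omegas, dtype=float)
        props = np.asarray(props, dtype=float)
        Qs = [gy94_unscaled(kappa, w, pi) for w in omegas]
        if normalize_mixture:
            rates = np.array([expected_rate(Q, pi) for Q in Qs])
            mean_rate = float(props @ rates)
            if mean_rate <= 0:
                raise ValueError(
                    "mixture has zero expected substitution rate"
                )
            mult = branch_scale / mean_rate
        else:
            mult = branch_scale
        per_pat = self._pattern_logliks(Qs, pi, mult)
        return per_pat[:, self.pattern_of_site]

    def mixture_log_likelihood(
        self,
        pi: np.ndarray,
        kappa: float,
        omegas: np.ndarray,
        props: np.ndarray,
        branch_scale: float = 1.0,
        normalize_mixture: bool = True,
    ) -> tuple[float, np.ndarray]:
        """(total lnL, per-site lnL) of the mixture model."""
        per_class = self.site_class_log_likelihoods(
            pi, kappa, omegas, props, branch_scale, normalize_mixture
        )
        props = np.asarray(props, dtype=float)
        m = per_class.max(axis=0)
        site_ln = m + np.log(
            np.clip((props[:, None] * np.exp(per_class - m)).sum(axis=0),
                    1e-300, None)
        )
        return float(site_ln.sum()), site_ln


class OmegaGridApproximator:
    """Fast site-likelihood surrogate on a fixed omega grid.

    With kappa and the absolute branch multiplier held fixed (the
    separable convention calibrated under M0), each site's
    log-likelihood is a smooth function of omega alone.  It is evaluated
    exactly on a dense grid once, then interpolated with a cubic spline
    in log(omega + eps) during mixture optimization, turning each
    optimizer step from a pruning pass into a table lookup.  Exposes the
    same ``mixture_log_likelihood`` / ``site_class_log_likelihoods``
    surface as :class:`PruningEngine` (the normalize_mixture flag must
    be False, matching what it was built with).
    """

    _EPS = 1e-3

    def __init__(
        self,
        engine: PruningEngine,
        pi: np.ndarray,
        kappa: float,
        branch_scale: float,
        omega_grid: np.ndarray | None = None,
    ):
        from scipy.interpolate import CubicSpline

        # omega=0 is excluded: sites demanding a nonsynonymous change
        # have zero likelihood there; queries below the floor are clipped
        if omega_grid is None:
            omega_grid = np.geomspace(1e-4, 50.0, 64)
        self.omega_grid = np.asarray(omega_grid, dtype=float)
        self.pi = pi
        self.kappa = float(kappa)
        self.branch_scale = float(branch_scale)
        self.n_sites = engine.n_sites
        self.n_patterns = engine.n_patterns
        self.has_variation = engine.has_variation
        table = engine.site_class_log_likelihoods(
            pi, kappa, self.omega_grid,
            np.full(len(self.omega_grid), 1.0 / len(self.omega_grid)),
            branch_scale, normalize_mixture=False,
        )  # (n_grid, n_sites)
        table = np.nan_to_num(table, neginf=-1e8)
        x = np.log(self.omega_grid + self._EPS)
        self._spline = CubicSpline(x, table, axis=0)

    def _check(self, kappa: float, branch_scale: float,
               normalize_mixture: bool) -> None:
        if normalize_mixture:
            raise ValueError(
                "grid approximator only supports the separable "
                "(normalize_mixture=False) convention"
            )
        if abs(kappa - self.kappa) > 1e-9 or \
                abs(branch_scale - self.branch_scale) > 1e-9:
            raise ValueError(
                "grid approximator was built for different kappa/scale"
            )

    def site_class_log_likelihoods(
        self, pi, kappa, omegas, props, branch_scale=1.0,
        normalize_mixture=True,
    ) -> np.ndarray:
        self._check(kappa, branch_scale, normalize_mixture)
        omegas = np.clip(np.asarray(omegas, dtype=float),
                         self.omega_grid[0], self.omega_grid[-1])
        return self._spline(np.log(omegas + self._EPS))

    def mixture_log_likelihood(
        self, pi, kappa, omegas, props, branch_scale=1.0,
        normalize_mixture=True,
    ) -> tuple[float, np.ndarray]:
        per_class = self.site_class_log_likelihoods(
            pi, kappa, omegas, props, branch_scale, normalize_mixture
        )
        props = np.asarray(props, dtype=float)
        m = per_class.max(axis=0)
        site_ln = m + np.log(
            np.clip((props[:, None] * np.exp(per_class - m)).sum(axis=0),
                    1e-300, None)
        )
        return float(site_ln.sum()), site_ln


def site_log_likelihood(
    aln: CodonAlignment, tree: dendropy.Tree, params: CodonModelParams
) -> np.ndarray:
    """Per-site log-likelihoods under a single-omega GY94 model.

    Branch lengths are expected substitutions per codon site at the
    supplied omega (the generator is scaled to unit expected rate).
    """
    engine = PruningEngine(aln, tree)
    _, site_ln = engine.mixture_log_likelihood(
        params.pi, params.kappa, np.array([params.omega]), np.array([1.0])
    )
    return site_ln
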