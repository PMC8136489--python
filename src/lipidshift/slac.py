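"""SLAC-style counting scan with Fitch parsimony ancestral reconstruction.

Per site, synonymous and nonsynonymous changes are counted along every
tree branch between parsimony-inferred ancestral codons (averaging over
minimal mutational paths for multi-nucleotide differences), normalized by
the expected numbers of synonymous/nonsynonymous sites from the codon
composition, and tested for nonsynonymous excess with a two-tailed
binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from .alignment import CodonAlignment
from .codons import CODON_INDEX, SENSE_CODONS, count_changes, site_counts
from .likelihood import check_concordance
from .site_models import SiteScanRecord

_ALL_STATES = frozenset(range(len(SENSE_CODONS)))


@dataclass
class AncestralStates:
    """Parsimony codon assignments for every node at every site.

    ``states`` maps node key -> int array of codon indices (-1 where no
    state is inferable, e.g. an all-missing column).  Leaf keys are taxon
    labels; internal nodes are keyed ``node<i>`` in post-order.  Fitch
    ties are recorded as (node_key, 1-based site, tied codon tuple).
    """

    states: dict[str, np.ndarray]
    ties: list[tuple[str, int, tuple[str, ...]]] = field(default_factory=list)
    node_keys_postorder: list[str] = field(default_factory=list)


def root_if_needed(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a rooted copy: unrooted (trifurcating) trees are rooted on
    the edge of their alphabetically first leaf."""
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) <= 2:
        return t
    first = min(t.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    t.reroot_at_edge(first.edge, update_bipartitions=False)
    return t


def fitch_ancestral(aln: CodonAlignment, tree: dendropy.Tree) -> AncestralStates:
    """Fitch parsimony over codon states, ties broken lexicographically.

    Gapped/ambiguous leaf codons are unconstrained (full state set).
    Multifurcating internal nodes are folded child-by-child with the
    standard intersection/union rule.
    """
    check_concordance(aln, tree)
    rtree = root_if_needed(tree)
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    postorder = list(rtree.postorder_node_iter())
    keys: dict[int, str] = {}
    internal_counter = 0
    for node in postorder:
        if node.is_leaf():
            keys[id(node)] = node.taxon.label
        else:
            keys[id(node)] = f"node{internal_counter}"
            internal_counter += 1

    n_sites = aln.n_sites
    states = {keys[id(n)]: np.full(n_sites, -1, dtype=np.int64)
              for n in postorder}
    ties: list[tuple[str, int, tuple[str, ...]]] = []

    for site in range(n_sites):
        # bottom-up Fitch sets
        sets: dict[int, frozenset[int]] = {}
        for node in postorder:
            if node.is_leaf():
                codon = aln.codon(taxon_row[node.taxon.label], site)
                idx = CODON_INDEX.get(codon)
                sets[id(node)] = (
                    frozenset({idx}) if idx is not None else _ALL_STATES
                )
            else:
                cur: frozenset[int] | None = None
                for ch in node.child_nodes():
                    s = sets[id(ch)]
                    if cur is None:
                        cur = s
                    else:
                        inter = cur & s
                        cur = inter if inter else cur | s
                sets[id(node)] = cur if cur is not None else _ALL_STATES
        # top-down assignment
        for node in reversed(postorder):
            key = keys[id(node)]
            if node.is_leaf():
                codon = aln.codon(taxon_row[node.taxon.label], site)
                idx = CODON_INDEX.get(codon)
                states[key][site] = idx if idx is not None else -1
                continue
            s = sets[id(node)]
            parent = node.parent_node
            if parent is not None and states[keys[id(parent)]][site] in s:
                states[key][site] = states[keys[id(parent)]][site]
            else:
                choice = min(s)
                states[key][site] = choice
                if len(s) > 1 and s is not _ALL_STATES:
                    ties.append(
                        (key, site + 1,
                         tuple(SENSE_CODONS[i] for i in sorted(s)))
                    )
    return AncestralStates(
        states=states,
        ties=ties,
        node_keys_postorder=[keys[id(n)] for n in postorder],
    )


def slac_site_scan(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    ancestors: AncestralStates | None = None,
    kappa: float = 1.0,
    alternative: str = "two-sided",
) -> list[SiteScanRecord]:
    """Counting-based per-site dN/dS scan.

    Branches with a gapped endpoint contribute no counts at that site.
    Expected synonymous/nonsynonymous site fractions are averaged over
    all node states at the site, weighting candidate changes kappa : 1
    for transitions vs transversions (pass a fitted kappa to remove
    transition bias; 1 gives plain NG86 counting).  The binomial
    p-value tests whether the nonsynonymous fraction of observed
    changes departs from its compositional expectation; ``alternative``
    is "two-sided" (default) or "greater" (one-tailed nonsynonymous
    excess, the SLAC positive-selection convention).
    """
    if ancestors is None:
        ancestors = fitch_ancestral(aln, tree)
    rtree = root_if_needed(tree)
    postorder = list(rtree.postorder_node_iter())
    # reconstruct keys the same way fitch_ancestral does
    keys: dict[int, str] = {}
    internal_counter = 0
    for node in postorder:
        if node.is_leaf():
            keys[id(node)] = node.taxon.label
        else:
            keys[id(node)] = f"node{internal_counter}"
            internal_counter += 1

    edges = [
        (keys[id(n.parent_node)], keys[id(n)])
        for n in postorder
        if n.parent_node is not None
    ]

    results: list[SiteScanRecord] = []
    for site in range(aln.n_sites):
        syn = nonsyn = 0.0
        for pk, ck in edges:
            a = ancestors.states[pk][site]
            d = ancestors.states[ck][site]
            if a < 0 or d < 0 or a == d:
                continue
            s, n = count_changes(SENSE_CODONS[a], SENSE_CODONS[d])
            syn += s
            nonsyn += n
        node_states = [
            ancestors.states[k][site]
            for k in ancestors.node_keys_postorder
            if ancestors.states[k][site] >= 0
        ]
        if not node_states:
            results.append(SiteScanRecord(site=site + 1, method="SLAC"))
            continue
        if syn == 0.0 and nonsyn == 0.0:  # invariant (or unchanged) site
            results.append(
                SiteScanRecord(site=site + 1, method="SLAC", dn=0.0,
                               ds=0.0, p_value=1.0)
            )
            continue
        es_en = np.array(
            [site_counts(SENSE_CODONS[s], kappa) for s in node_states]
        )
        es, en = es_en.mean(axis=0)
        if es <= 0 or en <= 0:  # composition admits no changes of one kind
            results.append(SiteScanRecord(site=site + 1, method="SLAC"))
            continue
        ds = syn / es
        dn = nonsyn / en
        dnds = dn / ds if ds > 0 else (np.inf if dn > 0 else np.nan)
        total = int(round(syn + nonsyn))
        x = int(round(nonsyn))
        if total <= 0:
            p = 1.0
        else:
            x = min(x, total)
            p = float(
                stats.binomtest(
                    x, total, en / (en + es), alternative=alternative
                ).pvalue
            )
        results.append(
            SiteScanRecord(
                site=site + 1,
                method="SLAC",
                dn=float(dn),
                ds=float(ds),
                dnds=float(dnds) if np.isfinite(dnds) else None,
                p_value=p,
            )
        )
    return results
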