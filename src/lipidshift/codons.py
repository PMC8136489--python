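"""Genetic-code tables and codon-level change classification.

The 61 sense codons of the standard nuclear code are indexed in
lexicographic order (AAA=0 ... TTT=60, stops removed).  All selection
statistics in the package operate on this state space.
"""

from __future__ import annotations

from itertools import permutations

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
GAP_CODON = "---"

_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: sense codons, lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

AA_OF = {c: _STANDARD_CODE[c] for c in SENSE_CODONS}

_PURINES = {"A", "G"}


def translate_codon(codon: str) -> str:
    """One-letter amino acid of a sense codon ('-' for the gap codon)."""
    if codon == GAP_CODON:
        return "-"
    aa = _STANDARD_CODE.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"cannot translate codon {codon!r}")
    return aa


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in _PURINES) == (b in _PURINES)


def single_nt_difference(c1: str, c2: str) -> int | None:
    """Position (0-2) of the single differing nucleotide, or None."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    return diffs[0] if len(diffs) == 1 else None


def minimal_paths(c1: str, c2: str) -> list[list[tuple[str, str]]]:
    """All minimal single-step mutational paths from codon c1 to c2.

    Each path is a list of (from_codon, to_codon) steps.  Paths passing
    through a stop codon are discarded; if every ordering passes through
    a stop, all orderings are returned (the change must be counted
    somehow even if no stop-free route exists).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    paths: list[list[tuple[str, str]]] = []
    for order in permutations(diffs):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:  # only stop-crossing routes exist
        for order in permutations(diffs):
            cur = c1
            steps = []
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                steps.append((cur, nxt))
                cur = nxt
            paths.append(steps)
    return paths


def count_changes(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) change counts between two sense codons.

    Counts are averaged over all minimal mutational paths (stop-free
    orderings preferred), the SLAC/NG86 convention for multi-nucleotide
    codon differences.
    """
    if c1 == c2:
        return 0.0, 0.0
    paths = minimal_paths(c1, c2)
    syn = nonsyn = 0.0
    for path in paths:
        for a, b in path:
            aa_a = _STANDARD_CODE.get(a, "*")
            aa_b = _STANDARD_CODE.get(b, "*")
            if aa_a == aa_b:
                syn += 1
            else:
                nonsyn += 1
    n = len(paths)
    return syn / n, nonsyn / n


def site_counts(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a codon (sum = 3).

    For each position, the fraction of single-nucleotide changes that
    are synonymous, with changes weighted ``kappa`` : 1 for transitions
    vs transversions (kappa=1 reproduces plain NG86 counting; passing a
    fitted kappa removes the transition-bias distortion of dN/dS).
    Changes to stop codons are excluded from the weights (inaccessible
    states).
    """
    aa = _STANDARD_CODE[codon]
    syn_sites = 0.0
    for pos in range(3):
        w_syn = 0.0
        w_valid = 0.0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[pos], nt) else 1.0
            w_valid += w
            if _STANDARD_CODE[alt] == aa:
                w_syn += w
        if w_valid:
            syn_sites += w_syn / w_valid
    return syn_sites, 3.0 - syn_sites
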