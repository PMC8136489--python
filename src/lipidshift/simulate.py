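"""Synthetic-data generators with known ground truth for every pipeline
stage: codon alignments evolved under site-class omega mixtures on a
random tree, pseudo-atom shell structures with analytically known cavity
volumes and channel counts, Calpha model ensembles with a planted mobile
loop, and docking-energy tables with a controlled endogenous/exogenous
affinity gap.

Randomness is organized as per-component streams spawned from one master
seed (tree / site classes / evolution / structure / affinity), so the
same seed reproduces every artifact byte-identically and adding a stage
does not perturb earlier streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import biotite.structure as struc

from .affinity import (
    DEFAULT_TEMPERATURE,
    DockingRecord,
    ENDOGENOUS,
    EXOGENOUS,
    R_KCAL,
)
from .alignment import CodonAlignment
from .codon_model import (
    eigen_decompose,
    expected_rate,
    gy94_unscaled,
    probs_from_eigen,
)
from .codons import N_CODONS, SENSE_CODONS
from .pocket import DEFAULT_RADII
from .site_models import beta_category_omegas
from .structure import StructureModel


@dataclass
class SyntheticScenario:
    """Ground-truth configuration for all generators.

    The defaults mirror the study conditions: a 19-taxon tree with
    exponential branch lengths of mean 0.05 substitutions per codon,
    300 codon sites, kappa 2, and M7/M8-type beta mixtures discretized
    into 10 categories.
    """

    seed: int = 0
    # tree / codon evolution
    n_taxa: int = 19
    branch_length_mean: float = 0.05
    n_sites: int = 300
    kappa: float = 2.0
    mixture_model: str = "M7"          # M7 | M8 | single
    beta_p: float = 0.5
    beta_q: float = 1.5
    p0: float = 0.90                    # M8: weight of the beta part
    omega_s: float = 4.0                # M8: selected-class omega
    omega: float = 1.0                  # single-class omega
    k_categories: int = 10
    # cavity fixture
    void_size: float = 4.0              # inner void edge length, angstrom
    n_channels: int = 0
    lattice: float = 0.5                # wall atom lattice spacing
    channel_removal_radius: float = 3.0
    probe_radius: float = 0.75
    # model ensemble
    n_models: int = 5
    n_residues: int = 40
    loop_range: tuple[int, int] = (16, 25)   # 1-based inclusive
    loop_amplitude: float = 0.0
    # affinity tables
    n_endogenous: int = 3
    endo_dg_mean: float = -7.0
    endo_dg_sd: float = 1.0
    exo_gap_factor: float = 10.0        # Kd_best_endo / Kd_exo truth fold
    mutant_tighten_factor: float = 1.0  # >1: mutant endo Kds divided by it
    exo_ligand: str = "DDM"
    temperature: float = DEFAULT_TEMPERATURE
    swap_threshold: float = 1.0

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("tree", "sites", "evolution", "structure", "affinity")
        return {
            n: np.random.default_rng(s) for n, s in zip(names, children)
        }


def random_tree(
    n_taxa: int, branch_length_mean: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Random bifurcating topology by sequential pair joining, with
    exponential branch lengths."""
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for label in taxa:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(label)
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(branch_length_mean))
    return tree


def _truth_mixture(sc: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    if sc.mixture_model == "single":
        return np.array([sc.omega]), np.array([1.0])
    beta_omegas = beta_category_omegas(sc.beta_p, sc.beta_q, sc.k_categories)
    if sc.mixture_model == "M7":
        return beta_omegas, np.full(sc.k_categories, 1.0 / sc.k_categories)
    if sc.mixture_model == "M8":
        omegas = np.append(beta_omegas, sc.omega_s)
        props = np.append(
            np.full(sc.k_categories, sc.p0 / sc.k_categories), 1.0 - sc.p0
        )
        return omegas, props
    raise ValueError(f"unknown mixture_model {sc.mixture_model!r}")


def simulate_codon_alignment(
    scenario: SyntheticScenario,
    tree: dendropy.Tree | None = None,
) -> tuple[CodonAlignment, dendropy.Tree, np.ndarray]:
    """Evolve a codon alignment on a tree under the scenario's mixture.

    Root codons are drawn from uniform sense-codon frequencies (the
    F3x4-consistent choice for uniform nucleotide usage); each site draws
    an omega class from the truth mixture and evolves along every branch
    with GY94 transition probabilities normalized by the mixture-average
    rate.  Returns (alignment, tree, per-site true class index), where
    class indices refer to the truth mixture's class list.
    """
    streams = scenario.streams()
    if tree is None:
        tree = random_tree(
            scenario.n_taxa, scenario.branch_length_mean, streams["tree"]
        )
    omegas, props = _truth_mixture(scenario)
    pi = np.full(N_CODONS, 1.0 / N_CODONS)
    Qs = [gy94_unscaled(scenario.kappa, w, pi) for w in omegas]
    rates = np.array([expected_rate(Q, pi) for Q in Qs])
    mean_rate = float(props @ rates)
    eigs = [eigen_decompose(Q, pi) for Q in Qs]

    site_rng = streams["sites"]
    classes = site_rng.choice(len(omegas), size=scenario.n_sites, p=props)
    evo_rng = streams["evolution"]
    n_sites = scenario.n_sites

    root_states = evo_rng.choice(N_CODONS, size=n_sites, p=pi)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t_eff = (node.edge.length or 0.0) / mean_rate
        parent_states = states[id(node.parent_node)]
        child = np.empty(n_sites, dtype=np.int64)
        for c, (vals, vecs, sqrt_pi) in enumerate(eigs):
            mask = classes == c
            if not mask.any():
                continue
            P = probs_from_eigen(vals, vecs, sqrt_pi, np.array([t_eff]))[0]
            P = P / P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            rows = cum[parent_states[mask]]
            u = evo_rng.random(mask.sum())
            child[mask] = (u[:, None] > rows).sum(axis=1)
        states[id(node)] = child

    taxa, rows = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append(
            "".join(SENSE_CODONS[s] for s in states[id(leaf)])
        )
    return CodonAlignment(taxa, rows), tree, classes


def _box_shell_atoms(
    half_inner: float, lattice: float
) -> np.ndarray:
    """Atom centers forming the six faces of a closed cubic shell."""
    n = int(np.ceil(2 * half_inner / lattice))
    grid = np.linspace(-half_inner, half_inner, n + 1)
    pts = []
    for axis in range(3):
        for sign in (-1.0, 1.0):
            for a in grid:
                for b in grid:
                    p = [a, b]
                    p.insert(axis, sign * half_inner)
                    pts.append(p)
    return np.unique(np.round(np.array(pts), 6), axis=0)


def make_cavity_fixture(
    scenario: SyntheticScenario,
) -> tuple[StructureModel, float, int]:
    """Pseudo-atom cubic shell enclosing a void of known volume.

    Wall planes sit at void_size/2 + vdW(C) + probe from the center, so
    the probe-inflated cavity is analytically a cube of edge
    ``void_size`` (up to lattice bumpiness).  ``n_channels`` bores of
    ~3 angstrom diameter are opened through opposite x faces by removing
    wall atoms near the face center.  Returns (structure, truth volume,
    truth channel count).
    """
    r_c = DEFAULT_RADII["C"]
    half_inner = scenario.void_size / 2 + r_c + scenario.probe_radius
    pts = _box_shell_atoms(half_inner, scenario.lattice)
    if scenario.n_channels > 0:
        keep = np.ones(len(pts), dtype=bool)
        faces = [(0, +1.0), (0, -1.0)][: scenario.n_channels]
        for axis, sign in faces:
            on_face = np.isclose(pts[:, axis], sign * half_inner)
            others = [d for d in range(3) if d != axis]
            r_lat = np.sqrt(
                pts[:, others[0]] ** 2 + pts[:, others[1]] ** 2
            )
            keep &= ~(on_face & (r_lat < scenario.channel_removal_radius))
        pts = pts[keep]
    atoms = struc.AtomArray(len(pts))
    atoms.coord = pts.astype(np.float32)
    atoms.chain_id = np.full(len(pts), "A")
    atoms.res_id = np.arange(1, len(pts) + 1)
    atoms.res_name = np.full(len(pts), "DUM")
    atoms.atom_name = np.full(len(pts), "C")
    atoms.element = np.full(len(pts), "C")
    atoms.hetero = np.full(len(pts), True)
    model = StructureModel(
        atoms,
        label=f"shell_{scenario.n_channels}ch",
        remarks=["SYNTHETIC PSEUDO-ATOM SHELL FIXTURE"],
    )
    return model, scenario.void_size ** 3, scenario.n_channels


def make_model_ensemble(
    scenario: SyntheticScenario,
) -> tuple[list[StructureModel], np.ndarray]:
    """Replicated Calpha helix traces with a planted mobile loop.

    Each model is the same ideal helix with loop residues perturbed by
    isotropic Gaussian noise of the scenario amplitude, then rigidly
    rotated/translated (so raw coordinates differ even at amplitude 0).
    Returns (models, boolean mask of loop residues).
    """
    rng = scenario.streams()["structure"]
    n = scenario.n_residues
    idx = np.arange(n)
    base = np.stack(
        [
            2.3 * np.cos(idx * np.deg2rad(100.0)),
            2.3 * np.sin(idx * np.deg2rad(100.0)),
            1.5 * idx,
        ],
        axis=1,
    )
    lo, hi = scenario.loop_range
    loop_mask = (idx + 1 >= lo) & (idx + 1 <= hi)
    models = []
    for m in range(scenario.n_models):
        coords = base.copy()
        if scenario.loop_amplitude > 0:
            coords[loop_mask] += rng.normal(
                scale=scenario.loop_amplitude, size=(loop_mask.sum(), 3)
            )
        # random rigid transform
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x),
                 1 - 2 * (x * x + y * y)],
            ]
        )
        coords = coords @ rot.T + rng.uniform(-20, 20, size=3)
        atoms = struc.AtomArray(n)
        atoms.coord = coords.astype(np.float32)
        atoms.chain_id = np.full(n, "A")
        atoms.res_id = idx + 1
        atoms.res_name = np.full(n, "ALA")
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        models.append(
            StructureModel(atoms, label=f"model{m + 1}",
                           remarks=["SYNTHETIC CALPHA TRACE FIXTURE"])
        )
    return models, loop_mask


def make_affinity_tables(
    scenario: SyntheticScenario,
) -> tuple[list[DockingRecord], list[DockingRecord], dict[str, str]]:
    """Docking tables for a background and a mutant receptor with truth
    swap verdicts.

    Endogenous free energies are drawn from the scenario's normal law;
    the exogenous ligand's energy is set so that its truth Kd fold gap to
    the best endogenous ligand equals ``exo_gap_factor``.  The mutant
    tightens every endogenous Kd by ``mutant_tighten_factor``.  Extra
    higher-energy decoy poses are added so consumers must select the
    lowest-energy pose.  Truth verdicts are computed by the swap rule
    applied directly to the truth Kds.
    """
    rng = scenario.streams()["affinity"]
    rt = R_KCAL * scenario.temperature
    endo_dgs = rng.normal(
        scenario.endo_dg_mean, scenario.endo_dg_sd, scenario.n_endogenous
    )
    best_endo_dg = endo_dgs.min()
    exo_dg = best_endo_dg - rt * np.log(scenario.exo_gap_factor)
    mut_shift = -rt * np.log(scenario.mutant_tighten_factor)

    def table(receptor: str, endo_shift: float) -> list[DockingRecord]:
        recs = []
        for i, dg in enumerate(endo_dgs):
            lig = f"endo{i + 1}"
            g = float(dg + endo_shift)
            recs.append(DockingRecord(receptor, lig, g, 1, ENDOGENOUS))
            for rank, bump in enumerate(
                rng.uniform(0.3, 2.0, size=2), start=2
            ):
                recs.append(
                    DockingRecord(receptor, lig, g + float(bump), rank,
                                  ENDOGENOUS)
                )
        recs.append(
            DockingRecord(receptor, scenario.exo_ligand, float(exo_dg), 1,
                          EXOGENOUS)
        )
        recs.append(
            DockingRecord(
                receptor, scenario.exo_ligand,
                float(exo_dg + rng.uniform(0.3, 2.0)), 2, EXOGENOUS,
            )
        )
        return recs

    wt = table("wt", 0.0)
    mut = table("mut", mut_shift)

    def truth_verdict(endo_shift: float) -> str:
        kd_endo = np.exp((endo_dgs + endo_shift) / rt)
        kd_exo = np.exp(exo_dg / rt)
        fold = kd_endo.min() / kd_exo
        return "swap" if fold >= scenario.swap_threshold else "no_swap"

    truth = {
        "wt": truth_verdict(0.0),
        "mut": truth_verdict(mut_shift),
    }
    return wt, mut, truth
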