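"""Structure I/O, Kabsch superposition, per-residue divergence and
conservation painting, and stub point mutations.

PDB files are read and written through biotite; coordinates are carried
as an ``AtomArray`` inside :class:`StructureModel`.  Superposition is a
least-squares Kabsch fit (SVD), optionally with iterative outlier
rejection mirroring the usual align-with-refinement convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .alignment import Alignment

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: atoms kept by the stub mutation (backbone + Cbeta)
_STUB_ATOMS = {"N", "CA", "C", "O", "OXT", "CB"}

UNPAIRED_SENTINEL = 99.99


@dataclass
class StructureModel:
    """Atom records of one structure plus a label and header remarks."""

    atoms: struc.AtomArray
    label: str = ""
    remarks: list[str] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def ca_mask(self) -> np.ndarray:
        return self.atoms.atom_name == "CA"

    def ca_coords(self) -> np.ndarray:
        return self.atoms.coord[self.ca_mask()]

    def ca_residue_ids(self) -> np.ndarray:
        return self.atoms.res_id[self.ca_mask()]

    def sequence(self) -> str:
        """One-letter sequence over Calpha-bearing residues, file order."""
        names = self.atoms.res_name[self.ca_mask()]
        return "".join(THREE_TO_ONE.get(n, "X") for n in names)

    def copy(self) -> "StructureModel":
        return StructureModel(self.atoms.copy(), self.label,
                              list(self.remarks))


@dataclass
class SuperpositionResult:
    """Rigid transform mapping the mobile set onto the reference."""

    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector, angstrom
    rmsd: float
    n_atoms_used: int
    cycles_run: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ResidueDivergenceProfile:
    """Mean pairwise Calpha deviation per paired residue, plus the
    normalized conservation score (min deviation -> 1, max -> 0)."""

    residue_ids: np.ndarray
    deviation: np.ndarray       # angstrom
    conservation: np.ndarray    # in [0, 1]


@dataclass
class MutationSpec:
    """A single point substitution, e.g. W98G on a given background."""

    position: int
    from_res: str
    to_res: str
    background: str = ""
    chain: str | None = None


def read_structure(
    path: str | Path, label: str | None = None, exclude_waters: bool = True
) -> StructureModel:
    """Read a PDB file: first model, highest-occupancy altlocs, waters
    excluded by default."""
    pdb = PDBFile.read(str(path))
    atoms = PDBFile.get_structure(
        pdb, model=1, altloc="occupancy",
        extra_fields=["b_factor", "occupancy"],
    )
    if atoms.array_length() == 0:
        raise ValueError(f"no ATOM records in {path}")
    if exclude_waters:
        atoms = atoms[~np.isin(atoms.res_name, ("HOH", "WAT"))]
        if atoms.array_length() == 0:
            raise ValueError(f"only water atoms in {path}")
    if not np.isfinite(atoms.coord).all():
        raise ValueError(f"non-finite coordinates in {path}")
    return StructureModel(atoms, label or Path(path).stem)


def write_structure(model: StructureModel, path: str | Path) -> None:
    pdb = PDBFile()
    PDBFile.set_structure(pdb, model.atoms)
    if model.remarks:
        remark_lines = [f"REMARK 999 {r}"[:80] for r in model.remarks]
        pdb.lines = remark_lines + pdb.lines
    pdb.write(str(path))


def kabsch_superpose(A: np.ndarray, B: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinate sets.

    Finds rotation R (det +1) and translation t minimizing
    ``sum ||R b_i + t - a_i||^2`` and reports the post-fit RMSD.
    Requires n >= 3 non-collinear pairs.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired atoms, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    H = Bc.T @ Ac
    U, S, Vt = np.linalg.svd(H)
    span = np.linalg.norm(Ac) * np.linalg.norm(Bc)
    if span > 0 and S[1] / max(S[0], 1e-300) < 1e-8:
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca - R @ cb
    diff = (B @ R.T + t) - A
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms_used=n, cycles_run=0)


def refined_superpose(
    A: np.ndarray,
    B: np.ndarray,
    cycles: int = 5,
    cutoff_sigma: float = 2.0,
) -> SuperpositionResult:
    """Kabsch superposition with iterative outlier rejection.

    After each fit, pairs deviating by more than ``cutoff_sigma`` times
    the current RMS deviation are dropped and the remaining pairs
    re-fitted, up to ``cycles`` times (the align-style outlier-rejection
    convention).  The refined RMSD is never larger than the plain Kabsch
    RMSD on the same pairing.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    keep = np.ones(A.shape[0], dtype=bool)
    result = kabsch_superpose(A, B)
    cycles_run = 0
    for _ in range(cycles):
        devs = np.linalg.norm(result.apply(B[keep]) - A[keep], axis=1)
        thr = cutoff_sigma * np.sqrt(np.mean(devs ** 2))
        bad = devs > max(thr, 1e-9)
        if not bad.any():
            break
        new_keep = keep.copy()
        new_keep[np.where(keep)[0][bad]] = False
        if new_keep.sum() < 3:
            if keep.sum() == A.shape[0] and bad.all():
                raise ValueError("outlier rejection removed every atom pair")
            break
        keep = new_keep
        result = kabsch_superpose(A[keep], B[keep])
        cycles_run += 1
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_atoms_used=int(keep.sum()),
        cycles_run=cycles_run,
    )


@dataclass
class AlignmentPairing:
    """Paired Calpha sets across structures, with a two-way map between
    alignment columns (1-based) and structure residue numbers."""

    columns: list[int]
    col_to_residue: list[dict[int, int]]   # per structure
    residue_to_col: list[dict[int, int]]   # per structure
    ca_sets: np.ndarray                    # (n_structures, n_paired, 3)


def pair_by_alignment(
    aln: Alignment,
    structures: list[StructureModel],
    max_mismatch: int = 0,
) -> AlignmentPairing:
    """Link alignment columns to structure residues and extract paired
    Calpha coordinates.

    Structures are matched to alignment rows by label when labels
    coincide with taxa, otherwise by order.  Each structure's Calpha
    sequence must equal its row's ungapped residues (up to
    ``max_mismatch`` tolerated substitutions).  Only columns with a
    residue in every structure are paired.
    """
    rows = []
    for i, sm in enumerate(structures):
        if sm.label in aln.taxa:
            rows.append(aln.taxa.index(sm.label))
        else:
            rows.append(i)
    col_to_residue: list[dict[int, int]] = []
    residue_to_col: list[dict[int, int]] = []
    per_struct_cols: list[set[int]] = []
    for sm, ri in zip(structures, rows):
        row = aln.rows[ri]
        seq = sm.sequence()
        res_ids = sm.ca_residue_ids()
        ungapped = [(j, ch) for j, ch in enumerate(row) if ch != "-"]
        if len(ungapped) != len(seq):
            raise ValueError(
                f"structure {sm.label!r}: {len(seq)} residues but alignment "
                f"row has {len(ungapped)} non-gap columns"
            )
        mismatches = [
            (j + 1, ch, s)
            for (j, ch), s in zip(ungapped, seq)
            if ch != s
        ]
        if len(mismatches) > max_mismatch:
            col, ch, s = mismatches[0]
            raise ValueError(
                f"structure {sm.label!r} disagrees with alignment at "
                f"column {col}: alignment {ch!r} vs structure {s!r}"
            )
        c2r = {j + 1: int(res_ids[k]) for k, (j, _) in enumerate(ungapped)}
        col_to_residue.append(c2r)
        residue_to_col.append({r: c for c, r in c2r.items()})
        per_struct_cols.append(set(c2r))
    common = sorted(set.intersection(*per_struct_cols)) if structures else []
    ca_sets = []
    for sm, c2r in zip(structures, col_to_residue):
        coords = sm.ca_coords()
        res_ids = list(sm.ca_residue_ids())
        idx = [res_ids.index(c2r[c]) for c in common]
        ca_sets.append(coords[idx])
    return AlignmentPairing(
        columns=common,
        col_to_residue=col_to_residue,
        residue_to_col=residue_to_col,
        ca_sets=np.array(ca_sets),
    )


def per_residue_divergence(
    ca_sets: np.ndarray,
    residue_ids: np.ndarray | None = None,
    superpose_onto_first: bool = True,
) -> ResidueDivergenceProfile:
    """Mean pairwise Calpha deviation per residue across >= 2 models.

    Models are rigidly superposed onto the first model (configurable off
    to analyse pre-superposed coordinates).  Conservation is a linear
    rescale of deviation with the smallest deviation mapped to 1 and the
    largest to 0; identical models score 1 everywhere.
    """
    ca_sets = np.asarray(ca_sets, dtype=float)
    if ca_sets.ndim != 3 or ca_sets.shape[0] < 2:
        raise ValueError("need at least 2 models of shape (n_res, 3)")
    m = ca_sets.shape[0]
    if superpose_onto_first:
        fitted = [ca_sets[0]]
        for i in range(1, m):
            sup = kabsch_superpose(ca_sets[0], ca_sets[i])
            fitted.append(sup.apply(ca_sets[i]))
        ca_sets = np.array(fitted)
    n_res = ca_sets.shape[1]
    dev = np.zeros(n_res)
    n_pairs = 0
    for i in range(m):
        for j in range(i + 1, m):
            dev += np.linalg.norm(ca_sets[i] - ca_sets[j], axis=1)
            n_pairs += 1
    dev /= n_pairs
    lo, hi = dev.min(), dev.max()
    if hi - lo < 1e-12:
        cons = np.ones(n_res)
    else:
        cons = 1.0 - (dev - lo) / (hi - lo)
    if residue_ids is None:
        residue_ids = np.arange(1, n_res + 1)
    return ResidueDivergenceProfile(
        residue_ids=np.asarray(residue_ids), deviation=dev,
        conservation=cons,
    )


def write_conservation_bfactor(
    model: StructureModel,
    profile: ResidueDivergenceProfile,
    path: str | Path,
    score: str = "conservation",
) -> StructureModel:
    """Write the structure with per-residue scores in the B-factor column.

    Every atom of a scored residue carries its residue score (2 decimals
    in the PDB output); residues absent from the profile get the sentinel
    99.99.  Returns the painted model.
    """
    values = getattr(profile, score)
    by_res = dict(zip((int(r) for r in profile.residue_ids), values))
    painted = model.copy()
    b = np.full(painted.n_atoms, UNPAIRED_SENTINEL)
    for i, rid in enumerate(painted.atoms.res_id):
        if int(rid) in by_res:
            b[i] = round(float(by_res[int(rid)]), 2)
    painted.atoms.set_annotation("b_factor", b)
    painted.remarks.append(
        f"B-FACTOR COLUMN CARRIES PER-RESIDUE {score.upper()} SCORES; "
        f"{UNPAIRED_SENTINEL} = UNPAIRED RESIDUE"
    )
    write_structure(painted, path)
    return painted


def apply_point_mutation(
    model: StructureModel, m: MutationSpec
) -> StructureModel:
    """Stub point mutation: rename the residue and truncate its side
    chain beyond Cbeta.

    No rotamer is built -- mutated structures destined for docking must
    be rebuilt with a side-chain packer; a provenance remark saying so is
    added to the header.  Raises if the residue present at the position
    does not match ``from_res``.
    """
    atoms = model.atoms
    sel = atoms.res_id == m.position
    if m.chain is not None:
        sel &= atoms.chain_id == m.chain
    if not sel.any():
        raise ValueError(f"no residue numbered {m.position} found")
    res_names = set(atoms.res_name[sel])
    if len(res_names) != 1:
        raise ValueError(
            f"position {m.position} is ambiguous across chains; "
            "specify chain"
        )
    observed = res_names.pop()
    observed_one = THREE_TO_ONE.get(observed, "X")
    if observed_one != m.from_res.upper():
        raise ValueError(
            f"expected {m.from_res} at position {m.position}, "
            f"structure has {observed_one} ({observed})"
        )
    to_three = ONE_TO_THREE.get(m.to_res.upper())
    if to_three is None:
        raise ValueError(f"unknown target residue {m.to_res!r}")
    mutated = model.copy()
    keep_atoms = _STUB_ATOMS - ({"CB"} if m.to_res.upper() == "G" else set())
    drop = sel & ~np.isin(atoms.atom_name, sorted(keep_atoms))
    mutated.atoms = mutated.atoms[~drop]
    new_sel = mutated.atoms.res_id == m.position
    if m.chain is not None:
        new_sel &= mutated.atoms.chain_id == m.chain
    names = mutated.atoms.res_name.copy()
    names[new_sel] = to_three
    mutated.atoms.set_annotation("res_name", names)
    note = (
        f"STUB MUTATION {m.from_res.upper()}{m.position}"
        f"{m.to_res.upper()}: SIDE CHAIN TRUNCATED AT CBETA; REBUILD "
        "ROTAMER BEFORE DOCKING"
    )
    mutated.remarks.append(note)
    mutated.label = f"{model.label}_{m.from_res}{m.position}{m.to_res}"
    return mutated
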