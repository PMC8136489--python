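"""Docking energies to dissociation constants, lipid-swap feasibility and
mutational-scan comparisons.

Binding free energies (kcal/mol, negative = favorable) are converted to
dissociation constants via Kd = exp(dG / RT).  A receptor is predicted to
swap its best (lowest-Kd) endogenous lipid for a named exogenous ligand
when the fold difference Kd_best_endogenous / Kd_exogenous reaches the
threshold (default 1: the exogenous ligand binds at least as tightly).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: gas constant in kcal / (mol K)
R_KCAL = 0.0019872
DEFAULT_TEMPERATURE = 298.15

ENDOGENOUS = "endogenous"
EXOGENOUS = "exogenous"


@dataclass
class DockingRecord:
    """One docking pose: receptor x ligand binding free energy."""

    receptor: str
    ligand: str
    delta_g: float              # kcal/mol
    pose_rank: int = 1
    ligand_class: str | None = None  # endogenous | exogenous

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")


@dataclass
class AffinityRecord:
    receptor: str
    ligand: str
    kd: float                   # molar
    temperature: float


@dataclass
class SwapCall:
    """Lipid-swap verdict for one receptor."""

    receptor: str
    best_endogenous: str
    best_endogenous_kd: float
    exogenous: str
    exogenous_kd: float
    fold: float                 # kd_best_endogenous / kd_exogenous
    verdict: str                # "swap" | "no_swap"
    threshold: float
    temperature: float


@dataclass
class LigandChange:
    ligand: str
    ligand_class: str | None
    kd_wt: float
    kd_mut: float
    fold: float                 # kd_mut / kd_wt; < 1 = affinity increased
    direction: str              # increased | decreased | unchanged


@dataclass
class ScanComparison:
    """Per-ligand affinity changes between a background and its mutant."""

    background: str
    mutant: str
    changes: list[LigandChange]
    wt_call: SwapCall | None = None
    mut_call: SwapCall | None = None
    verdict_changed: bool | None = None

    def summary(self) -> str:
        endo = [c for c in self.changes if c.ligand_class == ENDOGENOUS]
        parts = []
        for label, group in (("endogenous", endo),
                             ("exogenous",
                              [c for c in self.changes
                               if c.ligand_class == EXOGENOUS])):
            if not group:
                continue
            dirs = {c.direction for c in group}
            if dirs == {"increased"}:
                parts.append(
                    f"increased affinity for all {label} ligands"
                )
            elif dirs == {"decreased"}:
                parts.append(
                    f"decreased affinity for all {label} ligands"
                )
            elif dirs == {"unchanged"}:
                parts.append(f"unchanged affinity for {label} ligands")
            else:
                n_up = sum(c.direction == "increased" for c in group)
                parts.append(
                    f"mixed effect on {label} ligands "
                    f"({n_up}/{len(group)} increased)"
                )
        head = f"{self.mutant} vs {self.background}: " + "; ".join(parts)
        if self.verdict_changed is not None:
            head += (
                "; swap verdict "
                + ("changed" if self.verdict_changed else "unchanged")
            )
        return head


def kd_from_dg(
    delta_g: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Dissociation constant (molar) from binding free energy (kcal/mol).

    Kd = exp(dG / RT) with R = 0.0019872 kcal/(mol K): dG = 0 gives 1 M,
    and Kd is strictly increasing in dG (less negative = weaker binding).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if not math.isfinite(delta_g):
        raise ValueError("delta_g must be finite")
    return math.exp(delta_g / (R_KCAL * temperature))


_VINA_ROW = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+\S+\s+\S+\s*$")


def parse_vina_output(
    path: str | Path,
    receptor: str | None = None,
    ligand: str | None = None,
    ligand_class: str | None = None,
) -> list[DockingRecord]:
    """Parse an AutoDock-Vina-style log into docking records.

    Reads the "mode | affinity | dist..." result table; one record per
    pose with pose ranks preserved (rank 1 = lowest energy).  Receptor
    and ligand labels default to the file stem split on a double
    underscore (``receptor__ligand.log``).
    """
    path = Path(path)
    stem = path.stem
    if receptor is None or ligand is None:
        parts = stem.split("__")
        receptor = receptor or parts[0]
        ligand = ligand or (parts[1] if len(parts) > 1 else stem)
    records = []
    in_table = False
    for line in path.read_text().splitlines():
        if not in_table and "affinity" in line.lower():
            in_table = True
            continue
        if in_table:
            m = _VINA_ROW.match(line)
            if m:
                records.append(
                    DockingRecord(
                        receptor=receptor,
                        ligand=ligand,
                        delta_g=float(m.group(2)),
                        pose_rank=int(m.group(1)),
                        ligand_class=ligand_class,
                    )
                )
            elif records:
                break
    if not records:
        raise ValueError(f"no affinity table found in {path}")
    return records


def parse_vina_dir(
    directory: str | Path,
    class_map: dict[str, str] | None = None,
    pattern: str = "*.log",
) -> list[DockingRecord]:
    """Parse every Vina log in a directory (``receptor__ligand.log``)."""
    records: list[DockingRecord] = []
    for p in sorted(Path(directory).glob(pattern)):
        recs = parse_vina_output(p)
        if class_map:
            for r in recs:
                r.ligand_class = class_map.get(r.ligand, r.ligand_class)
        records.extend(recs)
    if not records:
        raise ValueError(f"no Vina logs matching {pattern} in {directory}")
    return records


_DG_COLUMNS = ["receptor", "ligand", "ligand_class", "delta_g_kcal_mol",
               "pose_rank"]


def records_to_frame(records: list[DockingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "receptor": r.receptor,
                "ligand": r.ligand,
                "ligand_class": r.ligand_class,
                "delta_g_kcal_mol": r.delta_g,
                "pose_rank": r.pose_rank,
            }
            for r in records
        ],
        columns=_DG_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[DockingRecord]:
    return [
        DockingRecord(
            receptor=str(row.receptor),
            ligand=str(row.ligand),
            delta_g=float(row.delta_g_kcal_mol),
            pose_rank=int(row.pose_rank),
            ligand_class=(None if pd.isna(row.ligand_class)
                          else str(row.ligand_class)),
        )
        for row in df.itertuples()
    ]


def read_dg_table(path: str | Path) -> list[DockingRecord]:
    return frame_to_records(pd.read_csv(path))


def write_dg_table(records: list[DockingRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def best_poses(records: list[DockingRecord]) -> dict[str, DockingRecord]:
    """Lowest-energy pose per ligand (single receptor expected)."""
    best: dict[str, DockingRecord] = {}
    for r in records:
        cur = best.get(r.ligand)
        if cur is None or r.delta_g < cur.delta_g:
            best[r.ligand] = r
    return best


def swap_feasibility(
    records: list[DockingRecord],
    exo_ligand: str,
    threshold: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> SwapCall:
    """Lipid-swap verdict from one receptor's docking table.

    Uses the lowest-energy pose per ligand; the best endogenous ligand is
    the one with minimal Kd.  ``fold = Kd_best_endo / Kd_exo``; verdict
    is "swap" iff fold >= threshold (ties count as swap).
    """
    receptors = {r.receptor for r in records}
    if len(receptors) != 1:
        raise ValueError(
            f"swap_feasibility expects one receptor, got {sorted(receptors)}"
        )
    receptor = receptors.pop()
    best = best_poses(records)
    endo = {
        lig: r for lig, r in best.items() if r.ligand_class == ENDOGENOUS
    }
    if not endo:
        raise ValueError(f"no endogenous ligands for receptor {receptor!r}")
    if exo_ligand not in best:
        raise ValueError(
            f"exogenous ligand {exo_ligand!r} absent for {receptor!r}"
        )
    kd = {lig: kd_from_dg(r.delta_g, temperature)
          for lig, r in best.items()}
    best_endo = min(endo, key=lambda lig: kd[lig])
    fold = kd[best_endo] / kd[exo_ligand]
    return SwapCall(
        receptor=receptor,
        best_endogenous=best_endo,
        best_endogenous_kd=kd[best_endo],
        exogenous=exo_ligand,
        exogenous_kd=kd[exo_ligand],
        fold=fold,
        verdict="swap" if fold >= threshold else "no_swap",
        threshold=threshold,
        temperature=temperature,
    )


def mutational_scan(
    wt: list[DockingRecord],
    mut: list[DockingRecord],
    exo_ligand: str | None = None,
    threshold: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ScanComparison:
    """Compare a mutant receptor's docking table against its background.

    Per shared ligand, the Kd fold change (mutant / background; < 1 means
    the mutation increased affinity) and direction; with ``exo_ligand``
    given, swap verdicts for both backgrounds and whether the verdict
    flipped.
    """
    wt_best = best_poses(wt)
    mut_best = best_poses(mut)
    if set(wt_best) != set(mut_best):
        only_wt = sorted(set(wt_best) - set(mut_best))
        only_mut = sorted(set(mut_best) - set(wt_best))
        raise ValueError(
            f"ligand panels differ: only in background {only_wt}; "
            f"only in mutant {only_mut}"
        )
    changes = []
    for lig in sorted(wt_best):
        kd_wt = kd_from_dg(wt_best[lig].delta_g, temperature)
        kd_mut = kd_from_dg(mut_best[lig].delta_g, temperature)
        fold = kd_mut / kd_wt
        if fold < 1.0:
            direction = "increased"
        elif fold > 1.0:
            direction = "decreased"
        else:
            direction = "unchanged"
        changes.append(
            LigandChange(
                ligand=lig,
                ligand_class=wt_best[lig].ligand_class,
                kd_wt=kd_wt,
                kd_mut=kd_mut,
                fold=fold,
                direction=direction,
            )
        )
    background = wt[0].receptor if wt else ""
    mutant = mut[0].receptor if mut else ""
    wt_call = mut_call = None
    verdict_changed = None
    if exo_ligand is not None:
        wt_call = swap_feasibility(wt, exo_ligand, threshold, temperature)
        mut_call = swap_feasibility(mut, exo_ligand, threshold, temperature)
        verdict_changed = wt_call.verdict != mut_call.verdict
    return ScanComparison(
        background=background,
        mutant=mutant,
        changes=changes,
        wt_call=wt_call,
        mut_call=mut_call,
        verdict_changed=verdict_changed,
    )
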