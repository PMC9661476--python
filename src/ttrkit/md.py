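"""Post-processing of molecular-dynamics output for ligand ranking.

Covers the binding-energy bookkeeping used to rank transthyretin (TTR)
ligands from simulation ensembles, contact-frequency statistics with
element-dependent distance cutoffs, even frame sampling, and two
structural metrics of the tetramer interface: the distance between the
two bound ligands' carbonyl carbons (how deep the ligand pair sits in
the thyroxine channel) and the Ser117 side-chain O-O distances across
the dimer-dimer interface.

Sign convention. The MD ranking uses a *positive-favorable* binding
energy: dG_bind = dE_gp + 2*dG_Lsolv with dE_gp = E_TTR + 2*E_L -
E_TTR2L, so larger positive values mean stronger predicted binding
(two ligands bind per tetramer, hence the factors of 2). This is the
opposite sign convention from the solution-thermodynamics ΔG < 0 used
in :mod:`ttrkit.thermo`; do not mix the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CL_CONTACT_CUTOFF, HBOND_CUTOFF

# ---------------------------------------------------------------------------
# Binding-energy bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class EnergyComponents:
    """Ensemble-mean energies feeding the binding-energy formula (kcal/mol)."""

    E_TTR: float
    E_L: float
    E_TTR2L: float
    dG_Lsolv: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.E_TTR, self.E_L, self.E_TTR2L, self.dG_Lsolv)
        if not all(np.isfinite(vals)):
            raise ValueError("energy components must be finite")


def gas_phase_energy(components: EnergyComponents) -> float:
    """Gas-phase interaction energy dE_gp = E_TTR + 2*E_L - E_TTR2L."""
    return components.E_TTR + 2.0 * components.E_L - components.E_TTR2L


def binding_energy(dE_gp: float, dG_Lsolv: float) -> float:
    """dG_bind = dE_gp + 2*dG_Lsolv (positive = stronger predicted binding).

    The solvation term enters twice because two ligands desolvate on
    binding the two symmetric sites; dG_Lsolv is negative, so ligand
    desolvation penalizes binding.
    """
    return dE_gp + 2.0 * dG_Lsolv


def rank_ligands(components: dict[str, EnergyComponents]) -> pd.DataFrame:
    """Rank ligands by predicted binding energy, strongest first.

    Returns a DataFrame indexed 0..n-1 with columns ligand, dE_gp,
    dG_Lsolv, dG_bind, sorted descending by dG_bind; ties broken
    lexicographically by ligand name.
    """
    if not components:
        raise ValueError("need at least one ligand")
    rows = []
    for name, comp in components.items():
        de = gas_phase_energy(comp)
        rows.append(
            {
                "ligand": name,
                "dE_gp": de,
                "dG_Lsolv": comp.dG_Lsolv,
                "dG_bind": binding_energy(de, comp.dG_Lsolv),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["dG_bind", "ligand"], ascending=[False, True], kind="mergesort"
    )
    return df.reset_index(drop=True)


def read_energy_table(path) -> dict[str, EnergyComponents]:
    """Read an energy-components CSV: ligand, E_TTR, E_L, E_TTR2L, dG_Lsolv."""
    df = pd.read_csv(path)
    return {
        str(r["ligand"]): EnergyComponents(
            E_TTR=float(r["E_TTR"]), E_L=float(r["E_L"]),
            E_TTR2L=float(r["E_TTR2L"]), dG_Lsolv=float(r["dG_Lsolv"]),
        )
        for _, r in df.iterrows()
    }


# ---------------------------------------------------------------------------
# Contact statistics
# ---------------------------------------------------------------------------

@dataclass
class ContactSeries:
    """Per-frame donor-acceptor distance series for one contact."""

    frame_times: np.ndarray
    distances: np.ndarray
    donor_label: str = ""
    acceptor_label: str = ""
    partner_element: str = "O"

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.frame_times) != len(self.distances):
            raise ValueError("frame_times and distances must have equal length")
        if len(self.distances) and np.any(self.distances <= 0):
            raise ValueError("distances must be positive")

    @classmethod
    def from_csv(cls, path) -> "ContactSeries":
        df = pd.read_csv(path)
        return cls(
            frame_times=df["time_ns"].to_numpy(),
            distances=df["distance_A"].to_numpy(),
            donor_label=str(df["donor"].iloc[0]) if "donor" in df else "",
            acceptor_label=str(df["acceptor"].iloc[0]) if "acceptor" in df else "",
            partner_element=(
                str(df["partner_element"].iloc[0]) if "partner_element" in df else "O"
            ),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_ns": self.frame_times,
                "distance_A": self.distances,
                "donor": self.donor_label,
                "acceptor": self.acceptor_label,
                "partner_element": self.partner_element,
            }
        ).to_csv(path, index=False)


@dataclass
class ContactSummary:
    """Frequency / min / mean report for one contact."""

    frequency: float  # % of frames in contact
    min_distance: float
    mean_distance: float
    cutoff: float
    n_frames: int


def contact_cutoff(
    partner_element: str,
    hbond_cutoff: float = HBOND_CUTOFF,
    cl_cutoff: float = CL_CONTACT_CUTOFF,
) -> float:
    """3.5 A for chlorine contacts, 3.0 A (hydrogen-bond default) otherwise."""
    return cl_cutoff if partner_element.strip().capitalize() == "Cl" else hbond_cutoff


def contact_frequency(
    series: ContactSeries,
    hbond_cutoff: float = HBOND_CUTOFF,
    cl_cutoff: float = CL_CONTACT_CUTOFF,
    mean_over: str = "contact",
) -> ContactSummary:
    """Summarize a distance series to contact frequency, min and mean distance.

    A frame is in contact when its donor-acceptor distance is at or below
    the cutoff for the partner element. ``mean_over`` selects whether the
    mean distance is taken over contact frames only (default, matching the
    usual trajectory-analysis report) or ``"all"`` frames. The minimum is
    always over all frames.
    """
    if len(series.distances) == 0:
        raise ValueError("empty contact series")
    if mean_over not in ("contact", "all"):
        raise ValueError(f"mean_over must be 'contact' or 'all', got {mean_over!r}")
    cutoff = contact_cutoff(series.partner_element, hbond_cutoff, cl_cutoff)
    d = series.distances
    in_contact = d <= cutoff
    n = len(d)
    freq = 100.0 * in_contact.sum() / n
    if mean_over == "contact" and in_contact.any():
        mean_d = float(d[in_contact].mean())
    else:
        mean_d = float(d.mean())
    return ContactSummary(
        frequency=float(freq),
        min_distance=float(d.min()),
        mean_distance=mean_d,
        cutoff=cutoff,
        n_frames=n,
    )


def sample_frames(total_ns: float, window_ns: float, n_frames: int) -> np.ndarray:
    """Times of n_frames structures evenly sampled from the last window of a run.

    Samples at the end of each stride interval so the final frame of the
    trajectory is always included:
    t_i = total_ns - window_ns + i * (window_ns / n_frames), i = 1..n_frames.
    E.g. a 150 ns run sampled 140x over its last 140 ns gives 11, 12, ..., 150.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if window_ns > total_ns:
        raise ValueError(f"window {window_ns} ns exceeds run length {total_ns} ns")
    if window_ns <= 0:
        raise ValueError("window must be positive")
    stride = window_ns / n_frames
    return total_ns - window_ns + stride * np.arange(1, n_frames + 1)


# ---------------------------------------------------------------------------
# Structural metrics
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    atom_name: str
    res_name: str
    res_id: int
    chain_id: str
    x: float
    y: float
    z: float
    element: str = ""
    hetero: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class StructureFrame:
    """One labeled coordinate frame (tetramer chains A-D plus ligands)."""

    atoms: list

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not np.all(np.isfinite(a.coord)):
                raise ValueError("atom coordinates must be finite")

    def select(self, **criteria) -> list:
        """Atoms matching all given field values (atom_name, res_name, ...)."""
        out = []
        for a in self.atoms:
            if all(getattr(a, k) == v for k, v in criteria.items()):
                out.append(a)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureFrame":
        """Rigidly transform the frame: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = []
        for a in self.atoms:
            xyz = R @ a.coord + t
            atoms.append(
                Atom(a.atom_name, a.res_name, a.res_id, a.chain_id,
                     *xyz, element=a.element, hetero=a.hetero)
            )
        return StructureFrame(atoms)

    # -- PDB round trip via biotite ------------------------------------
    def to_pdb(self, path) -> None:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n = len(self.atoms)
        arr = struc.AtomArray(n)
        arr.coord = np.array([a.coord for a in self.atoms], dtype=np.float32)
        arr.atom_name = np.array([a.atom_name for a in self.atoms])
        arr.res_name = np.array([a.res_name for a in self.atoms])
        arr.res_id = np.array([a.res_id for a in self.atoms])
        arr.chain_id = np.array([a.chain_id for a in self.atoms])
        arr.element = np.array(
            [a.element or a.atom_name[0] for a in self.atoms]
        )
        arr.hetero = np.array([a.hetero for a in self.atoms])
        pdb = PDBFile()
        pdb.set_structure(arr)
        pdb.write(path)

    @classmethod
    def from_pdb(cls, path) -> "StructureFrame":
        from biotite.structure.io.pdb import PDBFile

        arr = PDBFile.read(path).get_structure(model=1)
        atoms = [
            Atom(
                atom_name=str(arr.atom_name[i]),
                res_name=str(arr.res_name[i]),
                res_id=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                x=float(arr.coord[i, 0]),
                y=float(arr.coord[i, 1]),
                z=float(arr.coord[i, 2]),
                element=str(arr.element[i]),
                hetero=bool(arr.hetero[i]),
            )
            for i in range(arr.array_length())
        ]
        return cls(atoms)

    @classmethod
    def from_csv(cls, path) -> "StructureFrame":
        df = pd.read_csv(path)
        atoms = [
            Atom(
                atom_name=str(r["atom_name"]), res_name=str(r["res_name"]),
                res_id=int(r["res_id"]), chain_id=str(r["chain_id"]),
                x=float(r["x"]), y=float(r["y"]), z=float(r["z"]),
                element=str(r.get("element", "") or ""),
            )
            for _, r in df.iterrows()
        ]
        return cls(atoms)


def interligand_depth(
    frame: StructureFrame,
    ligand_res_name: str = "LIG",
    carbonyl_atom: str = "C7",
) -> float:
    """Distance between the carbonyl carbons of the two bound ligands (A).

    A larger separation means the two ligands sit farther out of the
    thyroxine channel; compact stabilizer pairs sit ~15-16 A apart.
    Requires exactly two ligand copies, each with one uniquely named
    carbonyl carbon.
    """
    carbons = frame.select(res_name=ligand_res_name, atom_name=carbonyl_atom)
    if len(carbons) != 2:
        raise ValueError(
            f"expected exactly 2 atoms matching res_name={ligand_res_name!r} "
            f"atom_name={carbonyl_atom!r}, found {len(carbons)}"
        )
    return float(np.linalg.norm(carbons[0].coord - carbons[1].coord))


def ser117_oo_distances(frame: StructureFrame) -> dict[tuple, float]:
    """Ser117 OG-OG distances across the dimer-dimer interface.

    Returns the two facing-pair distances keyed ("A","C") and ("B","D").
    Shorter distances mark a more tightly packed, stabilized tetramer.
    """
    og = {}
    missing = []
    for chain in "ABCD":
        atoms = frame.select(chain_id=chain, res_id=117, atom_name="OG")
        if len(atoms) != 1:
            missing.append(chain)
        else:
            og[chain] = atoms[0].coord
    if missing:
        raise ValueError(f"Ser117 OG missing or ambiguous in chains: {missing}")
    return {
        ("A", "C"): float(np.linalg.norm(og["A"] - og["C"])),
        ("B", "D"): float(np.linalg.norm(og["B"] - og["D"])),
    }
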