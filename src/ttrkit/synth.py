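"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a deterministic function of its parameters and an
explicit seed (one local ``numpy`` Generator per call, no global state),
and each closes a loop with its analyzer: running the analysis on
noiseless generator output returns the generating parameters — exactly
for the algebraic stages, to optimizer precision for the fitted ones.

Defaults emulate the assay conditions the analyzers were designed for:
titrations of 100 uM ligand into 5 uM protein in 2 uL injections at
25 degC, trajectory contact series of ~10^4 frames, urea-unfolding
traces read over four days, and paired control/treated densitometry
from a small donor panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assays import UnfoldingTimeCourse
from .itc import Thermogram, TitrationProtocol, TwoSiteModel, simulate_thermogram, solve_free_ligand
from .md import Atom, ContactSeries, StructureFrame


def gen_thermogram(
    model: TwoSiteModel,
    protocol: TitrationProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Thermogram:
    """Forward-simulated thermogram plus i.i.d. Gaussian heat noise.

    noise_sd is in kcal per mol of injectant; 0 returns the exact
    forward model.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    protocol = protocol or TitrationProtocol()
    tg = simulate_thermogram(model, protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tg = Thermogram(
            molar_ratio=tg.molar_ratio,
            heats=tg.heats + rng.normal(0.0, noise_sd, size=len(tg.heats)),
            injection_volumes=tg.injection_volumes,
        )
    return tg


def gen_contact_series(
    target_freq: float,
    cutoff: float = 3.0,
    n_frames: int = 10_000,
    seed: int = 0,
    partner_element: str = "O",
    dt_ns: float = 1.0,
) -> ContactSeries:
    """Distance series whose contact frequency is Bernoulli(target_freq/100).

    Contact frames draw distances Uniform(cutoff - 0.5, cutoff),
    non-contact frames Uniform(cutoff, cutoff + 2) — shifted just above
    the cutoff so the realized frequency equals the Bernoulli draw.
    """
    if not 0 <= target_freq <= 100:
        raise ValueError("target_freq must be in [0, 100]")
    rng = np.random.default_rng(seed)
    contact = rng.random(n_frames) < target_freq / 100.0
    d = np.where(
        contact,
        rng.uniform(cutoff - 0.5, cutoff, size=n_frames),
        # nextafter: strictly above the cutoff so non-contact frames never count
        rng.uniform(np.nextafter(cutoff, np.inf), cutoff + 2.0, size=n_frames),
    )
    return ContactSeries(
        frame_times=dt_ns * np.arange(1, n_frames + 1),
        distances=d,
        partner_element=partner_element,
    )


def gen_toy_tetramer(
    ser117_AC: float = 5.5,
    ser117_BD: float = 5.4,
    ligand_depth: float = 15.8,
    ligand_res_name: str = "LIG",
    carbonyl_atom: str = "C7",
) -> StructureFrame:
    """Minimal tetramer geometry with prescribed interface distances.

    Four chains A-D each contribute a Ser117 with its side-chain OG;
    the A/C pair sits on the x axis separated by ``ser117_AC``, the B/D
    pair on the y axis separated by ``ser117_BD``, and two one-atom
    ligand residues sit on the z axis ``ligand_depth`` apart. CA atoms
    are added 1.5 A from each OG so chains are not single atoms.
    Placement is deterministic — no randomness, no seed.
    """
    for v in (ser117_AC, ser117_BD, ligand_depth):
        if v <= 0:
            raise ValueError("all requested distances must be positive")
    og = {
        "A": (-ser117_AC / 2.0, 0.0, 0.0),
        "C": (+ser117_AC / 2.0, 0.0, 0.0),
        "B": (0.0, -ser117_BD / 2.0, 0.0),
        "D": (0.0, +ser117_BD / 2.0, 0.0),
    }
    atoms = []
    for chain, xyz in og.items():
        atoms.append(Atom("CA", "SER", 117, chain,
                          xyz[0], xyz[1], xyz[2] + 1.5, element="C"))
        atoms.append(Atom("OG", "SER", 117, chain, *xyz, element="O"))
    for i, z in enumerate((-ligand_depth / 2.0, +ligand_depth / 2.0)):
        atoms.append(Atom(carbonyl_atom, ligand_res_name, 201 + i, "E",
                          0.0, 0.0, z, element="C", hetero=True))
    return StructureFrame(atoms)


def gen_unfolding(
    k: float = 0.05,
    plateau: float = 0.173,
    noise_sd: float = 0.0,
    times=None,
    ref_folded: float = 0.9,
    ref_unfolded: float = 1.6,
    seed: int = 0,
) -> UnfoldingTimeCourse:
    """Mono-exponential unfolding trace mapped back to a 355/335 ratio.

    f(t) = plateau*(1 - exp(-k t)) is converted to the raw fluorescence
    ratio via the declared folded/unfolded references, with Gaussian
    noise of ``noise_sd`` (ratio units) added on top. Default time grid:
    0-96 h, hourly.
    """
    if not 0 <= plateau <= 1:
        raise ValueError("plateau must be in [0, 1]")
    if k < 0 or noise_sd < 0:
        raise ValueError("k and noise_sd must be >= 0")
    t = np.arange(0.0, 97.0) if times is None else np.asarray(times, dtype=float)
    f = plateau * (1.0 - np.exp(-k * t))
    ratio = ref_folded + f * (ref_unfolded - ref_folded)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio + rng.normal(0.0, noise_sd, size=len(ratio))
    return UnfoldingTimeCourse(
        times=t, ratio_355_335=ratio,
        ref_folded=ref_folded, ref_unfolded=ref_unfolded,
    )


def gen_aggregation_response(
    model: TwoSiteModel,
    ttr_uM: float = 3.6,
    conc_grid_uM=None,
    max_agg_pct: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Occupancy-driven aggregation dose-response table.

    Fixture logic (not a literature claim): only fully unliganded
    tetramers are dissociation-competent, so the aggregation percentage
    at each total compound concentration is ``max_agg_pct`` times the
    zero-bound fraction F0 from the two-site equilibrium. The noiseless
    curve is monotone non-increasing in compound concentration.
    """
    if conc_grid_uM is None:
        conc_grid_uM = np.array([0.0, 0.9, 1.8, 3.6, 7.2, 10.0, 20.0])
    conc_grid_uM = np.asarray(conc_grid_uM, dtype=float)
    if np.any(conc_grid_uM < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc_grid_uM:
        st = solve_free_ligand(c * 1e-6, ttr_uM * 1e-6, model)
        agg = max_agg_pct * st.F0
        if noise_sd > 0:
            agg = max(agg + rng.normal(0.0, noise_sd), 0.0)
        rows.append({"conc_uM": c, "aggregation_pct": agg})
    df = pd.DataFrame(rows)
    df["inhibition_pct"] = 100.0 - df["aggregation_pct"].clip(upper=100.0)
    return df


def gen_densitometry(
    effect_pct: float = 30.0,
    baseline_ratio: float = 0.5,
    n_donors: int = 6,
    noise_sd: float = 0.0,
    total_intensity: float = 1000.0,
    compound: str = "compound",
    seed: int = 0,
) -> pd.DataFrame:
    """Paired control/treated IEF densitometry rows for a donor panel.

    Each donor gets a control lane at ``baseline_ratio`` tetramer
    fraction and a treated lane at baseline*(1 + effect_pct/100) plus
    Gaussian ratio noise; ratios escaping (0, 1] are clipped with a
    warning. Ratios are converted to tetramer/monomer band intensities
    at a fixed total lane intensity.
    """
    import warnings

    if not 0 < baseline_ratio < 1:
        raise ValueError("baseline_ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_donors + 1):
        treated = baseline_ratio * (1.0 + effect_pct / 100.0)
        if noise_sd > 0:
            treated += rng.normal(0.0, noise_sd)
        if not 0.0 < treated <= 1.0:
            warnings.warn(
                f"donor {i}: treated ratio {treated:.3f} clipped into (0, 1]",
                stacklevel=2,
            )
            treated = min(max(treated, 1e-6), 1.0)
        for cond, ratio in (("control", baseline_ratio), ("treated", treated)):
            rows.append({
                "donor": f"donor{i}",
                "condition": cond,
                "compound": compound,
                "tetramer_intensity": total_intensity * ratio,
                "monomer_intensity": total_intensity * (1.0 - ratio),
            })
    return pd.DataFrame(rows)
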