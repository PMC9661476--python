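"""Shared fixtures: published reference tables encoded as in-memory data."""

import pytest

from ttrkit.md import EnergyComponents
from ttrkit.thermo import BindingThermodynamics


@pytest.fixture
def itc_thermo_rows():
    """Published two-site ITC thermodynamics for the TTR ligand panel.

    Columns: ligand, Kd (M, stepwise site constant), ΔG, ΔH, −TΔS
    (kcal/mol) at 298.15 K. Tafamidis contributes one row per binding
    step (negative cooperativity).
    """
    rows = [
        ("tolcapone", 34e-9, -10.2, -12.8, 2.6),
        ("tafamidis-site1", 9.9e-9, -10.9, -6.0, -4.9),
        ("tafamidis-site2", 260e-9, -9.0, -6.5, -2.5),
        ("M-14", 310e-9, -8.9, -9.2, 0.3),
        ("M-17", 31e-9, -10.3, -14.0, 3.7),
        ("M-20", 85e-9, -9.7, -11.7, 2.0),
        ("M-21", 26e-9, -10.4, -11.3, 0.9),
        ("M-23", 6.2e-9, -11.2, -16.6, 5.4),
    ]
    return [
        BindingThermodynamics(ligand=n, kd=kd, dG=dg, dH=dh, minus_TdS=ts)
        for n, kd, dg, dh, ts in rows
    ]


@pytest.fixture
def md_energy_table():
    """Published MD energy decomposition per ligand.

    (ΔEgp, ΔGL-solv, ΔGbind) in kcal/mol; E_TTR/E_L chosen so that
    E_TTR + 2·E_L − E_TTR2L reproduces the printed ΔEgp (only the
    combination is published).
    """
    printed = {
        # ligand: (dE_gp, dG_Lsolv, dG_bind)
        "tolcapone": (81.5, -10.9, 59.7),
        "M-14": (76.6, -10.6, 55.4),
        "M-17": (90.2, -11.1, 68.0),
        "M-20": (79.0, -11.0, 57.0),
        "M-21": (95.2, -10.6, 74.0),
        "M-23": (116.2, -15.9, 84.4),
    }
    components = {
        name: EnergyComponents(
            E_TTR=-1000.0, E_L=-50.0, E_TTR2L=-1100.0 - de, dG_Lsolv=ds
        )
        for name, (de, ds, _) in printed.items()
    }
    return components, printed
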