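"""Binding-thermodynamics bookkeeping shared by all pipeline stages.

Converts between dissociation constants and free energies of binding
(ΔG = RT ln Kd, 1 M standard state), decomposes Gibbs energy into
enthalpic and entropic terms (ΔG = ΔH − TΔS), and validates printed
thermodynamic tables for internal consistency.

Sign convention: ΔG < 0 favorable, the usual solution-thermodynamics
convention. (The MD-derived ranking in :mod:`ttrkit.md` uses the
opposite, positive-favorable bookkeeping; see that module's docs.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .constants import R_KCAL, T_STANDARD

#: Tolerance (kcal/mol) for ΔG vs ΔH + (−TΔS): absorbs 1-decimal rounding.
SUM_TOL = 0.05
#: Tolerance (kcal/mol) for ΔG vs RT ln Kd: absorbs 2-significant-figure Kd.
RTLN_TOL = 0.08


@dataclass
class BindingThermodynamics:
    """One ligand-protein interaction's thermodynamic signature.

    Parameters
    ----------
    dG, dH, minus_TdS : float
        Free energy, enthalpy and entropic term (−TΔS) of binding, kcal/mol.
    kd : float or None
        Dissociation constant in molar; optional.
    temperature : float
        Kelvin.
    ligand : str
        Label used in reports.
    """

    dG: float
    dH: float
    minus_TdS: float
    kd: float | None = None
    temperature: float = T_STANDARD
    ligand: str = ""

    def __post_init__(self) -> None:
        if self.kd is not None and self.kd <= 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


def free_energy_from_kd(kd: float, temperature: float = T_STANDARD) -> float:
    """Free energy of binding ΔG = RT ln Kd (kcal/mol, 1 M standard state).

    Negative for sub-molar dissociation constants; e.g. Kd = 6.2 nM at
    298.15 K gives −11.20 kcal/mol.
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature * math.log(kd)


def gibbs_from_components(dH: float, minus_TdS: float) -> float:
    """ΔG = ΔH + (−TΔS); both terms in kcal/mol."""
    return dH + minus_TdS


def fold_affinity(kd_ref: float, kd_test: float) -> float:
    """Affinity of the test ligand relative to the reference, Kd_ref / Kd_test.

    > 1 means the test ligand binds tighter than the reference.
    """
    if kd_ref <= 0 or kd_test <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_ref / kd_test


@dataclass
class ConsistencyReport:
    """Per-row result of :func:`validate_thermo_table`."""

    ligand: str
    sum_residual: float
    sum_ok: bool
    rtln_residual: float | None = None
    rtln_ok: bool | None = None
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = self.sum_ok and (self.rtln_ok is not False)


def validate_thermo_table(
    rows: list[BindingThermodynamics],
    sum_tol: float = SUM_TOL,
    rtln_tol: float = RTLN_TOL,
) -> list[ConsistencyReport]:
    """Check each row for ΔG = ΔH + (−TΔS) and (when Kd is given) ΔG = RT ln Kd.

    The two checks carry separate tolerances because printed tables round
    ΔG/ΔH/−TΔS to one decimal and Kd to two significant figures; the RT-ln
    check is skipped for rows without a Kd.
    """
    reports: list[ConsistencyReport] = []
    for row in rows:
        sum_res = abs(row.dG - gibbs_from_components(row.dH, row.minus_TdS))
        rtln_res = rtln_ok = None
        if row.kd is not None:
            rtln_res = abs(row.dG - free_energy_from_kd(row.kd, row.temperature))
            rtln_ok = rtln_res <= rtln_tol
        reports.append(
            ConsistencyReport(
                ligand=row.ligand,
                sum_residual=sum_res,
                sum_ok=sum_res <= sum_tol,
                rtln_residual=rtln_res,
                rtln_ok=rtln_ok,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_thermo_table(path) -> list[BindingThermodynamics]:
    """Read a thermodynamic table CSV.

    Columns: ligand, kd_nM (optional/blank allowed), dG_kcal, dH_kcal,
    minus_TdS_kcal, temperature_K (optional, defaults to 298.15).
    """
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        kd_nM = r.get("kd_nM")
        kd = None if kd_nM is None or pd.isna(kd_nM) else float(kd_nM) * 1e-9
        temp = r.get("temperature_K")
        temp = T_STANDARD if temp is None or pd.isna(temp) else float(temp)
        rows.append(
            BindingThermodynamics(
                ligand=str(r["ligand"]),
                kd=kd,
                dG=float(r["dG_kcal"]),
                dH=float(r["dH_kcal"]),
                minus_TdS=float(r["minus_TdS_kcal"]),
                temperature=temp,
            )
        )
    return rows


def reports_to_frame(reports: list[ConsistencyReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ligand": [r.ligand for r in reports],
            "sum_residual_kcal": [r.sum_residual for r in reports],
            "sum_ok": [r.sum_ok for r in reports],
            "rtln_residual_kcal": [r.rtln_residual for r in reports],
            "rtln_ok": [r.rtln_ok for r in reports],
            "passed": [r.passed for r in reports],
        }
    )
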