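"""Densitometry statistics for plasma-level TTR assays and solubility.

Isoelectric focusing under semidenaturing conditions separates the TTR
tetramer from monomer; the band densitometry gives a tetramer fraction
per sample, and tetramer stabilization is the relative increase of
that fraction in the compound-treated sample over the untreated control
from the same donor. The radiolabeled-thyroxine competition assay
distributes T4 among its three plasma carriers (TBG, albumin, TTR);
displacement of T4 from the TTR band reports ligand occupancy of the
thyroxine sites in whole plasma. Solubility assays weigh solid compound
into water to dissolution; results are mg/mL per replicate plus a mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# IEF tetramer stabilization
# ---------------------------------------------------------------------------

@dataclass
class IEFDensitometry:
    """Net band volumes of one IEF lane (background already subtracted)."""

    tetramer_intensity: float
    monomer_intensity: float
    sample_id: str = ""
    condition: str = "control"  # or "treated"
    donor: str = ""

    def __post_init__(self) -> None:
        if self.tetramer_intensity < 0 or self.monomer_intensity < 0:
            raise ValueError("band intensities must be >= 0")
        if self.tetramer_intensity + self.monomer_intensity <= 0:
            raise ValueError("total band intensity must be positive")


def tetramer_ratio(d: IEFDensitometry) -> float:
    """Tetramer over total TTR (tetramer + monomer), in [0, 1]."""
    total = d.tetramer_intensity + d.monomer_intensity
    if total <= 0:
        raise ValueError("total band intensity must be positive")
    return d.tetramer_intensity / total


def stabilization_percent(ratio_treated: float, ratio_control: float) -> float:
    """Tetramer stabilization: 100*(treated - control)/control.

    Treated and control lanes must come from the same donor; negative
    values mean destabilization.
    """
    if ratio_control <= 0:
        raise ValueError("control tetramer ratio must be positive")
    return 100.0 * (ratio_treated - ratio_control) / ratio_control


def stabilization_by_donor(df: pd.DataFrame) -> pd.DataFrame:
    """Per-donor stabilization percentages from a paired IEF table.

    Input columns: donor, condition ('control'/'treated'), compound,
    tetramer_intensity, monomer_intensity. Each donor needs exactly one
    control lane and one treated lane per compound.
    """
    out = []
    for (donor, compound), grp in df.groupby(["donor", "compound"], dropna=False):
        ctrl = grp[grp["condition"] == "control"]
        trt = grp[grp["condition"] == "treated"]
        if len(ctrl) != 1 or len(trt) != 1:
            raise ValueError(
                f"donor {donor!r} / compound {compound!r}: need exactly one "
                "control and one treated lane"
            )
        rc = tetramer_ratio(IEFDensitometry(
            float(ctrl["tetramer_intensity"].iloc[0]),
            float(ctrl["monomer_intensity"].iloc[0]),
        ))
        rt = tetramer_ratio(IEFDensitometry(
            float(trt["tetramer_intensity"].iloc[0]),
            float(trt["monomer_intensity"].iloc[0]),
        ))
        out.append({
            "donor": donor, "compound": compound,
            "ratio_control": rc, "ratio_treated": rt,
            "stabilization_pct": stabilization_percent(rt, rc),
        })
    return pd.DataFrame(out)


def stabilization_anova(df: pd.DataFrame) -> dict:
    """Group means +/- SEM and pairwise Tukey HSD across compounds.

    Standard one-way-ANOVA follow-up on per-donor stabilization
    percentages (column ``stabilization_pct`` grouped by ``compound``);
    a plain statsmodels report, not a contribution of this package.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = df.groupby("compound")["stabilization_pct"]
    summary = groups.agg(["mean", "sem", "count"]).reset_index()
    result = {"group_summary": summary, "tukey": None}
    if df["compound"].nunique() >= 2 and (groups.count() >= 2).all():
        tk = pairwise_tukeyhsd(df["stabilization_pct"], df["compound"])
        result["tukey"] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return result


# ---------------------------------------------------------------------------
# T4 binding competition
# ---------------------------------------------------------------------------

@dataclass
class T4Densitometry:
    """Band intensities of the three T4 plasma carriers in one lane."""

    tbg: float
    alb: float
    ttr: float
    condition: str = "control"

    def __post_init__(self) -> None:
        if min(self.tbg, self.alb, self.ttr) < 0:
            raise ValueError("band intensities must be >= 0")
        if self.tbg + self.alb + self.ttr <= 0:
            raise ValueError("total band intensity must be positive")

    @property
    def ttr_fraction(self) -> float:
        return self.ttr / (self.tbg + self.alb + self.ttr)


def t4_bound_fraction(d: T4Densitometry, control: T4Densitometry) -> float:
    """TTR-bound T4 fraction normalized to the untreated (negative) control.

    1.0 means no displacement; displacement % = 100*(1 - result).
    """
    if control.ttr_fraction <= 0:
        raise ValueError("control TTR fraction must be positive")
    return d.ttr_fraction / control.ttr_fraction


def t4_displacement_percent(d: T4Densitometry, control: T4Densitometry) -> float:
    """Percent of T4 displaced from TTR relative to the control."""
    return 100.0 * (1.0 - t4_bound_fraction(d, control))


# ---------------------------------------------------------------------------
# Solubility
# ---------------------------------------------------------------------------

@dataclass
class SolubilityAssay:
    """One dissolution replicate: solid weight (mg) into water (mL)."""

    solid_weight: float
    water_volume: float

    def __post_init__(self) -> None:
        if self.solid_weight <= 0 or self.water_volume <= 0:
            raise ValueError("weight and volume must be positive")


def _round3(x: float) -> float:
    """Round half away from zero to 3 decimals (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def solubility(assays: list[SolubilityAssay]) -> dict:
    """Per-replicate solubility (mg/mL) and their mean, rounded to 3 decimals."""
    if not assays:
        raise ValueError("need at least one assay")
    per = [a.solid_weight / a.water_volume for a in assays]
    return {
        "per_assay_mg_per_mL": [_round3(v) for v in per],
        "mean_mg_per_mL": _round3(float(np.mean(per))),
    }
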