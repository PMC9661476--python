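"""Statistics for tetramer-dissociation kinetics, aggregation and viability assays.

Urea-induced tetramer dissociation is followed by the tryptophan
fluorescence 355/335 nm intensity ratio, which red-shifts as the
tetramer dissociates and the released monomers unfold. The ratio is
normalized between a fully folded reference and the fully unfolded
96 h control, giving an unfolded fraction f(t) in [0, 1]. Because
tetramer dissociation is the rate-limiting first-order step of the
amyloid cascade, the time course is modeled as a mono-exponential
approach to a plateau,

    f(t) = plateau * (1 - exp(-k_obs * t)),

and "protection" by a kinetic stabilizer is the complement of that
plateau, 100*(1 - plateau) percent of tetramers never unfolding on
the assay timescale.

Acid-mediated aggregation is quantified by 340 nm turbidity relative
to a compound-free control, with compound-only blanks subtracted
because some ligands absorb at 340 nm themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator


# ---------------------------------------------------------------------------
# Urea-dissociation kinetics
# ---------------------------------------------------------------------------

@dataclass
class UnfoldingTimeCourse:
    """355/335 fluorescence ratio vs time with folded/unfolded references."""

    times: np.ndarray  # hours
    ratio_355_335: np.ndarray
    ref_folded: float
    ref_unfolded: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratio_355_335 = np.asarray(self.ratio_355_335, dtype=float)
        if self.ref_unfolded <= self.ref_folded:
            raise ValueError("ref_unfolded must exceed ref_folded")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    @classmethod
    def from_csv(cls, path) -> "UnfoldingTimeCourse":
        """CSV with columns time_h, ratio_355_335 and either header comment
        lines '# ref_folded=..' / '# ref_unfolded=..' or ref columns."""
        refs = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "=" in line:
                    key, val = line.lstrip("#").strip().split("=")
                    refs[key.strip()] = float(val)
                elif not line.startswith("#"):
                    break
        df = pd.read_csv(path, comment="#")
        ref_folded = refs.get("ref_folded", df.get("ref_folded", pd.Series([np.nan])).iloc[0])
        ref_unfolded = refs.get("ref_unfolded", df.get("ref_unfolded", pd.Series([np.nan])).iloc[0])
        return cls(
            times=df["time_h"].to_numpy(),
            ratio_355_335=df["ratio_355_335"].to_numpy(),
            ref_folded=float(ref_folded),
            ref_unfolded=float(ref_unfolded),
        )


def fraction_unfolded(course: UnfoldingTimeCourse) -> np.ndarray:
    """Normalize the 355/335 ratio to an unfolded fraction in [0, 1].

    f(t) = (r(t) - ref_folded) / (ref_unfolded - ref_folded), clipped to
    [0, 1]; 0 = fully folded, 1 = the 96 h fully unfolded control.
    """
    span = course.ref_unfolded - course.ref_folded
    if span <= 0:
        raise ValueError("ref_unfolded must exceed ref_folded")
    f = (course.ratio_355_335 - course.ref_folded) / span
    return np.clip(f, 0.0, 1.0)


@dataclass
class DissociationFit:
    """Mono-exponential dissociation fit: rate, plateau and protection."""

    k_obs: float  # 1/h
    plateau: float
    protection_pct: float
    rss: float = 0.0
    converged: bool = True


class DissociationKineticsFitter(BaseEstimator):
    """Least-squares fit of f(t) = plateau*(1 - exp(-k t)) to unfolding data.

    Attributes (after :meth:`fit`): ``k_obs_``, ``plateau_``,
    ``protection_pct_`` = 100*(1 - plateau), and ``result_``.

    ``protection`` selects the protection definition: ``"plateau"``
    (default) uses the fitted plateau complement; ``"endpoint"`` uses
    1 - f at the last observed time.
    """

    def __init__(self, protection: str = "plateau"):
        self.protection = protection

    def fit(self, X, y=None) -> "DissociationKineticsFitter":
        """X: array of times (hours); y: unfolded fractions in [0, 1]."""
        if self.protection not in ("plateau", "endpoint"):
            raise ValueError(f"unknown protection mode {self.protection!r}")
        t = np.asarray(X, dtype=float)
        f = np.asarray(y, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fractions must be equal-length 1-D arrays")
        if len(t) < 4:
            raise ValueError("need at least 4 time points")
        if np.any((f < -1e-9) | (f > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")

        if np.allclose(f, 0.0):  # fully protected: plateau pinned at 0
            self.k_obs_ = 0.0
            self.plateau_ = 0.0
            self.protection_pct_ = 100.0
            self.result_ = DissociationFit(0.0, 0.0, 100.0, rss=float(np.sum(f**2)))
            return self

        def model(p):
            k, plateau = p
            return plateau * (1.0 - np.exp(-k * t))

        p0 = np.array([max(1.0 / max(t.max(), 1e-9), 1e-3), min(max(f.max(), 1e-3), 1.0)])
        res = least_squares(
            lambda p: model(p) - f, p0,
            bounds=([0.0, 0.0], [np.inf, 1.0]),
            ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=10000,
        )
        k, plateau = res.x
        if self.protection == "plateau":
            prot = 100.0 * (1.0 - plateau)
        else:
            prot = 100.0 * (1.0 - float(f[-1]))
        self.k_obs_ = float(k)
        self.plateau_ = float(plateau)
        self.protection_pct_ = float(prot)
        self.result_ = DissociationFit(
            k_obs=self.k_obs_, plateau=self.plateau_,
            protection_pct=self.protection_pct_,
            rss=float(2.0 * res.cost), converged=bool(res.success),
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted unfolded fraction at the given times."""
        if not hasattr(self, "k_obs_"):
            raise RuntimeError("fit the estimator first")
        t = np.asarray(X, dtype=float)
        return self.plateau_ * (1.0 - np.exp(-self.k_obs_ * t))


def fit_dissociation(times, fractions, protection: str = "plateau") -> DissociationFit:
    """Thin functional wrapper over :class:`DissociationKineticsFitter`."""
    return DissociationKineticsFitter(protection=protection).fit(times, fractions).result_


# ---------------------------------------------------------------------------
# Aggregation turbidity
# ---------------------------------------------------------------------------

@dataclass
class AggregationMeasurement:
    """One turbidity measurement with its blanks (absorbance at 340 nm)."""

    a340_sample: float
    a340_compound_blank: float
    a340_control: float
    a340_buffer_blank: float = 0.0
    compound_conc: float = 0.0  # uM

    def __post_init__(self) -> None:
        for v in (self.a340_sample, self.a340_compound_blank,
                  self.a340_control, self.a340_buffer_blank):
            if v < 0:
                raise ValueError("absorbances must be >= 0")


def aggregation_percent(m: AggregationMeasurement) -> float:
    """Aggregation relative to the compound-free control, percent.

    100 * (sample - compound blank) / (control - buffer blank); the
    compound blank carries the same compound concentration but no
    protein, correcting for compounds that absorb at 340 nm. Negative
    corrected turbidities (instrument noise at full inhibition) are
    clipped to 0 with a warning.
    """
    control = m.a340_control - m.a340_buffer_blank
    if control <= 0:
        raise ValueError("corrected control turbidity must be positive")
    sample = m.a340_sample - m.a340_compound_blank
    if sample < 0:
        warnings.warn("negative corrected turbidity clipped to 0", stacklevel=2)
        sample = 0.0
    return 100.0 * sample / control


def inhibition_percent(aggregation_pct: float) -> float:
    """Aggregation inhibition = 100 - aggregation %, floored at 0."""
    if aggregation_pct < 0:
        raise ValueError("aggregation percentage must be >= 0")
    return max(100.0 - aggregation_pct, 0.0)


def process_aggregation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add aggregation_pct / inhibition_pct columns to an aggregation CSV table."""
    out = df.copy()
    aggs = []
    for _, r in df.iterrows():
        m = AggregationMeasurement(
            a340_sample=float(r["a340_sample"]),
            a340_compound_blank=float(r["a340_compound_blank"]),
            a340_control=float(r["a340_control"]),
            a340_buffer_blank=float(r.get("a340_buffer_blank", 0.0)),
            compound_conc=float(r.get("conc_uM", 0.0)),
        )
        aggs.append(aggregation_percent(m))
    out["aggregation_pct"] = aggs
    out["inhibition_pct"] = [inhibition_percent(a) for a in aggs]
    return out


# ---------------------------------------------------------------------------
# Cell viability
# ---------------------------------------------------------------------------

def viability_percent(intensity: float, mean_blank: float, mean_control: float) -> float:
    """Cell viability: (sample - blank) / (control - blank) * 100, uncapped."""
    denom = mean_control - mean_blank
    if denom == 0:
        raise ValueError("control and blank intensities coincide")
    return 100.0 * (intensity - mean_blank) / denom
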