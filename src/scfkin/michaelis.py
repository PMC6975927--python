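"""Multi-turnover velocities, Michaelis-Menten fits and efficiency ratios.

In the multi-turnover assay a fixed, limiting amount of ligase-substrate
complex is titrated with a 2-fold dilution series of the E2 or E3 under
study, so the titrated enzyme plays the role of [S] in the Michaelis-
Menten equation v = kcat.[S]/(Km + [S]).  Velocities are derived from
the fraction of radiolabelled substrate converted within the incubation
time, normalised by substrate and ligase concentrations; points are kept
in the initial-rate regime by requiring no more than 20% conversion.

Catalytic efficiency kobs/Km (per molar per second) combines a
pre-steady-state transfer rate with a Michaelis constant and is the
basis for comparing chain-elongating enzymes; fold ratios of rates or
efficiencies are reported alongside their integer rounding.

Concentrations are nanomolar, times minutes, kcat per minute; the
efficiency converts to M^-1 s^-1 internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._exceptions import ConvergenceWarning, OverConversionWarning, ValidationError

__all__ = [
    "VelocityPoint",
    "reaction_velocity",
    "MMDataset",
    "MichaelisMentenModel",
    "MichaelisMentenResults",
    "fit_michaelis",
    "EfficiencyRecord",
    "catalytic_efficiency",
    "fold_ratio",
]

#: initial-rate regime bound on fraction of substrate converted
MAX_CONVERSION = 0.20


@dataclass(frozen=True)
class VelocityPoint:
    """One titration point of a multi-turnover assay.

    ``velocity`` (per minute) is derived on construction:
    fraction_converted x [substrate] / ([SCF] x time).
    """

    enzyme_conc: float  # nM, the titrated E2/E3
    fraction_converted: float
    substrate_conc: float  # nM
    scf_conc: float  # nM
    incubation_time: float  # minutes
    velocity: float = field(init=False)
    over_converted: bool = field(init=False)

    def __post_init__(self):
        for name in ("enzyme_conc", "substrate_conc", "scf_conc"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.incubation_time <= 0:
            raise ValidationError("incubation_time must be positive")
        if not 0 <= self.fraction_converted <= 1:
            raise ValidationError("fraction_converted must lie in [0, 1]")
        v, flag = _velocity(self.fraction_converted, self.substrate_conc,
                            self.scf_conc, self.incubation_time)
        object.__setattr__(self, "velocity", v)
        object.__setattr__(self, "over_converted", flag)


def _velocity(fraction_converted, substrate_conc, scf_conc, time):
    flag = fraction_converted > MAX_CONVERSION
    v = fraction_converted * substrate_conc / (scf_conc * time)
    return float(v), bool(flag)


def reaction_velocity(fraction_converted: float, substrate_conc: float,
                      scf_conc: float, time: float) -> float:
    """Per-minute turnover from fraction of substrate converted.

    velocity = fraction x [substrate] / ([SCF] x time).  Emits an
    `OverConversionWarning` when more than 20% of the substrate was
    consumed, where the initial-rate assumption starts to fail.
    """
    if time <= 0:
        raise ValidationError("time must be positive")
    if scf_conc <= 0:
        raise ValidationError("scf_conc must be positive")
    if substrate_conc <= 0:
        raise ValidationError("substrate_conc must be positive")
    if not 0 <= fraction_converted <= 1:
        raise ValidationError("fraction_converted must lie in [0, 1]")
    v, flag = _velocity(fraction_converted, substrate_conc, scf_conc, time)
    if flag:
        warnings.warn(
            f"fraction_converted={fraction_converted:.2f} exceeds the 20% "
            "initial-rate bound", OverConversionWarning,
        )
    return v


@dataclass
class MMDataset:
    """Titration series ([enzyme] in nM, velocity per minute)."""

    points: list[VelocityPoint]
    substrate: str = ""

    def __post_init__(self):
        if len({p.enzyme_conc for p in self.points}) < 3:
            raise ValidationError(
                "insufficient titration points: need at least 3 distinct "
                "enzyme concentrations"
            )

    @property
    def conc(self) -> np.ndarray:
        return np.array([p.enzyme_conc for p in self.points])

    @property
    def velocity(self) -> np.ndarray:
        return np.array([p.velocity for p in self.points])

    @property
    def any_over_converted(self) -> bool:
        return any(p.over_converted for p in self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "enzyme_conc_nM": self.conc,
            "fraction_converted": [p.fraction_converted for p in self.points],
            "substrate_conc_nM": [p.substrate_conc for p in self.points],
            "scf_conc_nM": [p.scf_conc for p in self.points],
            "time_min": [p.incubation_time for p in self.points],
            "velocity_per_min": self.velocity,
        })


@dataclass
class MichaelisMentenResults:
    """Km (nM), kcat (1/min) estimates with SEs and R-squared."""

    model: "MichaelisMentenModel"
    Km: float
    kcat: float
    Km_se: float
    kcat_se: float
    r_squared: float
    converged: bool

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.kcat * conc / (self.Km + conc)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.array([
            [self.Km - z * self.Km_se, self.Km + z * self.Km_se],
            [self.kcat - z * self.kcat_se, self.kcat + z * self.kcat_se],
        ])

    def to_dict(self) -> dict:
        return {
            "Km_nM": self.Km, "Km_se_nM": self.Km_se,
            "kcat_per_min": self.kcat, "kcat_se_per_min": self.kcat_se,
            "r_squared": self.r_squared, "converged": self.converged,
        }

    def summary(self) -> str:
        return "\n".join([
            "Michaelis-Menten fit",
            "=" * 40,
            f"n points:   {len(self.model.data.points)}",
            f"Km:         {self.Km:.4g} nM (SE {self.Km_se:.3g})",
            f"kcat:       {self.kcat:.4g} 1/min (SE {self.kcat_se:.3g})",
            f"R-squared:  {self.r_squared:.3f}",
            f"Converged:  {self.converged}",
        ])


class MichaelisMentenModel:
    """Nonlinear least-squares fit of v = kcat.[E]/(Km + [E]).

    Initialised at Km = median titration concentration and
    kcat = 1.2 x the largest observed velocity.
    """

    def __init__(self, data: MMDataset):
        self.data = data
        conc, v = data.conc, data.velocity
        if np.ptp(v) == 0:
            raise ValidationError("degenerate titration: velocities are flat")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, substrate: str = ""
                       ) -> "MichaelisMentenModel":
        """Build from columns enzyme_conc_nM, fraction_converted,
        substrate_conc_nM, scf_conc_nM, time_min."""
        pts = [
            VelocityPoint(
                enzyme_conc=row["enzyme_conc_nM"],
                fraction_converted=row["fraction_converted"],
                substrate_conc=row["substrate_conc_nM"],
                scf_conc=row["scf_conc_nM"],
                incubation_time=row["time_min"],
            )
            for _, row in df.iterrows()
        ]
        return cls(MMDataset(pts, substrate=substrate))

    def fit(self) -> MichaelisMentenResults:
        conc, v = self.data.conc, self.data.velocity
        p0 = (float(np.median(conc)), 1.2 * float(v.max()))
        converged = True
        try:
            popt, pcov = optimize.curve_fit(
                lambda c, Km, kcat: kcat * c / (Km + c),
                conc, v, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            warnings.warn("Michaelis-Menten fit did not converge",
                          ConvergenceWarning)
            converged = False
            popt = np.array(p0)
            pcov = np.full((2, 2), np.nan)
        Km, kcat = popt
        if not (conc.min() < Km < conc.max()):
            warnings.warn(
                "fitted Km lies outside the titrated concentration range; "
                "the estimate is extrapolated", UserWarning,
            )
        pred = kcat * conc / (Km + conc)
        ss_res = float(np.sum((v - pred) ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        return MichaelisMentenResults(
            model=self, Km=float(Km), kcat=float(kcat),
            Km_se=float(se[0]), kcat_se=float(se[1]),
            r_squared=r2, converged=converged,
        )


def fit_michaelis(data: MMDataset) -> MichaelisMentenResults:
    """Functional wrapper around `MichaelisMentenModel.fit`."""
    return MichaelisMentenModel(data).fit()


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class EfficiencyRecord:
    """Catalytic efficiency kobs/Km in M^-1 s^-1."""

    kobs: float  # 1/s
    Km: float  # nM
    efficiency: float  # M^-1 s^-1, unrounded
    rounded: float  # to significant figures used for reporting
    sig_figs: int


def catalytic_efficiency(kobs: float, Km: float, sig_figs: int = 2
                         ) -> EfficiencyRecord:
    """kobs (1/s) divided by Km (nM converted to M).

    The unrounded value is retained; ``rounded`` carries the
    2-significant-figure presentation used in comparative tables.
    """
    if Km <= 0:
        raise ValidationError("Km must be positive")
    if kobs < 0:
        raise ValidationError("kobs must be non-negative")
    eff = kobs / (Km * 1e-9)
    return EfficiencyRecord(
        kobs=float(kobs), Km=float(Km), efficiency=float(eff),
        rounded=_round_sig(eff, sig_figs), sig_figs=sig_figs,
    )


def fold_ratio(a: float, b: float) -> tuple[float, int]:
    """Ratio a/b with its integer-rounded fold, e.g. (50.0, 50)."""
    if b <= 0:
        raise ValidationError("denominator must be positive")
    r = a / b
    return float(r), int(round(r))
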