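"""Seeded generators emulating each experimental data stream.

Every generator is the measurable inverse of its analysis stage: at zero
noise the downstream fit or arithmetic recovers the generating
parameters exactly, which anchors the parameter-recovery tests.

Quench-flow noise is applied to raw band intensities (densitometry is a
photon/phosphor signal, so noise lives on bands, not fractions) before
lane renormalisation; this induces the mild anticorrelation between
species fractions seen in real lane data.  Multi-turnover velocities and
SRM ratios carry multiplicative (CV) noise.  Screen scores are Gaussian
around zero with planted synthetic-lethal effects added to the
experimental table.

The `FIXTURES` catalog names the published parameter sets (chain rates
in 1/s; Km in nM with kcat in 1/min) so tests and the command line can
refer to a scenario like ``arih1_cycE`` by name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ValidationError
from .chain import RateSet, TimeCourse, closed_form_fractions
from .michaelis import MMDataset, VelocityPoint
from .screen import GeneScoreTable
from .srm import (
    SRMSample,
    cell_volume_from_diameter,
)
from scipy.constants import Avogadro

__all__ = [
    "NoiseSpec",
    "gen_quenchflow",
    "gen_mm_titration",
    "gen_srm",
    "gen_screen",
    "FIXTURES",
    "default_times",
]

#: densitometry scale for synthetic band intensities
BAND_SCALE = 1e4


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model shared by the generators.

    additive_sd   - SD of additive Gaussian noise on fractions (applied
                    at BAND_SCALE on raw band intensities for gels).
    multiplicative_cv - CV of multiplicative noise on velocities/ratios.
    replicates    - number of technical replicates to emit.
    seed          - RNG seed; identical seeds give identical datasets.
    """

    additive_sd: float = 0.0
    multiplicative_cv: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.additive_sd < 0 or self.multiplicative_cv < 0:
            raise ValidationError("noise magnitudes must be non-negative")
        if self.replicates < 1:
            raise ValidationError("replicates must be at least 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# Published parameter sets used as named scenarios.  Chain rates are the
# saturating-enzyme kobs estimates (1/s) for successive transfers; Km is
# nM, kcat 1/min.
FIXTURES: dict[str, dict] = {
    "arih1_cycE": {
        "rates": (0.5, 0.2, 0.08), "Km": 149.0, "kcat": 0.29,
        "enzyme": "ARIH1", "substrate": "Cyclin E",
    },
    "arih1_bcat": {
        "rates": (0.2, 0.3), "Km": 486.0, "kcat": 0.32,
        "enzyme": "ARIH1", "substrate": "beta-Catenin",
    },
    "ube2d3_cycE": {
        "rates": (0.1, 0.2), "Km": 1673.0, "kcat": 0.77,
        "enzyme": "UBE2D3", "substrate": "Cyclin E",
    },
    "ube2d3_bcat": {
        "rates": (5.0, 0.2), "Km": 488.0, "kcat": 1.9,
        "enzyme": "UBE2D3", "substrate": "beta-Catenin",
    },
    "ube2r2_sat": {
        "rates": (0.2, 40.0, 4.0), "Km": 317.0, "kcat": 3.7,
        "enzyme": "UBE2R2", "substrate": "Ub-Cyclin E",
    },
    "ube2r2_bcat": {
        "rates": (0.1, 30.0, 7.0), "Km": 292.0, "kcat": 3.2,
        "enzyme": "UBE2R2", "substrate": "Ub-beta-Catenin",
    },
    "ube2g1_ubcycE": {
        "rates": (1.0, 1.0), "Km": 1300.0, "kcat": 2.3,
        "enzyme": "UBE2G1", "substrate": "Ub-Cyclin E",
    },
}


def default_times(n: int = 13) -> np.ndarray:
    """Log-spaced quench-flow grid, 0.01-10 s."""
    return np.geomspace(0.01, 10.0, n)


def gen_quenchflow(rates, times=None, noise: NoiseSpec | None = None
                   ) -> list[TimeCourse]:
    """Synthetic duplicate densitometry time courses.

    Closed-form fractions are scaled to band intensities, perturbed with
    additive Gaussian noise (negatives clipped to zero), and renormalised
    per lane, one `TimeCourse` per replicate.
    """
    if not isinstance(rates, RateSet):
        rates = RateSet(rates)
    if times is None:
        times = default_times()
    noise = noise or NoiseSpec()
    rng = noise.rng()
    truth = closed_form_fractions(rates, times)
    out = []
    for r in range(noise.replicates):
        bands = truth.fractions * BAND_SCALE
        if noise.additive_sd > 0:
            bands = bands + rng.normal(
                0.0, noise.additive_sd * BAND_SCALE, size=bands.shape
            )
            bands = np.clip(bands, 0.0, None)
        sums = bands.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValidationError("noise produced an all-zero lane; lower sd")
        out.append(TimeCourse(
            times=np.asarray(times, dtype=float),
            fractions=bands / sums,
            replicate_id=f"rep{r + 1}",
            species_names=list(truth.species_names),
        ))
    return out


def gen_mm_titration(
    kcat: float, Km: float, scf_conc: float, substrate_conc: float,
    top_conc: float, n_dilutions: int = 10, time: float = 2.0,
    noise: NoiseSpec | None = None, substrate: str = "",
) -> MMDataset:
    """Synthetic 2-fold dilution titration series.

    True velocities follow v = kcat.c/(Km+c) at concentrations
    top_conc/2^i; each is inverted to a fraction converted, noised
    multiplicatively, and re-derived through `VelocityPoint` so the
    over-conversion rule applies to the synthetic data too.
    """
    if n_dilutions < 3:
        raise ValidationError("n_dilutions must be at least 3")
    for name, v in [("kcat", kcat), ("Km", Km), ("scf_conc", scf_conc),
                    ("substrate_conc", substrate_conc),
                    ("top_conc", top_conc), ("time", time)]:
        if v <= 0:
            raise ValidationError(f"{name} must be positive")
    noise = noise or NoiseSpec()
    rng = noise.rng()
    conc = top_conc / 2.0 ** np.arange(n_dilutions)
    v_true = kcat * conc / (Km + conc)
    frac_true = v_true * scf_conc * time / substrate_conc
    if np.any(frac_true > 1):
        raise ValidationError(
            "parameters imply fraction_converted > 1; shorten the "
            "incubation time or raise the substrate concentration"
        )
    points = []
    for _ in range(noise.replicates):
        frac = frac_true.copy()
        if noise.multiplicative_cv > 0:
            frac = frac * rng.normal(1.0, noise.multiplicative_cv,
                                     size=frac.shape)
        frac = np.clip(frac, 0.0, 1.0)
        for c, f in zip(conc, frac):
            points.append(VelocityPoint(
                enzyme_conc=float(c), fraction_converted=float(f),
                substrate_conc=substrate_conc, scf_conc=scf_conc,
                incubation_time=time,
            ))
    return MMDataset(points, substrate=substrate)


def gen_srm(
    true_conc_nm: float, diameter_um: float = 12.0, n_cells: float = 1e6,
    spike_fmol: float = 10.0, noise: NoiseSpec | None = None,
    protein: str = "protein",
) -> list[SRMSample]:
    """Synthetic spike-in SRM samples for a known true concentration.

    Inverts the quantification arithmetic to the heavy:light ratio that
    would be observed, then applies multiplicative CV noise.
    """
    if true_conc_nm < 0:
        raise ValidationError("true_conc_nm must be non-negative")
    noise = noise or NoiseSpec()
    rng = noise.rng()
    vol = cell_volume_from_diameter(diameter_um)
    copies = true_conc_nm * 1e-9 * Avogadro * vol
    moles = copies * n_cells / Avogadro
    ratio_true = moles / (spike_fmol * 1e-15)
    samples = []
    for r in range(noise.replicates):
        ratio = ratio_true
        if noise.multiplicative_cv > 0:
            ratio = max(ratio * rng.normal(1.0, noise.multiplicative_cv), 0.0)
        samples.append(SRMSample(
            protein=protein, heavy_light_ratio=float(ratio),
            spike_amount=spike_fmol, n_cells=n_cells,
            mean_cell_diameter=diameter_um, replicate=f"rep{r + 1}",
        ))
    return samples


def gen_screen(
    n_genes: int, planted_hits: dict[str, float] | None = None,
    noise: NoiseSpec | None = None, n_controls: int = 2,
) -> tuple[GeneScoreTable, list[GeneScoreTable]]:
    """Synthetic screen score tables with planted fitness effects.

    Controls are Normal(0, sd) per gene; the experimental table adds the
    planted effects (negative = synthetic lethality).  Returns
    (experimental, controls).
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be at least 1")
    noise = noise or NoiseSpec(additive_sd=0.3)
    rng = noise.rng()
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    planted_hits = planted_hits or {}
    unknown = set(planted_hits) - set(genes)
    if unknown:
        raise ValidationError(f"planted genes not in table: {sorted(unknown)}")
    sd = noise.additive_sd
    controls = [
        GeneScoreTable(
            dict(zip(genes, rng.normal(0.0, sd, size=n_genes))),
            label=f"control_{i + 1}",
        )
        for i in range(n_controls)
    ]
    exp_scores = dict(zip(genes, rng.normal(0.0, sd, size=n_genes)))
    for g, effect in planted_hits.items():
        exp_scores[g] += effect
    experimental = GeneScoreTable(exp_scores, label="experimental")
    return experimental, controls
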