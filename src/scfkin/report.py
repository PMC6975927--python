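"""Catalytic-efficiency comparison reports.

Joins a table of pre-steady-state transfer rates (kobs, 1/s) with a
table of Michaelis constants (Km, nM) on enzyme/substrate labels,
computes efficiencies kobs/Km in M^-1 s^-1 and, for every pair of
enzymes sharing a substrate, their fold ratio.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd

from ._exceptions import ValidationError
from .michaelis import catalytic_efficiency, fold_ratio

__all__ = ["build_comparison_report"]


def build_comparison_report(
    rates: pd.DataFrame, mm: pd.DataFrame, sig_figs: int = 2
) -> dict[str, pd.DataFrame]:
    """Efficiency and pairwise fold-ratio tables.

    Parameters
    ----------
    rates
        Columns ``enzyme, substrate, kobs_per_s``.
    mm
        Columns ``enzyme, substrate, Km_nM``.

    Returns
    -------
    dict with ``"efficiency"`` (one row per joined enzyme/substrate) and
    ``"pairs"`` (fold ratios for enzyme pairs sharing a substrate; empty
    for single-enzyme input).
    """
    for df, cols, what in [
        (rates, ["enzyme", "substrate", "kobs_per_s"], "rates table"),
        (mm, ["enzyme", "substrate", "Km_nM"], "Km table"),
    ]:
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"{what}: missing column(s) {missing}")

    joined = rates.merge(mm, on=["enzyme", "substrate"], how="inner")
    if joined.empty:
        unmatched_r = set(map(tuple, rates[["enzyme", "substrate"]].values))
        unmatched_m = set(map(tuple, mm[["enzyme", "substrate"]].values))
        raise ValidationError(
            "no joinable rows; unmatched keys: "
            f"rates={sorted(unmatched_r)}, Km={sorted(unmatched_m)}"
        )
    recs = [
        catalytic_efficiency(row.kobs_per_s, row.Km_nM, sig_figs=sig_figs)
        for row in joined.itertuples()
    ]
    eff = joined.assign(
        efficiency_M_per_s=[r.efficiency for r in recs],
        efficiency_rounded=[r.rounded for r in recs],
    )

    pair_rows = []
    for substrate, sub in eff.groupby("substrate", sort=False):
        for a, b in combinations(sub.itertuples(), 2):
            hi, lo = (a, b) if a.efficiency_M_per_s >= b.efficiency_M_per_s \
                else (b, a)
            ratio, fold = fold_ratio(hi.efficiency_M_per_s,
                                     lo.efficiency_M_per_s)
            pair_rows.append({
                "substrate": substrate,
                "enzyme_hi": hi.enzyme, "enzyme_lo": lo.enzyme,
                "efficiency_hi": hi.efficiency_M_per_s,
                "efficiency_lo": lo.efficiency_M_per_s,
                "ratio": ratio, "fold": fold,
            })
    pairs = pd.DataFrame(
        pair_rows,
        columns=["substrate", "enzyme_hi", "enzyme_lo", "efficiency_hi",
                 "efficiency_lo", "ratio", "fold"],
    )
    return {"efficiency": eff, "pairs": pairs}
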