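"""System-level permeability prediction and validation statistics.

The membrane-system permeability per unit area, p_f, is proportional to the
product of the per-tetramer permeability and the areal protein density,
p_f = ρ_prot · p_u,tet.  Since p_u,tet scales like the inverse hydrophobic
mismatch 1/Δd_P−P,adj, the p_f *trend* across compositions can be ranked by

    pf_trend = ρ_prot / Δd_P−P,adj        (proteins / (cm² · Å))

without ever estimating an absolute permeability.  ρ_prot is the protein
count divided by the (time-averaged) lateral box area.  The link between
p_u,tet and 1/Δd is validated with a Pearson correlation and its two-sided
t-test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, SpecError

__all__ = [
    "SystemComposition",
    "protein_density",
    "pf_trend",
    "pearson_with_p",
    "relative_cost_comparison",
    "prediction_report",
]

_A2_TO_CM2 = 1e-16


@dataclass(frozen=True)
class SystemComposition:
    """One membrane system: protein/lipid counts and lateral box area (Å²)."""

    n_proteins: int
    n_lipids: int
    box_xy_area: float  # Å², time-averaged over analysed frames
    molar_ratio: str = ""

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_lipids <= 0:
            raise SpecError("protein and lipid counts must be positive")
        if self.box_xy_area <= 0:
            raise SpecError("lateral box area must be positive")


def protein_density(composition: SystemComposition) -> float:
    """Channel proteins per cm² of membrane."""
    return composition.n_proteins / (composition.box_xy_area * _A2_TO_CM2)


def pf_trend(rho_prot: float, delta_adj: float) -> float:
    """ρ_prot / Δd, the system-permeability ranking value.

    The proportionality is stated for compressive mismatch only, so Δd ≤ 0
    yields NaN (flagged, excluded from ranking) rather than a negative
    "permeability".
    """
    if delta_adj <= 0:
        return float("nan")
    return rho_prot / delta_adj


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value.

    p follows the exact t test: t = r·√(n−2)/√(1−r²) against Student's t
    with n−2 degrees of freedom, two-sided.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise SpecError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise InsufficientDataError("Pearson test needs at least three pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise SpecError("non-finite observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for the Pearson correlation (cross-check
    companion to :func:`pearson_with_p`, not a replacement)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    r_obs, _ = pearson_with_p(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r_perm = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-15:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def relative_cost_comparison(
    rho_a: float, p_a: float, rho_b: float, p_b: float
) -> tuple[float, float]:
    """How much more protein (%) and how much more permeability (%) system A
    needs/delivers relative to system B: 100·(rho_a/rho_b − 1),
    100·(p_a/p_b − 1)."""
    if rho_b == 0 or p_b == 0:
        raise SpecError("reference system values must be nonzero")
    return 100.0 * (rho_a / rho_b - 1.0), 100.0 * (p_a / p_b - 1.0)


def prediction_report(
    conditions: Sequence[dict],
    p_u_tet: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rank compositions by pf_trend and, when per-tetramer permeabilities are
    supplied, validate p_u,tet ∝ 1/Δd with a Pearson test.

    Each condition dict needs ``label``, ``delta_adj`` and either
    ``rho_prot`` or (``n_proteins``, ``box_xy_area``).  Returns the ranked
    table and a stats dict {r, p, n} (empty when no permeabilities given).
    """
    rows = []
    for cond in conditions:
        if "rho_prot" in cond:
            rho = float(cond["rho_prot"])
        else:
            rho = protein_density(
                SystemComposition(
                    n_proteins=int(cond["n_proteins"]),
                    n_lipids=int(cond.get("n_lipids", 1)),
                    box_xy_area=float(cond["box_xy_area"]),
                    molar_ratio=str(cond.get("label", "")),
                )
            )
        delta = float(cond["delta_adj"])
        rows.append(
            {
                "label": cond["label"],
                "rho_prot_per_cm2": rho,
                "delta_adj_A": delta,
                "inverse_delta_per_A": 1.0 / delta if delta > 0 else float("nan"),
                "pf_trend": pf_trend(rho, delta),
            }
        )
    table = pd.DataFrame(rows)
    table["rank"] = (
        table["pf_trend"].rank(ascending=False, na_option="bottom").astype(int)
    )
    table = table.sort_values("rank").reset_index(drop=True)
    stats_out: dict = {}
    if p_u_tet is not None:
        inv = [r["inverse_delta_per_A"] for r in rows]
        r, p = pearson_with_p(np.asarray(p_u_tet), np.asarray(inv))
        stats_out = {"r": r, "p": p, "n": len(rows)}
    return table, stats_out
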