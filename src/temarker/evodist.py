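"""Genetic distances and molecular-clock divergence dating.

The Tamura–Nei (TN93) distance distinguishes the two transition classes
(A<->G and C<->T) from transversions and allows unequal base frequencies;
with equal frequencies and proportional substitution classes it collapses
to the Jukes–Cantor correction. Divergence time follows the neutral clock
t = K / nu, with K the corrected distance in substitutions per site and nu
the neutral substitution rate per site per million generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SequenceSet

DAYS_PER_YEAR = 365.25

#: Neutral single-nucleotide rate, substitutions/site per million
#: generations (Drosophila melanogaster direct estimate).
DEFAULT_NU = 0.0058
#: 95% interval on nu, back-solved so the clock's uncertainty spans the
#: roughly 2-14 million-generation band a distance of 0.029 implies; a
#: reconstruction used for reporting, not a measured quantity.
DEFAULT_NU_CI = (0.0021, 0.0146)
DEFAULT_GENERATION_DAYS = 30.0


class SaturationError(ValueError):
    """Raised when divergence exceeds the model's invertible range."""


@dataclass(frozen=True)
class RateSpec:
    """Neutral-clock calibration: rate per million generations plus its CI."""

    nu: float = DEFAULT_NU
    nu_ci: tuple[float, float] = DEFAULT_NU_CI
    generation_days: float = DEFAULT_GENERATION_DAYS

    def __post_init__(self) -> None:
        low, high = self.nu_ci
        if not (0 < low <= self.nu <= high):
            raise ValueError(f"require 0 < nu_low <= nu <= nu_high, got {low}, {self.nu}, {high}")
        if self.generation_days <= 0:
            raise ValueError("generation_days must be positive")


@dataclass(frozen=True)
class DivergenceEstimate:
    """t = K/nu in millions of generations, and in Myr via the generation time."""

    K: float
    t_generations: float            # millions of generations
    t_generations_ci: tuple[float, float]
    t_years: float                  # Myr
    t_years_ci: tuple[float, float]


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _comparable(a_row: str, b_row: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a_row) != len(b_row):
        raise ValueError("rows differ in length")
    a = np.frombuffer(a_row.encode(), dtype="S1")
    b = np.frombuffer(b_row.encode(), dtype="S1")
    ok = np.isin(a, _BASES) & np.isin(b, _BASES)  # pairwise deletion: gaps and N out
    if not ok.any():
        raise ValueError("no comparable columns between rows")
    return a[ok], b[ok]


def pair_counts(a_row: str, b_row: str) -> tuple[float, float, float, np.ndarray, int]:
    """Observed proportions (P1: A<->G, P2: C<->T, Q: transversions),
    empirical base frequencies pooled over both rows, and the number of
    comparable sites."""
    a, b = _comparable(a_row, b_row)
    n = a.size
    ab = a + b
    p1 = int(np.isin(ab, [b"AG", b"GA"]).sum()) / n
    p2 = int(np.isin(ab, [b"CT", b"TC"]).sum()) / n
    q = int((a != b).sum()) / n - p1 - p2
    pooled = np.concatenate([a, b])
    freqs = np.array([(pooled == base).mean() for base in _BASES])
    return p1, p2, q, freqs, n


def p_distance(a_row: str, b_row: str) -> float:
    """Uncorrected proportion of differing comparable sites."""
    a, b = _comparable(a_row, b_row)
    return float((a != b).mean())


def tn93_distance(a_row: str, b_row: str) -> float:
    """Tamura–Nei (1993) maximum-likelihood distance between two gapped rows.

    Computed on comparable (gap-free, unambiguous) columns only, with base
    frequencies pooled from both sequences. Raises :class:`SaturationError`
    when any log argument is non-positive (distance undefined).
    """
    p1, p2, q, f, _ = pair_counts(a_row, b_row)
    ga, gc, gg, gt = f
    gr, gy = ga + gg, gc + gt
    if min(ga, gc, gg, gt) <= 0:
        # a base missing entirely: fall back to the F81-style terms that
        # remain defined is not meaningful here; treat as undefined
        raise SaturationError("distance undefined (a base is absent from both sequences)")
    k1 = 2 * ga * gg / gr
    k2 = 2 * gc * gt / gy
    k3 = 2 * (gr * gy - ga * gg * gy / gr - gc * gt * gr / gy)
    w1 = 1 - p1 / k1 - q / (2 * gr)
    w2 = 1 - p2 / k2 - q / (2 * gy)
    w3 = 1 - q / (2 * gr * gy)
    if min(w1, w2, w3) <= 0:
        raise SaturationError("distance undefined (saturated)")
    return float(-k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3))


def jc_distance(a_row: str, b_row: str) -> float:
    """Jukes–Cantor distance -(3/4) ln(1 - 4p/3) on comparable columns."""
    p = p_distance(a_row, b_row)
    w = 1 - 4 * p / 3
    if w <= 0:
        raise SaturationError("distance undefined (saturated)")
    return float(-0.75 * np.log(w))


_MODELS = {"tn93": tn93_distance, "jc": jc_distance}


def pairwise_distance_matrix(msa: SequenceSet, model: str = "tn93") -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of pairwise model distances."""
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_MODELS)}")
    if len(msa) < 2:
        raise ValueError("distance matrix needs at least 2 rows")
    dist = _MODELS[model]
    ids = msa.ids
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(msa.entries[i][1], msa.entries[j][1])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def divergence_time(K: float, rates: RateSpec = RateSpec(),
                    lineage_split: str = "none") -> DivergenceEstimate:
    """Date a divergence with the neutral clock t = K/nu.

    ``lineage_split='none'`` assigns all divergence to the descendant
    lineage (the ancestor is treated as the observed ancestral state);
    ``'half'`` splits K evenly between the two lineages.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    if lineage_split not in ("none", "half"):
        raise ValueError("lineage_split must be 'none' or 'half'")
    k_eff = K / 2 if lineage_split == "half" else K
    low, high = rates.nu_ci
    t_gen = k_eff / rates.nu
    t_gen_ci = (k_eff / high, k_eff / low)
    years_per_gen = rates.generation_days / DAYS_PER_YEAR
    return DivergenceEstimate(
        K=K,
        t_generations=t_gen,
        t_generations_ci=t_gen_ci,
        t_years=t_gen * years_per_gen,
        t_years_ci=(t_gen_ci[0] * years_per_gen, t_gen_ci[1] * years_per_gen),
    )


def divergence_table(msa: SequenceSet, reference_id: str,
                     rates: RateSpec = RateSpec(), model: str = "tn93",
                     lineage_split: str = "none") -> pd.DataFrame:
    """Per-strain distance to the ancestral reference and its clock dating.

    Times are reported in millions of generations and Myr, with the CI
    induced by the rate CI.
    """
    if reference_id not in msa.ids:
        raise ValueError(f"reference id {reference_id!r} not in alignment")
    ref_row = msa[reference_id]
    dist = _MODELS[model]
    rows = []
    for sid, row in msa.entries:
        if sid == reference_id:
            continue
        K = dist(ref_row, row)
        est = divergence_time(K, rates=rates, lineage_split=lineage_split)
        rows.append({
            "strain": sid,
            "K": K,
            "t_Mgen": est.t_generations,
            "t_Mgen_low": est.t_generations_ci[0],
            "t_Mgen_high": est.t_generations_ci[1],
            "t_Myr": est.t_years,
            "t_Myr_low": est.t_years_ci[0],
            "t_Myr_high": est.t_years_ci[1],
        })
    return pd.DataFrame(rows)
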