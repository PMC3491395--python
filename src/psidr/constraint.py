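"""Evolutionary constraint: preservation rates, the Poisson conservation
test with Benjamini-Hochberg selection, and derived-allele-frequency
spectra.

The conservation test models the substitution count of a pseudogene of
length L against an ortholog as Poisson with mean r*L, r the neutral
background substitution rate for that species pair (1.5% to chimp, 5% to
mouse).  The lower tail P(X <= k) is the probability of seeing this few
substitutions under neutrality; pseudogenes significant after BH at FDR
0.05 are flagged conserved.  Dividing by pseudogene length (not aligned
length) treats unaligned bases as unmutated — a conservative bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConservationResult",
    "preservation_rate",
    "poisson_conservation_p",
    "bh_select",
    "conservation_pipeline",
    "daf_spectra",
    "variant_density",
    "SPECIES_BACKGROUND_RATES",
]

SPECIES_BACKGROUND_RATES = {"chimp": 0.015, "mouse": 0.05}


@dataclass(frozen=True)
class ConservationResult:
    pseudogene_id: str
    species: str
    substitutions: int
    length: int
    p_value: float
    conserved: bool


def preservation_rate(divergence: pd.DataFrame, class_by_id: dict[str, str] | None = None) -> pd.DataFrame:
    """Percent of pseudogene sequence aligned per species (and per class).

    Returns a DataFrame (species, cls, preservation_pct) where
    preservation is 100 * sum(aligned_bp) / sum(length).
    """
    df = divergence.copy()
    df["cls"] = (
        df["pseudogene_id"].map(class_by_id).fillna("all") if class_by_id else "all"
    )
    grouped = df.groupby(["species", "cls"], as_index=False).agg(
        aligned_bp=("aligned_bp", "sum"), length=("length", "sum")
    )
    if (grouped["length"] == 0).any():
        raise ValueError("zero total length in a (species, class) cell")
    grouped["preservation_pct"] = 100.0 * grouped.aligned_bp / grouped.length
    return grouped[["species", "cls", "preservation_pct"]]


def poisson_conservation_p(k: int, length: int, rate: float) -> float:
    """Lower-tail Poisson probability P(X <= k) with X ~ Poisson(rate*length)."""
    if k < 0 or length <= 0 or rate < 0:
        raise ValueError("need k >= 0, length > 0, rate >= 0")
    lam = rate * length
    if lam == 0:
        return 1.0
    return float(stats.poisson.cdf(k, lam))


def bh_select(p_values, fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection.

    Select all hypotheses with rank <= k*, where k* is the largest k such
    that p_(k) <= fdr * k / n.  Returns a boolean array aligned with the
    input order; ties are handled by the step-up rule itself (all
    hypotheses with p <= the k*-th order statistic are selected).
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = fdr * np.arange(1, n + 1) / n
    passing = np.flatnonzero(sorted_p <= thresholds)
    selected = np.zeros(n, dtype=bool)
    if passing.size:
        selected[order[: passing[-1] + 1]] = True
    return selected


def conservation_pipeline(
    divergence: pd.DataFrame,
    rates: dict[str, float] | None = None,
    fdr: float = 0.05,
    combine: str = "union",
) -> tuple[list[ConservationResult], dict[str, bool]]:
    """Per-species Poisson test + within-species BH; combined flag per id.

    ``combine``: 'union' (conserved in either species), 'intersection',
    or a single species name.
    """
    rates = rates or SPECIES_BACKGROUND_RATES
    results: list[ConservationResult] = []
    flags_by_species: dict[str, dict[str, bool]] = {}
    for species, rate in rates.items():
        sub = divergence[divergence.species == species]
        if sub.empty:
            continue
        ids = sub.pseudogene_id.to_numpy()
        p = np.array(
            [
                poisson_conservation_p(int(k), int(L), rate)
                for k, L in zip(sub.substitutions, sub.length)
            ]
        )
        sel = bh_select(p, fdr=fdr)
        flags_by_species[species] = dict(zip(ids, sel))
        for pid, k, L, pv, s in zip(ids, sub.substitutions, sub.length, p, sel):
            results.append(
                ConservationResult(str(pid), species, int(k), int(L), float(pv), bool(s))
            )
    all_ids = sorted({r.pseudogene_id for r in results})
    combined: dict[str, bool] = {}
    for pid in all_ids:
        per_sp = [flags.get(pid) for flags in flags_by_species.values() if pid in flags]
        if combine == "union":
            combined[pid] = any(per_sp)
        elif combine == "intersection":
            combined[pid] = bool(per_sp) and all(per_sp)
        elif combine in flags_by_species:
            combined[pid] = flags_by_species[combine].get(pid, False)
        else:
            raise ValueError(f"unknown combine rule {combine!r}")
    return results, combined


def daf_spectra(
    daf_by_class: dict[str, np.ndarray], bins: int = 10
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], float]]:
    """DAF histograms per variant class and pairwise two-sample KS p-values.

    ``daf_by_class`` maps class label (e.g. 'SNP/transcribed') to an array
    of derived allele frequencies in [0, 1].  Histograms use ``bins``
    uniform bins on [0, 1] and sum to the class variant count.  Empty
    classes are skipped in the comparisons.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    spectra = {}
    for label, daf in daf_by_class.items():
        daf = np.asarray(daf, dtype=float)
        if daf.size and ((daf < 0) | (daf > 1)).any():
            raise ValueError(f"DAFs outside [0,1] in class {label}")
        spectra[label] = np.histogram(daf, bins=edges)[0]
    comparisons: dict[tuple[str, str], float] = {}
    labels = sorted(daf_by_class)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            xa, xb = np.asarray(daf_by_class[a]), np.asarray(daf_by_class[b])
            if xa.size == 0 or xb.size == 0:
                continue
            comparisons[(a, b)] = float(stats.ks_2samp(xa, xb).pvalue)
    return spectra, comparisons


def variant_density(n_variants_by_class: dict[str, int], bp_by_class: dict[str, int]) -> dict[str, float]:
    """Variants per kb of sequence per class."""
    out = {}
    for label, n in n_variants_by_class.items():
        bp = bp_by_class.get(label, 0)
        if bp <= 0:
            raise ValueError(f"zero sequence length for class {label}")
        out[label] = 1000.0 * n / bp
    return out
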