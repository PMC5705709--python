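"""Scalar calculators: morphometry ratios, qPCR delta-delta-Ct relative
expression, protein/DNA ratio, and densitometry normalization."""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .datatypes import MorphometryRecord


def relative_cell_count(
    test: MorphometryRecord, reference: MorphometryRecord
) -> dict:
    """Relative cell count of a test group vs. reference, in percent.

    Cell content is estimated as (cells per field of view) x thickness;
    the result is ``100 * test / reference``.  Both the unrounded value and
    the nearest-percent report value are returned.
    """
    value = 100.0 * (test.cells_per_fov * test.thickness_um) / (
        reference.cells_per_fov * reference.thickness_um
    )
    return {"percent": value, "percent_rounded": int(round(value))}


def percent_difference(test_mean: float, ref_mean: float) -> dict:
    """Percent reduction of a test mean relative to a reference mean."""
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    value = 100.0 * (1.0 - test_mean / ref_mean)
    return {"percent": value, "percent_rounded": int(round(value))}


def pooled_percent(counts: Sequence[tuple]) -> dict:
    """Pool (successes, attempts) pairs and convert to percent."""
    succ = sum(c[0] for c in counts)
    tot = sum(c[1] for c in counts)
    if tot <= 0:
        raise ValueError("total attempts must be positive")
    value = 100.0 * succ / tot
    return {
        "percent": value,
        "percent_rounded": int(round(value)),
        "pooled": (succ, tot),
    }


# ---------------------------------------------------------------------------
# qPCR


def _mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Average Ct replicates -> one row per (sample, gene)."""
    required = {"sample", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not np.all(np.isfinite(table["ct"])):
        raise ValueError("Ct values must be finite")
    return table.groupby(["sample", "gene"], as_index=False)["ct"].mean()


def ddct(
    table: pd.DataFrame,
    target_gene: str,
    sample: str,
    reference_sample: str,
    housekeeping_gene: str = "GAPDH",
) -> float:
    """Relative expression by the delta-delta-Ct method.

    Replicate Cts are averaged first; then per sample
    ``dCt = Ct_target - Ct_housekeeping``, ``ddCt = dCt_sample - dCt_ref``,
    and expression is ``2 ** -ddCt``.  The reference sample maps to 1.0 by
    construction.
    """
    means = _mean_ct(table).set_index(["sample", "gene"])["ct"]

    def get(s: str, g: str) -> float:
        try:
            return float(means.loc[(s, g)])
        except KeyError:
            raise ValueError(f"missing Ct for sample {s!r}, gene {g!r}") from None

    dct_sample = get(sample, target_gene) - get(sample, housekeeping_gene)
    dct_ref = get(reference_sample, target_gene) - get(reference_sample, housekeeping_gene)
    return float(2.0 ** -(dct_sample - dct_ref))


def ddct_table(
    table: pd.DataFrame,
    reference_sample: str,
    housekeeping_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Relative expression of every (sample, gene) pair vs. the reference
    sample; long-format output with an ``expression`` column."""
    means = _mean_ct(table)
    genes = [g for g in means["gene"].unique() if g != housekeeping_gene]
    samples = means["sample"].unique()
    rows = []
    for g in genes:
        for s in samples:
            rows.append(
                {
                    "sample": s,
                    "gene": g,
                    "expression": ddct(
                        table, g, s, reference_sample, housekeeping_gene
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protein


def protein_dna_ratio(protein_ug: float, dna_ug: float) -> float:
    """Total protein / total DNA."""
    if dna_ug <= 0:
        raise ValueError("DNA amount must be positive")
    return protein_ug / dna_ug


def densitometry_normalize(
    bands: Dict[str, Sequence[float]],
    controls: Dict[str, Sequence[float]],
    reference_group: str,
) -> Dict[str, np.ndarray]:
    """Western-blot band levels normalized lane-wise to a loading control and
    reported relative to the reference group's mean (reference mean -> 1.0).
    """
    if reference_group not in bands:
        raise ValueError(f"reference group {reference_group!r} not present")
    levels = {}
    for group in bands:
        b = np.asarray(bands[group], dtype=float)
        c = np.asarray(controls[group], dtype=float)
        if b.shape != c.shape:
            raise ValueError(f"group {group!r}: band/control lane count mismatch")
        if np.any(c <= 0):
            raise ValueError(f"group {group!r}: zero or negative control intensity")
        if np.any(b < 0):
            raise ValueError(f"group {group!r}: negative band intensity")
        levels[group] = b / c
    ref_mean = levels[reference_group].mean()
    if ref_mean <= 0:
        raise ValueError("reference group mean level must be positive")
    return {g: v / ref_mean for g, v in levels.items()}
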