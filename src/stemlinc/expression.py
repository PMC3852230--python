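"""Expression profiles and embryonic-stem-cell lincRNA calling.

From a gene × sample FPKM matrix with a sample→group map, one
representative value per condition is built (the per-group median; the ES
group is over-represented in sample count, so the median is the robust
summary). Genes are then called:

* expressed — FPKM >= 1 in at least one condition (inclusive),
* ES-expressed — ES median FPKM strictly > 1,
* ES-biased — ES-expressed with tissue-specificity index tau > 0.9 and the
  maximum of the profile in the ES condition.

The tau index is Σ(1 − v_i/v_max)/(N−1) over the N condition values:
0 for a flat profile, 1 for single-condition expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError

HES_LABEL = "hES"


@dataclass
class CallThresholds:
    """Calling thresholds.

    ``expressed_min`` is inclusive (FPKM >= 1 anywhere), ``hes_min`` is
    exclusive (ES median strictly > 1) — the two printed criteria differ
    deliberately; both are exposed here. ``tau_biased`` is the exclusive
    tau cutoff for biased expression.
    """

    expressed_min: float = 1.0
    hes_min: float = 1.0
    tau_biased: float = 0.9

    def __post_init__(self):
        if min(self.expressed_min, self.hes_min, self.tau_biased) < 0:
            raise DataError("thresholds must be >= 0")
        if not 0 <= self.tau_biased <= 1:
            raise DataError("tau_biased must be in [0, 1]")


class ExpressionMatrix:
    """FPKM values per (gene, sample) with a sample→group map."""

    def __init__(self, values: pd.DataFrame, groups: Mapping[str, str]):
        if values.index.duplicated().any():
            raise DataError("duplicate gene ids in expression matrix")
        if values.columns.duplicated().any():
            raise DataError("duplicate sample ids in expression matrix")
        if (values.values < 0).any():
            raise DataError("negative FPKM values")
        missing = [s for s in values.columns if s not in groups]
        if missing:
            raise DataError(f"samples without a group: {missing}")
        self.values = values.astype(float)
        self.groups = {s: groups[s] for s in values.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, fpkm_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        """Load from a genes × samples TSV and a two-column sample→group TSV."""
        values = pd.read_csv(fpkm_path, sep="\t", index_col=0)
        gdf = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"])
        return cls(values, dict(zip(gdf["sample"].astype(str), gdf["group"])))


@dataclass
class ExpressionProfile:
    """Representative FPKM per condition for one gene."""

    gene_id: str
    conditions: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.conditions):
            raise DataError(f"profile {self.gene_id}: values/conditions mismatch")
        if (self.values < 0).any():
            raise DataError(f"profile {self.gene_id}: negative values")


def representative_profile(
    m: ExpressionMatrix, collapse: str = "median", hes_label: str = HES_LABEL
) -> pd.DataFrame:
    """Per-condition representative values (genes × conditions).

    Each group's samples collapse to their median (even counts average the
    central pair). The condition order is fixed: the ES group first, then
    the tissues alphabetically.
    """
    if collapse != "median":
        raise DataError(f"unknown collapse method {collapse!r}")
    by_group: dict[str, list[str]] = {}
    for sample, group in m.groups.items():
        by_group.setdefault(group, []).append(sample)
    for group, samples in by_group.items():
        if not samples:
            raise DataError(f"group {group} has no samples")
    tissues = sorted(g for g in by_group if g != hes_label)
    order = ([hes_label] if hes_label in by_group else []) + tissues
    cols = {g: m.values[by_group[g]].median(axis=1) for g in order}
    return pd.DataFrame(cols, index=m.values.index)[order]


def profile_of(table: pd.DataFrame, gene_id: str) -> ExpressionProfile:
    """Extract one gene's profile from a representative-value table."""
    if gene_id not in table.index:
        raise DataError(f"gene {gene_id} not in expression table")
    row = table.loc[gene_id]
    return ExpressionProfile(gene_id, tuple(table.columns), row.to_numpy())


def tau(p: ExpressionProfile | np.ndarray, log2: bool = False) -> float:
    """Tissue-specificity index in [0, 1].

    tau = Σ_i (1 − v_i / v_max) / (N − 1). With ``log2=True`` values are
    transformed to log2(v + 1) first.
    """
    values = p.values if isinstance(p, ExpressionProfile) else np.asarray(p, float)
    if len(values) < 2:
        raise DataError("tau needs at least 2 conditions")
    if log2:
        values = np.log2(values + 1.0)
    vmax = values.max()
    if vmax <= 0:
        raise DataError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - values / vmax) / (len(values) - 1))


def call_expressed(p: ExpressionProfile, th: CallThresholds | None = None) -> bool:
    """True iff any condition reaches the (inclusive) expression floor."""
    th = th or CallThresholds()
    return bool((p.values >= th.expressed_min).any())


def _hes_index(p: ExpressionProfile, hes_label: str) -> int:
    try:
        return p.conditions.index(hes_label)
    except ValueError:
        raise DataError(f"profile {p.gene_id} has no {hes_label} condition") from None


def call_hes(
    p: ExpressionProfile, th: CallThresholds | None = None, hes_label: str = HES_LABEL
) -> bool:
    """True iff the ES representative value strictly exceeds ``hes_min``."""
    th = th or CallThresholds()
    return bool(p.values[_hes_index(p, hes_label)] > th.hes_min)


def call_hes_biased(
    p: ExpressionProfile, th: CallThresholds | None = None, hes_label: str = HES_LABEL
) -> bool:
    """ES-biased: ES-expressed, tau above threshold, and maximum in ES.

    tau alone is direction-blind, so the profile's argmax is additionally
    required to be the ES condition.
    """
    th = th or CallThresholds()
    if not call_hes(p, th, hes_label):
        return False
    if not tau(p) > th.tau_biased:
        return False
    return int(np.argmax(p.values)) == _hes_index(p, hes_label)


def call_table(
    profiles: pd.DataFrame,
    th: CallThresholds | None = None,
    hes_label: str = HES_LABEL,
) -> pd.DataFrame:
    """Per-gene call table over a representative-value table.

    Columns: hES_fpkm, expressed, hes, tau, biased. Genes whose profile is
    all-zero get tau = NaN and are never called.
    """
    th = th or CallThresholds()
    rows = []
    for gene_id in profiles.index:
        p = profile_of(profiles, gene_id)
        all_zero = p.values.max() <= 0
        t = np.nan if all_zero else tau(p)
        rows.append(
            {
                "gene_id": gene_id,
                "hES_fpkm": p.values[_hes_index(p, hes_label)],
                "expressed": call_expressed(p, th),
                "hes": call_hes(p, th, hes_label),
                "tau": t,
                "biased": False if all_zero else call_hes_biased(p, th, hes_label),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
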