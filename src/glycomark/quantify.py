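"""Feature-table assembly: normalization, charge-state averaging, imputation.

The statistical substrate of the biomarker analysis is a samples ×
glycated-site table of XIC peak areas with binary group labels (T2DM cases
vs normoglycemic controls).  Peak areas are first normalized to the protein
amount taken for digestion (per-sample plasma protein concentration relative
to a cohort reference), and the areas of a peptide's multiple charge states
— which are highly correlated — are averaged into a single abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CASE_LABEL",
    "CONTROL_LABEL",
    "normalize_by_protein",
    "average_charge_states",
    "impute_missing",
]

CASE_LABEL = "T2DM"
CONTROL_LABEL = "CONTROL"


@dataclass
class FeatureTable:
    """Samples × glycated-peptide abundances with group labels.

    ``abundances`` is a DataFrame indexed by sample id with one column per
    feature (e.g. ``HSA_K525``); ``groups`` is a parallel Series of
    ``T2DM``/``CONTROL`` labels; ``protein_conc`` optionally holds per-sample
    plasma protein concentrations (mg/mL) for normalization.
    """

    abundances: pd.DataFrame
    groups: pd.Series
    protein_conc: pd.Series | None = None

    def __post_init__(self) -> None:
        self.abundances = self.abundances.astype(float)
        self.groups = self.groups.reindex(self.abundances.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.groups.unique()) - {CASE_LABEL, CONTROL_LABEL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.protein_conc is not None:
            self.protein_conc = self.protein_conc.reindex(self.abundances.index)
            if self.protein_conc.isna().any() or (self.protein_conc <= 0).any():
                raise ValueError("protein concentrations must be positive")

    @property
    def case_mask(self) -> np.ndarray:
        return (self.groups == CASE_LABEL).to_numpy()

    def split(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        """Case and control value vectors for one feature."""
        col = self.abundances[feature].to_numpy()
        mask = self.case_mask
        return col[mask], col[~mask]

    # -- CSV round-trip: sample_id, group[, protein_conc], features... -----
    def to_csv(self, path) -> None:
        df = self.abundances.copy()
        df.insert(0, "group", self.groups)
        if self.protein_conc is not None:
            df.insert(1, "protein_conc", self.protein_conc)
        df.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        df.index.name = None
        groups = df.pop("group")
        conc = df.pop("protein_conc") if "protein_conc" in df.columns else None
        return cls(df, groups, conc)


def normalize_by_protein(
    areas: pd.DataFrame,
    conc: pd.Series,
    reference: float | None = None,
) -> pd.DataFrame:
    """Scale each sample's areas by ``reference / concentration``.

    Samples digested from more concentrated plasma contribute proportionally
    more peptide, so their areas are scaled down.  The reference defaults to
    the cohort median concentration, which makes the normalization invariant
    to a common rescaling of all concentrations.
    """
    conc = conc.reindex(areas.index)
    if conc.isna().any() or (conc <= 0).any():
        raise ValueError("every sample needs a positive protein concentration")
    if reference is None:
        reference = float(conc.median())
    return areas.mul(reference / conc, axis=0)


def average_charge_states(
    areas: pd.DataFrame, feature_of_column: dict[str, str]
) -> pd.DataFrame:
    """Collapse per-charge-state area columns into one abundance per peptide.

    ``feature_of_column`` maps each input column (one ion, e.g.
    ``HSA_K525_z2``) to its peptide feature id.  Charge states of the same
    peptide are strongly correlated, so their areas are arithmetically
    averaged; undetected states (NaN) are excluded from the mean, and a
    peptide with no detected state stays NaN (flagged missing).
    """
    missing = set(areas.columns) - set(feature_of_column)
    if missing:
        raise ValueError(f"columns without feature mapping: {sorted(missing)}")
    return areas.T.groupby(pd.Series(feature_of_column)).mean().T


def impute_missing(areas: pd.DataFrame) -> pd.DataFrame:
    """Replace missing abundances by half the feature's minimum detected value.

    A feature that was never detected in any sample cannot be imputed and is
    rejected.
    """
    out = areas.copy()
    for col in out.columns:
        vals = out[col]
        if vals.isna().all():
            raise ValueError(f"feature {col!r} has no detected values to impute from")
        out[col] = vals.fillna(vals.min() / 2.0)
    return out
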